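"""Scanning of protein/CDS sequences for NXS/T sites and near-sites.

A *site* is the tripeptide Asn-X-Ser/Thr with X ≠ Pro.  A *near-site* is a
codon-triple window exactly one nucleotide substitution away from encoding
a site: ``X_N.X.S/T`` (first codon one step from Asn), ``N.X.X_S/T``
(third codon one step from the Ser/Thr block), or ``N.P.S/T`` (the
Pro-blocked class).  Near-site classification is done at the codon level —
the sets of codons actually reachable by one substitution — not at the
amino-acid level.

Coordinates are 1-based residue positions; densities are per 100 amino
acids with the full protein length (initial Met included) as denominator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import (
    ASN_BLOCK,
    NUCLEOTIDES,
    SER_THR_BLOCK,
    CodonTable,
    InputError,
    MutationGraph,
)

logger = logging.getLogger(__name__)

NEAR_SITE_CLASSES = ("X_N.X.S/T", "N.X.X_S/T", "N.P.S/T")

_TABLE = CodonTable.standard()
_GRAPH = MutationGraph(table=_TABLE, stop_policy="exclude")
_ASN_NEAR = _GRAPH.neighbor_set(ASN_BLOCK)
_ST_NEAR = _GRAPH.neighbor_set(SER_THR_BLOCK)
_PRO = _TABLE.codons_for("P")

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SequenceRecord:
    """A protein with optional CDS and a compartment label."""

    id: str
    protein: str
    cds: Optional[str] = None
    compartment: str = "unlabeled"

    def __post_init__(self) -> None:
        object.__setattr__(self, "protein", self.protein.upper())
        if self.cds is not None:
            cds = self.cds.upper()
            object.__setattr__(self, "cds", cds)
            translated = _TABLE.translate(cds)
            if "*" in translated:
                raise InputError(f"{self.id}: internal stop codon in CDS")
            if translated != self.protein:
                raise InputError(f"{self.id}: CDS does not translate to protein")

    @classmethod
    def from_cds(cls, id: str, cds: str, compartment: str = "unlabeled"
                 ) -> "SequenceRecord":
        return cls(id=id, protein=_TABLE.translate(cds.upper()), cds=cds,
                   compartment=compartment)

    @property
    def length_aa(self) -> int:
        return len(self.protein)

    @property
    def a_content(self) -> Optional[float]:
        if self.cds is None:
            return None
        return self.cds.count("A") / len(self.cds)


def find_sites(protein: str,
               middle_excluded: Iterable[str] = ("P",)) -> List[int]:
    """1-based positions i where residue i = N, i+1 ∉ excluded, i+2 ∈ {S,T}.

    Overlapping sites are each reported; windows truncated by the sequence
    end are not sites.  Raises on letters outside the 20-aa alphabet (the
    caller decides whether to skip the record).
    """
    protein = protein.upper()
    bad = set(protein) - _AA20
    if bad:
        raise InputError(f"non-standard amino acids {sorted(bad)}")
    excluded = set(middle_excluded)
    return [
        i + 1
        for i in range(len(protein) - 2)
        if protein[i] == "N"
        and protein[i + 1] not in excluded
        and protein[i + 2] in "ST"
    ]


def find_near_sites(cds: str) -> List[Tuple[int, str]]:
    """Classified near-site windows of a CDS, as (1-based residue pos, class).

    True sites are excluded; the three classes are mutually exclusive.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise InputError("CDS length not divisible by 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    for c in codons:
        if c in _TABLE.stops:
            raise InputError("internal stop codon in CDS")
    out: List[Tuple[int, str]] = []
    for w in range(len(codons) - 2):
        c1, c2, c3 = codons[w], codons[w + 1], codons[w + 2]
        if c1 in ASN_BLOCK:
            if c2 in _PRO:
                if c3 in SER_THR_BLOCK:
                    out.append((w + 1, "N.P.S/T"))
            elif c3 in SER_THR_BLOCK:
                continue  # a true site, not a near-site
            elif c3 in _ST_NEAR:
                out.append((w + 1, "N.X.X_S/T"))
        elif c1 in _ASN_NEAR and c2 not in _PRO and c3 in SER_THR_BLOCK:
            out.append((w + 1, "X_N.X.S/T"))
    return out


@dataclass(frozen=True)
class SiteReport:
    """Per-sequence census of sites and classified near-sites."""

    id: str
    compartment: str
    length_aa: int
    site_positions: Tuple[int, ...]
    near_sites: Tuple[Tuple[int, str], ...]
    asn_total: int
    a_content: Optional[float]

    @property
    def site_density(self) -> float:
        return 100.0 * len(self.site_positions) / self.length_aa

    def near_site_density(self, cls: str) -> float:
        if cls not in NEAR_SITE_CLASSES:
            raise InputError(f"unknown near-site class {cls!r}")
        n = sum(1 for _, c in self.near_sites if c == cls)
        return 100.0 * n / self.length_aa

    @property
    def asn_fraction_in_sites(self) -> float:
        if self.asn_total == 0:
            return 0.0
        return len(self.site_positions) / self.asn_total


def scan_record(record: SequenceRecord) -> SiteReport:
    """Site and near-site census of one record (near-sites need a CDS)."""
    sites = tuple(find_sites(record.protein))
    near = tuple(find_near_sites(record.cds)) if record.cds else ()
    return SiteReport(
        id=record.id,
        compartment=record.compartment,
        length_aa=record.length_aa,
        site_positions=sites,
        near_sites=near,
        asn_total=record.protein.count("N"),
        a_content=record.a_content,
    )


def scan_records(records: Iterable[SequenceRecord]) -> List[SiteReport]:
    """Scan many records, skipping (with a warning) non-standard sequences."""
    out = []
    skipped = 0
    for rec in records:
        try:
            out.append(scan_record(rec))
        except InputError as exc:
            skipped += 1
            logger.warning("skipping record %s: %s", rec.id, exc)
    if skipped:
        logger.warning("%d record(s) skipped", skipped)
    return out


# ---------------------------------------------------------------------------
# Expected densities


def expected_density_from_aa(aa_composition: Mapping[str, float]) -> float:
    """Expected sites per 100 aa from amino-acid composition.

    Windows are treated as independent: 100 × f_N × (1 − f_P) × (f_S + f_T).
    """
    f = {a: aa_composition.get(a, 0.0) for a in "NPST"}
    total = sum(aa_composition.values())
    if total > 0 and not math.isclose(total, 1.0, abs_tol=1e-6):
        f = {a: v / total for a, v in f.items()}
    return 100.0 * f["N"] * (1.0 - f["P"]) * (f["S"] + f["T"])


def expected_density_from_nt(
    nt_composition: Mapping[str, float],
    codon_usage: Optional[Mapping[str, float]] = None,
) -> float:
    """Expected sites per 100 aa from nucleotide composition.

    Codon probabilities are formed from independent nucleotide draws,
    re-weighted by the supplied codon-usage prior (uniform by default) and
    renormalized over sense codons; the motif probability is then the
    product over the three window positions.
    """
    comp = {n: float(nt_composition.get(n, 0.0)) for n in NUCLEOTIDES}
    total = sum(comp.values())
    if total <= 0:
        raise InputError("nucleotide composition must have positive total")
    comp = {n: v / total for n, v in comp.items()}

    sense = _TABLE.sense_codons
    prior = {c: 1.0 for c in sense}
    if codon_usage is not None:
        prior = {c: float(codon_usage.get(c, 0.0)) for c in sense}
    p = np.array([
        prior[c] * comp[c[0]] * comp[c[1]] * comp[c[2]] for c in sense
    ])
    if p.sum() == 0:
        return 0.0
    p = p / p.sum()
    probs = dict(zip(sense, p))
    p_asn = sum(probs[c] for c in ASN_BLOCK.codons)
    p_pro = sum(probs[c] for c in _PRO)
    p_st = sum(probs[c] for c in SER_THR_BLOCK.codons)
    return 100.0 * p_asn * (1.0 - p_pro) * p_st


# ---------------------------------------------------------------------------
# Spacing and group summaries


def spacing_histogram(site_positions: Sequence[int], length: int,
                      first_bin: int = 20, width: int = 10) -> pd.Series:
    """Nearest-neighbor spacing of sites, binned ``[1, 20)`` then width 10.

    Each site contributes the distance to its nearest neighboring site;
    fractions (normalized to 1) are returned.  Fewer than two sites yields
    an empty histogram.
    """
    pos = sorted(site_positions)
    if len(pos) < 2:
        return pd.Series(dtype=float)
    dists = []
    for i, p in enumerate(pos):
        cand = []
        if i > 0:
            cand.append(p - pos[i - 1])
        if i < len(pos) - 1:
            cand.append(pos[i + 1] - p)
        dists.append(min(cand))
    top = max(dists)
    edges = [1, first_bin]
    while edges[-1] <= top:
        edges.append(edges[-1] + width)
    labels = [f"<{first_bin}"] + [
        f"[{edges[i]},{edges[i+1]})" for i in range(1, len(edges) - 1)
    ]
    counts = pd.Series(0.0, index=labels)
    for d in dists:
        idx = 0 if d < first_bin else 1 + (d - first_bin) // width
        counts.iloc[idx] += 1
    return counts / counts.sum()


@dataclass(frozen=True)
class GroupComparison:
    """Site-number-stratified compartment comparison."""

    summary: pd.DataFrame
    paired_tests: Dict[str, Tuple[float, float]]  # metric -> (t, p)


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else float("nan")


def group_by_site_number(reports: Iterable[SiteReport], cap: int = 15
                         ) -> GroupComparison:
    """Per-site-number-bin compartment means ± SE of near-site densities etc.

    Proteins with more than ``cap`` sites are excluded.  For every metric a
    paired t-test (secretory − cytosolic across bins present in both
    compartments) is reported; bins with fewer than 2 sequences are
    excluded from SE (and from pairing).
    """
    rows = []
    for rep in reports:
        n_sites = len(rep.site_positions)
        if n_sites > cap:
            continue
        row = {
            "id": rep.id,
            "compartment": rep.compartment,
            "site_number": n_sites,
            "site_density": rep.site_density,
            "a_content": rep.a_content,
            "asn_fraction_in_sites": rep.asn_fraction_in_sites,
        }
        for cls in NEAR_SITE_CLASSES:
            row[f"density[{cls}]"] = rep.near_site_density(cls)
        rows.append(row)
    if not rows:
        raise InputError("no records within the site-number cap")
    df = pd.DataFrame(rows)
    metrics = [c for c in df.columns
               if c not in ("id", "compartment", "site_number")]

    summary_rows = []
    for (comp, nbin), grp in df.groupby(["compartment", "site_number"]):
        row = {"compartment": comp, "site_number": nbin, "n": len(grp)}
        for m in metrics:
            vals = grp[m].dropna().to_numpy(dtype=float)
            row[f"{m}_mean"] = float(np.mean(vals)) if len(vals) else float("nan")
            row[f"{m}_se"] = _sem(vals) if len(vals) else float("nan")
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows).sort_values(
        ["compartment", "site_number"]).reset_index(drop=True)

    tests: Dict[str, Tuple[float, float]] = {}
    sec = summary[(summary["compartment"] == "secretory") & (summary["n"] >= 2)]
    cyt = summary[(summary["compartment"] == "cytosolic") & (summary["n"] >= 2)]
    shared = sorted(set(sec["site_number"]) & set(cyt["site_number"]))
    if len(shared) >= 2:
        s = sec.set_index("site_number").loc[shared]
        c = cyt.set_index("site_number").loc[shared]
        for m in metrics:
            a = s[f"{m}_mean"].to_numpy(dtype=float)
            b = c[f"{m}_mean"].to_numpy(dtype=float)
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() >= 2 and not np.allclose(a[ok], b[ok]):
                t, p = stats.ttest_rel(a[ok], b[ok])
                tests[m] = (float(t), float(p))
            elif ok.sum() >= 2:
                tests[m] = (0.0, 1.0)
    return GroupComparison(summary=summary, paired_tests=tests)
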