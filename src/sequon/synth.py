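"""Synthetic coding-sequence panels with controlled sequon statistics.

The generators emulate the shape of a proteome extract split into
secretory-like and cytosolic-like sets: stop-free CDS drawn from a target
nucleotide composition (with per-gene compositional dispersion), planted
NXS/T site densities (0.6 vs 0.4 per 100 aa by default), optional planted
near-site densities, homolog pairs whose divergence depends on site
number, SNP-like variant tables, and acetyl-Lys-style PTM tables.  All
generators are deterministic per seed.

Planting works by census adjustment: the sequence is drawn from the codon
usage, scanned, and sites (or near-sites) are planted at random
non-overlapping windows or knocked out until the census matches a
Poisson-drawn target count, re-scanning after every edit so that edits
that disturb neighboring windows are repaired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genetic_code import (
    ASN_BLOCK,
    NUCLEOTIDES,
    SER_THR_BLOCK,
    CodonTable,
    InputError,
    MutationGraph,
    codon_neighbors,
)
from .rates import HomologPair
from .scan import SequenceRecord, find_near_sites, find_sites
from .simulate import SimParams, evolve

_TABLE = CodonTable.standard()
_GRAPH = MutationGraph(table=_TABLE, stop_policy="exclude")
_ASN_NEAR = sorted(_GRAPH.neighbor_set(ASN_BLOCK))
_ST_NEAR = sorted(_GRAPH.neighbor_set(SER_THR_BLOCK))
_PRO = _TABLE.codons_for("P")
_SENSE = _TABLE.sense_codons

# per-codon proposal bookkeeping for branch-length calibration
_NONSTOP = {c: [n for n in codon_neighbors(c) if n not in _TABLE.stops]
            for c in _SENSE}
_NONSYN_NONSTOP = {
    c: sum(1 for n in _NONSTOP[c] if _TABLE.codon_to_aa[n] != _TABLE.codon_to_aa[c])
    for c in _SENSE
}


def usage_from_composition(composition: Mapping[str, float]) -> Dict[str, float]:
    """Codon usage implied by independent nucleotide draws, stops removed."""
    comp = {n: float(composition.get(n, 0.0)) for n in NUCLEOTIDES}
    total = sum(comp.values())
    if total <= 0:
        raise InputError("composition must have positive total")
    comp = {n: v / total for n, v in comp.items()}
    usage = {c: comp[c[0]] * comp[c[1]] * comp[c[2]] for c in _SENSE}
    z = sum(usage.values())
    if z == 0:
        raise InputError("composition admits no sense codons")
    return {c: v / z for c, v in usage.items()}


@dataclass(frozen=True)
class GeneratorConfig:
    """Controls one synthetic CDS panel.

    ``site_density`` and the per-class ``near_site_density`` values are in
    sites per 100 amino acids; ``None`` leaves the census at whatever the
    codon usage naturally produces.  ``composition_dispersion`` is the
    inverse Dirichlet concentration of the per-gene nucleotide
    composition around the panel target (0 = every gene identical).
    """

    n_sequences: int
    seed: int
    compartment: str = "unlabeled"
    mean_length_aa: float = 400.0
    length_sigma: float = 0.35
    min_length_aa: int = 100
    max_length_aa: int = 5000
    composition: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.26, "C": 0.25, "G": 0.26, "T": 0.23})
    codon_usage: Optional[Mapping[str, float]] = None
    composition_dispersion: float = 0.002
    at_gc_sd: float = 0.0
    site_density: Optional[float] = None
    exact_site_count: Optional[int] = None
    near_site_density: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise InputError("n_sequences must be >= 1")
        if self.site_density is not None and self.site_density < 0:
            raise InputError("site_density must be >= 0")
        if self.site_density:
            # a site occupies 3 residues; the density must be achievable
            if self.site_density / 100.0 * 3 > 1.0:
                raise InputError("site density not achievable: sites overlap")
        if self.near_site_density:
            bad = set(self.near_site_density) - {"X_N.X.S/T", "N.X.X_S/T"}
            if bad:
                raise InputError(f"unsupported near-site classes {sorted(bad)}")


def secretory_config(n_sequences: int, seed: int, **overrides) -> GeneratorConfig:
    """Secretory-like preset: slightly A-rich, 0.6 sites/100 aa."""
    base = GeneratorConfig(
        n_sequences=n_sequences, seed=seed, compartment="secretory",
        composition={"A": 0.27, "C": 0.24, "G": 0.26, "T": 0.23},
        site_density=0.6,
    )
    return replace(base, **overrides)


def cytosolic_config(n_sequences: int, seed: int, **overrides) -> GeneratorConfig:
    """Cytosolic-like preset: 0.4 sites/100 aa."""
    base = GeneratorConfig(
        n_sequences=n_sequences, seed=seed, compartment="cytosolic",
        composition={"A": 0.26, "C": 0.25, "G": 0.27, "T": 0.22},
        site_density=0.4,
    )
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# CDS panel


def _draw_length(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    mu = math.log(cfg.mean_length_aa)
    L = int(round(rng.lognormal(mu, cfg.length_sigma)))
    return int(np.clip(L, cfg.min_length_aa, cfg.max_length_aa))


def _gene_usage(cfg: GeneratorConfig, rng: np.random.Generator
                ) -> Tuple[List[str], np.ndarray]:
    if cfg.codon_usage is not None:
        codons = [c for c in _SENSE if cfg.codon_usage.get(c, 0.0) > 0]
        p = np.array([cfg.codon_usage[c] for c in codons], dtype=float)
        return codons, p / p.sum()
    comp = {n: cfg.composition.get(n, 0.0) for n in NUCLEOTIDES}
    total = sum(comp.values())
    comp = {n: v / total for n, v in comp.items()}
    if cfg.composition_dispersion > 0:
        alpha = np.array([comp[n] for n in NUCLEOTIDES]) / cfg.composition_dispersion
        alpha = np.clip(alpha, 1e-3, None)
        draw = rng.dirichlet(alpha)
        comp = dict(zip(NUCLEOTIDES, draw))
    if cfg.at_gc_sd > 0:
        # per-gene shift along the A+T <-> G+C axis, the dominant mode of
        # compositional variation among real genes
        at = comp["A"] + comp["T"]
        new_at = float(np.clip(at + rng.normal(0.0, cfg.at_gc_sd), 0.15, 0.85))
        f_at = new_at / at if at > 0 else 1.0
        f_gc = (1.0 - new_at) / (1.0 - at) if at < 1 else 1.0
        comp = {"A": comp["A"] * f_at, "T": comp["T"] * f_at,
                "G": comp["G"] * f_gc, "C": comp["C"] * f_gc}
    usage = usage_from_composition(comp)
    codons = list(usage)
    return codons, np.array([usage[c] for c in codons])


def _weighted_choice(rng: np.random.Generator, items: Sequence[str],
                     p: Optional[np.ndarray] = None) -> str:
    return items[int(rng.choice(len(items), p=p))]


def _site_windows(codon_list: List[str]) -> List[int]:
    protein = "".join(_TABLE.codon_to_aa[c] for c in codon_list)
    return [p - 1 for p in find_sites(protein)]


def _plant_site(codon_list: List[str], rng: np.random.Generator,
                codons: Sequence[str], p: np.ndarray) -> None:
    n = len(codon_list)
    existing = set(_site_windows(codon_list))
    for _ in range(200):
        w = int(rng.integers(0, n - 2))
        if any(abs(w - e) <= 2 for e in existing):
            continue
        codon_list[w] = _weighted_choice(rng, sorted(ASN_BLOCK.codons))
        middle = _weighted_choice(rng, codons, p)
        while middle in _PRO:
            middle = _weighted_choice(rng, codons, p)
        codon_list[w + 1] = middle
        block = sorted(SER_THR_BLOCK.codons)
        bw = np.array([p[codons.index(c)] if c in codons else 0.0 for c in block])
        codon_list[w + 2] = (_weighted_choice(rng, block, bw / bw.sum())
                             if bw.sum() > 0 else _weighted_choice(rng, block))
        return
    raise InputError("could not place a site: windows saturated")


def _knockout_site(codon_list: List[str], rng: np.random.Generator,
                   codons: Sequence[str], p: np.ndarray) -> None:
    sites = _site_windows(codon_list)
    w = sites[int(rng.integers(0, len(sites)))]
    for _ in range(200):
        c = _weighted_choice(rng, codons, p)
        if c not in ASN_BLOCK:
            codon_list[w] = c
            return
    raise InputError("could not knock out a site")


def _near_windows(codon_list: List[str], cls: str) -> List[int]:
    cds = "".join(codon_list)
    return [p - 1 for p, c in find_near_sites(cds) if c == cls]


# knockout replacements avoid re-creating the class being removed, and avoid
# Asn codons so they do not seed fresh site windows that the fixpoint loop
# would then have to undo
_AVOID_XN = frozenset(ASN_BLOCK.codons) | frozenset(_ASN_NEAR)
_AVOID_NX = (frozenset(SER_THR_BLOCK.codons) | frozenset(_ST_NEAR)
             | frozenset(ASN_BLOCK.codons))


def _adjust_near(codon_list: List[str], cls: str, target: int,
                 rng: np.random.Generator, codons: Sequence[str],
                 p: np.ndarray) -> bool:
    """One near-site census edit toward ``target``; True when on target."""
    current = _near_windows(codon_list, cls)
    if len(current) == target:
        return True
    n = len(codon_list)
    if len(current) < target:
        protected = set(_site_windows(codon_list))
        for _ in range(200):
            w = int(rng.integers(0, n - 2))
            if any(abs(w - e) <= 2 for e in protected):
                continue
            if cls == "X_N.X.S/T":
                codon_list[w] = _ASN_NEAR[int(rng.integers(len(_ASN_NEAR)))]
                third = sorted(SER_THR_BLOCK.codons)
                codon_list[w + 2] = third[int(rng.integers(len(third)))]
            else:  # N.X.X_S/T
                codon_list[w] = sorted(ASN_BLOCK.codons)[int(rng.integers(2))]
                codon_list[w + 2] = _ST_NEAR[int(rng.integers(len(_ST_NEAR)))]
            middle = _weighted_choice(rng, codons, p)
            while middle in _PRO or middle in ASN_BLOCK:
                middle = _weighted_choice(rng, codons, p)
            codon_list[w + 1] = middle
            return False
        raise InputError("could not place a near-site: windows saturated")
    w = current[int(rng.integers(0, len(current)))]
    avoid = _AVOID_XN if cls == "X_N.X.S/T" else _AVOID_NX
    edit_at = w if cls == "X_N.X.S/T" else w + 2
    for _ in range(200):
        c = _weighted_choice(rng, codons, p)
        if c not in avoid:
            codon_list[edit_at] = c
            return False
    raise InputError("could not knock out a near-site")


def _build_sequence(cfg: GeneratorConfig, rng: np.random.Generator,
                    index: int) -> SequenceRecord:
    L = _draw_length(cfg, rng)
    codons, p = _gene_usage(cfg, rng)
    codon_list = [codons[i] for i in rng.choice(len(codons), size=L, p=p)]

    site_target: Optional[int] = None
    if cfg.exact_site_count is not None:
        site_target = min(cfg.exact_site_count, (L - 1) // 3)
    elif cfg.site_density is not None:
        lam = cfg.site_density * L / 100.0
        site_target = min(int(rng.poisson(lam)), (L - 1) // 3)
    near_targets: Dict[str, int] = {}
    if cfg.near_site_density:
        for cls, dens in cfg.near_site_density.items():
            near_targets[cls] = min(int(rng.poisson(dens * L / 100.0)),
                                    (L - 1) // 3)

    # census fixpoint: one edit per pass, re-scanning after every edit,
    # because a planted window can disturb its neighbors' classification
    for _ in range(2000):
        if site_target is not None:
            n_sites = len(_site_windows(codon_list))
            if n_sites < site_target:
                _plant_site(codon_list, rng, codons, p)
                continue
            if n_sites > site_target:
                _knockout_site(codon_list, rng, codons, p)
                continue
        pending = [cls for cls, tgt in near_targets.items()
                   if len(_near_windows(codon_list, cls)) != tgt]
        if not pending:
            break
        _adjust_near(codon_list, pending[0], near_targets[pending[0]],
                     rng, codons, p)
    else:
        raise InputError("site/near-site census failed to converge")

    return SequenceRecord.from_cds(
        id=f"{cfg.compartment[:3]}_{cfg.seed}_{index:05d}",
        cds="".join(codon_list),
        compartment=cfg.compartment,
    )


def gen_coding_panel(config: GeneratorConfig) -> List[SequenceRecord]:
    """Generate a deterministic panel of stop-free CDS records."""
    rng = np.random.default_rng(config.seed)
    return [_build_sequence(config, rng, i) for i in range(config.n_sequences)]


def gen_study_panel(seed: int, n_sequences: int = 30,
                    mean_length_aa: float = 600.0) -> List[SequenceRecord]:
    """A 30-gene secretory-like panel for mutagenesis studies.

    Genes differ in nucleotide composition mainly along the A+T <-> G+C
    axis (standard deviation 0.07 in A+T fraction), so A-content, Asn
    content and near-site counts vary across the panel the way they do
    across real glycoprotein genes while Ser+Thr content stays nearly
    flat.
    """
    cfg = secretory_config(n_sequences, seed,
                           mean_length_aa=mean_length_aa,
                           length_sigma=0.25,
                           at_gc_sd=0.07)
    return gen_coding_panel(cfg)


def gen_site_span_panel(seed: int, max_sites: int = 15, per_count: int = 2,
                        mean_length_aa: float = 400.0) -> List[SequenceRecord]:
    """Secretory-like genes with exact planted site counts spanning 0..max."""
    out = []
    for s in range(max_sites + 1):
        cfg = secretory_config(
            per_count, seed + 1000 * s, mean_length_aa=mean_length_aa,
            site_density=None, exact_site_count=s, length_sigma=0.1)
        for rec in gen_coding_panel(cfg):
            out.append(SequenceRecord(
                id=f"{rec.id}_s{s}", protein=rec.protein, cds=rec.cds,
                compartment=rec.compartment))
    return out


# ---------------------------------------------------------------------------
# Homolog pairs


def _nonsyn_fraction_of_cds(cds: str) -> float:
    """Fraction of non-stop single-substitution proposals that change the aa."""
    nonsyn = nonstop = 0
    for i in range(0, len(cds), 3):
        c = cds[i:i + 3]
        nonsyn += _NONSYN_NONSTOP[c]
        nonstop += len(_NONSTOP[c])
    return nonsyn / nonstop


class _CodonChain:
    """Spectral form of the neutral accepted-substitution chain on codons.

    An accepted event moves a codon to a uniformly chosen non-stop
    neighbor, so per codon the process is a continuous-time Markov chain;
    expected amino-acid identity after any number of events follows from
    the eigendecomposition of (T − I), including multiple hits and back
    substitutions exactly.  Used to calibrate branch lengths so the
    homolog generator's realized divergence matches its target without
    first-order bias.
    """

    def __init__(self) -> None:
        idx = {c: i for i, c in enumerate(_SENSE)}
        n = len(_SENSE)
        T = np.zeros((n, n))
        for i, c in enumerate(_SENSE):
            nbs = _NONSTOP[c]
            for nb in nbs:
                T[i, idx[nb]] += 1.0 / len(nbs)
        w, V = np.linalg.eig(T - np.eye(n))
        Vinv = np.linalg.inv(V)
        coef = np.empty((n, n), dtype=complex)
        for i, c in enumerate(_SENSE):
            mask = np.array([1.0 if _TABLE.codon_to_aa[x] == _TABLE.codon_to_aa[c]
                             else 0.0 for x in _SENSE])
            coef[i] = V[i, :] * (Vinv @ mask)
        self.eigenvalues = w
        self.coef = coef
        self.index = idx
        self.nonstop = np.array([len(_NONSTOP[c]) for c in _SENSE], dtype=float)

    def expected_identity(self, codon_counts: np.ndarray, b: float) -> float:
        """Mean P(amino acid preserved) at branch length ``b`` (per nt)."""
        L = codon_counts.sum()
        total_events = 3.0 * L * b
        weight_sum = float(codon_counts @ self.nonstop)
        lam = total_events * self.nonstop / weight_sum
        kept = np.real(np.exp(np.outer(lam, self.eigenvalues)) * self.coef
                       ).sum(axis=1)
        return float(codon_counts @ kept / L)


_CHAIN: Optional[_CodonChain] = None


def branch_length_for_divergence(cds: str, p_sub: float) -> float:
    """Neutral branch length giving expected per-residue divergence ``p_sub``.

    Solved numerically against the codon-chain identity curve (exact in
    multiple hits and back substitutions); falls back to the first-order
    form −ln(1−p)/(3·f_N) only as the bracketing guess.
    """
    global _CHAIN
    if not 0.0 <= p_sub < 1.0:
        raise InputError("per-residue substitution probability must be in [0, 1)")
    if p_sub == 0.0:
        return 0.0
    if _CHAIN is None:
        _CHAIN = _CodonChain()
    counts = np.zeros(len(_SENSE))
    for i in range(0, len(cds), 3):
        counts[_CHAIN.index[cds[i:i + 3]]] += 1
    guess = -math.log1p(-p_sub) / (3.0 * _nonsyn_fraction_of_cds(cds))
    from scipy.optimize import brentq

    target = 1.0 - p_sub
    lo, hi = 0.0, max(4.0 * guess, 1e-6)
    while _CHAIN.expected_identity(counts, hi) > target:
        hi *= 2.0
        if hi > 1e3:
            raise InputError("divergence target unreachable")
    return float(brentq(
        lambda b: _CHAIN.expected_identity(counts, b) - target, lo, hi,
        xtol=1e-12))


def gen_homolog_panel(
    config: GeneratorConfig,
    divergence_model: Callable[[int], float],
) -> List[HomologPair]:
    """Homolog pairs: references plus neutrally simulated partners.

    ``divergence_model`` maps a reference's sequon count to the target
    per-residue substitution probability; the partner is produced by the
    neutral simulator at the calibrated branch length.  Alignments are
    gap-free (the simulator is indel-free).
    """
    refs = gen_coding_panel(config)
    pairs = []
    for i, ref in enumerate(refs):
        s = len(find_sites(ref.protein))
        bl = branch_length_for_divergence(ref.cds, divergence_model(s))
        traj = evolve(ref.cds, SimParams(branch_length=bl, seed=config.seed + 1),
                      replicate=i)
        partner = _TABLE.translate(traj.end_cds)
        pairs.append(HomologPair(
            id_a=ref.id, id_b=ref.id + "_hom",
            aligned_a=ref.protein, aligned_b=partner,
            compartment=ref.compartment, site_number=s,
        ))
    return pairs


# ---------------------------------------------------------------------------
# SNP-like variant tables


def gen_variant_table(
    n_genes: int,
    seed: int,
    compartment: str = "secretory",
    max_sites: int = 10,
    mean_syn: float = 20.0,
    base_ns: float = 1.0,
    ns_decline_per_site: float = 0.0,
) -> pd.DataFrame:
    """Per-variant table with a configurable N/S trend in site number.

    Each gene gets a site-number bin (uniform on 0..max_sites), a Poisson
    count of synonymous variants, and nonsynonymous variants at rate
    ``base_ns × (1 − ns_decline_per_site)^sites``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_genes):
        s = int(rng.integers(0, max_sites + 1))
        n_syn = int(rng.poisson(mean_syn))
        ns = base_ns * (1.0 - ns_decline_per_site) ** s
        n_non = int(rng.poisson(mean_syn * ns))
        gene = f"g{g:05d}"
        rows.extend(
            {"gene": gene, "compartment": compartment, "site_number": s,
             "consequence": "synonymous"} for _ in range(n_syn)
        )
        rows.extend(
            {"gene": gene, "compartment": compartment, "site_number": s,
             "consequence": "nonsynonymous"} for _ in range(n_non)
        )
    if not rows:
        raise InputError("variant generator produced no variants")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Acetyl-Lys-style PTM tables


@dataclass(frozen=True)
class PTMConfig:
    """Controls the generic PTM (acetyl-Lys-style) protein table."""

    n_proteins: int
    seed: int
    modified_fraction: float = 0.5
    mean_length_aa: float = 450.0
    lys_fraction_mean: float = 0.057
    lys_fraction_sd: float = 0.012
    base_a_content: float = 0.258
    a_per_lys_slope: float = 1.0
    a_offset_modified: float = 0.0
    a_noise_sd: float = 0.02
    mean_sites: float = 2.3


def gen_ptm_table(config: PTMConfig) -> pd.DataFrame:
    """Proteins with Lys content, A-content and PTM site counts.

    A-content follows a linear regression on Lys fraction plus an optional
    offset for modified proteins (the planted excess-A signal), so the
    modified-vs-expected A-content contrast is testable end to end.
    ``site_count`` never exceeds the Lys count and is zero for unmodified
    proteins.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for i in range(config.n_proteins):
        L = max(50, int(rng.lognormal(math.log(config.mean_length_aa), 0.4)))
        lys_frac = float(np.clip(
            rng.normal(config.lys_fraction_mean, config.lys_fraction_sd),
            0.005, 0.25))
        lys_count = max(1, int(round(lys_frac * L)))
        modified = bool(rng.random() < config.modified_fraction)
        sites = 0
        if modified:
            sites = min(1 + int(rng.poisson(config.mean_sites - 1)), lys_count)
        a = (config.base_a_content
             + config.a_per_lys_slope * (lys_frac - config.lys_fraction_mean)
             + (config.a_offset_modified if modified else 0.0)
             + rng.normal(0.0, config.a_noise_sd))
        rows.append({
            "id": f"p{i:05d}", "length_aa": L, "lys_count": lys_count,
            "lys_fraction": lys_count / L, "site_count": sites,
            "modified": modified, "a_content": float(np.clip(a, 0.05, 0.6)),
        })
    return pd.DataFrame(rows)


def excess_a_contrast(table: pd.DataFrame) -> Tuple[float, float, float]:
    """Mean A-content difference (modified − unmodified) with Welch p-value.

    Returns (mean modified, mean unmodified, p).
    """
    from scipy import stats

    mod = table.loc[table["modified"], "a_content"]
    unmod = table.loc[~table["modified"], "a_content"]
    if mod.empty or unmod.empty:
        raise InputError("need both modified and unmodified proteins")
    _, p = stats.ttest_ind(mod, unmod, equal_var=False)
    return float(mod.mean()), float(unmod.mean()), float(p)
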