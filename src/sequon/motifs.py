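"""Motif creation/destruction path calculus for bipartite PTM motifs.

A bipartite motif such as the N-glycosylation sequon NXS/T(X≠P) has a
*target* codon block at its first position (Asn) and a *recognition* block
at its third (the 10 Ser/Thr codons treated as one synonymy class).  Under
uniform mutation, the two ends differ in how many single-substitution
paths destroy them and how many paths from nearby codons create them;
the product of the two ratios — the encoding asymmetry — determines
whether repositioning of lost sites is more probable than reversal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Optional

import numpy as np
import pandas as pd

from .genetic_code import (
    AMINO_ACIDS,
    ASN_BLOCK,
    NUCLEOTIDES,
    SER_THR_BLOCK,
    CodonBlock,
    CodonTable,
    InputError,
    MutationGraph,
    codon_neighbors,
)


@dataclass(frozen=True)
class MotifSpec:
    """A three-residue bipartite motif: target · X · recognition.

    ``middle_excluded`` lists amino acids disallowed at the middle
    position (Pro for the sequon, because it kinks the backbone and
    blocks oligosaccharyltransferase).
    """

    target: CodonBlock
    recognition: CodonBlock
    middle_excluded: FrozenSet[str] = frozenset({"P"})
    span: int = 3

    @classmethod
    def nxst(cls) -> "MotifSpec":
        """The N-glycosylation sequon NXS/T with X ≠ P."""
        return cls(target=ASN_BLOCK, recognition=SER_THR_BLOCK)

    @property
    def symmetric(self) -> bool:
        return self.target.codons == self.recognition.codons


@dataclass(frozen=True)
class AsymmetryResult:
    loss_ratio: float
    gain_ratio: float

    @property
    def asymmetry(self) -> float:
        return self.loss_ratio * self.gain_ratio


def _graph(weights: Optional[Dict[str, float]]) -> MutationGraph:
    return MutationGraph(stop_policy="exclude", weights=weights)


def loss_path_ratio(motif: MotifSpec,
                    weights: Optional[Dict[str, float]] = None) -> float:
    """Rate of motif destruction via the target end over the recognition end.

    (mean destroying substitutions per target codon) /
    (mean destroying substitutions per recognition codon); paths into stop
    codons are excluded throughout.
    """
    if motif.symmetric:
        return 1.0
    g = _graph(weights)
    return g.mean_destroying(motif.target) / g.mean_destroying(motif.recognition)


def gain_path_ratio(motif: MotifSpec,
                    weights: Optional[Dict[str, float]] = None) -> float:
    """Per-near-codon rate of gain via recognition creation over target creation.

    (mean substitution paths into the recognition block per member of its
    neighbor set) / (the same for the target block).  Stop codons are never
    sources.  The per-near-codon averaging is what makes the ratio a
    *rate*: a near-site window contains one near codon, and the expected
    number of creating substitutions at that window is the mean in-path
    count of such a codon.
    """
    if motif.symmetric:
        return 1.0
    g = _graph(weights)
    return g.mean_in_paths(motif.recognition) / g.mean_in_paths(motif.target)


def motif_asymmetry(motif: MotifSpec,
                    weights: Optional[Dict[str, float]] = None) -> AsymmetryResult:
    """Loss ratio, gain ratio and their product for a bipartite motif."""
    return AsymmetryResult(
        loss_ratio=loss_path_ratio(motif, weights),
        gain_ratio=gain_path_ratio(motif, weights),
    )


@dataclass(frozen=True)
class BipartiteMatrix:
    """20x20 asymmetry values for all X1..X2 amino-acid pairs.

    ``canonical`` holds each value folded to >= 1 (the orientation that
    makes the motif asymmetric toward repositioning); ``raw`` keeps the
    row-as-target orientation.
    """

    raw: pd.DataFrame
    canonical: pd.DataFrame

    @property
    def mean(self) -> float:
        return float(self.canonical.values.mean())

    @property
    def median(self) -> float:
        return float(np.median(self.canonical.values))


def bipartite_matrix(weights: Optional[Dict[str, float]] = None,
                     table: Optional[CodonTable] = None) -> BipartiteMatrix:
    """Asymmetry of every simple bipartite motif X1..X2 (no middle rule)."""
    table = table or CodonTable.standard()
    blocks = {
        a: CodonBlock.for_amino_acids(a, table) for a in AMINO_ACIDS
    }
    g = _graph(weights)
    dest = {a: g.mean_destroying(b) for a, b in blocks.items()}
    gain = {a: g.mean_in_paths(b) for a, b in blocks.items()}
    raw = pd.DataFrame(
        [[(dest[a1] / dest[a2]) * (gain[a2] / gain[a1]) for a2 in AMINO_ACIDS]
         for a1 in AMINO_ACIDS],
        index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS), dtype=float,
    )
    canonical = raw.where(raw >= 1.0, 1.0 / raw)
    return BipartiteMatrix(raw=raw, canonical=canonical)


# ---------------------------------------------------------------------------
# Exhaustive enumerations


def enumerate_two_codon_space(table: Optional[CodonTable] = None) -> Dict[str, int]:
    """Classify all 4^6 six-nucleotide sequences read as two codons.

    Classes (mutually exclusive, tested in order):

    * ``N.S/T``   — intact Asn codon followed by an intact Ser/Thr-block codon;
    * ``N.X_S/T`` — intact Asn, second codon one substitution from the block
      (stop codons admissible as the neighbor's identity);
    * ``X_N.S/T`` — first codon one substitution from Asn (not Asn itself),
      second codon intact in the block;
    * ``remainder`` — everything else.
    """
    table = table or CodonTable.standard()
    g_incl = MutationGraph(table=table, stop_policy="include")
    st_near = g_incl.neighbor_set(SER_THR_BLOCK, exclude_stops=False)
    asn_near = g_incl.neighbor_set(ASN_BLOCK, exclude_stops=True)
    counts = {"N.S/T": 0, "N.X_S/T": 0, "X_N.S/T": 0, "remainder": 0}
    codons = ["".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)]
    for a in codons:
        for b in codons:
            if a in ASN_BLOCK and b in SER_THR_BLOCK:
                counts["N.S/T"] += 1
            elif a in ASN_BLOCK and b in st_near:
                counts["N.X_S/T"] += 1
            elif a in asn_near and b in SER_THR_BLOCK:
                counts["X_N.S/T"] += 1
            else:
                counts["remainder"] += 1
    return counts


def enumerate_nine_mer_space(table: Optional[CodonTable] = None) -> pd.DataFrame:
    """Classify all 61^3 coding 9-mers under the X ≠ P middle rule.

    Classes: ``NXS/T`` (intact site), ``X_N.X.S/T`` and ``N.X.X_S/T``
    (near-sites one substitution away, middle non-Pro), ``N.P.S/T``
    (the Pro-blocked class), plus the remainder; counts and fractions of
    226,981 are returned.  The space is sense codons only.
    """
    table = table or CodonTable.standard()
    g = MutationGraph(table=table, stop_policy="exclude")
    asn_near = g.neighbor_set(ASN_BLOCK)
    st_near = g.neighbor_set(SER_THR_BLOCK)
    pro = table.codons_for("P")
    sense = table.sense_codons
    n_sense = len(sense)
    n_pro = len(pro)
    n_nonpro = n_sense - n_pro

    counts = {
        "NXS/T": len(ASN_BLOCK) * n_nonpro * len(SER_THR_BLOCK),
        "X_N.X.S/T": len(asn_near) * n_nonpro * len(SER_THR_BLOCK),
        "N.X.X_S/T": len(ASN_BLOCK) * n_nonpro * len(st_near),
        "N.P.S/T": len(ASN_BLOCK) * n_pro * len(SER_THR_BLOCK),
    }
    space = n_sense ** 3
    counts["remainder"] = space - sum(counts.values())
    df = pd.DataFrame({"count": pd.Series(counts, dtype=int)})
    df["fraction"] = df["count"] / space
    return df


# ---------------------------------------------------------------------------
# Nucleotide-composition effect of substitution classes


def composition_effect_table(
    weights: Optional[Dict[str, float]] = None,
    stratify_by_codon_count: bool = False,
    table: Optional[CodonTable] = None,
) -> pd.DataFrame:
    """Expected per-event nucleotide gain/loss for syn vs nonsyn substitutions.

    Every sense→sense single-substitution event changes exactly one
    nucleotide, so each row's four deltas sum to zero for any weighting.
    Events are weighted by source-codon usage (uniform by default) and
    uniformly over each codon's admissible neighbors; paths to stop codons
    are excluded.  With ``stratify_by_codon_count`` rows are split by the
    codon multiplicity of the source amino acid, which exposes the A-rich
    encoding of the 2-codon amino acids (Asn, Lys, ...): their
    nonsynonymous substitutions lose A on balance.
    """
    table = table or CodonTable.standard()
    g = MutationGraph(table=table, stop_policy="exclude", weights=weights)
    codon_count = {}
    for a in AMINO_ACIDS:
        codon_count[a] = len(table.codons_for(a))

    acc: Dict[tuple, np.ndarray] = {}
    wsum: Dict[tuple, float] = {}
    for src in table.sense_codons:
        w = g.weight(src)
        if w == 0:
            continue
        aa = table.codon_to_aa[src]
        for dst in codon_neighbors(src):
            if dst in table.stops:
                continue
            cls = "synonymous" if table.codon_to_aa[dst] == aa else "nonsynonymous"
            key = (cls, codon_count[aa]) if stratify_by_codon_count else (cls,)
            delta = np.array([dst.count(n) - src.count(n) for n in NUCLEOTIDES],
                             dtype=float)
            acc[key] = acc.get(key, np.zeros(4)) + w * delta
            wsum[key] = wsum.get(key, 0.0) + w

    rows = []
    for key in sorted(acc):
        row = {"mutation_class": key[0]}
        if stratify_by_codon_count:
            row["source_codon_count"] = key[1]
        for i, n in enumerate(NUCLEOTIDES):
            row[f"delta_{n}"] = acc[key][i] / wsum[key]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# A-enrichment


def a_enrichment(motif: MotifSpec, table: Optional[CodonTable] = None) -> float:
    """A-nucleotide enrichment of the motif's encoding over all sense codons.

    Mean A-fraction of the admissible codon triplets (target codon,
    middle codon outside ``middle_excluded``, recognition codon), uniform
    over admissible codons, divided by the mean A-fraction of the 61
    sense codons.
    """
    table = table or CodonTable.standard()
    sense = table.sense_codons
    excluded = table.codons_for(motif.middle_excluded) if motif.middle_excluded else frozenset()
    middles = [c for c in sense if c not in excluded]
    if not middles:
        raise InputError("middle-position exclusion leaves no admissible codons")

    def mean_a(codons) -> float:
        return sum(c.count("A") for c in codons) / len(codons)

    motif_a = (mean_a(motif.target.codons) + mean_a(middles)
               + mean_a(motif.recognition.codons)) / 9.0
    baseline = mean_a(sense) / 3.0
    return motif_a / baseline
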