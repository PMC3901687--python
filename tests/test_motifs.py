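"""Motif path calculus: ratios, enumerations, composition effects."""

import itertools
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sequon as sq
from sequon.genetic_code import (
    AMINO_ACIDS,
    NUCLEOTIDES,
    STANDARD_CODE,
    STOP_CODONS,
    CodonBlock,
    MutationGraph,
    codon_neighbors,
)
from sequon.motifs import (
    MotifSpec,
    a_enrichment,
    bipartite_matrix,
    composition_effect_table,
    enumerate_nine_mer_space,
    enumerate_two_codon_space,
    gain_path_ratio,
    loss_path_ratio,
    motif_asymmetry,
)

ALL_CODONS = ["".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)]
SENSE = [c for c in ALL_CODONS if c not in STOP_CODONS]


def brute_mean_destroying(block_codons, weights=None):
    """Independent event-loop oracle for block-destroying exits per codon."""
    num = den = 0.0
    for c in block_codons:
        w = 1.0 if weights is None else weights.get(c, 0.0)
        dest = sum(
            1 for n in codon_neighbors(c)
            if n not in block_codons and n not in STOP_CODONS
        )
        num += w * dest
        den += w
    return num / den


def brute_mean_in_paths(block_codons, weights=None):
    near = set()
    for c in block_codons:
        near |= codon_neighbors(c)
    near -= set(block_codons) | STOP_CODONS
    num = den = 0.0
    for c in near:
        w = 1.0 if weights is None else weights.get(c, 0.0)
        k = sum(1 for n in codon_neighbors(c) if n in block_codons)
        num += w * k
        den += w
    return num / den


class TestPathRatios:
    def test_nxst_loss_ratio_frozen(self, nxst):
        # 8 destroying events per Asn codon; 49 over the 10 S/T codons
        assert loss_path_ratio(nxst) == pytest.approx(8 / 4.9)

    def test_nxst_gain_ratio_frozen(self, nxst):
        assert gain_path_ratio(nxst) == pytest.approx((49 / 31) / (16 / 14))

    def test_nxst_asymmetry(self, nxst):
        res = motif_asymmetry(nxst)
        assert res.asymmetry == res.loss_ratio * res.gain_ratio
        assert res.asymmetry == pytest.approx(2.2580645161, rel=1e-9)

    def test_symmetric_motif_is_one(self):
        sym = MotifSpec(target=sq.ASN_BLOCK, recognition=sq.ASN_BLOCK)
        res = motif_asymmetry(sym)
        assert res.loss_ratio == res.gain_ratio == res.asymmetry == 1.0

    def test_fxp_destroying_path_counts(self, graph):
        phe = CodonBlock.for_amino_acids("F")
        pro = CodonBlock.for_amino_acids("P")
        assert graph.mean_destroying(phe) == 8.0
        assert graph.mean_destroying(pro) == 6.0
        fxp = MotifSpec(target=phe, recognition=pro,
                        middle_excluded=frozenset())
        assert loss_path_ratio(fxp) == pytest.approx(8 / 6)

    def test_ratios_match_brute_force_for_random_pairs(self):
        rnd = random.Random(7)
        pairs = set()
        while len(pairs) < 20:
            a, b = rnd.sample(AMINO_ACIDS, 2)
            pairs.add((a, b))
        for a, b in pairs:
            motif = MotifSpec(
                target=CodonBlock.for_amino_acids(a),
                recognition=CodonBlock.for_amino_acids(b),
                middle_excluded=frozenset(),
            )
            ca = frozenset(c for c in SENSE if STANDARD_CODE[c] == a)
            cb = frozenset(c for c in SENSE if STANDARD_CODE[c] == b)
            assert loss_path_ratio(motif) == pytest.approx(
                brute_mean_destroying(ca) / brute_mean_destroying(cb))
            assert gain_path_ratio(motif) == pytest.approx(
                brute_mean_in_paths(cb) / brute_mean_in_paths(ca))


class TestBipartiteMatrix:
    def test_diagonal_is_exactly_one(self):
        bm = bipartite_matrix()
        assert (np.diag(bm.raw.values) == 1.0).all()
        assert (np.diag(bm.canonical.values) == 1.0).all()

    def test_canonical_is_at_least_one_and_transpose_invariant(self):
        bm = bipartite_matrix()
        assert (bm.canonical.values >= 1.0).all()
        assert np.allclose(bm.canonical.values, bm.canonical.values.T)

    def test_raw_orientation_is_reciprocal(self):
        bm = bipartite_matrix()
        assert np.allclose(bm.raw.values * bm.raw.values.T, 1.0)

    def test_uniform_summary_frozen(self):
        bm = bipartite_matrix()
        assert bm.mean == pytest.approx(1.195833, rel=1e-5)
        assert bm.median == pytest.approx(7 / 6, rel=1e-9)


class TestTwoCodonEnumeration:
    def test_class_counts(self):
        counts = enumerate_two_codon_space()
        assert counts["N.S/T"] == 20
        assert counts["N.X_S/T"] == 68
        assert counts["X_N.S/T"] == 140

    def test_partition_is_exact(self):
        counts = enumerate_two_codon_space()
        assert sum(counts.values()) == 4096
        assert counts["remainder"] == 4096 - 20 - 68 - 140


class TestNineMerEnumeration:
    def test_npst_count_is_80(self):
        df = enumerate_nine_mer_space()
        assert df.loc["N.P.S/T", "count"] == 2 * 4 * 10 == 80

    def test_partition_is_exact(self):
        df = enumerate_nine_mer_space()
        assert df["count"].sum() == 61 ** 3
        assert (df["count"] >= 0).all()

    def test_near_site_counts_from_direct_products(self):
        df = enumerate_nine_mer_space()
        assert df.loc["NXS/T", "count"] == 2 * 57 * 10
        assert df.loc["X_N.X.S/T", "count"] == 14 * 57 * 10
        assert df.loc["N.X.X_S/T", "count"] == 2 * 57 * 31


class TestCompositionEffects:
    def test_rows_sum_to_zero_uniform(self):
        df = composition_effect_table()
        deltas = df[[f"delta_{n}" for n in NUCLEOTIDES]].to_numpy()
        assert np.allclose(deltas.sum(axis=1), 0.0, atol=1e-12)

    @given(st.lists(st.floats(min_value=0.01, max_value=10.0),
                    min_size=61, max_size=61))
    @settings(max_examples=25, deadline=None)
    def test_rows_sum_to_zero_for_arbitrary_weights(self, raw):
        weights = dict(zip(SENSE, raw))
        df = composition_effect_table(weights=weights,
                                      stratify_by_codon_count=True)
        deltas = df[[f"delta_{n}" for n in NUCLEOTIDES]].to_numpy()
        assert np.allclose(deltas.sum(axis=1), 0.0, atol=1e-12)

    def test_two_codon_amino_acids_lose_a_nonsynonymously(self):
        df = composition_effect_table(stratify_by_codon_count=True)
        row = df[(df["mutation_class"] == "nonsynonymous")
                 & (df["source_codon_count"] == 2)].iloc[0]
        assert row["delta_A"] < 0

    def test_single_codon_weight_reproduces_direct_enumeration(self):
        # all weight on AAT: nonsynonymous events are its 8 non-Asn,
        # non-stop neighbors, each changing exactly one nucleotide
        df = composition_effect_table(weights={"AAT": 1.0})
        row = df[df["mutation_class"] == "nonsynonymous"].iloc[0]
        events = [n for n in codon_neighbors("AAT")
                  if n not in STOP_CODONS and STANDARD_CODE[n] != "N"]
        expected = {
            n: np.mean([e.count(n) - "AAT".count(n) for e in events])
            for n in NUCLEOTIDES
        }
        for n in NUCLEOTIDES:
            assert row[f"delta_{n}"] == pytest.approx(expected[n])


class TestAEnrichment:
    def test_nxst_frozen_value(self, nxst):
        assert a_enrichment(nxst) == pytest.approx(1.6425571504, rel=1e-9)

    def test_unconstrained_motif_is_one(self):
        everything = CodonBlock("any", frozenset(SENSE))
        motif = MotifSpec(target=everything, recognition=everything,
                          middle_excluded=frozenset())
        assert a_enrichment(motif) == pytest.approx(1.0)

    def test_kxk_exceeds_nxst(self, nxst):
        lys = CodonBlock.for_amino_acids("K")
        kxk = MotifSpec(target=lys, recognition=lys)
        assert a_enrichment(kxk) == pytest.approx(2.659224, rel=1e-5)
        assert a_enrichment(kxk) > a_enrichment(nxst)
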