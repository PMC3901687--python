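"""Sequon scanning: site/near-site detection, densities, group comparisons."""

import re

import numpy as np
import pytest

import sequon as sq
from sequon.genetic_code import InputError
from sequon.scan import (
    SequenceRecord,
    expected_density_from_aa,
    expected_density_from_nt,
    find_near_sites,
    find_sites,
    group_by_site_number,
    scan_record,
    scan_records,
    spacing_histogram,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestFindSites:
    @pytest.mark.parametrize("protein,expected", [
        ("NAS", [1]),
        ("NPS", []),
        ("NNSS", [1, 2]),
        ("NAT", [1]),
        ("NA", []),           # truncated window
        ("ANASA", [2]),
        ("NASNAT", [1, 4]),
    ])
    def test_examples(self, protein, expected):
        assert find_sites(protein) == expected

    def test_non_standard_letters_rejected(self):
        with pytest.raises(InputError):
            find_sites("NXS")

    def test_agrees_with_regex_oracle_on_random_proteins(self):
        rng = np.random.default_rng(42)
        pattern = re.compile(r"(?=N[^P][ST])")
        for _ in range(10_000):
            length = int(rng.integers(3, 60))
            prot = "".join(AA[i] for i in rng.integers(0, 20, size=length))
            expected = [m.start() + 1 for m in pattern.finditer(prot)]
            assert find_sites(prot) == expected


class TestFindNearSites:
    def test_first_codon_one_step_from_asn(self):
        # GAT (Asp) is one substitution from AAT
        assert find_near_sites("GATGCTTCT") == [(1, "X_N.X.S/T")]

    def test_pro_blocked_class(self):
        assert find_near_sites("AATCCTTCA") == [(1, "N.P.S/T")]

    def test_third_codon_one_step_from_block(self):
        # TAT (Tyr) is one substitution from TCT
        assert find_near_sites("AATGCTTAT") == [(1, "N.X.X_S/T")]

    def test_true_sites_are_not_near_sites(self):
        assert find_near_sites("AATGCTTCT") == []

    def test_classes_are_mutually_exclusive_on_random_cds(self):
        rng = np.random.default_rng(5)
        panel = sq.gen_coding_panel(sq.GeneratorConfig(
            n_sequences=30, seed=6, mean_length_aa=150, length_sigma=0.1))
        for rec in panel:
            near = find_near_sites(rec.cds)
            positions = [p for p, _ in near]
            assert len(positions) == len(set(positions))
            assert not set(positions) & set(find_sites(rec.protein))

    def test_frame_error(self):
        with pytest.raises(InputError):
            find_near_sites("AATG")

    def test_internal_stop_error(self):
        with pytest.raises(InputError):
            find_near_sites("AATTAAGCT")


class TestSequenceRecord:
    def test_cds_protein_consistency_enforced(self):
        with pytest.raises(InputError):
            SequenceRecord(id="x", protein="NA", cds="AATGCTTCT")

    def test_from_cds_translates(self):
        rec = SequenceRecord.from_cds("x", "AATGCTTCT")
        assert rec.protein == "NAS"
        assert rec.a_content == pytest.approx(2 / 9)

    def test_records_with_ambiguous_bases_are_skipped_with_warning(self, caplog):
        good = SequenceRecord.from_cds("ok", "AATGCTTCT")
        bad = SequenceRecord(id="bad", protein="NXS")
        reports = scan_records([good, bad])
        assert [r.id for r in reports] == ["ok"]
        assert "bad" in caplog.text


class TestSiteReport:
    def test_densities_and_asn_fraction(self):
        rec = SequenceRecord.from_cds("x", "AATGCTTCT" + "GCT" * 7)
        rep = scan_record(rec)
        assert rep.site_positions == (1,)
        assert rep.length_aa == 10
        assert rep.site_density == pytest.approx(10.0)
        assert rep.asn_fraction_in_sites == 1.0

    def test_translated_and_codon_level_scans_agree(self):
        panel = sq.gen_coding_panel(sq.secretory_config(20, seed=9,
                                                        mean_length_aa=200))
        table = sq.CodonTable.standard()
        for rec in panel:
            assert find_sites(table.translate(rec.cds)) == find_sites(rec.protein)


class TestExpectedDensities:
    def test_aa_uniform_composition(self):
        comp = {a: 1 / 20 for a in AA}
        assert expected_density_from_aa(comp) == pytest.approx(
            100 * (1 / 20) * (19 / 20) * (2 / 20))

    def test_aa_no_asn_gives_zero(self):
        assert expected_density_from_aa({"S": 0.5, "T": 0.5}) == 0.0

    def test_aa_closed_form(self):
        comp = {"N": 1 / 3, "S": 1 / 3, "T": 1 / 3}
        assert expected_density_from_aa(comp) == pytest.approx(100 * (1 / 3) * (2 / 3))

    def test_nt_uniform_matches_exhaustive_count(self):
        val = expected_density_from_nt({n: 0.25 for n in "ACGT"})
        assert val == pytest.approx(100 * 1140 / 61 ** 3)

    def test_nt_zero_a_gives_zero(self):
        assert expected_density_from_nt({"C": 1 / 3, "G": 1 / 3, "T": 1 / 3}) == 0.0

    def test_nt_monotone_in_at_fraction(self):
        vals = []
        for at in np.linspace(0.30, 0.70, 9):
            comp = {"A": at / 2, "T": at / 2, "G": (1 - at) / 2,
                    "C": (1 - at) / 2}
            vals.append(expected_density_from_nt(comp))
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestSpacingHistogram:
    def test_single_close_pair(self):
        h = spacing_histogram([1, 10], length=100)
        assert h["<20"] == 1.0

    def test_equidistant_triplet(self):
        h = spacing_histogram([1, 25, 49], length=100)
        assert h["[20,30)"] == 1.0

    def test_fewer_than_two_sites_is_empty(self):
        assert spacing_histogram([5], length=100).empty
        assert spacing_histogram([], length=100).empty


class TestGroupBySiteNumber:
    def _reports(self, seed, compartment, **kw):
        cfg_maker = (sq.secretory_config if compartment == "secretory"
                     else sq.cytosolic_config)
        cfg = cfg_maker(kw.pop("n", 120), seed, **kw)
        return [scan_record(r) for r in sq.gen_coding_panel(cfg)]

    def test_identical_compartments_show_no_difference(self):
        base = self._reports(31, "secretory", n=80)
        mirrored = [
            sq.SiteReport(id=r.id + "_c", compartment="cytosolic",
                          length_aa=r.length_aa,
                          site_positions=r.site_positions,
                          near_sites=r.near_sites, asn_total=r.asn_total,
                          a_content=r.a_content)
            for r in base
        ]
        res = group_by_site_number(base + mirrored)
        for metric, (t, p) in res.paired_tests.items():
            assert p == pytest.approx(1.0)

    def test_depressed_near_site_density_detected(self):
        sec = [scan_record(r) for r in sq.gen_coding_panel(sq.secretory_config(
            500, 33, near_site_density={"X_N.X.S/T": 2.4}))]
        cyt = [scan_record(r) for r in sq.gen_coding_panel(sq.cytosolic_config(
            500, 34, site_density=0.6, near_site_density={"X_N.X.S/T": 3.0}))]
        res = group_by_site_number(sec + cyt)
        t, p = res.paired_tests["density[X_N.X.S/T]"]
        assert t < 0 and p < 0.05

    def test_cap_excludes_high_site_proteins(self):
        reports = [scan_record(r) for r in sq.gen_coding_panel(
            sq.secretory_config(5, 35, site_density=None, exact_site_count=20,
                                mean_length_aa=200, length_sigma=0.05))]
        low = [scan_record(r) for r in sq.gen_coding_panel(
            sq.secretory_config(5, 36, mean_length_aa=200))]
        res = group_by_site_number(reports + low, cap=15)
        assert res.summary["site_number"].max() <= 15

    def test_all_records_above_cap_is_an_error(self):
        reports = [scan_record(r) for r in sq.gen_coding_panel(
            sq.secretory_config(3, 37, site_density=None, exact_site_count=20,
                                mean_length_aa=200, length_sigma=0.05))]
        with pytest.raises(InputError):
            group_by_site_number(reports, cap=15)
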