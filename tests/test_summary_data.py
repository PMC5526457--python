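"""Reading, validation, harmonization and instrument selection."""

import math

import numpy as np
import pytest

from lipidmr import datasets, pvalues
from lipidmr.summary_data import (
    AssociationTable,
    VariantAssociation,
    harmonize,
    read_association_table,
    select_instruments,
    write_association_table,
)
from lipidmr.synthetic import SyntheticTruth, generate_two_sample
from lipidmr.univariable import egger, ivw, weighted_median

from conftest import make_table


def _write_tsv(path, rows, header="SNP\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestReader:
    def test_identity_read_back(self, tmp_path):
        p = tmp_path / "t.tsv"
        rows = [
            f"rs{i}\tA\tG\t0.2\t{0.01*i}\t0.01\t0.0{i+1}\t1000" for i in range(1, 6)
        ]
        _write_tsv(p, rows)
        table, rejected = read_association_table(p)
        assert len(table) == 5 and not rejected
        rec = table.get("rs3")
        assert rec.beta == pytest.approx(0.03)
        assert rec.p == pytest.approx(0.04)

    def test_sub_underflow_p_survives(self, tmp_path):
        p = tmp_path / "t.tsv"
        _write_tsv(p, ["rs1\tA\tG\t0.3\t0.147\t0.008\t8e-373\t100000",
                       "rs2\tA\tG\t0.3\t0.1\t0.01\t1e-300\t100000"])
        table, _ = read_association_table(p)
        assert table.get("rs1").log10_p < math.log10(1e-300)
        assert table.get("rs1").log10_p < table.get("rs2").log10_p

    def test_nonpositive_se_row_dropped_with_reason(self, tmp_path):
        p = tmp_path / "t.tsv"
        _write_tsv(p, ["rs1\tA\tG\t0.2\t0.1\t0.01\t0.05\t10",
                       "rs2\tA\tG\t0.2\t0.1\t0\t0.05\t10"])
        table, rejected = read_association_table(p)
        assert table.variant_ids == ["rs1"]
        assert rejected == [("rs2", "nonpositive SE")]

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("SNP\tbeta\nrs1\t0.1\n")
        with pytest.raises(ValueError, match="missing mapped column"):
            read_association_table(p)

    def test_duplicate_variant_id_named_in_error(self, tmp_path):
        p = tmp_path / "t.tsv"
        _write_tsv(p, ["rs1\tA\tG\t0.2\t0.1\t0.01\t0.05\t10"] * 2)
        with pytest.raises(ValueError, match="rs1"):
            read_association_table(p)

    def test_write_read_round_trip(self, tmp_path):
        table = make_table("x", [0.1, -0.2], [0.01, 0.02], eafs=[0.2, 0.7])
        out = tmp_path / "o.tsv"
        write_association_table(table, out)
        back, _ = read_association_table(out, trait_name="x")
        for vid in table.variant_ids:
            a, b = table.get(vid), back.get(vid)
            assert b.beta == pytest.approx(a.beta)
            assert b.log10_p == pytest.approx(a.log10_p, rel=1e-5)


class TestValidation:
    def test_se_must_be_positive(self):
        with pytest.raises(ValueError, match="se"):
            VariantAssociation("rs1", "A", "G", 0.1, 0.0, -1.0)

    def test_alleles_must_differ(self):
        with pytest.raises(ValueError):
            VariantAssociation("rs1", "A", "A", 0.1, 0.1, -1.0)

    def test_duplicate_ids_rejected(self):
        rec = VariantAssociation("rs1", "A", "G", 0.1, 0.1, -1.0)
        with pytest.raises(ValueError, match="duplicate"):
            AssociationTable("t", "sd-units", [rec, rec])


class TestHarmonize:
    def test_identical_alleles_unchanged(self):
        exp = make_table("e", [0.1, 0.2], [0.01, 0.01])
        out = make_table("o", [0.05, 0.07], [0.02, 0.02], scale="log-odds")
        hs = harmonize([exp], out)
        assert not hs.orientation_flags.any()
        np.testing.assert_allclose(hs.by, [0.05, 0.07])

    def test_swapped_alleles_flip_outcome_beta(self):
        exp = make_table("e", [0.1, 0.2], [0.01, 0.01])
        out = make_table(
            "o", [0.05, 0.07], [0.02, 0.02],
            alleles=[("A", "G"), ("G", "A")], scale="log-odds",
        )
        hs = harmonize([exp], out)
        np.testing.assert_allclose(hs.by, [0.05, -0.07])
        assert list(hs.orientation_flags) == [False, True]

    def test_missing_variants_dropped_with_reason_and_accounting(self):
        truth = SyntheticTruth(J=185, seed=3)
        exps, out, _ = generate_two_sample(truth)
        # drop 3 variants from the outcome table
        gone = out.variant_ids[:3]
        out2 = AssociationTable(
            "outcome", "log-odds", [r for r in out.records if r.variant_id not in gone]
        )
        hs = harmonize(exps, out2)
        assert hs.n_variants == 182
        assert len(hs.dropped) == 3
        assert all(reason == "missing in outcome" for _, reason in hs.dropped)
        assert hs.n_variants + len(hs.dropped) == 185

    def test_irreconcilable_alleles_dropped_never_kept(self):
        exp = make_table("e", [0.1, 0.2], [0.01, 0.01])
        out = make_table(
            "o", [0.05, 0.07], [0.02, 0.02],
            alleles=[("A", "G"), ("A", "C")], scale="log-odds",
        )
        hs = harmonize([exp], out)
        assert hs.variant_ids == ["rs1"]
        assert hs.dropped == [("rs2", "allele mismatch in o")]

    def test_empty_intersection_errors(self):
        exp = make_table("e", [0.1], [0.01], ids=["rs1"])
        out = make_table("o", [0.1], [0.01], ids=["rs9"], scale="log-odds")
        with pytest.raises(ValueError, match="intersection"):
            harmonize([exp], out)

    @pytest.mark.parametrize("policy,expected_ids", [
        ("drop", ["rs2"]),
        ("keep", ["rs1", "rs2"]),
    ])
    def test_palindromic_policies(self, policy, expected_ids):
        exp = make_table("e", [0.1, 0.2], [0.01, 0.01],
                         alleles=[("A", "T"), ("A", "G")], eafs=[0.2, 0.3])
        out = make_table("o", [0.05, 0.07], [0.02, 0.02],
                         alleles=[("A", "T"), ("A", "G")], eafs=[0.2, 0.3],
                         scale="log-odds")
        hs = harmonize([exp], out, palindromic_policy=policy)
        assert hs.variant_ids == expected_ids

    def test_palindromic_frequency_policy_drops_ambiguous_maf(self):
        # maf 0.45 > 0.42: frequency cannot disambiguate strand
        exp = make_table("e", [0.1, 0.2], [0.01, 0.01],
                         alleles=[("A", "T"), ("C", "G")], eafs=[0.45, 0.1])
        out = make_table("o", [0.05, 0.07], [0.02, 0.02],
                         alleles=[("A", "T"), ("C", "G")], eafs=[0.45, 0.9],
                         scale="log-odds")
        hs = harmonize([exp], out, palindromic_policy="frequency")
        # rs1 dropped (maf too high); rs2 kept and frequency-flipped
        assert hs.variant_ids == ["rs2"]
        assert hs.by[0] == pytest.approx(-0.07)

    def test_involution_double_flip_restores_betas(self):
        truth = SyntheticTruth(J=40, flip_fraction=0.5, seed=9)
        exps, out, _ = generate_two_sample(truth)
        hs = harmonize(exps, out)
        flipped_out = AssociationTable(
            "outcome", "log-odds",
            [r.flipped().flipped() for r in out.records],
        )
        hs2 = harmonize(exps, flipped_out)
        np.testing.assert_array_equal(hs.by, hs2.by)
        np.testing.assert_array_equal(hs.orientation_flags, hs2.orientation_flags)

    def test_estimators_invariant_to_allele_orientation(self):
        """Flipping rows flips (bx, by) together; estimates must not move."""
        truth = SyntheticTruth(J=30, seed=4)
        exps, out, _ = generate_two_sample(truth)
        hs = harmonize(exps, out)
        rng = np.random.default_rng(0)
        sign = np.where(rng.random(hs.n_variants) < 0.5, -1.0, 1.0)
        flipped = (hs.bx[:, 0] * sign, hs.sx[:, 0], hs.by * sign, hs.sy)
        base = (hs.bx[:, 0], hs.sx[:, 0], hs.by, hs.sy)
        assert ivw(flipped).theta == pytest.approx(ivw(base).theta, abs=1e-12)
        assert egger(flipped).theta == pytest.approx(egger(base).theta, abs=1e-12)
        assert weighted_median(flipped, seed=1).theta == pytest.approx(
            weighted_median(base, seed=1).theta, abs=1e-12
        )


class TestSelectInstruments:
    def test_threshold_one_keeps_everything(self):
        table = make_table("t", [0.1, 0.2, 0.3], [0.1, 0.1, 0.1])
        assert select_instruments(table, 1.0) == table.variant_ids

    def test_printed_hdl_column_at_genome_wide_threshold(self):
        hdl = datasets.association_table(datasets.table1(), "hdl")
        assert select_instruments(hdl, 5e-8) == [
            "rs1883025", "rs653178", "rs1532085", "rs261342",
            "rs9989419", "rs5880", "rs103294", "rs4465830",
        ]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        lps = -rng.uniform(0, 12, 50)
        table = make_table("t", [0.1] * 50, [0.01] * 50, log10_ps=list(lps))
        for thr in (1e-8, 1e-4, 0.05):
            expected = [
                r.variant_id for r in table.records if 10.0 ** r.log10_p < thr
            ]
            assert select_instruments(table, thr) == expected
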