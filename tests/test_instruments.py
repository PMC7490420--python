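"""Instrument construction: filtering, clumping, harmonization."""

import numpy as np
import pandas as pd
import pytest

from predimr.instruments import (
    HarmonizationError,
    exclude_disease_associated,
    harmonize,
    ld_clump,
    select_significant,
)
from predimr.simulate import MrSimConfig, gen_mr_dataset
from predimr.sumstats import LdMatrix, SummaryStatSet


def make_set(rows, trait_id="exp"):
    """rows: (rsid, ea, oa, beta, se, p[, chrom, pos, eaf])"""
    recs = []
    for r in rows:
        rec = dict(
            rsid=r[0], effect_allele=r[1], other_allele=r[2],
            beta=r[3], se=r[4], pvalue=r[5],
        )
        if len(r) > 6:
            rec.update(chrom=r[6], pos=r[7])
        if len(r) > 8:
            rec.update(eaf=r[8])
        recs.append(rec)
    return SummaryStatSet(trait_id, pd.DataFrame(recs))


class TestSelectSignificant:
    def test_strict_threshold(self):
        s = make_set(
            [("rs1", "A", "G", 0.1, 0.01, 4e-8),
             ("rs2", "A", "G", 0.1, 0.01, 5e-8),
             ("rs3", "A", "G", 0.1, 0.01, 6e-8)]
        )
        assert select_significant(s).rsids == ["rs1"]

    def test_all_null_gives_empty(self):
        s = make_set([("rs1", "A", "G", 0.0, 0.01, 1.0)])
        assert select_significant(s).n_snps == 0

    def test_generator_truth_recovered(self):
        cfg = MrSimConfig(n_snps=40, n_null_snps=960, seed=11)
        exposure, *_, truth = gen_mr_dataset(cfg)
        sig = select_significant(exposure)
        planted = set(truth.per_snp.loc[truth.per_snp["is_instrument"], "rsid"])
        assert set(sig.rsids) == planted


class TestDiseaseExclusion:
    def test_threshold_is_strict(self):
        cand = make_set(
            [("rs1", "A", "G", 0.1, 0.01, 1e-9),
             ("rs2", "A", "G", 0.1, 0.01, 1e-9)]
        )
        disease = make_set(
            [("rs1", "A", "G", 0.0, 0.01, 0.04),
             ("rs2", "A", "G", 0.0, 0.01, 0.06)], "t2d"
        )
        kept, report = exclude_disease_associated(cand, disease)
        assert kept.rsids == ["rs2"]
        assert report["excluded_associated"] == ["rs1"]

    def test_missing_from_disease_set_dropped(self):
        cand = make_set([("rs1", "A", "G", 0.1, 0.01, 1e-9)])
        disease = make_set([("rsX", "A", "G", 0.0, 0.01, 0.5)], "t2d")
        kept, report = exclude_disease_associated(cand, disease)
        assert kept.n_snps == 0
        assert report["excluded_missing_from_disease"] == ["rs1"]

    def test_generator_planted_associations(self):
        cfg = MrSimConfig(n_snps=30, disease_assoc_indices=tuple(range(5)), seed=5)
        exposure, _, disease, _, truth = gen_mr_dataset(cfg)
        kept, report = exclude_disease_associated(exposure, disease)
        assert kept.n_snps == 25
        flagged = set(truth.per_snp.loc[truth.per_snp["disease_associated"], "rsid"])
        assert set(report["excluded_associated"]) == flagged


def ld_from_pairs(rsids, pairs):
    m = np.eye(len(rsids))
    idx = {r: i for i, r in enumerate(rsids)}
    for a, b, r2 in pairs:
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = r2
    return LdMatrix(list(rsids), m)


class TestLdClump:
    def test_greedy_keeps_best_and_independent(self):
        cand = make_set(
            [("rsA", "A", "G", 0.1, 0.01, 1e-10, "1", 1_000_000),
             ("rsB", "A", "G", 0.1, 0.01, 1e-9, "1", 1_200_000),
             ("rsC", "A", "G", 0.1, 0.01, 1e-8, "1", 1_100_000)]
        )
        ld = ld_from_pairs(["rsA", "rsB", "rsC"], [("rsA", "rsB", 0.5), ("rsA", "rsC", 0.05)])
        assert sorted(ld_clump(cand, ld).rsids) == ["rsA", "rsC"]

    def test_outside_window_retained_despite_high_r2(self):
        cand = make_set(
            [("rsA", "A", "G", 0.1, 0.01, 1e-10, "1", 1_000_000),
             ("rsB", "A", "G", 0.1, 0.01, 1e-9, "1", 2_500_000)]
        )
        ld = ld_from_pairs(["rsA", "rsB"], [("rsA", "rsB", 0.9)])
        assert sorted(ld_clump(cand, ld).rsids) == ["rsA", "rsB"]

    def test_cross_chromosome_never_clumps(self):
        cand = make_set(
            [("rsA", "A", "G", 0.1, 0.01, 1e-10, "1", 1_000_000),
             ("rsB", "A", "G", 0.1, 0.01, 1e-9, "2", 1_000_100)]
        )
        ld = ld_from_pairs(["rsA", "rsB"], [("rsA", "rsB", 0.99)])
        assert sorted(ld_clump(cand, ld).rsids) == ["rsA", "rsB"]

    def test_block_fixture_against_brute_force(self):
        """On a 50-SNP block-LD fixture: no retained pair violates the
        threshold, and every removed SNP conflicts with a better-p kept SNP."""
        cfg = MrSimConfig(n_snps=50, ld_block_size=5, ld_within_r2=0.6, seed=21)
        exposure, _, _, ld, _ = gen_mr_dataset(cfg)
        kept = ld_clump(exposure, ld, r2_threshold=0.2, window_kb=1000)
        kept_ids = set(kept.rsids)
        df = exposure.df.set_index("rsid")

        def conflict(a, b):
            if str(df.loc[a, "chrom"]) != str(df.loc[b, "chrom"]):
                return False
            if abs(int(df.loc[a, "pos"]) - int(df.loc[b, "pos"])) > 1_000_000:
                return False
            r2 = ld.lookup(a, b)
            return r2 is not None and r2 >= 0.2

        for a in kept_ids:
            for b in kept_ids:
                if a != b:
                    assert not conflict(a, b)
        for r in set(exposure.rsids) - kept_ids:
            better = [
                k for k in kept_ids
                if conflict(r, k) and (df.loc[k, "pvalue"], k) < (df.loc[r, "pvalue"], r)
            ]
            assert better, f"{r} was removed without a better retained conflict"

    def test_order_invariance(self):
        cfg = MrSimConfig(n_snps=30, ld_block_size=3, ld_within_r2=0.5, seed=8)
        exposure, _, _, ld, _ = gen_mr_dataset(cfg)
        shuffled = SummaryStatSet(
            exposure.trait_id,
            exposure.df.sample(frac=1, random_state=4).reset_index(drop=True),
        )
        assert sorted(ld_clump(exposure, ld).rsids) == sorted(ld_clump(shuffled, ld).rsids)

    def test_snp_absent_from_ld_treated_independent(self):
        cand = make_set(
            [("rsA", "A", "G", 0.1, 0.01, 1e-10, "1", 1_000_000),
             ("rsB", "A", "G", 0.1, 0.01, 1e-9, "1", 1_000_100)]
        )
        ld = LdMatrix(["rsA"], np.eye(1))
        assert sorted(ld_clump(cand, ld).rsids) == ["rsA", "rsB"]


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_sign(self):
        exp = make_set([("rs1", "A", "G", 0.10, 0.01, 1e-9)])
        out = make_set([("rs1", "G", "A", -0.05, 0.01, 0.01)], "out")
        h = harmonize(exp, out)
        assert h.df.loc[0, "gamma"] == pytest.approx(0.10)
        assert h.df.loc[0, "Gamma"] == pytest.approx(0.05)
        assert list(h.log["action"]) == ["sign_flipped"]

    def test_strand_complement_kept(self):
        exp = make_set([("rs1", "A", "G", 0.10, 0.01, 1e-9)])
        out = make_set([("rs1", "T", "C", 0.05, 0.01, 0.01)], "out")
        h = harmonize(exp, out)
        assert h.df.loc[0, "Gamma"] == pytest.approx(0.05)
        assert list(h.log["action"]) == ["kept"]

    def test_ambiguous_palindrome_dropped_under_infer(self):
        exp = make_set(
            [("rs1", "A", "T", 0.10, 0.01, 1e-9, "1", 100, 0.50),
             ("rs2", "A", "G", 0.10, 0.01, 1e-9, "1", 200, 0.30)]
        )
        out = make_set(
            [("rs1", "A", "T", 0.05, 0.01, 0.01, "1", 100, 0.50),
             ("rs2", "A", "G", 0.05, 0.01, 0.01, "1", 200, 0.30)], "out"
        )
        h = harmonize(exp, out, palindrome_policy="infer")
        assert h.rsids == ["rs2"]
        assert dict(zip(h.log["rsid"], h.log["action"]))["rs1"] == "dropped_palindrome"

    def test_palindrome_frequency_inference_flips(self):
        exp = make_set([("rs1", "A", "T", 0.10, 0.01, 1e-9, "1", 100, 0.20)])
        out = make_set([("rs1", "A", "T", 0.05, 0.01, 0.01, "1", 100, 0.80)], "out")
        h = harmonize(exp, out)
        # frequencies on opposite sides of 0.5: effect allele differs by strand
        assert h.df.loc[0, "Gamma"] == pytest.approx(-0.05)
        assert list(h.log["action"]) == ["palindrome_aligned"]

    def test_drop_policy_removes_all_palindromes(self):
        exp = make_set(
            [("rs1", "C", "G", 0.10, 0.01, 1e-9, "1", 100, 0.20),
             ("rs2", "A", "G", 0.10, 0.01, 1e-9, "1", 200, 0.30)]
        )
        out = make_set(
            [("rs1", "C", "G", 0.05, 0.01, 0.01, "1", 100, 0.20),
             ("rs2", "A", "G", 0.05, 0.01, 0.01, "1", 200, 0.30)], "out"
        )
        h = harmonize(exp, out, palindrome_policy="drop")
        assert h.rsids == ["rs2"]

    def test_mismatched_and_missing_dropped(self):
        exp = make_set(
            [("rs1", "A", "G", 0.10, 0.01, 1e-9),
             ("rs2", "A", "G", 0.10, 0.01, 1e-9),
             ("rs3", "A", "G", 0.10, 0.01, 1e-9)]
        )
        out = make_set(
            [("rs1", "A", "C", 0.05, 0.01, 0.01),
             ("rs2", "A", "G", 0.05, 0.01, 0.01)], "out"
        )
        h = harmonize(exp, out)
        actions = dict(zip(h.log["rsid"], h.log["action"]))
        assert actions == {"rs1": "dropped_mismatch", "rs2": "kept", "rs3": "dropped_missing"}

    def test_exposure_effects_oriented_positive(self):
        exp = make_set([("rs1", "A", "G", -0.10, 0.01, 1e-9)])
        out = make_set([("rs1", "A", "G", 0.05, 0.01, 0.01)], "out")
        h = harmonize(exp, out)
        assert h.df.loc[0, "gamma"] == pytest.approx(0.10)
        assert h.df.loc[0, "Gamma"] == pytest.approx(-0.05)

    def test_empty_result_is_hard_error(self):
        exp = make_set([("rs1", "A", "G", 0.10, 0.01, 1e-9)])
        out = make_set([("rsX", "A", "G", 0.05, 0.01, 0.01)], "out")
        with pytest.raises(HarmonizationError, match="retained no variants"):
            harmonize(exp, out)

    def test_corruption_recovery_matches_generator_truth(self):
        cfg = MrSimConfig(
            n_snps=28, frac_strand_flip=0.2, frac_allele_swap=0.2,
            frac_palindromic=0.25, seed=17,
        )
        exposure, outcome, _, _, truth = gen_mr_dataset(cfg)
        h = harmonize(exposure, outcome)
        t = truth.per_snp.set_index("rsid")
        got = h.df.set_index("rsid")
        assert set(got.index) == set(t.index)  # nothing lost
        np.testing.assert_allclose(got["gamma"], t.loc[got.index, "gamma_oriented"])
        np.testing.assert_allclose(got["Gamma"], t.loc[got.index, "Gamma_oriented"])

    def test_idempotence(self):
        cfg = MrSimConfig(n_snps=20, frac_allele_swap=0.3, frac_palindromic=0.2, seed=9)
        exposure, outcome, *_ = gen_mr_dataset(cfg)
        h1 = harmonize(exposure, outcome)
        h2 = harmonize(*h1.to_summary_stat_sets())
        np.testing.assert_allclose(h2.df["gamma"], h1.df["gamma"])
        np.testing.assert_allclose(h2.df["Gamma"], h1.df["Gamma"])

    def test_sign_consistency_under_allele_relabeling(self):
        """Recoding any input record (swap alleles, negate beta, mirror eaf)
        leaves the harmonized pair invariant."""
        cfg = MrSimConfig(n_snps=15, seed=13)
        exposure, outcome, *_ = gen_mr_dataset(cfg)
        base = harmonize(exposure, outcome)

        flipped = exposure.df.copy()
        for i in range(0, len(flipped), 2):  # recode every other record
            flipped.loc[i, ["effect_allele", "other_allele"]] = list(
                flipped.loc[i, ["other_allele", "effect_allele"]]
            )
            flipped.loc[i, "beta"] = -flipped.loc[i, "beta"]
            flipped.loc[i, "eaf"] = 1 - flipped.loc[i, "eaf"]
        exp2 = SummaryStatSet("exposure", flipped)
        h2 = harmonize(exp2, outcome)
        b = base.df.set_index("rsid")
        g = h2.df.set_index("rsid")
        np.testing.assert_allclose(g["gamma"], b.loc[g.index, "gamma"])
        np.testing.assert_allclose(g["Gamma"], b.loc[g.index, "Gamma"])
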