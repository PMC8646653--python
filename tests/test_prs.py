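"""Thresholding, greedy LD clumping, sum-mode scoring, association."""

import numpy as np
import pandas as pd
import pytest

import pathprs as pp
from pathprs.prs import PrsConfig

from test_gwas import _tiny_genotypes


def _sumstat_rows(rows):
    df = pd.DataFrame(
        rows, columns=["id", "chrom", "pos", "effect_allele", "other_allele",
                       "beta", "p"]
    )
    df["se"] = 0.1
    df["z"] = df["beta"] / df["se"]
    df["n"] = 1000
    return df


class TestSelectVariants:
    def test_threshold_one_keeps_all_nonmissing(self, male_gwas):
        out = pp.select_variants(male_gwas, 1.0)
        assert len(out) == male_gwas["p"].notna().sum()

    def test_boundary_is_strict(self):
        ss = _sumstat_rows([("v0", "1", 100, "A", "G", 0.1, 5e-5),
                            ("v1", "1", 200, "A", "G", 0.1, 4.9e-5)])
        out = pp.select_variants(ss, 5e-5)
        assert list(out["id"]) == ["v1"]

    def test_hand_filtered_toy_at_both_default_thresholds(self):
        ps = [1e-9, 3e-8, 5e-8, 6e-8, 1e-6, 4.9e-5, 5e-5, 1e-4, 0.03, 0.9]
        ss = _sumstat_rows(
            [(f"v{j}", "1", 100 * (j + 1), "A", "G", 0.1, p) for j, p in enumerate(ps)]
        )
        got8 = set(pp.select_variants(ss, 5e-8)["id"])
        got5 = set(pp.select_variants(ss, 5e-5)["id"])
        assert got8 == {"v0", "v1"}
        assert got5 == {"v0", "v1", "v2", "v3", "v4", "v5"}

    def test_empty_selection_warns_not_raises(self):
        ss = _sumstat_rows([("v0", "1", 100, "A", "G", 0.1, 0.5)])
        out = pp.select_variants(ss, 5e-8)
        assert out.empty


class TestLdClump:
    def test_independent_variants_unchanged(self):
        cfg = pp.SimulationConfig(n_individuals=3000, n_variants=30,
                                  within_block_corr=0.0, seed=50)
        g = pp.simulate_genotypes(cfg)
        ss = _sumstat_rows(
            [(r["id"], r["chrom"], r["pos"], "A", "G", 0.1, 1e-6)
             for _, r in g.variants.iterrows()]
        )
        out = pp.ld_clump(ss, g, clump_r2=0.5, clump_window_bp=10**9)
        assert len(out) == 30

    def test_perfectly_correlated_pair_keeps_best_p(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, 500).astype(np.int8)
        g = _tiny_genotypes(np.column_stack([col, col]))
        ss = _sumstat_rows([("v0", "1", 1000, "A", "G", 0.1, 1e-6),
                            ("v1", "1", 2000, "A", "G", 0.1, 1e-9)])
        out = pp.ld_clump(ss, g, clump_r2=0.5, clump_window_bp=10_000)
        assert list(out["id"]) == ["v1"]

    def test_matches_brute_force_greedy(self):
        """12-variant instance: retained set equals an explicit Python
        re-implementation of the greedy procedure on the same LD matrix."""
        cfg = pp.SimulationConfig(n_individuals=2000, n_variants=12, n_chromosomes=1,
                                  ld_block_size=4, within_block_corr=0.7, seed=51)
        g = pp.simulate_genotypes(cfg)
        rng = np.random.default_rng(2)
        ps = rng.uniform(1e-10, 1e-4, 12)
        ss = _sumstat_rows(
            [(r["id"], r["chrom"], r["pos"], "A", "G", 0.1, ps[j])
             for j, (_, r) in enumerate(g.variants.iterrows())]
        )
        r2_thresh, window = 0.2, 10**9
        out = pp.ld_clump(ss, g, r2_thresh, window)
        # brute force
        X = g.dosages.astype(float)
        R2 = np.corrcoef(X.T) ** 2
        pos = g.variants["pos"].to_numpy()
        unclaimed = set(range(12))
        kept = []
        while unclaimed:
            i = min(unclaimed, key=lambda k: (ps[k], pos[k]))
            kept.append(i)
            unclaimed.discard(i)
            for k in list(unclaimed):
                if abs(pos[k] - pos[i]) <= window and R2[i, k] >= r2_thresh:
                    unclaimed.discard(k)
        assert list(out["id"]) == [f"snp_{j:06d}" for j in sorted(kept)]

    def test_clumped_is_subset_and_r2_above_one_disables(self, male_gwas, small_cohort):
        sel = pp.select_variants(male_gwas, 1e-3)
        clumped = pp.ld_clump(sel, small_cohort.genotypes, 0.1, 250_000)
        assert set(clumped["id"]) <= set(sel["id"])
        noclump = pp.ld_clump(sel, small_cohort.genotypes, 1.0 + 1e-9, 250_000)
        assert len(noclump) == len(sel)


class TestComputePrs:
    def test_zero_betas_zero_scores(self):
        g = _tiny_genotypes(np.array([[0, 1], [2, 1]], dtype=np.int8))
        ss = _sumstat_rows([("v0", "1", 1000, "A", "G", 0.0, 1e-9),
                            ("v1", "1", 2000, "A", "G", 0.0, 1e-9)])
        res = pp.compute_prs(g, ss)
        assert (res.scores == 0).all() and res.n_variants_used == 2

    def test_single_term_sum(self):
        g = _tiny_genotypes(np.array([[2]], dtype=np.int8))
        ss = _sumstat_rows([("v0", "1", 1000, "A", "G", 0.5, 1e-9)])
        res = pp.compute_prs(g, ss)
        assert res.scores.iloc[0] == 1.0

    def test_matches_double_loop(self):
        """3 variants x 4 individuals written out explicitly."""
        d = np.array([[0, 1, 2], [2, 0, 1], [1, 1, 0], [2, 2, 2]], dtype=np.int8)
        betas = [0.2, -0.1, 0.4]
        g = _tiny_genotypes(d)
        ss = _sumstat_rows(
            [(f"v{j}", "1", 1000 * (j + 1), "A", "G", betas[j], 1e-9)
             for j in range(3)]
        )
        res = pp.compute_prs(g, ss)
        for i in range(4):
            expected = sum(betas[j] * d[i, j] for j in range(3))
            assert abs(res.scores.iloc[i] - expected) < 1e-12

    def test_order_invariance(self, male_gwas, small_cohort):
        sel = pp.select_variants(male_gwas, 1e-3)
        a = pp.compute_prs(small_cohort.genotypes, sel)
        b = pp.compute_prs(small_cohort.genotypes, sel.iloc[::-1].reset_index(drop=True))
        assert np.abs(a.scores - b.scores).max() < 1e-12

    def test_flip_invariance_shifts_by_constant(self):
        """Recoding a variant to the opposite allele (dosage 2-d, labels
        swapped) with beta negated and alleles swapped in the sumstats shifts
        every score by the same constant."""
        d = np.array([[0, 1], [2, 0], [1, 2]], dtype=np.int8)
        g = _tiny_genotypes(d)
        ss = _sumstat_rows([("v0", "1", 1000, "A", "G", 0.3, 1e-9),
                            ("v1", "1", 2000, "A", "G", -0.2, 1e-9)])
        base = pp.compute_prs(g, ss)
        flipped_d = d.copy()
        flipped_d[:, 0] = 2 - flipped_d[:, 0]
        g2 = _tiny_genotypes(flipped_d, coded=["G", "A"], other=["A", "G"])
        ss2 = ss.copy()
        ss2.loc[0, "beta"] = -0.3
        ss2.loc[0, ["effect_allele", "other_allele"]] = ["G", "A"]
        flipped = pp.compute_prs(g2, ss2)
        shifts = (flipped.scores - base.scores).to_numpy()
        assert np.abs(shifts - shifts[0]).max() < 1e-12
        assert abs(shifts[0] - (-2 * 0.3)) < 1e-12

    def test_absent_variant_dropped_with_count(self):
        g = _tiny_genotypes(np.array([[1]], dtype=np.int8))
        ss = _sumstat_rows([("v0", "1", 1000, "A", "G", 0.5, 1e-9),
                            ("missing", "1", 9999, "A", "G", 0.5, 1e-9)])
        res = pp.compute_prs(g, ss)
        assert res.n_variants_used == 1 and res.n_dropped_absent == 1

    def test_male_x_dosage_coding(self):
        d = np.array([[2, 2], [2, 2]], dtype=np.int8)
        g = _tiny_genotypes(d, chroms=["X", "1"], sex=["male", "female"])
        ss = _sumstat_rows([("v0", "X", 1000, "A", "G", 1.0, 1e-9),
                            ("v1", "1", 2000, "A", "G", 1.0, 1e-9)])
        two = pp.compute_prs(g, ss, PrsConfig(male_x_dosage="zero_two"))
        one = pp.compute_prs(g, ss, PrsConfig(male_x_dosage="zero_one"))
        assert two.scores.iloc[0] == 4.0 and two.scores.iloc[1] == 4.0
        assert one.scores.iloc[0] == 3.0 and one.scores.iloc[1] == 4.0
        nox = pp.compute_prs(g, ss, PrsConfig(include_x=False))
        assert nox.scores.iloc[0] == 2.0 and nox.n_variants_used == 1


class TestAssociatePrs:
    def test_scale_equivariance(self, male_gwas, small_cohort):
        """Doubling all scores leaves the standardised-PRS z and p unchanged."""
        sel = pp.select_variants(male_gwas, 1e-3)
        res = pp.compute_prs(small_cohort.genotypes, sel)
        a = pp.associate_prs(res, small_cohort.phenotypes, "male")
        doubled = pp.PrsResult(
            scores=res.scores * 2.0,
            n_variants_used=res.n_variants_used,
            threshold=res.threshold,
            variant_ids=res.variant_ids,
        )
        b = pp.associate_prs(doubled, small_cohort.phenotypes, "male")
        assert abs(a.beta - b.beta) < 1e-8  # standardisation absorbs the scale
        assert abs(a.p - b.p) < 1e-8

    def test_zero_variance_score_rejected(self, small_cohort):
        res = pp.PrsResult(
            scores=pd.Series(0.0, index=small_cohort.phenotypes["individual_id"]),
            n_variants_used=0, threshold=None, variant_ids=[],
        )
        with pytest.raises(ValueError):
            pp.associate_prs(res, small_cohort.phenotypes, "male")

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PrsConfig(p_thresholds=(0.0,))
        with pytest.raises(ValueError):
            PrsConfig(clump_r2=0.0)
        with pytest.raises(ValueError):
            PrsConfig(male_x_dosage="bad")
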