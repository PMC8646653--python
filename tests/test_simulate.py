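"""Generator contracts: Hardy-Weinberg moments, LD block structure, gene
tiling, liability phenotypes, planted-pathway containment, and the bivariate
summary-statistic sampling model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pathprs as pp
from pathprs.pathways import map_snps_to_genes
from pathprs.simulate import _block_slices


def test_invalid_configs_rejected():
    with pytest.raises(pp.InvalidConfigError):
        pp.SimulationConfig(maf_range=(0.0, 0.5))
    with pytest.raises(pp.InvalidConfigError):
        pp.SimulationConfig(maf_range=(0.1, 0.6))
    with pytest.raises(pp.InvalidConfigError):
        pp.SimulationConfig(within_block_corr=1.0)
    with pytest.raises(pp.InvalidConfigError):
        pp.SimulationConfig(aga_h2=1.0)
    with pytest.raises(pp.InvalidConfigError):
        pp.SimulationConfig(n_genes=5, genes_per_pathway=10)


def test_genotypes_deterministic_and_valid(small_config, small_cohort):
    again = pp.simulate_genotypes(small_config)
    assert np.array_equal(again.dosages, small_cohort.genotypes.dosages)
    pd.testing.assert_frame_equal(again.variants, small_cohort.genotypes.variants)
    small_cohort.genotypes.validate()


def test_hardy_weinberg_moments():
    """Per-variant dosage mean ~ 2f and variance ~ 2f(1-f) at n = 5000."""
    cfg = pp.SimulationConfig(n_individuals=5000, n_variants=200, seed=2)
    g = pp.simulate_genotypes(cfg)
    f = g.variants["maf"].to_numpy()
    mean = g.dosages.mean(axis=0)
    var = g.dosages.var(axis=0)
    # binomial sampling error at n=5000: sd(mean) ~ sqrt(2f(1-f)/n) < 0.011
    assert np.abs(mean - 2 * f).max() < 0.06
    assert np.abs(var - 2 * f * (1 - f)).max() < 0.1


def test_independent_blocks_have_no_ld():
    cfg = pp.SimulationConfig(
        n_individuals=5000, n_variants=100, within_block_corr=0.0, seed=3
    )
    g = pp.simulate_genotypes(cfg)
    r = np.corrcoef(g.dosages.T)
    off = r[np.triu_indices_from(r, k=1)]
    assert np.abs(off).max() < 0.06


def test_within_block_ld_dominates_between():
    """Mean within-block dosage r^2 at rho = 0.9 exceeds the between-block
    (null) mean by a large factor."""
    cfg = pp.SimulationConfig(
        n_individuals=5000, n_variants=100, n_chromosomes=1,
        ld_block_size=10, within_block_corr=0.9, seed=4,
    )
    g = pp.simulate_genotypes(cfg)
    r2 = np.corrcoef(g.dosages.T) ** 2
    blocks = _block_slices([100], 10)
    within_mask = np.zeros_like(r2, dtype=bool)
    for sl in blocks:
        within_mask[sl, sl] = True
    np.fill_diagonal(within_mask, False)
    off_diag = ~np.eye(100, dtype=bool)
    within = r2[within_mask & off_diag].mean()
    between = r2[~within_mask & off_diag].mean()
    assert within / between >= 10


def test_truncated_final_block_allowed():
    cfg = pp.SimulationConfig(n_individuals=50, n_variants=25, n_chromosomes=1,
                              ld_block_size=10, seed=5)
    g = pp.simulate_genotypes(cfg)
    assert g.n_variants == 25


def test_gene_tiling_arithmetic():
    cfg = pp.SimulationConfig(n_genes=6, n_chromosomes=1, gene_length_bp=1000,
                              intergenic_gap_bp=20_000, genes_per_pathway=3, seed=6)
    ann, _ = pp.simulate_annotation(cfg)
    assert ann.loc[0, "start"] == 1 and ann.loc[0, "end"] == 1000
    assert ann.loc[1, "start"] == 1 + 1000 + 20_000
    # non-overlapping within chromosome
    assert (ann["start"].to_numpy()[1:] > ann["end"].to_numpy()[:-1]).all()


def test_library_sizes_and_planted_membership():
    cfg = pp.SimulationConfig(n_pathways_per_library=50, planted_pathway_id="planted",
                              seed=7)
    _, libs = pp.simulate_annotation(cfg)
    assert len(libs) == 3
    assert all(len(lib.pathways) == 50 for lib in libs)
    assert "planted" in libs[0].pathways
    assert all(len(genes) == cfg.genes_per_pathway
               for lib in libs for genes in lib.pathways.values())


def test_wide_gaps_give_unique_gene_mapping():
    """With a 25 kb gap and a 10 kb window no variant can reach two genes;
    verified against a brute-force double loop over all variant-gene pairs."""
    cfg = pp.SimulationConfig(n_individuals=10, n_variants=200, n_genes=20,
                              intergenic_gap_bp=25_000, seed=8)
    g = pp.simulate_genotypes(cfg)
    ann, _ = pp.simulate_annotation(cfg)
    snp_map = map_snps_to_genes(g.variants, ann, window_bp=10_000)
    assert all(len(genes) <= 1 for genes in snp_map.variant_to_genes.values())
    # brute force
    for _, v in g.variants.iterrows():
        hits = set()
        for _, gene in ann.iterrows():
            if gene["chrom"] != v["chrom"]:
                continue
            dist = max(0, gene["start"] - v["pos"], v["pos"] - gene["end"])
            if dist < 10_000:
                hits.add(gene["gene_id"])
        assert hits == set(snp_map.variant_to_genes.get(v["id"], frozenset()))


def test_pattern_marginals_and_age_monotonicity(small_cohort):
    phen = small_cohort.phenotypes
    males = phen[phen["sex"] == "male"]
    freqs = males["aga_pattern"].value_counts(normalize=True).sort_index()
    expected = np.array([0.31, 0.23, 0.27, 0.19])
    assert np.abs(freqs.to_numpy() - expected).max() < 0.05
    # females carry no pattern
    assert phen.loc[phen["sex"] == "female", "aga_pattern"].isna().all()
    # mean pattern nondecreasing across age quartiles (aga_age_slope > 0)
    q = pd.qcut(males["age_at_assessment"], 4, labels=False)
    means = males.groupby(q)["aga_pattern"].mean()
    assert means.is_monotonic_increasing


def test_phenotype_invariants(small_cohort):
    phen = small_cohort.phenotypes
    assert (phen["age_at_event"] >= phen["age_at_assessment"]).all()
    assert phen.loc[phen["hospitalized"], "sars_cov2_positive"].all()
    assert abs(phen["hospitalized"].mean() - small_cohort.config.covid_base_rate) < 0.02


def test_age_effect_recovery_in_hospitalization():
    """Logistic regression of the outcome on age recovers the generating
    log-OR (0.1/year) within 2 SE at n = 20 000."""
    import statsmodels.api as sm

    cfg = pp.SimulationConfig(n_individuals=20_000, n_variants=40, aga_h2=0.0,
                              covid_age_log_or=0.1, seed=9)
    g = pp.simulate_genotypes(cfg)
    ann, libs = pp.simulate_annotation(cfg)
    phen, _ = pp.simulate_phenotypes(g, ann, libs, cfg)
    X = sm.add_constant(phen["age_at_event"].to_numpy())
    fit = sm.Logit(phen["hospitalized"].to_numpy(float), X).fit(disp=0)
    assert abs(fit.params[1] - 0.1) < 2 * fit.bse[1]


def test_planted_effects_confined_to_pathway():
    """Shared effects are exactly zero at every variant >= 10 kb away from
    all planted-pathway genes (brute-force distance check)."""
    cfg = pp.SimulationConfig(n_individuals=500, n_variants=400, n_genes=40,
                              planted_pathway_id="planted", shared_effect_size=0.3,
                              genes_per_pathway=8, n_pathways_per_library=10, seed=10)
    g = pp.simulate_genotypes(cfg)
    ann, libs = pp.simulate_annotation(cfg)
    _, eff = pp.simulate_phenotypes(g, ann, libs, cfg)
    assert eff.planted_pathway == "planted"
    assert (eff.shared_effects != 0).any()
    planted_genes = libs[0].pathways["planted"]
    sub = ann[ann["gene_id"].isin(planted_genes)]
    for j, (_, v) in enumerate(g.variants.iterrows()):
        dmin = np.inf
        for _, gene in sub.iterrows():
            if gene["chrom"] != v["chrom"]:
                continue
            dmin = min(dmin, max(0, gene["start"] - v["pos"], v["pos"] - gene["end"]))
        if dmin >= 10_000:
            assert eff.shared_effects[j] == 0.0


def test_unknown_planted_pathway_rejected(small_cohort):
    cfg = pp.SimulationConfig(planted_pathway_id="no_such_pathway",
                              shared_effect_size=0.3, seed=12)
    g = pp.simulate_genotypes(cfg)
    ann, libs = pp.simulate_annotation(pp.SimulationConfig(seed=12))
    with pytest.raises(pp.InvalidConfigError):
        pp.simulate_phenotypes(g, ann, libs, cfg)


class TestModelSumstats:
    def test_null_model_gives_unit_chi2(self):
        ld = np.ones(5000)
        ss1, ss2 = pp.simulate_model_sumstats(5000, ld, 10_000, 10_000, 0.0, 0.0,
                                              0.0, seed=1)
        for ss in (ss1, ss2):
            assert abs((ss["z"] ** 2).mean() - 1.0) < 0.05
            # z standard normal => KS does not reject wildly
            assert stats.kstest(ss["z"], "norm").pvalue > 1e-4

    def test_mean_chi2_matches_closed_form(self):
        """E[chi2] = 1 + n h2 l_bar / M, averaged over 20 seeds."""
        m, n, h2 = 2000, 20_000, 0.3
        rng = np.random.default_rng(0)
        ld = rng.uniform(1.0, 3.0, m)
        expected = 1.0 + n * h2 * ld.mean() / m
        means = []
        for s in range(20):
            ss1, _ = pp.simulate_model_sumstats(m, ld, n, n, h2, h2, 0.0, seed=s)
            means.append((ss1["z"] ** 2).mean())
        assert abs(np.mean(means) - expected) / expected < 0.05

    def test_perfect_correlation_limit(self):
        """At rg = 1 with equal h2 and N the z-pair correlation approaches
        Cov/Var as l_j grows."""
        m, n, h2 = 4000, 50_000, 0.5
        ld = np.full(m, 50.0)
        ss1, ss2 = pp.simulate_model_sumstats(m, ld, n, n, h2, h2, 1.0, seed=3)
        r = np.corrcoef(ss1["z"], ss2["z"])[0, 1]
        lm = ld[0] / m
        expected = (n * h2 * lm) / (1 + n * h2 * lm)
        assert abs(r - expected) < 0.02

    def test_sumstats_internal_consistency(self):
        from pathprs.gwas import validate_sumstats

        ss1, _ = pp.simulate_model_sumstats(500, np.ones(500), 1000, 1000,
                                            0.2, 0.2, 0.5, seed=4)
        validate_sumstats(ss1)

    def test_invalid_rg_rejected(self):
        with pytest.raises(ValueError):
            pp.simulate_model_sumstats(10, np.ones(10), 100, 100, 0.5, 0.5,
                                       1.5, seed=0)
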