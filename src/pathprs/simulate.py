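"""Synthetic GWAS cohort generation.

Everything downstream (age-corrected epidemiology, LD score regression,
genome-wide and pathway-restricted polygenic scores) is exercised on cohorts
produced here, with known ground truth:

* a diploid dosage matrix with block-structured linkage disequilibrium and
  tunable allele frequencies (threshold-Gaussian haplotype model),
* a tiled gene annotation plus three random gene-set libraries emulating
  KEGG-2019 / WikiPathways-2019 / Panther-2016 style collections,
* a 4-level ordinal male-pattern-baldness phenotype generated from a liability
  threshold model with an additive genetic component and an age trend,
* a binary hospitalised-COVID outcome from a logistic model with an age effect
  and an optional shared genetic component confined to one "planted" pathway,
* model-consistent pairs of GWAS summary statistics drawn directly from the
  bivariate LD score regression sampling model, for testing that estimator.

All draws are controlled by a single integer seed; identical configuration
(including the seed) yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "SimulationConfig",
    "GenotypeMatrix",
    "GeneSetLibrary",
    "TrueEffects",
    "InvalidConfigError",
    "DegenerateSimulationError",
    "simulate_genotypes",
    "simulate_annotation",
    "simulate_phenotypes",
    "simulate_model_sumstats",
    "implied_rg",
    "subset_individuals",
]

# Stage tags mixed into the seed stream so each operation draws from its own
# deterministic substream, independent of call order.
_SEED_GENOTYPES = 11
_SEED_ANNOTATION = 12
_SEED_PHENOTYPES = 13

_NUCLEOTIDES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class InvalidConfigError(ValueError):
    """A SimulationConfig field is outside its admissible range."""


class DegenerateSimulationError(RuntimeError):
    """The configured simulation cannot produce the requested structure."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate a UK-Biobank-style SARS-CoV-2-positive cohort: ~6000
    individuals aged 52-83, a hospitalisation rate near 9%, a heritable
    4-level balding pattern whose marginal distribution matches the
    self-reported 31/23/27/19% split, and hospitalisation risk rising with
    age (log-OR 0.05 per year).
    """

    n_individuals: int = 6000
    n_variants: int = 2000
    n_chromosomes: int = 2
    ld_block_size: int = 10
    within_block_corr: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int = 200
    gene_length_bp: int = 1000
    intergenic_gap_bp: int = 20_000
    n_pathways_per_library: int = 50
    genes_per_pathway: int = 20
    planted_pathway_id: str | None = None
    aga_h2: float = 0.3
    n_causal_variants: int = 50
    planted_causal_fraction: float = 0.2
    aga_age_slope: float = 0.03
    covid_age_log_or: float = 0.05
    shared_effect_size: float = 0.0
    covid_base_rate: float = 0.09
    age_range: tuple[float, float] = (52.0, 83.0)
    aga_pattern_freqs: tuple[float, float, float, float] = (0.31, 0.23, 0.27, 0.19)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidConfigError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.within_block_corr < 1.0):
            raise InvalidConfigError(
                f"within_block_corr must lie in [0, 1), got {self.within_block_corr}"
            )
        if not (0.0 <= self.aga_h2 < 1.0):
            raise InvalidConfigError(f"aga_h2 must lie in [0, 1), got {self.aga_h2}")
        if self.genes_per_pathway > self.n_genes:
            raise InvalidConfigError(
                f"genes_per_pathway ({self.genes_per_pathway}) exceeds n_genes ({self.n_genes})"
            )
        for name in ("n_individuals", "n_variants", "n_chromosomes", "ld_block_size"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be a positive count")
        if not np.isclose(sum(self.aga_pattern_freqs), 1.0):
            raise InvalidConfigError("aga_pattern_freqs must sum to 1")
        if not (0.0 < self.covid_base_rate < 1.0):
            raise InvalidConfigError("covid_base_rate must lie in (0, 1)")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with variant and sample metadata.

    ``dosages`` holds effect-allele counts in {0, 1, 2}; -1 marks a missing
    genotype (possible only in data read from VCF, never in simulated output).
    ``variants`` has columns id, chrom, pos, coded_allele, other_allele with
    1-based positions strictly increasing within each chromosome.
    ``samples`` has columns individual_id and sex ("male"/"female").
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def validate(self) -> None:
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage matrix shape does not match metadata")
        vals = np.unique(self.dosages)
        if not np.isin(vals, [-1, 0, 1, 2]).all():
            raise ValueError("dosages must be in {0,1,2} (-1 for missing)")
        if (self.variants["coded_allele"] == self.variants["other_allele"]).any():
            raise ValueError("coded_allele equals other_allele for some variant")
        for _, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError("positions must be strictly increasing within chromosome")


@dataclass
class GeneSetLibrary:
    """A named collection of pathways, each a set of gene identifiers."""

    library_name: str
    pathways: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {name!r} in {self.library_name!r} is empty")


@dataclass
class TrueEffects:
    """Generating-model ground truth for parameter-recovery tests.

    Effect vectors are indexed like the genotype variant table and expressed
    per standardised-genotype unit. ``shared_effects`` is exactly zero at
    every variant not positionally mapped (< 10 kb) to a planted-pathway gene.
    """

    aga_effects: np.ndarray
    shared_effects: np.ndarray
    planted_pathway: str | None
    variance_components: dict[str, float]


# ---------------------------------------------------------------------------
# genotypes


def _variant_layout(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign variants to chromosomes with evenly spaced 1-based positions.

    The chromosome span is derived from the gene tiling so variants and the
    annotation share a coordinate frame.
    """
    period = config.gene_length_bp + config.intergenic_gap_bp
    genes_per_chrom = -(-config.n_genes // config.n_chromosomes)  # ceil
    span = genes_per_chrom * period
    per_chrom = np.full(config.n_chromosomes, config.n_variants // config.n_chromosomes)
    per_chrom[: config.n_variants % config.n_chromosomes] += 1
    rows = []
    j = 0
    for c, m in enumerate(per_chrom, start=1):
        if m == 0:
            continue
        spacing = max(1, span // (m + 1))
        for k in range(m):
            rows.append((f"snp_{j:06d}", str(c), (k + 1) * spacing))
            j += 1
    variants = pd.DataFrame(rows, columns=["id", "chrom", "pos"])
    coded = rng.choice(4, size=len(variants))
    # other allele drawn from the two non-complement bases so simulated
    # variants are never strand-ambiguous (A/T, C/G)
    other = np.empty(len(variants), dtype="<U1")
    for i, c in enumerate(coded):
        base = _NUCLEOTIDES[c]
        choices = [b for b in _NUCLEOTIDES if b != base and b != _COMPLEMENT[base]]
        other[i] = choices[rng.integers(2)]
    variants["coded_allele"] = _NUCLEOTIDES[coded]
    variants["other_allele"] = other
    return variants


def _block_slices(chrom_sizes: Sequence[int], block_size: int) -> list[slice]:
    """Contiguous LD blocks per chromosome; a short final block is allowed."""
    out, start = [], 0
    for m in chrom_sizes:
        for b in range(0, m, block_size):
            out.append(slice(start + b, start + min(b + block_size, m)))
        start += m
    return out


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw a diploid dosage matrix with equicorrelated-block LD.

    Per variant j a frequency f_j is uniform on ``maf_range``. Within each
    block of ``ld_block_size`` consecutive variants, latent per-haplotype
    Gaussians share pairwise correlation ``within_block_corr`` and are
    thresholded at the (1 - f_j) quantile to give carrier alleles; the dosage
    is the sum of two independent haplotypes. Blocks are mutually independent,
    so within-block r^2 is tunable while between-block r^2 is ~0.
    """
    rng = np.random.default_rng([_SEED_GENOTYPES, config.seed])
    variants = _variant_layout(config, rng)
    n, m = config.n_individuals, config.n_variants
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    thresholds = stats.norm.ppf(1.0 - freqs)

    chrom_sizes = variants.groupby("chrom", sort=False).size().tolist()
    blocks = _block_slices(chrom_sizes, config.ld_block_size)
    rho = config.within_block_corr
    dosages = np.zeros((n, m), dtype=np.int8)
    for _ in range(2):  # two independent haplotypes
        latent = np.empty((n, m))
        for sl in blocks:
            width = sl.stop - sl.start
            shared = rng.standard_normal((n, 1))
            eps = rng.standard_normal((n, width))
            latent[:, sl] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps
        dosages += (latent > thresholds).astype(np.int8)

    sex = np.where(rng.random(n) < 0.5, "male", "female")
    samples = pd.DataFrame(
        {"individual_id": [f"ind_{i:06d}" for i in range(n)], "sex": sex}
    )
    variants["maf"] = freqs
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


# ---------------------------------------------------------------------------
# annotation and gene-set libraries

_LIBRARY_NAMES = ("kegg_2019_like", "wikipathways_2019_like", "panther_2016_like")


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[GeneSetLibrary]]:
    """Tile non-overlapping genes and draw three random gene-set libraries.

    Genes have fixed length and a fixed intergenic gap, split evenly across
    chromosomes: gene k on a chromosome spans
    ``[1 + k*(len+gap), k*(len+gap) + len]`` (1-based, inclusive). Each of the
    three libraries holds ``n_pathways_per_library`` random gene subsets; when
    ``planted_pathway_id`` is set, the first library's first pathway carries
    that name (its member genes are the planted genes).
    """
    if config.genes_per_pathway > config.n_genes:
        raise InvalidConfigError("genes_per_pathway exceeds n_genes")
    rng = np.random.default_rng([_SEED_ANNOTATION, config.seed])
    period = config.gene_length_bp + config.intergenic_gap_bp
    genes_per_chrom = -(-config.n_genes // config.n_chromosomes)

    rows = []
    for g in range(config.n_genes):
        chrom = str(g // genes_per_chrom + 1)
        k = g % genes_per_chrom
        start = 1 + k * period
        rows.append((f"gene_{g:04d}", chrom, start, start + config.gene_length_bp - 1))
    annotation = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])

    gene_ids = annotation["gene_id"].to_numpy()
    libraries: list[GeneSetLibrary] = []
    for li, lib_name in enumerate(_LIBRARY_NAMES):
        pathways: dict[str, frozenset[str]] = {}
        for p in range(config.n_pathways_per_library):
            members = frozenset(
                rng.choice(gene_ids, size=config.genes_per_pathway, replace=False)
            )
            if li == 0 and p == 0 and config.planted_pathway_id is not None:
                pathways[config.planted_pathway_id] = members
            else:
                pathways[f"{lib_name}_pw_{p:03d}"] = members
        libraries.append(GeneSetLibrary(library_name=lib_name, pathways=pathways))
    return annotation, libraries


# ---------------------------------------------------------------------------
# phenotypes


def _standardize_columns(dosages: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Center/scale dosage columns by their Hardy-Weinberg moments 2f, 2f(1-f)."""
    sd = np.sqrt(2.0 * freqs * (1.0 - freqs))
    sd = np.where(sd > 0, sd, 1.0)
    return (dosages - 2.0 * freqs) / sd


def _planted_variant_mask(
    genotypes: GenotypeMatrix,
    annotation: pd.DataFrame,
    libraries: Sequence[GeneSetLibrary],
    planted_id: str,
) -> np.ndarray:
    from .pathways import map_snps_to_genes  # local import; no cycle

    planted_genes: frozenset[str] | None = None
    for lib in libraries:
        if planted_id in lib.pathways:
            planted_genes = lib.pathways[planted_id]
            break
    if planted_genes is None:
        raise InvalidConfigError(
            f"planted pathway {planted_id!r} not found in any generated library"
        )
    sub = annotation[annotation["gene_id"].isin(planted_genes)]
    snp_map = map_snps_to_genes(genotypes.variants, sub, window_bp=10_000)
    mapped_ids = set(snp_map.variant_to_genes)
    return genotypes.variants["id"].isin(mapped_ids).to_numpy()


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    annotation: pd.DataFrame,
    libraries: Sequence[GeneSetLibrary],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, TrueEffects]:
    """Generate ages, the ordinal balding pattern, and the COVID outcome.

    Male balding liability = sqrt(h2) * standardised genome-wide genetic score
    + ``aga_age_slope`` x centred assessment age + sqrt(1-h2) Gaussian noise;
    the 4-level pattern comes from three fixed liability thresholds placed at
    the quantiles implied by ``aga_pattern_freqs`` (liability variance is
    computed analytically, so the marginal frequencies are approximate).
    Hospitalisation is Bernoulli under a logistic model whose intercept is
    tuned so the mean risk equals ``covid_base_rate``, with a per-year age
    effect and, when a pathway is planted, ``shared_effect_size`` log-odds per
    SD of the standardised planted-pathway genetic score. Every individual in
    the cohort is SARS-CoV-2 positive; females carry no balding pattern.
    """
    rng = np.random.default_rng([_SEED_PHENOTYPES, config.seed])
    n = genotypes.n_individuals
    m = genotypes.n_variants
    lo, hi = config.age_range
    age_assess = rng.uniform(lo, hi, size=n)
    age_event = age_assess + rng.uniform(0.0, 8.0, size=n)
    is_male = (genotypes.samples["sex"] == "male").to_numpy()

    freqs = genotypes.variants["maf"].to_numpy()
    planted_mask = np.zeros(m, dtype=bool)
    if config.planted_pathway_id is not None:
        planted_mask = _planted_variant_mask(
            genotypes, annotation, libraries, config.planted_pathway_id
        )
        if not planted_mask.any():
            raise DegenerateSimulationError(
                f"no variant maps within 10 kb of planted pathway "
                f"{config.planted_pathway_id!r} genes"
            )

    # Causal architecture: n_causal_variants effects drawn genome-wide; when a
    # pathway is planted, a fixed share of them is forced into its mapped
    # variants so the shared component is aligned with the AGA weights there.
    n_causal = min(config.n_causal_variants, m)
    causal_idx: np.ndarray
    if config.planted_pathway_id is not None:
        planted_idx = np.flatnonzero(planted_mask)
        k_planted = min(
            len(planted_idx), max(1, round(config.planted_causal_fraction * n_causal))
        )
        chosen_planted = rng.choice(planted_idx, size=k_planted, replace=False)
        rest_pool = np.flatnonzero(~planted_mask)
        chosen_rest = rng.choice(
            rest_pool, size=min(n_causal - k_planted, len(rest_pool)), replace=False
        )
        causal_idx = np.sort(np.concatenate([chosen_planted, chosen_rest]))
    else:
        causal_idx = np.sort(rng.choice(m, size=n_causal, replace=False))

    weights = np.zeros(m)
    weights[causal_idx] = rng.standard_normal(len(causal_idx))

    x_std = _standardize_columns(genotypes.dosages, freqs)
    raw_score = x_std @ weights
    score_sd = raw_score.std()
    genetic = (raw_score - raw_score.mean()) / (score_sd if score_sd > 0 else 1.0)

    # liability and ordinal pattern (males only)
    age_c = age_assess - age_assess.mean()
    noise = rng.standard_normal(n)
    liability = (
        np.sqrt(config.aga_h2) * genetic
        + config.aga_age_slope * age_c
        + np.sqrt(1.0 - config.aga_h2) * noise
    )
    var_liab = 1.0 + config.aga_age_slope**2 * (hi - lo) ** 2 / 12.0
    cum = np.cumsum(config.aga_pattern_freqs)[:3]
    thresholds = np.sqrt(var_liab) * stats.norm.ppf(cum)
    pattern = 1 + (liability[:, None] > thresholds[None, :]).sum(axis=1)
    aga_pattern = np.where(is_male, pattern.astype(float), np.nan)

    # shared planted-pathway genetic score for the COVID outcome
    shared_weights = np.where(planted_mask, weights, 0.0)
    if config.shared_effect_size != 0.0 and config.planted_pathway_id is not None:
        raw_shared = x_std @ shared_weights
        ssd = raw_shared.std()
        if ssd == 0:
            raise DegenerateSimulationError(
                "planted-pathway genetic score has zero variance"
            )
        shared_score = (raw_shared - raw_shared.mean()) / ssd
    else:
        shared_score = np.zeros(n)

    eta_rest = config.covid_age_log_or * (
        age_event - age_event.mean()
    ) + config.shared_effect_size * shared_score

    def mean_rate(b0: float) -> float:
        return float(special.expit(b0 + eta_rest).mean()) - config.covid_base_rate

    b0 = optimize.brentq(mean_rate, -30.0, 30.0)
    hospitalized = rng.random(n) < special.expit(b0 + eta_rest)

    phenotypes = pd.DataFrame(
        {
            "individual_id": genotypes.samples["individual_id"].to_numpy(),
            "sex": genotypes.samples["sex"].to_numpy(),
            "age_at_assessment": age_assess,
            "age_at_event": age_event,
            "aga_pattern": aga_pattern,
            "sars_cov2_positive": np.ones(n, dtype=bool),
            "hospitalized": hospitalized,
        }
    )
    effects = TrueEffects(
        aga_effects=np.sqrt(config.aga_h2) * weights / (score_sd if score_sd > 0 else 1.0),
        shared_effects=config.shared_effect_size * shared_weights,
        planted_pathway=config.planted_pathway_id,
        variance_components={
            "aga_genetic": config.aga_h2,
            "aga_age": config.aga_age_slope**2 * (hi - lo) ** 2 / 12.0,
            "aga_noise": 1.0 - config.aga_h2,
            "covid_intercept": b0,
        },
    )
    return phenotypes, effects


def subset_individuals(genotypes: GenotypeMatrix, idx: np.ndarray) -> GenotypeMatrix:
    """Row-subset of a genotype matrix (e.g. one sex stratum)."""
    return GenotypeMatrix(
        dosages=genotypes.dosages[idx],
        variants=genotypes.variants,
        samples=genotypes.samples.iloc[idx].reset_index(drop=True),
    )


def implied_rg(effects: TrueEffects) -> float:
    """Generating-model genetic correlation between the two traits.

    With per-standardised-genotype effect vectors a (balding) and s (shared
    COVID component), rg = <a, s> / (||a|| ||s||); 0 when no shared component
    was planted. Because the shared effects are the balding effects restricted
    to planted-pathway variants and rescaled, this equals the signed square
    root of the planted share of the balding heritability.
    """
    a, s = effects.aga_effects, effects.shared_effects
    na, ns = np.linalg.norm(a), np.linalg.norm(s)
    if na == 0 or ns == 0:
        return 0.0
    return float(np.dot(a, s) / (na * ns))


# ---------------------------------------------------------------------------
# model-consistent summary statistics (bivariate LD score regression model)


def simulate_model_sumstats(
    m_variants: int,
    ld_scores: np.ndarray,
    n1: int,
    n2: int,
    h2_1: float,
    h2_2: float,
    rg: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw paired GWAS z-scores from the bivariate LD score regression model.

    Per variant j with LD score l_j, the z-score pair is bivariate normal with
    Var(z_ij) = 1 + n_i h2_i l_j / M and
    Cov(z_1j, z_2j) = sqrt(n1 n2) rg sqrt(h2_1 h2_2) l_j / M
    (no sample-overlap term). Betas and standard errors are back-filled
    assuming unit phenotypic variance: se_i = 1/sqrt(n_i), beta = z * se.
    """
    ld_scores = np.asarray(ld_scores, dtype=float)
    if ld_scores.shape != (m_variants,):
        raise ValueError("ld_scores must have length m_variants")
    if (ld_scores <= 0).any():
        raise ValueError("ld_scores must be positive")
    for h2 in (h2_1, h2_2):
        if not (0.0 <= h2 < 1.0):
            raise ValueError(f"h2 must lie in [0, 1), got {h2}")
    if abs(rg) > 1.0:
        raise ValueError(f"|rg| must be <= 1, got {rg}")

    rng = np.random.default_rng(seed)
    lm = ld_scores / m_variants
    v1 = 1.0 + n1 * h2_1 * lm
    v2 = 1.0 + n2 * h2_2 * lm
    cov = np.sqrt(n1 * n2) * rg * np.sqrt(h2_1 * h2_2) * lm
    bad = cov**2 > v1 * v2 + 1e-12
    if bad.any():
        j = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"implied z-score covariance matrix not positive semi-definite at "
            f"variant index {j} (l_j={ld_scores[j]:.4g})"
        )
    a = rng.standard_normal(m_variants)
    b = rng.standard_normal(m_variants)
    z1 = np.sqrt(v1) * a
    z2 = cov / np.sqrt(v1) * a + np.sqrt(v2 - cov**2 / v1) * b

    def _table(z: np.ndarray, n: int) -> pd.DataFrame:
        se = np.full(m_variants, 1.0 / np.sqrt(n))
        return pd.DataFrame(
            {
                "id": [f"snp_{j:06d}" for j in range(m_variants)],
                "chrom": "1",
                "pos": np.arange(1, m_variants + 1) * 1000,
                "effect_allele": "A",
                "other_allele": "G",
                "beta": z * se,
                "se": se,
                "z": z,
                "p": 2.0 * stats.norm.sf(np.abs(z)),
                "n": n,
            }
        )

    return _table(z1, n1), _table(z2, n2)
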