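"""Polygenic risk scores in sum-calculation mode.

A PRS is the per-individual sum of GWAS effect sizes times effect-allele
dosages over variants passing a p-value threshold (defaults 5e-8 and 5e-5,
strict "<"), optionally after greedy LD clumping. Association with the binary
outcome is tested per sex by logistic regression of hospitalisation on the
standardised score with age at event as a covariate; weights are never
re-fitted on the phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import SeparationError, fit_logit
from .simulate import GenotypeMatrix

__all__ = [
    "PrsConfig",
    "PrsResult",
    "PrsAssociationResult",
    "select_variants",
    "ld_clump",
    "compute_prs",
    "associate_prs",
]

logger = logging.getLogger(__name__)

_X_CHROMS = {"X", "23", "chrX"}


@dataclass(frozen=True)
class PrsConfig:
    """Scoring options.

    ``male_x_dosage`` controls hemizygous male coding on the X chromosome:
    ``"zero_two"`` keeps the diploid-style 0/2 coding, ``"zero_one"`` halves
    male X dosages to count a single allele copy.
    """

    p_thresholds: tuple[float, ...] = (5e-8, 5e-5)
    clump_enabled: bool = True
    clump_r2: float = 0.1
    clump_window_bp: int = 250_000
    include_x: bool = True
    male_x_dosage: str = "zero_two"

    def __post_init__(self) -> None:
        if any(not (0.0 < t <= 1.0) for t in self.p_thresholds):
            raise ValueError("p thresholds must lie in (0, 1]")
        if not (0.0 < self.clump_r2 <= 1.0):
            raise ValueError("clump_r2 must lie in (0, 1]")
        if self.male_x_dosage not in ("zero_two", "zero_one"):
            raise ValueError("male_x_dosage must be 'zero_two' or 'zero_one'")


@dataclass
class PrsResult:
    """Per-individual scores plus provenance of the variants used."""

    scores: pd.Series  # indexed by individual_id
    n_variants_used: int
    threshold: float | None
    variant_ids: list[str] = field(repr=False)
    n_dropped_absent: int = 0
    n_missing_dosage: int = 0


@dataclass(frozen=True)
class PrsAssociationResult:
    sex: str
    threshold: float | None
    beta: float
    se: float
    p: float
    n_cases: int
    n_controls: int


def select_variants(sumstats: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Variants with p strictly below the threshold; missing p excluded."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    out = sumstats[sumstats["p"].notna() & (sumstats["p"] < threshold)].reset_index(
        drop=True
    )
    if out.empty:
        logger.warning("no variants pass p < %g; downstream PRS will be all-zero", threshold)
    return out


def ld_clump(
    subset: pd.DataFrame,
    genotypes: GenotypeMatrix,
    clump_r2: float = 0.1,
    clump_window_bp: int = 250_000,
) -> pd.DataFrame:
    """Greedy LD clumping of a thresholded variant subset.

    Repeatedly takes the unclaimed variant with the smallest p as an index
    variant and claims all unclaimed variants on the same chromosome within
    ``clump_window_bp`` whose dosage r^2 with the index is >= ``clump_r2``.
    Ties in p break by (chromosome, position), so the result is
    deterministic. Returns the retained rows in their input order.
    """
    if subset.empty:
        return subset.copy()
    geno_idx = pd.Series(
        np.arange(genotypes.n_variants), index=genotypes.variants["id"]
    )
    present = subset["id"].isin(geno_idx.index)
    if not present.all():
        raise ValueError("genotypes do not cover the variant subset to clump")

    cols = geno_idx[subset["id"]].to_numpy()
    X = genotypes.dosages[:, cols].astype(float)
    X = np.where(X < 0, np.nan, X)
    mu = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mu[None, :], X)
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    n = X.shape[0]

    order = subset.reset_index(drop=True).sort_values(
        ["p", "chrom", "pos"], kind="mergesort"
    )
    chrom = subset["chrom"].to_numpy()
    pos = subset["pos"].to_numpy(dtype=np.int64)
    unclaimed = np.ones(len(subset), dtype=bool)
    retained = np.zeros(len(subset), dtype=bool)
    for i in order.index:
        if not unclaimed[i]:
            continue
        unclaimed[i] = False
        retained[i] = True
        near = (
            unclaimed
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= clump_window_bp)
        )
        if near.any():
            r = (Z[:, near].T @ Z[:, i]) / n
            claim = np.flatnonzero(near)[r**2 >= clump_r2]
            unclaimed[claim] = False
    return subset.reset_index(drop=True)[retained].reset_index(drop=True)


def _effective_dosages(
    genotypes: GenotypeMatrix, cols: np.ndarray, config: PrsConfig
) -> tuple[np.ndarray, np.ndarray, int]:
    """Dosage block for scoring with X-chromosome male coding applied.

    Returns (dosages, kept_col_mask, n_missing) where missing entries are
    zeroed (they contribute nothing to the sum) and counted.
    """
    chroms = genotypes.variants["chrom"].to_numpy()[cols]
    on_x = np.isin(chroms, list(_X_CHROMS))
    keep = np.ones(len(cols), dtype=bool)
    if not config.include_x:
        keep &= ~on_x
    D = genotypes.dosages[:, cols[keep]].astype(float)
    miss = D < 0
    n_missing = int(miss.sum())
    D[miss] = 0.0
    if config.male_x_dosage == "zero_one":
        male = (genotypes.samples["sex"] == "male").to_numpy()
        x_cols = on_x[keep]
        if x_cols.any() and male.any():
            D[np.ix_(male, x_cols)] /= 2.0
    return D, keep, n_missing


def compute_prs(
    genotypes: GenotypeMatrix,
    scored_variants: pd.DataFrame,
    config: PrsConfig = PrsConfig(),
    threshold: float | None = None,
) -> PrsResult:
    """Sum-calculation-mode score: score_i = sum_j beta_j x dosage_ij.

    ``scored_variants`` is a (thresholded, optionally clumped) summary-
    statistic subset whose alleles are assumed harmonised to the genotype
    coding; a variant whose effect allele matches the genotype's *other*
    allele is still usable (its beta is applied to the complementary dosage
    orientation by negation, shifting all scores by a constant). Variants
    absent from the genotypes are dropped and counted; missing dosages
    contribute 0 and are counted.
    """
    geno = genotypes.variants
    idx = pd.Series(np.arange(len(geno)), index=geno["id"])
    present_mask = scored_variants["id"].isin(idx.index).to_numpy()
    n_dropped = int((~present_mask).sum())
    if n_dropped:
        logger.info("compute_prs: %d scored variants absent from genotypes", n_dropped)
    sub = scored_variants[present_mask].reset_index(drop=True)
    if sub.empty:
        scores = pd.Series(
            np.zeros(genotypes.n_individuals),
            index=genotypes.samples["individual_id"],
            name="prs",
        )
        return PrsResult(scores, 0, threshold, [], n_dropped, 0)

    cols = idx[sub["id"]].to_numpy()
    coded = geno["coded_allele"].to_numpy()[cols]
    other = geno["other_allele"].to_numpy()[cols]
    eff = sub["effect_allele"].to_numpy()
    sign = np.where(eff == coded, 1.0, np.where(eff == other, -1.0, np.nan))
    bad = np.isnan(sign)
    if bad.any():
        logger.warning(
            "compute_prs: %d variants with irreconcilable alleles dropped", bad.sum()
        )
    keep_allele = ~bad
    sub = sub[keep_allele].reset_index(drop=True)
    cols = cols[keep_allele]
    sign = sign[keep_allele]

    D, keep_x, n_missing = _effective_dosages(genotypes, cols, config)
    betas = (sub["beta"].to_numpy() * sign)[keep_x]
    raw = D @ betas
    scores = pd.Series(raw, index=genotypes.samples["individual_id"], name="prs")
    used = sub["id"].to_numpy()[keep_x].tolist()
    return PrsResult(
        scores=scores,
        n_variants_used=len(used),
        threshold=threshold,
        variant_ids=used,
        n_dropped_absent=n_dropped + int(bad.sum()),
        n_missing_dosage=n_missing,
    )


def associate_prs(
    prs: PrsResult, phenotypes: pd.DataFrame, sex: str
) -> PrsAssociationResult:
    """Logistic regression of hospitalisation on the standardised score.

    Fits hospitalised ~ intercept + z(PRS) + age_at_event within the given
    sex stratum; the reported beta is log-odds per PRS standard deviation.
    """
    stratum = phenotypes[phenotypes["sex"] == sex].set_index("individual_id")
    common = stratum.index.intersection(prs.scores.index)
    stratum = stratum.loc[common]
    score = prs.scores.loc[common].to_numpy(float)
    y = stratum["hospitalized"].to_numpy(float)
    n_cases = int(y.sum())
    n_controls = len(y) - n_cases
    if n_cases == 0 or n_controls == 0:
        raise ValueError(f"need at least one case and one control among {sex}s")
    sd = score.std()
    if sd == 0:
        raise ValueError("PRS has zero variance in this stratum; association undefined")
    z = (score - score.mean()) / sd
    X = np.column_stack([np.ones(len(y)), z, stratum["age_at_event"].to_numpy(float)])
    try:
        fit = fit_logit(y, X)
    except SeparationError as exc:
        raise SeparationError(f"PRS association failed in {sex} stratum: {exc}") from exc
    return PrsAssociationResult(
        sex=sex,
        threshold=prs.threshold,
        beta=float(fit.params[1]),
        se=float(fit.se[1]),
        p=float(fit.pvalues[1]),
        n_cases=n_cases,
        n_controls=n_controls,
    )
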