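"""LD score regression: heritability and cross-trait genetic correlation.

Implements the LD score regression estimator directly rather than shelling
out to an external tool. Per-variant LD scores l_j are sums of squared
dosage correlations within a physical window. Single-trait heritability is
the slope of a weighted regression of chi-square statistics on N l_j / M
with a free intercept; genetic covariance is the slope of z1 z2 on
sqrt(N1 N2) l_j / M, and the genetic correlation is
rg = gencov / sqrt(h2_1 h2_2). Standard errors come from a leave-one-block-out
jackknife over contiguous variant blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GenotypeMatrix

__all__ = [
    "LdscResult",
    "H2Result",
    "compute_ld_scores",
    "estimate_h2",
    "estimate_rg",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class H2Result:
    h2: float
    intercept: float
    se_h2: float
    se_intercept: float
    m: int
    n_blocks: int


@dataclass(frozen=True)
class LdscResult:
    """Cross-trait LD score regression output.

    ``rg`` is None (with ``reason``) when either heritability estimate is
    non-positive, in which case the genetic correlation is undefined; the
    component estimates are still reported.
    """

    h2_trait1: float
    h2_trait2: float
    gencov: float
    rg: float | None
    se_rg: float | None
    intercept1: float
    intercept2: float
    intercept_cross: float
    p: float | None
    m: int
    n_blocks: int
    reason: str | None = None
    jackknife_rg: tuple[float, ...] | None = None  # per-block delete estimates


# ---------------------------------------------------------------------------
# LD scores


def compute_ld_scores(
    genotypes: GenotypeMatrix, window_bp: int, adjusted: bool = False
) -> pd.DataFrame:
    """Per-variant LD scores within a physical window.

    l_j = sum over variants k on the same chromosome with |pos_k - pos_j| <=
    window_bp of r^2_{jk}, including k = j, so l_j >= 1 for polymorphic
    variants under the unadjusted estimator. With ``adjusted=True`` the
    finite-sample bias correction r^2 - (1 - r^2)/(n - 2) is applied to each
    term. Monomorphic variants get all correlations set to 0 (l_j counts only
    the self term, kept at 1) and are flagged in the ``flag`` column.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    n = genotypes.n_individuals
    if n < 2:
        raise ValueError("need at least 2 individuals to estimate correlations")
    if adjusted and n < 3:
        raise ValueError("bias adjustment requires at least 3 individuals")

    X = genotypes.dosages.astype(float)
    X = np.where(X < 0, np.nan, X)
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean[None, :], X)
    sd = X.std(axis=0)
    mono = sd == 0

    variants = genotypes.variants
    l2 = np.empty(genotypes.n_variants)
    for _, idx in variants.groupby("chrom", sort=False).indices.items():
        pos = variants["pos"].to_numpy()[idx]
        sub = X[:, idx]
        sub_sd = sd[idx]
        Z = (sub - sub.mean(axis=0)) / np.where(sub_sd > 0, sub_sd, 1.0)
        r = (Z.T @ Z) / n
        r2 = r**2
        if adjusted:
            r2 = r2 - (1.0 - r2) / (n - 2)
        sub_mono = mono[idx]
        r2[sub_mono, :] = 0.0
        r2[:, sub_mono] = 0.0
        np.fill_diagonal(r2, 1.0)
        in_window = np.abs(pos[:, None] - pos[None, :]) <= window_bp
        l2[idx] = (r2 * in_window).sum(axis=1)

    out = variants[["id", "chrom", "pos"]].copy()
    out["l2"] = l2
    out["flag"] = np.where(mono, "monomorphic", "")
    out.attrs["window_bp"] = window_bp
    out.attrs["adjusted"] = adjusted
    return out


# ---------------------------------------------------------------------------
# regressions


def _wls(y: np.ndarray, x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of y on [1, x]; returns (slope, intercept)."""
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError(
            "regressor has zero variance (all N*l/M identical): slope unidentified"
        )
    W = np.sqrt(w)
    A = np.column_stack([W, W * x])
    coef, *_ = np.linalg.lstsq(A, W * y, rcond=None)
    return float(coef[1]), float(coef[0])


def _block_bounds(m: int, n_blocks: int) -> list[tuple[int, int]]:
    edges = np.linspace(0, m, min(n_blocks, m) + 1).astype(int)
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:]) if b > a]


def _jackknife_se(estimates: np.ndarray) -> float:
    b = len(estimates)
    theta_bar = estimates.mean()
    return float(np.sqrt((b - 1) / b * ((estimates - theta_bar) ** 2).sum()))


def _merge_ld(sumstats: pd.DataFrame, ld: pd.DataFrame) -> pd.DataFrame:
    merged = sumstats.merge(ld[["id", "l2"]], on="id", how="inner")
    merged = merged[merged["z"].notna()].reset_index(drop=True)
    if len(merged) < 50:
        raise ValueError(
            f"only {len(merged)} variants overlap between summary statistics "
            "and LD scores; need at least 50"
        )
    return merged


def estimate_h2(
    sumstats: pd.DataFrame,
    ld: pd.DataFrame,
    n_blocks: int = 50,
    weighted: bool = True,
) -> H2Result:
    """Single-trait LD score regression.

    Regresses chi2_j = z_j^2 on N_j l_j / M with a free intercept; the slope
    is the SNP heritability attributable to the M overlapping variants, and
    the intercept captures uniform inflation (confounding). Weights default
    to 1/max(l_j, 1); jackknife SEs use ``n_blocks`` contiguous blocks.
    """
    d = _merge_ld(sumstats, ld)
    m = len(d)
    chi2 = d["z"].to_numpy() ** 2
    x = d["n"].to_numpy(float) * d["l2"].to_numpy() / m
    w = 1.0 / np.maximum(d["l2"].to_numpy(), 1.0) if weighted else np.ones(m)

    slope, intercept = _wls(chi2, x, w)
    bounds = _block_bounds(m, n_blocks)
    jk = np.empty((len(bounds), 2))
    for i, (a, b) in enumerate(bounds):
        keep = np.ones(m, dtype=bool)
        keep[a:b] = False
        jk[i] = _wls(chi2[keep], x[keep], w[keep])
    return H2Result(
        h2=slope,
        intercept=intercept,
        se_h2=_jackknife_se(jk[:, 0]),
        se_intercept=_jackknife_se(jk[:, 1]),
        m=m,
        n_blocks=len(bounds),
    )


def estimate_rg(
    sumstats1: pd.DataFrame,
    sumstats2: pd.DataFrame,
    ld: pd.DataFrame,
    n_blocks: int = 50,
    weighted: bool = True,
) -> LdscResult:
    """Cross-trait LD score regression with a block-jackknife SE on rg.

    Both tables must already be harmonised to a common effect-allele
    orientation. The cross-trait slope regression of z1_j z2_j on
    sqrt(N1_j N2_j) l_j / M estimates the genetic covariance;
    rg = gencov / sqrt(h2_1 h2_2). All intercepts are free. The jackknife
    recomputes the full rg (both heritabilities and the covariance) per
    leave-one-block-out sample; the two-sided p tests rg = 0 against a
    normal reference.
    """
    merged = sumstats1.merge(
        sumstats2[["id", "z", "n"]], on="id", suffixes=("_1", "_2")
    ).rename(columns={"z": "z_2", "n": "n_2", "z_1": "z_1", "n_1": "n_1"})
    if "z_1" not in merged.columns:  # suffix applied only on collision
        merged = merged.rename(columns={"z": "z_1", "n": "n_1"})
    d = _merge_ld(
        merged[merged["z_1"].notna() & merged["z_2"].notna()].assign(
            z=lambda f: f["z_1"]
        ),
        ld,
    )
    m = len(d)
    z1, z2 = d["z_1"].to_numpy(), d["z_2"].to_numpy()
    n1, n2 = d["n_1"].to_numpy(float), d["n_2"].to_numpy(float)
    l2 = d["l2"].to_numpy()
    w = 1.0 / np.maximum(l2, 1.0) if weighted else np.ones(m)

    x1 = n1 * l2 / m
    x2 = n2 * l2 / m
    xc = np.sqrt(n1 * n2) * l2 / m

    def _all_three(keep: np.ndarray) -> tuple[float, float, float, float, float, float]:
        h2_1, i1 = _wls(z1[keep] ** 2, x1[keep], w[keep])
        h2_2, i2 = _wls(z2[keep] ** 2, x2[keep], w[keep])
        gc, ic = _wls((z1 * z2)[keep], xc[keep], w[keep])
        return h2_1, h2_2, gc, i1, i2, ic

    full = np.ones(m, dtype=bool)
    h2_1, h2_2, gencov, i1, i2, ic = _all_three(full)

    if h2_1 <= 0 or h2_2 <= 0:
        reason = (
            f"genetic correlation undefined: non-positive heritability estimate "
            f"(h2_1={h2_1:.4g}, h2_2={h2_2:.4g})"
        )
        logger.warning(reason)
        return LdscResult(
            h2_trait1=h2_1, h2_trait2=h2_2, gencov=gencov, rg=None, se_rg=None,
            intercept1=i1, intercept2=i2, intercept_cross=ic, p=None,
            m=m, n_blocks=0, reason=reason,
        )

    rg = gencov / np.sqrt(h2_1 * h2_2)
    bounds = _block_bounds(m, n_blocks)
    jk = []
    dropped = 0
    for a, b in bounds:
        keep = np.ones(m, dtype=bool)
        keep[a:b] = False
        h1_i, h2_i, gc_i, *_ = _all_three(keep)
        if h1_i <= 0 or h2_i <= 0:
            dropped += 1
            continue
        jk.append(gc_i / np.sqrt(h1_i * h2_i))
    if dropped:
        logger.warning(
            "rg jackknife: %d/%d blocks dropped (non-positive delete-block h2)",
            dropped, len(bounds),
        )
    if len(jk) < 2:
        raise RuntimeError("too few valid jackknife blocks to estimate se(rg)")
    se_rg = _jackknife_se(np.asarray(jk))
    p = float(2.0 * stats.norm.sf(abs(rg) / se_rg)) if se_rg > 0 else np.nan
    return LdscResult(
        h2_trait1=h2_1, h2_trait2=h2_2, gencov=gencov, rg=float(rg),
        se_rg=se_rg, intercept1=i1, intercept2=i2, intercept_cross=ic,
        p=p, m=m, n_blocks=len(jk), jackknife_rg=tuple(float(v) for v in jk),
    )
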