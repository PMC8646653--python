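"""Per-variant association scans and summary-statistic harmonisation.

``run_gwas`` produces GWAS summary statistics (beta, SE, p, z, N per variant)
from a cohort by regressing a phenotype on each variant's dosage plus
covariates, either by ordinary least squares (via the Frisch-Waugh projection,
fully vectorised) or by a batched per-variant Newton-Raphson logistic fit.

``harmonize`` aligns a summary-statistic table to the effect-allele
orientation of a reference (another table or a genotype matrix), flipping
betas where alleles are swapped, resolving strand flips by complementing, and
removing strand-ambiguous (A/T, C/G) and irreconcilable variants.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats

from .simulate import GenotypeMatrix

__all__ = ["run_gwas", "harmonize", "validate_sumstats", "SUMSTAT_COLUMNS"]

logger = logging.getLogger(__name__)

SUMSTAT_COLUMNS = [
    "id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "p", "z", "n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def validate_sumstats(sumstats: pd.DataFrame) -> None:
    """Check the internal summary-statistic contract (se>0, z=beta/se, p~z)."""
    missing = [c for c in SUMSTAT_COLUMNS if c not in sumstats.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    ok = sumstats["beta"].notna()
    if (sumstats.loc[ok, "se"] <= 0).any():
        raise ValueError("summary statistics contain non-positive standard errors")
    z = sumstats.loc[ok, "beta"] / sumstats.loc[ok, "se"]
    if not np.allclose(z, sumstats.loc[ok, "z"], atol=1e-6):
        raise ValueError("z inconsistent with beta/se")
    p_expect = 2.0 * stats.norm.sf(np.abs(sumstats.loc[ok, "z"]))
    rel = np.abs(sumstats.loc[ok, "p"] - p_expect) / np.maximum(p_expect, 1e-300)
    if not (rel[p_expect > 1e-280] < 1e-6 + 1e-6 / np.maximum(p_expect[p_expect > 1e-280], 1e-6)).all():
        if not np.allclose(sumstats.loc[ok, "p"], p_expect, rtol=1e-6, atol=1e-12):
            raise ValueError("p inconsistent with two-sided normal tail of z")


# ---------------------------------------------------------------------------
# association scans


def _linear_scan(
    y: np.ndarray, dosages: np.ndarray, covariates: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-variant OLS slope and SE adjusting for covariates.

    Projects phenotype and dosages onto the orthogonal complement of
    [1, covariates]; the per-variant simple regression on the residualised
    dosage then equals the multiple-regression dosage coefficient.
    """
    n = len(y)
    C = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    X_r = dosages - Q @ (Q.T @ dosages)
    sxx = (X_r**2).sum(axis=0)
    sxy = X_r.T @ y_r
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        dof = n - C.shape[1] - 1
        rss = (y_r**2).sum() - beta * sxy
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / sxx)
    return beta, se


def _logistic_scan(
    y: np.ndarray,
    dosages: np.ndarray,
    covariates: np.ndarray | None,
    max_iter: int = 30,
    tol: float = 1e-8,
    chunk: int = 256,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched per-variant Newton-Raphson logistic fits.

    Each variant gets its own (intercept, dosage, covariates...) fit; the
    Newton updates for all variants in a chunk are performed simultaneously.
    Returns (beta, se, converged) for the dosage coefficient.
    """
    n = len(y)
    C = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    k = C.shape[1] + 1
    m = dosages.shape[1]
    beta_out = np.empty(m)
    se_out = np.empty(m)
    conv = np.zeros(m, dtype=bool)
    for s in range(0, m, chunk):
        G = dosages[:, s : s + chunk]
        mb = G.shape[1]
        # design per variant: [C | g_j]; parameters B (mb, k), dosage coef last
        B = np.zeros((mb, k))
        B[:, 0] = special.logit(np.clip(y.mean(), 1e-9, 1 - 1e-9))
        ok = np.ones(mb, dtype=bool)
        for _ in range(max_iter):
            eta = C @ B[:, :-1].T + G * B[:, -1]
            mu = special.expit(eta)
            w = mu * (1.0 - mu)
            r = y[:, None] - mu
            # gradient blocks
            gC = C.T @ r                          # (k-1, mb)
            gG = (G * r).sum(axis=0)              # (mb,)
            grad = np.vstack([gC, gG]).T          # (mb, k)
            # Hessian blocks
            H = np.empty((mb, k, k))
            wC = w[:, :, None] * C[:, None, :]    # (n, mb, k-1)
            H[:, : k - 1, : k - 1] = np.einsum("na,nmb->mab", C, wC)
            hCG = np.einsum("nm,na->ma", w * G, C)
            H[:, : k - 1, -1] = hCG
            H[:, -1, : k - 1] = hCG
            H[:, -1, -1] = (w * G * G).sum(axis=0)
            try:
                step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                # fall back to per-variant solves, marking singular fits
                step = np.zeros_like(grad)
                for j in range(mb):
                    try:
                        step[j] = np.linalg.solve(H[j], grad[j])
                    except np.linalg.LinAlgError:
                        ok[j] = False
            B += step
            if np.abs(step).max() < tol:
                break
        eta = C @ B[:, :-1].T + G * B[:, -1]
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        H = np.empty((mb, k, k))
        wC = w[:, :, None] * C[:, None, :]
        H[:, : k - 1, : k - 1] = np.einsum("na,nmb->mab", C, wC)
        hCG = np.einsum("nm,na->ma", w * G, C)
        H[:, : k - 1, -1] = hCG
        H[:, -1, : k - 1] = hCG
        H[:, -1, -1] = (w * G * G).sum(axis=0)
        finite = np.isfinite(B).all(axis=1)
        ok &= finite & (np.abs(step).max(axis=1) < 1e-4)
        var = np.full(mb, np.nan)
        for j in range(mb):
            if ok[j]:
                try:
                    var[j] = np.linalg.inv(H[j])[-1, -1]
                except np.linalg.LinAlgError:
                    ok[j] = False
        ok &= var > 0
        beta_out[s : s + chunk] = B[:, -1]
        se_out[s : s + chunk] = np.sqrt(np.where(var > 0, var, np.nan))
        conv[s : s + chunk] = ok
    return beta_out, se_out, conv


def run_gwas(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.Series | pd.DataFrame | None = None,
    model: str = "linear",
) -> pd.DataFrame:
    """Per-variant association scan of a phenotype on dosage plus covariates.

    Parameters
    ----------
    genotypes
        Cohort genotypes; missing dosages (-1) are mean-imputed per variant
        before regression.
    phenotype
        Length-n vector (continuous for ``model="linear"``, 0/1 for
        ``model="logistic"``); must not be constant.
    covariates
        Optional n-vector or n x c matrix (e.g. age) included in every fit.
    model
        ``"linear"`` or ``"logistic"``.

    Returns
    -------
    DataFrame in the internal summary-statistic schema. Monomorphic variants
    are emitted with missing beta and ``flag="monomorphic"``; logistic fits
    that fail to converge are flagged ``"nonconverged"`` and the scan
    continues.
    """
    y = np.asarray(phenotype, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant; GWAS undefined")
    if model not in ("linear", "logistic"):
        raise ValueError(f"unknown model {model!r}")
    covs = None if covariates is None else np.atleast_2d(np.asarray(covariates, float))
    if covs is not None and covs.shape[0] == 1:
        covs = covs.T

    X = genotypes.dosages.astype(float)
    miss = X < 0
    if miss.any():
        col_mean = np.where(
            (~miss).sum(axis=0) > 0,
            np.where(miss, 0, X).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1),
            0.0,
        )
        X = np.where(miss, col_mean[None, :], X)
    mono = X.std(axis=0) == 0

    beta = np.full(genotypes.n_variants, np.nan)
    se = np.full(genotypes.n_variants, np.nan)
    flag = np.where(mono, "monomorphic", "").astype(object)
    poly = ~mono
    if model == "linear":
        b, s = _linear_scan(y, X[:, poly], covs)
        beta[poly], se[poly] = b, s
    else:
        b, s, conv = _logistic_scan(y, X[:, poly], covs)
        beta[poly] = np.where(conv, b, np.nan)
        se[poly] = np.where(conv, s, np.nan)
        idx = np.flatnonzero(poly)[~conv]
        flag[idx] = "nonconverged"
        if len(idx):
            logger.warning("logistic GWAS: %d variants failed to converge", len(idx))

    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    out = genotypes.variants[["id", "chrom", "pos", "coded_allele", "other_allele"]].copy()
    out = out.rename(columns={"coded_allele": "effect_allele"})
    out["beta"] = beta
    out["se"] = se
    out["p"] = 2.0 * stats.norm.sf(np.abs(z))
    out["z"] = z
    out["n"] = len(y)
    out["flag"] = flag
    return out


# ---------------------------------------------------------------------------
# harmonisation


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return a2 == a1.map(_COMPLEMENT)


def _reference_frame(reference: pd.DataFrame | GenotypeMatrix) -> pd.DataFrame:
    if isinstance(reference, GenotypeMatrix):
        ref = reference.variants[["id", "chrom", "pos", "coded_allele", "other_allele"]]
        return ref.rename(columns={"coded_allele": "effect_allele"})
    return reference[["id", "chrom", "pos", "effect_allele", "other_allele"]]


def harmonize(
    target: pd.DataFrame, reference: pd.DataFrame | GenotypeMatrix
) -> pd.DataFrame:
    """Align ``target`` summary statistics to the reference allele orientation.

    Variants are matched by id, with a chromosome+position fallback for ids
    absent from the reference. Aligned variants pass through; swapped-allele
    variants have beta and z negated and alleles swapped; strand flips are
    resolved by complementing. Strand-ambiguous (A/T, C/G) variants and
    variants whose allele pairs cannot be reconciled are removed. Action
    counts are logged and stored in ``result.attrs["harmonization_counts"]``.
    """
    ref = _reference_frame(reference).rename(
        columns={"effect_allele": "ref_a1", "other_allele": "ref_a2"}
    )
    t = target.copy()
    merged = t.merge(ref[["id", "ref_a1", "ref_a2"]], on="id", how="left")
    unmatched = merged["ref_a1"].isna()
    if unmatched.any():
        pos_ref = ref.drop_duplicates(["chrom", "pos"])
        fb = (
            merged.loc[unmatched, ["chrom", "pos"]]
            .merge(pos_ref[["chrom", "pos", "ref_a1", "ref_a2"]], on=["chrom", "pos"], how="left")
        )
        merged.loc[unmatched, ["ref_a1", "ref_a2"]] = fb[["ref_a1", "ref_a2"]].to_numpy()

    counts = {"aligned": 0, "flipped": 0, "strand_flipped": 0,
              "strand_flipped_swapped": 0, "ambiguous_removed": 0,
              "mismatch_removed": 0, "unmatched_removed": 0}

    a1, a2 = merged["effect_allele"], merged["other_allele"]
    r1, r2 = merged["ref_a1"], merged["ref_a2"]
    no_ref = r1.isna()
    palin = _is_palindromic(a1, a2)
    direct = (a1 == r1) & (a2 == r2)
    swapped = (a1 == r2) & (a2 == r1)
    c1, c2 = a1.map(_COMPLEMENT), a2.map(_COMPLEMENT)
    strand = (c1 == r1) & (c2 == r2)
    strand_swap = (c1 == r2) & (c2 == r1)

    keep = ~no_ref & ~palin & (direct | swapped | strand | strand_swap)
    counts["unmatched_removed"] = int(no_ref.sum())
    counts["ambiguous_removed"] = int((palin & ~no_ref).sum())
    counts["mismatch_removed"] = int(
        (~no_ref & ~palin & ~(direct | swapped | strand | strand_swap)).sum()
    )
    counts["aligned"] = int((keep & direct).sum())
    counts["flipped"] = int((keep & swapped).sum())
    counts["strand_flipped"] = int((keep & strand & ~direct).sum())
    counts["strand_flipped_swapped"] = int((keep & strand_swap & ~swapped).sum())

    flip = keep & (swapped | (strand_swap & ~swapped))
    merged.loc[flip, "beta"] = -merged.loc[flip, "beta"]
    if "z" in merged.columns:
        merged.loc[flip, "z"] = -merged.loc[flip, "z"]
    merged.loc[keep, "effect_allele"] = r1[keep]
    merged.loc[keep, "other_allele"] = r2[keep]

    out = merged.loc[keep, target.columns].reset_index(drop=True)
    out.attrs["harmonization_counts"] = counts
    logger.info("harmonize: %s", counts)
    return out
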