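"""Epidemiological stage: cohort summary, age-corrected two-stage regression
of hospitalised COVID-19 on the balding pattern, and prevalence-by-age-group
comparison of severe balding between hospitalised men and a general male
population.

Both the balding pattern and COVID-19 hospitalisation rise with age, so a
naive regression of hospitalisation on pattern is confounded. The two-stage
procedure first residualises the ordinal pattern (treated as numeric 1-4) on
age at assessment by ordinary least squares, then fits a logistic regression
of hospitalisation on those residuals while additionally adjusting for age at
the event (hospitalisation or most recent positive test).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import SeparationError, fit_logit

__all__ = [
    "CohortSummary",
    "AgeCorrectedRegressionResult",
    "DEFAULT_AGE_BINS",
    "SEVERITY_DEFINITIONS",
    "summarize_cohort",
    "residualize_aga_on_age",
    "regress_severity_on_aga",
    "prevalence_by_age_group",
]

logger = logging.getLogger(__name__)

#: Seven age groups spanning 52-83: two narrow groups where the severe-AGA
#: ratio peaks, then 5-year bins, then the 80-83 remainder.
DEFAULT_AGE_BINS: tuple[tuple[int, int], ...] = (
    (52, 54), (55, 59), (60, 64), (65, 69), (70, 74), (75, 79), (80, 83),
)

SEVERITY_DEFINITIONS = ("patterns_3_and_4", "pattern_4_only")


@dataclass(frozen=True)
class CohortSummary:
    n_total: int
    n_male: int
    n_female: int
    n_hospitalized_male: int
    n_hospitalized_female: int
    control_case_ratio_male: float | None
    control_case_ratio_female: float | None
    aga_pattern_freqs: dict[int, float]
    age_summary: pd.DataFrame = field(repr=False)


@dataclass(frozen=True)
class AgeCorrectedRegressionResult:
    beta: float
    se: float
    p: float
    n: int
    age_window: tuple[float, float] | None


def _ratio(n_sex: int, n_cases: int) -> float | None:
    """Controls per case, one decimal; None when there are no cases."""
    if n_cases == 0:
        return None
    return round((n_sex - n_cases) / n_cases, 1)


def summarize_cohort(phenotypes: pd.DataFrame) -> CohortSummary:
    """Counts, control:case ratios, pattern frequencies and age quartiles.

    The control:case ratio per sex is (n_sex - cases_sex)/cases_sex rounded to
    one decimal (the "1:x" convention); with zero cases it is reported as
    None rather than raising. Pattern frequencies are computed among males
    with a non-missing pattern.
    """
    if phenotypes.empty:
        raise ValueError("phenotypes table is empty")
    male = phenotypes[phenotypes["sex"] == "male"]
    female = phenotypes[phenotypes["sex"] == "female"]
    n_hosp_m = int(male["hospitalized"].sum())
    n_hosp_f = int(female["hospitalized"].sum())

    pat = male["aga_pattern"].dropna()
    freqs = {k: float((pat == k).mean()) if len(pat) else np.nan for k in (1, 2, 3, 4)}

    rows = []
    for sex, grp in (("male", male), ("female", female)):
        for hosp in (False, True):
            ages = grp.loc[grp["hospitalized"] == hosp, "age_at_event"]
            rows.append(
                {
                    "sex": sex,
                    "hospitalized": hosp,
                    "n": len(ages),
                    "median_age": float(ages.median()) if len(ages) else np.nan,
                    "iqr_age": float(ages.quantile(0.75) - ages.quantile(0.25))
                    if len(ages)
                    else np.nan,
                }
            )
    age_summary = pd.DataFrame(rows)

    return CohortSummary(
        n_total=len(phenotypes),
        n_male=len(male),
        n_female=len(female),
        n_hospitalized_male=n_hosp_m,
        n_hospitalized_female=n_hosp_f,
        control_case_ratio_male=_ratio(len(male), n_hosp_m),
        control_case_ratio_female=_ratio(len(female), n_hosp_f),
        aga_pattern_freqs=freqs,
        age_summary=age_summary,
    )


def residualize_aga_on_age(phenotypes: pd.DataFrame) -> pd.Series:
    """First stage: OLS of the numeric pattern (1-4) on age at assessment.

    Returns residuals indexed by individual_id for males with a non-missing
    pattern; they sum to zero up to numerical tolerance. A constant pattern
    yields all-zero residuals with a warning; a constant age is a
    rank-deficiency error.
    """
    males = phenotypes[
        (phenotypes["sex"] == "male") & phenotypes["aga_pattern"].notna()
    ]
    if len(males) < 3:
        raise ValueError("need at least 3 males with a non-missing pattern")
    age = males["age_at_assessment"].to_numpy(float)
    pattern = males["aga_pattern"].to_numpy(float)
    if np.ptp(age) == 0:
        raise np.linalg.LinAlgError(
            "age at assessment is constant: design matrix is rank-deficient"
        )
    if np.ptp(pattern) == 0:
        warnings.warn("balding pattern is constant; residuals are all zero")
        return pd.Series(
            np.zeros(len(males)), index=males["individual_id"], name="aga_residual"
        )
    X = np.column_stack([np.ones(len(males)), age])
    coef, *_ = np.linalg.lstsq(X, pattern, rcond=None)
    resid = pattern - X @ coef
    out = pd.Series(resid, index=males["individual_id"], name="aga_residual")
    out.attrs["slope"] = float(coef[1])
    out.attrs["intercept"] = float(coef[0])
    return out


def regress_severity_on_aga(
    phenotypes: pd.DataFrame,
    residuals: pd.Series,
    age_window: tuple[float, float] | None = None,
) -> AgeCorrectedRegressionResult:
    """Second stage: logistic regression of hospitalisation on the pattern
    residuals, adjusting for age at the event.

    ``age_window`` restricts to males whose age at event lies in [lo, hi]
    (used for the 52-59 subset analysis). The reported coefficient is the
    log-odds of hospitalisation per unit of age-residualised pattern, with an
    observed-information Wald SE and two-sided p.
    """
    males = phenotypes[phenotypes["sex"] == "male"].set_index("individual_id")
    common = males.index.intersection(residuals.index)
    males = males.loc[common]
    resid = residuals.loc[common]
    if age_window is not None:
        lo, hi = age_window
        mask = (males["age_at_event"] >= lo) & (males["age_at_event"] <= hi)
        males, resid = males[mask], resid[mask]
        if males.empty:
            raise ValueError(f"no males with age at event in window {age_window}")
    y = males["hospitalized"].to_numpy(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one case and one control in the window")
    X = np.column_stack(
        [np.ones(len(males)), resid.to_numpy(), males["age_at_event"].to_numpy(float)]
    )
    try:
        fit = fit_logit(y, X)
    except SeparationError as exc:
        raise SeparationError(
            f"severity-on-residual regression failed ({exc}); "
            "likely complete separation in this window"
        ) from exc
    return AgeCorrectedRegressionResult(
        beta=float(fit.params[1]),
        se=float(fit.se[1]),
        p=float(fit.pvalues[1]),
        n=len(males),
        age_window=age_window,
    )


def _severe(pattern: pd.Series, definition: str) -> pd.Series:
    if definition == "patterns_3_and_4":
        return pattern >= 3
    if definition == "pattern_4_only":
        return pattern == 4
    raise ValueError(
        f"unknown severity definition {definition!r}; expected one of {SEVERITY_DEFINITIONS}"
    )


def prevalence_by_age_group(
    phenotypes: pd.DataFrame,
    general_population: pd.DataFrame,
    definition: str = "patterns_3_and_4",
    bins: tuple[tuple[int, int], ...] = DEFAULT_AGE_BINS,
) -> pd.DataFrame:
    """Severe-balding prevalence per age group: hospitalised vs general men.

    A bin (lo, hi) covers ages in [lo, hi+1) on the continuous age-at-event
    scale, so consecutive integer-labelled bins tile the axis without gaps.
    Empty bins report NaN prevalence with a zero count. Prevalence under
    ``pattern_4_only`` is bounded above by ``patterns_3_and_4`` in every bin.
    """
    lows = [b[0] for b in bins]
    if any(bins[i][1] < bins[i][0] for i in range(len(bins))) or sorted(lows) != list(lows):
        raise ValueError("age bins must be ordered and non-degenerate")
    for (lo1, hi1), (lo2, _) in zip(bins, bins[1:]):
        if lo2 <= hi1:
            raise ValueError("age bins must be non-overlapping")

    hosp = phenotypes[
        (phenotypes["sex"] == "male")
        & phenotypes["hospitalized"]
        & phenotypes["aga_pattern"].notna()
    ]
    gen = general_population[
        (general_population["sex"] == "male")
        & general_population["aga_pattern"].notna()
    ]
    if hosp.empty or gen.empty:
        raise ValueError("both cohorts must contain males with a non-missing pattern")

    rows = []
    for lo, hi in bins:
        row: dict[str, object] = {"age_bin": f"{lo}-{hi}", "lo": lo, "hi": hi}
        for label, cohort in (("hospitalized", hosp), ("general", gen)):
            sel = cohort[(cohort["age_at_event"] >= lo) & (cohort["age_at_event"] < hi + 1)]
            row[f"n_{label}"] = len(sel)
            row[f"prev_{label}"] = (
                float(_severe(sel["aga_pattern"], definition).mean()) if len(sel) else np.nan
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["severity_definition"] = definition
    return out
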