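"""Small shared regression helpers (single logistic fits, separation handling)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

__all__ = ["LogitFit", "fit_logit", "SeparationError"]


class SeparationError(RuntimeError):
    """Logistic MLE did not converge (typically complete/quasi separation)."""


@dataclass(frozen=True)
class LogitFit:
    params: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    n: int


def fit_logit(y: np.ndarray, X: np.ndarray) -> LogitFit:
    """Maximum-likelihood logistic fit with observed-information Wald SEs.

    Raises :class:`SeparationError` on non-convergence or separation instead
    of returning unusable infinite estimates.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(
            "logistic regression failed: perfect separation between outcome "
            "and predictors"
        ) from exc
    except np.linalg.LinAlgError as exc:
        raise SeparationError(f"logistic regression failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError(
            "logistic regression did not converge (possible quasi-separation)"
        )
    if not np.all(np.isfinite(res.bse)):
        raise SeparationError("logistic regression produced non-finite standard errors")
    return LogitFit(params=res.params, se=res.bse, pvalues=res.pvalues, n=len(y))
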