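"""Shared random-intercept model fitting.

statsmodels' MixedLM optimizers can stall or report spurious
convergence when the group variance is near its boundary, so fits are
attempted with a fixed sequence of optimizers and accepted only when
the result is finite and flagged converged.  Callers fall back to OLS
when every attempt fails (the documented singular-plate-variance path).
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

_OPTIMIZERS = ("lbfgs", "cg", "powell")


def fit_random_intercept(
    endog: np.ndarray,
    exog: np.ndarray,
    groups: np.ndarray,
    reml: bool = True,
):
    """REML (or ML) random-intercept fit, or None if no optimizer
    produces a finite converged solution."""
    for method in _OPTIMIZERS:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            try:
                res = sm.MixedLM(endog, exog, groups=groups).fit(
                    reml=reml, method=method, maxiter=200)
                acceptable = (res.converged
                              and np.isfinite(res.llf)
                              and np.isfinite(np.asarray(res.fe_params)).all()
                              and np.isfinite(np.asarray(res.bse_fe)).all())
            except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
                continue
        if acceptable:
            return res
    return None


def conditional_residuals(res, endog: np.ndarray, exog: np.ndarray) -> np.ndarray:
    """Residuals after removing fixed effects and predicted group
    effects; at a zero group variance the prediction is zero and the
    marginal residuals are returned."""
    try:
        return np.asarray(res.resid)
    except (np.linalg.LinAlgError, ValueError):
        return endog - exog @ np.asarray(res.fe_params)
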