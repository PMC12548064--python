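"""Per-CpG cross-sectional association between conception mode and
M-values at one timepoint.

Each probe is regressed on ART status plus maternal age, smoking, BMI,
parity, child's sex, multiple pregnancy and — postnatally — child's
age, with a random intercept for the 96-well plate, fitted by REML.
Inference on the ART coefficient is a two-sided Wald test against the
normal reference (the cohorts are in the hundreds), with a 1.96-SE
confidence interval.  When the plate variance is estimated singular or
the mixed model fails to converge, the fit falls back to ordinary least
squares with the plate variance reported as 0.  Raw p-values are
Benjamini-Hochberg adjusted within the candidate probe family at each
timepoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from methylong._lmm import fit_random_intercept
from methylong.errors import AnalysisError, DataValidationError
from methylong.io_data import (
    MethylationMatrix,
    ProbeAnnotation,
    SampleRecord,
    samples_at,
)
from methylong.preprocess import beta_to_m, encode_covariates, mad_filter

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class AssociationResult:
    """ART effect estimate for one probe at one timepoint."""

    probe_id: str
    timepoint: str
    beta_hat: float
    se: float
    ci_low: float
    ci_high: float
    p_raw: Optional[float]
    n_used: int
    plate_variance: float
    converged: bool
    p_fdr: Optional[float] = None


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted_(i) = min_{j : rank(j) >= rank(i)} p_(j) * m / rank(j),
    capped at 1 and returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DataValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _ols_fit(endog: np.ndarray, exog: np.ndarray) -> tuple[float, float]:
    res = sm.OLS(endog, exog).fit()
    return float(res.params[1]), float(res.bse[1])


def fit_cpg_lmm(
    values: np.ndarray,
    design: pd.DataFrame,
    plates: Sequence[str],
    timepoint: str,
    probe_id: str = "",
    reml: bool = True,
) -> AssociationResult:
    """Fit one probe's random-intercept (plate) model; Wald inference on
    the ART coefficient.

    ``design`` must contain an ``art`` column as its first covariate and
    only complete-case rows; an intercept is added internally.
    """
    endog = np.asarray(values, dtype=float)
    if endog.size != len(design) or endog.size != len(plates):
        raise DataValidationError("values, design and plates length mismatch")
    exog = np.column_stack([np.ones(endog.size), design.to_numpy(dtype=float)])
    art_idx = 1 + list(design.columns).index("art")
    groups = np.asarray(plates)

    beta = se = None
    plate_var = 0.0
    converged = True
    if len(np.unique(groups)) >= 2:
        res = fit_random_intercept(endog, exog, groups, reml=reml)
        if res is not None:
            beta = float(res.params[art_idx])
            se = float(res.bse[art_idx])
            plate_var = max(0.0, float(np.asarray(res.cov_re)[0, 0]))
    if beta is None:
        # documented fallback: singular or non-converged plate variance
        try:
            b, s = _ols_fit(endog, exog)
        except Exception:
            logger.warning("probe %s (%s): model fit failed", probe_id, timepoint)
            return AssociationResult(probe_id, timepoint, np.nan, np.nan,
                                     np.nan, np.nan, None, endog.size, 0.0,
                                     converged=False)
        beta, se, plate_var = b, s, 0.0
    if se == 0 or not np.isfinite(se):
        return AssociationResult(probe_id, timepoint, beta, se, np.nan,
                                 np.nan, None, endog.size, plate_var,
                                 converged=False)
    z = beta / se
    p_raw = float(2.0 * stats.norm.sf(abs(z)))
    return AssociationResult(
        probe_id=probe_id, timepoint=timepoint, beta_hat=beta, se=se,
        ci_low=beta - Z_95 * se, ci_high=beta + Z_95 * se, p_raw=p_raw,
        n_used=int(endog.size), plate_variance=plate_var, converged=converged,
    )


def run_association(
    matrix: MethylationMatrix,
    samples: Sequence[SampleRecord],
    manifest: Sequence[ProbeAnnotation],
    timepoint: str,
    include_cell_fractions: bool = False,
    mad_multiplier: float = 5.0,
    mad_scale_constant: float = 1.0,
) -> list[AssociationResult]:
    """Full per-timepoint association pass over the candidate probes.

    Per probe: MAD outlier filter within the timepoint dataset, then the
    mixed-model fit on complete-case rows; BH adjustment across the
    probe family; results sorted by genomic position.
    """
    tp_samples = samples_at(samples, timepoint)
    if not tp_samples:
        raise AnalysisError(f"no samples at timepoint {timepoint!r}")
    probe_order = [p.probe_id for p in manifest if p.probe_id in
                   set(matrix.probe_ids)]
    if not probe_order:
        raise AnalysisError("no manifest probes present in the matrix")
    sub = matrix.subset(probe_ids=probe_order,
                        sample_ids=[r.sample_id for r in tp_samples])
    values = sub.values
    if sub.scale == "beta":
        values = pd.DataFrame(beta_to_m(values.to_numpy()),
                              index=values.index, columns=values.columns)
    design_all, complete = encode_covariates(
        tp_samples, include_cell_fractions=include_cell_fractions)
    plates = pd.Series({r.sample_id: r.plate_id for r in tp_samples})
    sample_ids = np.array(values.columns)

    results = []
    for probe_id in probe_order:
        row = values.loc[probe_id].to_numpy(dtype=float)
        _, keep = mad_filter(row, sample_ids, probe_id=probe_id,
                             multiplier=mad_multiplier,
                             scale_constant=mad_scale_constant)
        use = keep & complete.loc[sample_ids].to_numpy()
        ids = sample_ids[use]
        results.append(fit_cpg_lmm(
            row[use], design_all.loc[ids], plates.loc[ids].tolist(),
            timepoint=timepoint, probe_id=probe_id,
        ))
    _attach_fdr(results)
    return results


def _attach_fdr(results: Sequence) -> None:
    """BH-adjust p_raw within the family of converged results, in place."""
    idx = [i for i, r in enumerate(results) if r.p_raw is not None]
    if not idx:
        return
    adjusted = bh_adjust([results[i].p_raw for i in idx])
    for i, p in zip(idx, adjusted):
        results[i].p_fdr = float(p)


__all__ = [
    "AssociationResult", "Z_95", "bh_adjust", "fit_cpg_lmm",
    "run_association",
]
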