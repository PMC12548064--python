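"""Within-child change in methylation between birth and a later age.

Each timepoint's M-values are first residualized on child's sex (plus
child's age postnatally) with a plate random intercept, so that
technical batch structure and the covariates that differ between the
two blood draws are removed.  Residuals are standardized (mean 0,
SD 1, n-1 denominator) within each timepoint dataset to make the two
scales comparable, and the per-child difference

    d = z_postnatal - z_birth

is regressed by ordinary least squares on ART exposure with maternal
age, smoking, BMI and parity as covariates.  A positive ART coefficient
means ART-associated methylation increasing with age relative to birth;
the difference direction is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from methylong._lmm import conditional_residuals, fit_random_intercept
from methylong.errors import AnalysisError, DataValidationError
from methylong.association import Z_95, _attach_fdr
from methylong.io_data import (
    MethylationMatrix,
    ProbeAnnotation,
    SampleRecord,
    samples_at,
)
from methylong.preprocess import MATERNAL_COLUMNS, encode_covariates, mad_filter

logger = logging.getLogger(__name__)

MIN_PAIRED_CHILDREN = 10


@dataclass
class ChangeResult:
    """ART effect on the standardized within-child residual difference."""

    probe_id: str
    beta_hat: float
    se: float
    ci_low: float
    ci_high: float
    p_raw: Optional[float]
    n_children: int
    p_fdr: Optional[float] = None


def residualize_standardize(
    values: np.ndarray,
    samples: Sequence[SampleRecord],
    timepoint: str,
) -> pd.Series:
    """Standardized conditional residuals of one probe at one timepoint.

    The model has fixed effects for sex (and child's age when
    postnatal) and a plate random intercept; residuals subtract both
    the fixed-effect fit and the predicted plate effects, then are
    centred and scaled to unit SD within the dataset.
    """
    endog = np.asarray(values, dtype=float)
    if endog.size != len(samples):
        raise DataValidationError("values and samples length mismatch")
    if any(r.timepoint != timepoint for r in samples):
        raise DataValidationError(f"all samples must be at {timepoint!r}")
    cols = [np.ones(endog.size),
            np.array([1.0 if r.sex == "male" else 0.0 for r in samples])]
    if timepoint == "postnatal":
        cols.append(np.array([r.child_age for r in samples], dtype=float))
    exog = np.column_stack(cols)
    groups = np.array([r.plate_id for r in samples])

    resid = None
    if len(np.unique(groups)) >= 2:
        res = fit_random_intercept(endog, exog, groups, reml=True)
        if res is not None:
            # conditional residuals: observed - fixed - predicted plate
            resid = conditional_residuals(res, endog, exog)
    if resid is None:
        resid = np.asarray(sm.OLS(endog, exog).fit().resid)
    sd = float(np.std(resid, ddof=1))
    # numerically zero relative to the outcome scale counts as degenerate
    if sd <= 1e-10 * (np.abs(endog).max() + 1.0) or not np.isfinite(sd):
        raise AnalysisError(
            "residual SD is 0 (degenerate probe); cannot standardize")
    z = (resid - resid.mean()) / sd
    return pd.Series(z, index=[r.sample_id for r in samples])


def within_child_change(
    z_birth: pd.Series,
    z_postnatal: pd.Series,
    samples: Sequence[SampleRecord],
    probe_id: str = "",
    direction: str = "postnatal_minus_birth",
) -> ChangeResult:
    """Regress the per-child standardized-residual difference on ART.

    Only children present in both residual series enter; maternal
    covariates (age, smoking, BMI, parity) are taken complete-case.
    """
    if direction not in ("postnatal_minus_birth", "birth_minus_postnatal"):
        raise DataValidationError(f"unknown direction {direction!r}")
    birth_by_child = {}
    post_by_child = {}
    for rec in samples:
        target = birth_by_child if rec.timepoint == "birth" else post_by_child
        if rec.child_id in target:
            raise DataValidationError(
                f"child {rec.child_id} has duplicate {rec.timepoint} samples")
        target[rec.child_id] = rec
    paired = [c for c in birth_by_child
              if c in post_by_child
              and birth_by_child[c].sample_id in z_birth.index
              and post_by_child[c].sample_id in z_postnatal.index]
    # one covariate row per child, from the birth record (maternal
    # covariates are identical across a child's samples)
    child_recs = [birth_by_child[c] for c in paired]
    if len(child_recs) < MIN_PAIRED_CHILDREN:
        raise AnalysisError(
            f"only {len(child_recs)} children with both timepoints; "
            f">= {MIN_PAIRED_CHILDREN} required")
    design_all, complete = encode_covariates(child_recs)
    keep = complete.to_numpy()
    child_recs = [r for r, k in zip(child_recs, keep) if k]
    paired = [c for c, k in zip(paired, keep) if k]
    if len(child_recs) < MIN_PAIRED_CHILDREN:
        raise AnalysisError("too few complete-case children for the change model")
    d = np.array([
        z_postnatal[post_by_child[c].sample_id] - z_birth[birth_by_child[c].sample_id]
        for c in paired])
    if direction == "birth_minus_postnatal":
        d = -d
    design = design_all.loc[[r.sample_id for r in child_recs], MATERNAL_COLUMNS]
    exog = np.column_stack([np.ones(len(d)), design.to_numpy(dtype=float)])
    if np.allclose(d, 0.0):
        logger.warning("probe %s: all within-child differences are 0", probe_id)
        return ChangeResult(probe_id, 0.0, 0.0, 0.0, 0.0, 1.0, len(d), None)
    res = sm.OLS(d, exog).fit()
    beta, se = float(res.params[1]), float(res.bse[1])
    if se == 0 or not np.isfinite(se):
        return ChangeResult(probe_id, beta, se, np.nan, np.nan, None,
                            len(d), None)
    p_raw = float(2.0 * stats.norm.sf(abs(beta / se)))
    return ChangeResult(probe_id, beta, se, beta - Z_95 * se,
                        beta + Z_95 * se, p_raw, len(d), None)


def run_change(
    matrix_birth: MethylationMatrix,
    matrix_postnatal: MethylationMatrix,
    samples: Sequence[SampleRecord],
    manifest: Sequence[ProbeAnnotation],
    mad_multiplier: float = 5.0,
    direction: str = "postnatal_minus_birth",
) -> list[ChangeResult]:
    """Full change pipeline per probe: MAD filter and residualization at
    each timepoint, within-child differencing, BH across the family."""
    for m in (matrix_birth, matrix_postnatal):
        if m.scale != "M":
            raise DataValidationError("change analysis expects M-scale matrices")
    common = [p.probe_id for p in manifest
              if p.probe_id in set(matrix_birth.probe_ids)
              and p.probe_id in set(matrix_postnatal.probe_ids)]
    if not common:
        raise AnalysisError("no manifest probes shared by the two matrices")
    birth_samples = samples_at(samples, "birth")
    post_samples = samples_at(samples, "postnatal")
    birth_samples = [r for r in birth_samples
                     if r.sample_id in set(matrix_birth.sample_ids)]
    post_samples = [r for r in post_samples
                    if r.sample_id in set(matrix_postnatal.sample_ids)]
    if not birth_samples or not post_samples:
        raise AnalysisError("no overlapping samples between sheet and matrices")

    results = []
    for probe_id in common:
        z_by_tp = {}
        for tp, mat, recs in (("birth", matrix_birth, birth_samples),
                              ("postnatal", matrix_postnatal, post_samples)):
            row = mat.values.loc[probe_id, [r.sample_id for r in recs]]
            _, keep = mad_filter(row.to_numpy(dtype=float),
                                 list(row.index), probe_id=probe_id,
                                 multiplier=mad_multiplier)
            kept = [r for r, k in zip(recs, keep) if k]
            z_by_tp[tp] = residualize_standardize(
                row.to_numpy(dtype=float)[keep], kept, tp)
        results.append(within_child_change(
            z_by_tp["birth"], z_by_tp["postnatal"], samples,
            probe_id=probe_id, direction=direction))
    _attach_fdr(results)
    return results


__all__ = [
    "ChangeResult", "residualize_standardize", "run_change",
    "within_child_change",
]
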