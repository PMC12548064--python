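"""Preprocessing ahead of modelling: scale transforms, twin
deduplication, robust outlier filtering and covariate encoding.

The outlier rule excludes samples whose M-value at a probe falls outside
``median +/- multiplier * MAD``, with the MAD taken literally as the
median of absolute deviations from the median (no 1.4826
normal-consistency constant by default; pass ``scale_constant=1.4826``
for the scaled variant).  Filtering is applied per probe, within each
timepoint dataset, in a single pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

from methylong.errors import AnalysisError, DataValidationError
from methylong.io_data import SampleRecord

logger = logging.getLogger(__name__)


def beta_to_m(beta):
    """logit2 transform: M = log2(beta / (1 - beta)).

    Accepts scalars or arrays; beta must lie strictly in (0, 1).
    """
    arr = np.asarray(beta, dtype=float)
    if ((arr <= 0) | (arr >= 1)).any():
        raise DataValidationError(
            "beta values must lie strictly in (0, 1) for the M transform"
        )
    out = np.log2(arr / (1.0 - arr))
    return float(out) if np.isscalar(beta) else out


def m_to_beta(m):
    """Inverse logit2: beta = 2^M / (1 + 2^M), numerically stable."""
    arr = np.asarray(m, dtype=float)
    out = special.expit(arr * np.log(2.0))  # logistic in base 2
    return float(out) if np.isscalar(m) else out


def dedup_twins(samples: Sequence[SampleRecord], seed: int) -> list[SampleRecord]:
    """Keep one randomly selected child per twin pair (both timepoints).

    Children without a ``twin_pair_id`` pass through unchanged.  Each
    pair must contain exactly two children.  Deterministic under
    ``seed``.
    """
    pairs: dict[str, list[str]] = {}
    for rec in samples:
        if rec.twin_pair_id is not None:
            children = pairs.setdefault(rec.twin_pair_id, [])
            if rec.child_id not in children:
                children.append(rec.child_id)
    for pair_id, children in pairs.items():
        if len(children) != 2:
            raise DataValidationError(
                f"twin pair {pair_id} links {len(children)} children "
                f"({children}); expected exactly 2"
            )
    if not pairs:
        return list(samples)
    rng = np.random.default_rng(seed)
    keep = {pair_id: children[rng.integers(0, 2)]
            for pair_id, children in sorted(pairs.items())}
    return [rec for rec in samples
            if rec.twin_pair_id is None or keep[rec.twin_pair_id] == rec.child_id]


@dataclass(frozen=True)
class OutlierReport:
    """Result of the median +/- k*MAD filter for one probe."""

    probe_id: str
    median: float
    mad: float
    multiplier: float
    excluded_sample_ids: tuple[str, ...]
    directions: tuple[str, ...]  # "above"/"below", parallel to excluded


def mad_filter(
    values: np.ndarray,
    sample_ids: Sequence[str],
    probe_id: str = "",
    multiplier: float = 5.0,
    scale_constant: float = 1.0,
) -> tuple[OutlierReport, np.ndarray]:
    """Flag values outside ``median +/- multiplier * scale_constant * MAD``.

    Returns the report and a boolean mask of retained samples.  A zero
    MAD (degenerate spread) excludes nothing and logs a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3 or not np.isfinite(values).all():
        raise AnalysisError(
            f"probe {probe_id}: need >= 3 finite values for the MAD filter"
        )
    if len(sample_ids) != values.size:
        raise DataValidationError("sample_ids and values length mismatch")
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med))) * scale_constant
    if mad == 0.0:
        logger.warning(
            "probe %s: MAD is 0 (degenerate spread); no samples excluded",
            probe_id,
        )
        report = OutlierReport(probe_id, med, 0.0, multiplier, (), ())
        return report, np.ones(values.size, dtype=bool)
    dev = values - med
    mask = np.abs(dev) <= multiplier * mad
    excluded = [sid for sid, keep in zip(sample_ids, mask) if not keep]
    directions = ["above" if d > 0 else "below"
                  for d, keep in zip(dev, mask) if not keep]
    report = OutlierReport(probe_id, med, mad, multiplier,
                           tuple(excluded), tuple(directions))
    return report, mask


# design-matrix column order; child_age appended for postnatal models
DESIGN_COLUMNS = [
    "art", "maternal_age", "smoking_sometimes", "smoking_daily",
    "bmi_underweight", "bmi_overweight", "bmi_obese", "parity",
    "sex_male", "multiple_birth",
]

MATERNAL_COLUMNS = [
    "art", "maternal_age", "smoking_sometimes", "smoking_daily",
    "bmi_underweight", "bmi_overweight", "bmi_obese", "parity",
]


def encode_covariates(
    samples: Sequence[SampleRecord],
    include_cell_fractions: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Encode the model covariates into numeric design columns.

    Reference levels: conception=natural, smoking=No, BMI=Normal,
    sex=female.  Parity enters as a continuous integer and maternal age
    in years.  ``child_age`` is included only when every sample is
    postnatal (the covariate does not exist at birth).  Cell fractions,
    when requested, are appended with the first fraction dropped as the
    reference.

    Returns ``(design, complete)`` where ``complete`` flags rows with no
    missing required covariate; model fits use complete cases only.
    """
    if not samples:
        raise AnalysisError("no samples to encode")
    rows = {}
    complete = {}
    postnatal_only = all(r.timepoint == "postnatal" for r in samples)
    cf_names: list[str] = []
    if include_cell_fractions:
        for rec in samples:
            if rec.cell_fractions:
                cf_names = list(rec.cell_fractions)
                break
        if not cf_names:
            raise AnalysisError(
                "cell fractions requested but absent from every sample"
            )
    for rec in samples:
        row = {
            "art": 1.0 if rec.conception == "ART" else 0.0,
            "maternal_age": rec.maternal_age,
            "smoking_sometimes": 1.0 if rec.smoking == "Sometimes" else 0.0,
            "smoking_daily": 1.0 if rec.smoking == "Daily" else 0.0,
            "bmi_underweight": 1.0 if rec.bmi_category == "Underweight" else 0.0,
            "bmi_overweight": 1.0 if rec.bmi_category == "Overweight" else 0.0,
            "bmi_obese": 1.0 if rec.bmi_category == "Obese" else 0.0,
            "parity": float(rec.parity),
            "sex_male": 1.0 if rec.sex == "male" else 0.0,
            "multiple_birth": 1.0 if rec.multiple_birth else 0.0,
        }
        ok = rec.bmi_category is not None
        if postnatal_only:
            row["child_age"] = rec.child_age if rec.child_age is not None else np.nan
            ok = ok and rec.child_age is not None
        if include_cell_fractions:
            cf = rec.cell_fractions or {}
            for name in cf_names[1:]:  # first fraction is the reference
                row[f"cf_{name}"] = cf.get(name, np.nan)
            ok = ok and bool(rec.cell_fractions)
        rows[rec.sample_id] = row
        complete[rec.sample_id] = ok
    design = pd.DataFrame.from_dict(rows, orient="index")
    complete_s = pd.Series(complete, name="complete")
    if not complete_s.any():
        raise AnalysisError("every sample is missing a required covariate")
    return design, complete_s


__all__ = [
    "DESIGN_COLUMNS", "MATERNAL_COLUMNS", "OutlierReport", "beta_to_m",
    "dedup_twins", "encode_covariates", "m_to_beta", "mad_filter",
]
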