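"""Synthetic two-timepoint methylation cohort generator.

Emulates a longitudinal mother-child cohort in which ~250 naturally
conceived and ~105 ART-conceived children contribute cord-blood samples
at birth and peripheral-blood samples at ages 3-22.  Defaults reproduce
the study cohort's descriptive marginals: covariate distributions per
conception group, twin pairs in the ART group only, per-group
two-timepoint availability, 96-well plate batch effects, and M-values
generated as

    M = intercept + delta_timepoint * 1[ART] + plate_effect + sigma * T,

with T ~ Student t(df) to capture slightly heavy tails.  The generator
produces no within-child correlation beyond the shared plate effects;
see the methods note for what this does and does not emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from methylong.errors import AnalysisError, ConfigurationError, DataValidationError
from methylong.io_data import MethylationMatrix, ProbeAnnotation, SampleRecord

_PROB_TOL = 1e-9


def _default_marginals() -> dict:
    # category probabilities per conception group (cohort descriptive table)
    return {
        "sex": {
            "natural": {"male": 0.408, "female": 0.592},
            "ART": {"male": 46 / 105, "female": 59 / 105},
        },
        "smoking": {
            "natural": {"No": 0.764, "Sometimes": 0.188, "Daily": 0.048},
            "ART": {"No": 91 / 105, "Sometimes": 9 / 105, "Daily": 5 / 105},
        },
        # "NA" is generated missingness (questionnaire non-response)
        "bmi_category": {
            "natural": {"Underweight": 0.028, "Normal": 0.688,
                        "Overweight": 0.164, "Obese": 0.064, "NA": 0.056},
            "ART": {"Underweight": 4 / 105, "Normal": 69 / 105,
                    "Overweight": 22 / 105, "Obese": 7 / 105, "NA": 3 / 105},
        },
        "parity": {
            "natural": {0: 0.500, 1: 0.328, 2: 0.144, 3: 0.020, 4: 0.008},
            "ART": {0: 71 / 105, 1: 27 / 105, 2: 7 / 105, 3: 0.0, 4: 0.0},
        },
        # probability that a child NOT in a generated twin pair is
        # nevertheless from a multiple birth (co-twin outside the cohort)
        "multiple_birth": {"natural": 2 / 250, "ART": 10 / 91},
        # truncated-normal maternal age (years)
        "maternal_age": {
            "natural": {"mean": 31.3, "sd": 4.5, "lo": 17.0, "hi": 45.0},
            "ART": {"mean": 33.8, "sd": 4.5, "lo": 17.0, "hi": 45.0},
        },
    }


def _default_age_distribution() -> dict:
    # postnatal-age bands (years) with observed per-group counts as
    # weights; uniform within band, clipped to the sampled 3-22 range
    return {
        "bands": [(3.0, 5.0), (5.0, 10.0), (10.0, 15.0),
                  (15.0, 20.0), (20.0, 22.0)],
        "weights": {"natural": [53, 19, 137, 33, 4],
                    "ART": [28, 2, 61, 10, 3]},
    }


@dataclass
class CohortSpec:
    """Configuration of the synthetic cohort.

    ``n_natural``/``n_art`` are the numbers of *independent* children;
    the ART group additionally contains ``twin_pair_count_art`` twin
    pairs, each contributing two children to the generated sheet (so
    105 independent ART children with 14 pairs yields a 119-child
    sheet; twin deduplication is a downstream step).
    """

    n_natural: int = 250
    n_art: int = 105
    twin_pair_count_art: int = 14
    p_two_timepoints_natural: float = 243 / 250
    p_two_timepoints_art: float = 80 / 105
    # among single-timepoint children, probability the available sample
    # is the birth one (cohort: 4/7 natural, 1/25 ART)
    p_birth_given_single: Mapping[str, float] = field(
        default_factory=lambda: {"natural": 4 / 7, "ART": 1 / 25})
    covariate_marginals: dict = field(default_factory=_default_marginals)
    postnatal_age_distribution: dict = field(
        default_factory=_default_age_distribution)
    n_plates: Optional[int] = None  # default: ceil(n_samples / 96)
    plate_sd: float = 0.05  # SD of plate random intercepts, M-value units
    seed: int = 0

    def validate(self) -> None:
        for name, value in [("n_natural", self.n_natural),
                            ("n_art", self.n_art),
                            ("twin_pair_count_art", self.twin_pair_count_art)]:
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {value}")
        if self.twin_pair_count_art > self.n_art:
            raise ConfigurationError(
                "twin_pair_count_art cannot exceed n_art")
        for name, p in [("p_two_timepoints_natural", self.p_two_timepoints_natural),
                        ("p_two_timepoints_art", self.p_two_timepoints_art)]:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        for covariate in ("sex", "smoking", "bmi_category", "parity"):
            for group, cats in self.covariate_marginals[covariate].items():
                probs = np.array(list(cats.values()), dtype=float)
                if (probs < 0).any() or (probs > 1).any():
                    raise ConfigurationError(
                        f"covariate {covariate!r} ({group}): probabilities "
                        f"outside [0, 1]")
                if abs(probs.sum() - 1.0) > _PROB_TOL:
                    raise ConfigurationError(
                        f"covariate {covariate!r} ({group}): category "
                        f"probabilities sum to {probs.sum():.12f}, not 1")
        if self.plate_sd < 0:
            raise ConfigurationError("plate_sd must be >= 0")
        for group, weights in self.postnatal_age_distribution["weights"].items():
            if sum(weights) <= 0 or min(weights) < 0:
                raise ConfigurationError(
                    f"postnatal age weights ({group}) must be nonnegative "
                    f"with positive sum")


@dataclass
class EffectProfile:
    """Per-probe ART effects and the shared noise model.

    ``delta_birth``/``delta_postnatal`` map probe IDs to the ART effect
    in M-value units at each timepoint (unlisted probes get 0).  Noise
    is sigma * t(df): ``noise_scale`` multiplies a standard Student t
    draw, so the total noise SD is sigma * sqrt(df / (df - 2)).
    """

    probe_ids: tuple[str, ...]
    delta_birth: Mapping[str, float] = field(default_factory=dict)
    delta_postnatal: Mapping[str, float] = field(default_factory=dict)
    intercept: float = 1.2
    noise_scale: float = 0.49
    noise_df: float = 10.0

    def __post_init__(self) -> None:
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ConfigurationError("probe_ids must be unique")
        if self.noise_scale <= 0:
            raise ConfigurationError("noise_scale must be > 0")
        if self.noise_df <= 2:
            raise ConfigurationError(
                "noise_df must exceed 2 for finite noise variance")
        for name, deltas in [("delta_birth", self.delta_birth),
                             ("delta_postnatal", self.delta_postnatal)]:
            unknown = sorted(set(deltas) - set(self.probe_ids))
            if unknown:
                raise ConfigurationError(
                    f"{name} references probes outside probe_ids: {unknown}")

    @classmethod
    def null(cls, probes: Sequence[ProbeAnnotation], **kwargs) -> "EffectProfile":
        """No ART effect at any probe (type-I-error conditions)."""
        return cls(probe_ids=tuple(p.probe_id for p in probes), **kwargs)

    @classmethod
    def uniform(cls, probes: Sequence[ProbeAnnotation], delta_birth: float,
                delta_postnatal: float, **kwargs) -> "EffectProfile":
        """Same ART effect at every probe."""
        ids = tuple(p.probe_id for p in probes)
        return cls(probe_ids=ids,
                   delta_birth={p: delta_birth for p in ids},
                   delta_postnatal={p: delta_postnatal for p in ids},
                   **kwargs)


def _draw_category(rng: np.random.Generator, cats: Mapping) -> object:
    labels = list(cats.keys())
    probs = np.array([cats[k] for k in labels], dtype=float)
    return labels[rng.choice(len(labels), p=probs / probs.sum())]


def _draw_truncnorm(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    while True:  # acceptance region covers >99% of mass; loop is short
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)


def generate_cohort(spec: CohortSpec) -> list[SampleRecord]:
    """Generate the sample sheet: one row per available child sample.

    Twin-pair children share a ``twin_pair_id`` and all maternal
    covariates; every sample gets a plate assignment.  Deterministic
    under ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 0])
    marg = spec.covariate_marginals
    age_bands = spec.postnatal_age_distribution["bands"]
    age_weights = spec.postnatal_age_distribution["weights"]

    # (child_id, group, twin_pair_id, mother_key) — twins share a mother
    children: list[tuple[str, str, Optional[str], str]] = []
    for i in range(spec.n_natural):
        cid = f"N{i + 1:04d}"
        children.append((cid, "natural", None, cid))
    n_single_art = spec.n_art - spec.twin_pair_count_art
    for i in range(n_single_art):
        cid = f"A{i + 1:04d}"
        children.append((cid, "ART", None, cid))
    for i in range(spec.twin_pair_count_art):
        pair = f"TP{i + 1:02d}"
        for letter in "ab":
            children.append((f"{pair}{letter}", "ART", pair, pair))

    mothers: dict[str, dict] = {}
    records_wo_plate = []
    for cid, group, pair_id, mother in children:
        if mother not in mothers:
            mothers[mother] = {
                "maternal_age": _draw_truncnorm(
                    rng, **marg["maternal_age"][group]),
                "smoking": _draw_category(rng, marg["smoking"][group]),
                "bmi": _draw_category(rng, marg["bmi_category"][group]),
                "parity": _draw_category(rng, marg["parity"][group]),
            }
        mom = mothers[mother]
        sex = _draw_category(rng, marg["sex"][group])
        if pair_id is not None:
            multiple = True
        else:
            multiple = bool(rng.random() < marg["multiple_birth"][group])
        p_two = (spec.p_two_timepoints_art if group == "ART"
                 else spec.p_two_timepoints_natural)
        if rng.random() < p_two:
            timepoints = ["birth", "postnatal"]
        elif rng.random() < spec.p_birth_given_single[group]:
            timepoints = ["birth"]
        else:
            timepoints = ["postnatal"]
        weights = np.asarray(age_weights[group], dtype=float)
        band = age_bands[rng.choice(len(age_bands), p=weights / weights.sum())]
        child_age = float(rng.uniform(band[0], band[1]))
        for tp in timepoints:
            records_wo_plate.append(dict(
                sample_id=f"{cid}_{'birth' if tp == 'birth' else 'post'}",
                child_id=cid,
                timepoint=tp,
                conception=group,
                sex=sex,
                child_age=child_age if tp == "postnatal" else None,
                multiple_birth=multiple,
                twin_pair_id=pair_id,
                maternal_age=mom["maternal_age"],
                smoking=mom["smoking"],
                bmi_category=None if mom["bmi"] == "NA" else mom["bmi"],
                parity=int(mom["parity"]),
            ))

    n_samples = len(records_wo_plate)
    n_plates = spec.n_plates or max(1, math.ceil(n_samples / 96))
    order = rng.permutation(n_samples)
    plate_ids = np.empty(n_samples, dtype=object)
    for rank, idx in enumerate(order):
        plate_ids[idx] = f"P{rank % n_plates + 1:02d}"
    return [SampleRecord(plate_id=plate_ids[i], **rec)
            for i, rec in enumerate(records_wo_plate)]


def generate_methylation(
    samples: Sequence[SampleRecord],
    probes: Sequence[ProbeAnnotation],
    effects: EffectProfile,
    spec: CohortSpec,
) -> MethylationMatrix:
    """Simulate an M-scale matrix for the given samples and probes.

    Plate random intercepts ~ Normal(0, plate_sd) are drawn once per
    plate; residual noise is noise_scale * t(noise_df) i.i.d. per cell.
    """
    if not probes:
        raise DataValidationError("probe list is empty")
    manifest_ids = [p.probe_id for p in probes]
    missing = sorted(set(effects.probe_ids) - set(manifest_ids))
    if missing:
        raise DataValidationError(
            f"effect profile references probes absent from the manifest: "
            f"{missing}")
    rng = np.random.default_rng([spec.seed, 1])
    plates = sorted({r.plate_id for r in samples})
    plate_effect = dict(zip(plates, rng.normal(0.0, spec.plate_sd, len(plates))))

    art = np.array([1.0 if r.conception == "ART" else 0.0 for r in samples])
    is_birth = np.array([r.timepoint == "birth" for r in samples])
    plate_shift = np.array([plate_effect[r.plate_id] for r in samples])

    n_p, n_s = len(manifest_ids), len(samples)
    noise = effects.noise_scale * rng.standard_t(effects.noise_df, (n_p, n_s))
    values = effects.intercept + plate_shift[None, :] + noise
    for i, pid in enumerate(manifest_ids):
        db = effects.delta_birth.get(pid, 0.0)
        dp = effects.delta_postnatal.get(pid, 0.0)
        values[i] += art * np.where(is_birth, db, dp)
    df = pd.DataFrame(values, index=manifest_ids,
                      columns=[r.sample_id for r in samples])
    return MethylationMatrix(values=df, scale="M")


def inject_outliers(
    matrix: MethylationMatrix,
    probe_id: str,
    sample_ids: Sequence[str],
    offset_in_mads: float,
) -> MethylationMatrix:
    """Place the listed samples at ``median + offset_in_mads * MAD`` of
    the probe's current distribution (fixture for the outlier filter)."""
    if probe_id not in matrix.values.index:
        raise DataValidationError(f"probe {probe_id} not in matrix")
    missing = sorted(set(sample_ids) - set(matrix.values.columns))
    if missing:
        raise DataValidationError(f"samples not in matrix: {missing}")
    row = matrix.values.loc[probe_id].to_numpy(dtype=float)
    med = float(np.median(row))
    mad = float(np.median(np.abs(row - med)))
    if mad == 0.0:
        raise AnalysisError(
            f"probe {probe_id}: MAD is 0, cannot scale the outlier offset")
    values = matrix.values.copy()
    values.loc[probe_id, list(sample_ids)] = med + offset_in_mads * mad
    return MethylationMatrix(values=values, scale=matrix.scale)


__all__ = [
    "CohortSpec", "EffectProfile", "generate_cohort",
    "generate_methylation", "inject_outliers",
]
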