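"""Shared fixtures: the bundled manifest, small synthetic cohorts, and
a deterministic sheet with the study cohort's exact descriptive counts."""

from __future__ import annotations

import numpy as np
import pytest

from methylong.io_data import SampleRecord, load_default_manifest
from methylong.preprocess import dedup_twins
from methylong.synthetic_cohort import (
    CohortSpec,
    EffectProfile,
    generate_cohort,
    generate_methylation,
)


@pytest.fixture(scope="session")
def manifest():
    return load_default_manifest()


@pytest.fixture
def small_spec():
    """A fast, downsized cohort for unit tests."""
    return CohortSpec(n_natural=60, n_art=30, twin_pair_count_art=4, seed=7)


@pytest.fixture
def small_cohort(small_spec, manifest):
    """(deduplicated sheet, M matrix) with a uniform ART effect."""
    sheet = generate_cohort(small_spec)
    effects = EffectProfile.uniform(manifest, 0.13, 0.13)
    matrix = generate_methylation(sheet, manifest, effects, small_spec)
    return dedup_twins(sheet, seed=small_spec.seed), matrix


def _distribute(n: int, counts: dict) -> list:
    """Assign categorical labels to indices 0..n-1 with exact counts."""
    labels = []
    for label, count in counts.items():
        labels.extend([label] * count)
    assert len(labels) == n
    return labels


def build_study_counts_sheet() -> list[SampleRecord]:
    """A twin-deduplicated sheet whose per-group marginals equal the
    study's descriptive table exactly (250 natural / 105 ART children).

    Covariates are assigned independently by index, which preserves
    every marginal count while inventing the joint distribution.
    """
    records = []
    groups = {
        "natural": dict(
            n=250, prefix="N",
            timepoints=_distribute(250, {"both": 243, "birth": 4, "post": 3}),
            sex=_distribute(250, {"male": 102, "female": 148}),
            multiple=_distribute(250, {True: 2, False: 248}),
            smoking=_distribute(250, {"No": 191, "Sometimes": 47, "Daily": 12}),
            bmi=_distribute(250, {"Underweight": 7, "Normal": 172,
                                  "Overweight": 41, "Obese": 16, None: 14}),
            parity=_distribute(250, {0: 125, 1: 82, 2: 36, 3: 5, 4: 2}),
            maternal_age=31.3,
        ),
        "ART": dict(
            n=105, prefix="A",
            timepoints=_distribute(105, {"both": 80, "birth": 1, "post": 24}),
            sex=_distribute(105, {"male": 46, "female": 59}),
            multiple=_distribute(105, {True: 24, False: 81}),
            smoking=_distribute(105, {"No": 91, "Sometimes": 9, "Daily": 5}),
            bmi=_distribute(105, {"Underweight": 4, "Normal": 69,
                                  "Overweight": 22, "Obese": 7, None: 3}),
            parity=_distribute(105, {0: 71, 1: 27, 2: 7}),
            maternal_age=33.8,
        ),
    }
    for conception, g in groups.items():
        for i in range(g["n"]):
            cid = f"{g['prefix']}{i + 1:04d}"
            tps = {"both": ["birth", "postnatal"], "birth": ["birth"],
                   "post": ["postnatal"]}[g["timepoints"][i]]
            for tp in tps:
                records.append(SampleRecord(
                    sample_id=f"{cid}_{tp}",
                    child_id=cid,
                    timepoint=tp,
                    conception=conception,
                    sex=g["sex"][i],
                    child_age=10.0 if tp == "postnatal" else None,
                    multiple_birth=g["multiple"][i],
                    maternal_age=g["maternal_age"],
                    smoking=g["smoking"][i],
                    bmi_category=g["bmi"][i],
                    parity=g["parity"][i],
                    plate_id=f"P{i % 4 + 1:02d}",
                ))
    return records


@pytest.fixture(scope="session")
def study_counts_sheet():
    return build_study_counts_sheet()


# --- independent oracles -------------------------------------------------

def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Explicit min-over-ranks Benjamini-Hochberg definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    adjusted = np.empty(m)
    for pos in range(m):
        candidates = [p_sorted[j] * m / (j + 1) for j in range(pos, m)]
        adjusted[order[pos]] = min(1.0, min(candidates))
    return adjusted


def mad_interval_oracle(values: np.ndarray, multiplier: float) -> np.ndarray:
    """Direct per-value evaluation of the median +/- k*MAD rule; returns
    the retained mask."""
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        return np.ones(values.size, dtype=bool)
    return np.array([abs(v - med) <= multiplier * mad for v in values])
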