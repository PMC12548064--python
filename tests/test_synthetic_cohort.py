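"""The synthetic cohort generator: reproducibility, marginals, and the
methylation model."""

import numpy as np
import pytest

from methylong.errors import AnalysisError, ConfigurationError, DataValidationError
from methylong.preprocess import mad_filter
from methylong.synthetic_cohort import (
    CohortSpec,
    EffectProfile,
    generate_cohort,
    generate_methylation,
    inject_outliers,
)


def test_fixed_seed_is_bit_reproducible(manifest):
    spec = CohortSpec(n_natural=30, n_art=20, twin_pair_count_art=3, seed=42)
    effects = EffectProfile.uniform(manifest, 0.1, 0.05)
    sheet1, sheet2 = generate_cohort(spec), generate_cohort(spec)
    assert sheet1 == sheet2
    m1 = generate_methylation(sheet1, manifest, effects, spec)
    m2 = generate_methylation(sheet2, manifest, effects, spec)
    assert (m1.values.to_numpy() == m2.values.to_numpy()).all()


def test_zero_twin_rate_sets_no_pair_ids():
    spec = CohortSpec(n_natural=15, n_art=10, twin_pair_count_art=0, seed=0)
    assert all(r.twin_pair_id is None for r in generate_cohort(spec))


def test_invalid_marginals_name_the_covariate():
    spec = CohortSpec(seed=0)
    spec.covariate_marginals["smoking"]["natural"]["No"] = 0.9  # breaks sum
    with pytest.raises(ConfigurationError, match="smoking"):
        generate_cohort(spec)


def test_two_timepoint_fraction_matches_study():
    # ART children with both samples: ~76.2% on average
    fractions = []
    for seed in range(10):
        sheet = generate_cohort(CohortSpec(seed=seed))
        art = {}
        for rec in sheet:
            if rec.conception == "ART":
                art.setdefault(rec.child_id, set()).add(rec.timepoint)
        fractions.append(np.mean([len(tps) == 2 for tps in art.values()]))
    # 3 SE of a binomial mean over 10 x 119 children
    se = np.sqrt(0.762 * 0.238 / (10 * 119))
    assert abs(np.mean(fractions) - 0.762) < 3 * se + 1e-9


def test_smoking_marginal_matches_study():
    sheet = generate_cohort(CohortSpec(seed=123))
    mothers = {}
    for rec in sheet:
        if rec.conception == "natural":
            mothers[rec.child_id] = rec.smoking
    prop_no = np.mean([s == "No" for s in mothers.values()])
    assert abs(prop_no - 0.764) < 3 * np.sqrt(0.764 * 0.236 / 250)


def test_large_cohort_marginals_within_3se(manifest):
    spec = CohortSpec(n_natural=10_000, n_art=0, twin_pair_count_art=0, seed=9)
    sheet = generate_cohort(spec)
    children = {}
    for rec in sheet:
        children.setdefault(rec.child_id, rec)
    recs = list(children.values())
    n = len(recs)
    for value, p in [(np.mean([r.sex == "male" for r in recs]), 0.408),
                     (np.mean([r.parity == 0 for r in recs]), 0.500),
                     (np.mean([r.bmi_category is None for r in recs]), 0.056)]:
        assert abs(value - p) < 3 * np.sqrt(p * (1 - p) / n)
    ages = [r.maternal_age for r in recs]
    assert abs(np.mean(ages) - 31.3) < 3 * 4.5 / np.sqrt(n)
    assert min(ages) >= 17 and max(ages) <= 45


def test_maternal_covariates_shared_within_child_and_twin_pair():
    sheet = generate_cohort(CohortSpec(seed=4))
    by_child, by_pair = {}, {}
    for rec in sheet:
        key = (rec.maternal_age, rec.smoking, rec.bmi_category, rec.parity)
        by_child.setdefault(rec.child_id, set()).add(key)
        if rec.twin_pair_id:
            by_pair.setdefault(rec.twin_pair_id, set()).add(key)
    assert all(len(v) == 1 for v in by_child.values())
    assert all(len(v) == 1 for v in by_pair.values())


class TestGenerateMethylation:
    def test_noise_free_limit_approaches_intercept(self, manifest):
        spec = CohortSpec(n_natural=10, n_art=5, twin_pair_count_art=0,
                          plate_sd=0.0, seed=1)
        sheet = generate_cohort(spec)
        effects = EffectProfile.null(manifest, noise_scale=1e-9)
        matrix = generate_methylation(sheet, manifest, effects, spec)
        assert np.allclose(matrix.values.to_numpy(), 1.2, atol=1e-6)

    def test_group_mean_difference_recovers_delta(self, manifest):
        spec = CohortSpec(n_natural=2000, n_art=2000, twin_pair_count_art=0,
                          p_two_timepoints_natural=0.0,
                          p_two_timepoints_art=0.0,
                          p_birth_given_single={"natural": 1.0, "ART": 1.0},
                          plate_sd=0.0, seed=2)
        sheet = generate_cohort(spec)
        effects = EffectProfile.uniform(manifest, 0.13, 0.0)
        matrix = generate_methylation(sheet, manifest, effects, spec)
        art_cols = [r.sample_id for r in sheet if r.conception == "ART"]
        nat_cols = [r.sample_id for r in sheet if r.conception == "natural"]
        diff = (matrix.values[art_cols].to_numpy().mean()
                - matrix.values[nat_cols].to_numpy().mean())
        # SE of the mean difference over 25 x 2000 cells per group
        se = 0.49 * np.sqrt(10 / 8) * np.sqrt(2 / (25 * 2000))
        assert abs(diff - 0.13) < 3 * se

    def test_noise_sd_matches_t_distribution_theory(self, manifest):
        # SD of sigma * t(df) is sigma * sqrt(df/(df-2)) ~ 0.548
        spec = CohortSpec(n_natural=2000, n_art=0, twin_pair_count_art=0,
                          plate_sd=0.0, seed=3)
        sheet = generate_cohort(spec)
        effects = EffectProfile.null(manifest)
        matrix = generate_methylation(sheet, manifest, effects, spec)
        sd = matrix.values.to_numpy().std()
        assert sd == pytest.approx(0.49 * np.sqrt(10 / 8), abs=0.01)

    def test_unknown_effect_probe_is_rejected(self, manifest):
        spec = CohortSpec(n_natural=5, n_art=5, twin_pair_count_art=0, seed=1)
        sheet = generate_cohort(spec)
        effects = EffectProfile(probe_ids=("cg_not_real",),
                                delta_birth={"cg_not_real": 0.1})
        with pytest.raises(DataValidationError, match="cg_not_real"):
            generate_methylation(sheet, manifest, effects, spec)


class TestInjectOutliers:
    @pytest.fixture
    def matrix(self, manifest):
        spec = CohortSpec(n_natural=40, n_art=20, twin_pair_count_art=0,
                          seed=6)
        sheet = generate_cohort(spec)
        return generate_methylation(sheet, manifest,
                                    EffectProfile.null(manifest), spec)

    def test_offset_ten_is_flagged_downstream(self, matrix):
        target = matrix.sample_ids[0]
        out = inject_outliers(matrix, "cg04110421", [target], 10.0)
        row = out.values.loc["cg04110421"]
        report, _ = mad_filter(row.to_numpy(), list(row.index),
                               probe_id="cg04110421")
        assert target in report.excluded_sample_ids

    def test_offset_four_is_not_flagged(self, matrix):
        target = matrix.sample_ids[0]
        out = inject_outliers(matrix, "cg04110421", [target], 4.0)
        row = out.values.loc["cg04110421"]
        report, _ = mad_filter(row.to_numpy(), list(row.index),
                               probe_id="cg04110421")
        assert target not in report.excluded_sample_ids

    def test_offset_zero_places_value_at_median(self, matrix):
        target = matrix.sample_ids[3]
        row = matrix.values.loc["cg08386886"]
        out = inject_outliers(matrix, "cg08386886", [target], 0.0)
        assert out.values.loc["cg08386886", target] == np.median(row)
        untouched = out.values.drop(columns=[target])
        assert (untouched == matrix.values.drop(columns=[target])).all().all()

    def test_zero_mad_probe_cannot_scale(self, matrix):
        flat = matrix.values.copy()
        flat.loc["cg08386886"] = 1.2
        from methylong.io_data import MethylationMatrix
        with pytest.raises(AnalysisError, match="MAD is 0"):
            inject_outliers(MethylationMatrix(values=flat, scale="M"),
                            "cg08386886", [matrix.sample_ids[0]], 3.0)
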