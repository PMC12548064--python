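"""Scale transforms, twin deduplication, the MAD filter and covariate
encoding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylong.errors import AnalysisError, DataValidationError
from methylong.preprocess import (
    beta_to_m,
    dedup_twins,
    encode_covariates,
    m_to_beta,
    mad_filter,
)
from methylong.synthetic_cohort import CohortSpec, generate_cohort

from conftest import build_study_counts_sheet, mad_interval_oracle


class TestBetaM:
    def test_known_values(self):
        assert beta_to_m(0.5) == pytest.approx(0.0, abs=1e-15)
        assert beta_to_m(0.8) == pytest.approx(2.0, abs=1e-12)

    def test_round_trip_uniform_draws(self):
        beta = np.random.default_rng(1).uniform(1e-6, 1 - 1e-6, 1000)
        assert np.max(np.abs(m_to_beta(beta_to_m(beta)) - beta)) < 1e-12

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_inverse_pair_or_domain_error(self, b):
        if 0.0 < b < 1.0:
            assert m_to_beta(beta_to_m(b)) == pytest.approx(b, abs=1e-12)
        else:
            with pytest.raises(DataValidationError):
                beta_to_m(b)


class TestDedupTwins:
    def test_study_sized_dedup(self):
        # 119 ART children with 14 twin pairs -> 105 retained
        spec = CohortSpec(seed=5)
        sheet = generate_cohort(spec)
        art = {r.child_id for r in sheet if r.conception == "ART"}
        assert len(art) == 119
        dedup = dedup_twins(sheet, seed=0)
        assert len({r.child_id for r in dedup if r.conception == "ART"}) == 105
        # naturally conceived children are untouched (only ART twins exist)
        nat_before = {r.sample_id for r in sheet if r.conception == "natural"}
        nat_after = {r.sample_id for r in dedup if r.conception == "natural"}
        assert nat_before == nat_after

    def test_no_twin_pairs_is_identity(self):
        spec = CohortSpec(n_natural=20, n_art=10, twin_pair_count_art=0, seed=2)
        sheet = generate_cohort(spec)
        assert dedup_twins(sheet, seed=9) == sheet

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exactly_one_child_per_pair_any_seed(self, seed):
        spec = CohortSpec(n_natural=10, n_art=10, twin_pair_count_art=5, seed=3)
        sheet = generate_cohort(spec)
        dedup = dedup_twins(sheet, seed=seed)
        pairs = {}
        for rec in dedup:
            if rec.twin_pair_id:
                pairs.setdefault(rec.twin_pair_id, set()).add(rec.child_id)
        assert len(pairs) == 5
        assert all(len(children) == 1 for children in pairs.values())

    def test_malformed_pair_rejected(self):
        spec = CohortSpec(n_natural=5, n_art=5, twin_pair_count_art=2, seed=1)
        sheet = generate_cohort(spec)
        broken = [r for r in sheet
                  if not (r.twin_pair_id == "TP01" and r.child_id.endswith("b"))]
        with pytest.raises(DataValidationError, match="TP01"):
            dedup_twins(broken, seed=0)


class TestMadFilter:
    def test_simple_vector_no_exclusions(self):
        values = np.array([1.0, 2, 3, 4, 5])
        report, mask = mad_filter(values, list("abcde"), probe_id="cg1")
        assert report.median == 3 and report.mad == 1
        assert mask.all() and report.excluded_sample_ids == ()

    def test_degenerate_mad_warns_and_keeps_all(self, caplog):
        values = np.r_[np.zeros(20), 1.0]
        ids = [f"s{i}" for i in range(21)]
        with caplog.at_level("WARNING"):
            report, mask = mad_filter(values, ids, probe_id="cgx")
        assert report.mad == 0 and mask.all()
        assert "MAD is 0" in caplog.text

    def test_injected_outlier_flagged_with_direction(self):
        rng = np.random.default_rng(4)
        values = rng.normal(1.2, 0.5, 50)
        med = np.median(values)
        mad = np.median(np.abs(values - med))
        values[7] = med + 10 * mad
        ids = [f"s{i}" for i in range(50)]
        report, mask = mad_filter(values, ids, probe_id="cgy")
        assert report.excluded_sample_ids == ("s7",)
        assert report.directions == ("above",)
        assert not mask[7] and mask.sum() == 49

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_interval_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 60))
        values = rng.standard_t(3, n) * rng.uniform(0.1, 2)
        _, mask = mad_filter(values, [str(i) for i in range(n)])
        assert (mask == mad_interval_oracle(values, 5.0)).all()

    def test_single_pass_idempotence(self):
        # re-applying the rule with the first-pass median/MAD excludes
        # nothing further among retained values
        rng = np.random.default_rng(11)
        values = rng.standard_t(3, 200)
        report, mask = mad_filter(values, [str(i) for i in range(200)])
        retained = values[mask]
        assert (np.abs(retained - report.median)
                <= report.multiplier * report.mad).all()

    def test_scaled_variant_is_one_flag_away(self):
        values = np.r_[np.random.default_rng(0).normal(0, 1, 40), 6.0]
        _, mask_unscaled = mad_filter(values, [str(i) for i in range(41)])
        _, mask_scaled = mad_filter(values, [str(i) for i in range(41)],
                                    scale_constant=1.4826)
        # scaling widens the interval, so it can only retain more
        assert (mask_scaled | ~mask_unscaled).all()


class TestEncodeCovariates:
    def test_reference_levels_are_all_zero(self, study_counts_sheet):
        rec = next(r for r in study_counts_sheet
                   if r.smoking == "No" and r.bmi_category == "Normal")
        design, complete = encode_covariates([rec])
        row = design.iloc[0]
        assert row[["smoking_sometimes", "smoking_daily", "bmi_underweight",
                    "bmi_overweight", "bmi_obese"]].sum() == 0
        assert complete.iloc[0]

    def test_missing_bmi_flagged_counts(self):
        # study marginals: 14 natural + 3 ART children lack BMI
        sheet = build_study_counts_sheet()
        children = {}
        for rec in sheet:
            children.setdefault(rec.child_id, rec)
        recs = list(children.values())
        _, complete = encode_covariates(recs)
        flagged = [r for r in recs if not complete[r.sample_id]]
        assert sum(1 for r in flagged if r.conception == "natural") == 14
        assert sum(1 for r in flagged if r.conception == "ART") == 3

    def test_child_age_only_for_postnatal_models(self, study_counts_sheet):
        birth = [r for r in study_counts_sheet if r.timepoint == "birth"][:10]
        post = [r for r in study_counts_sheet if r.timepoint == "postnatal"][:10]
        design_birth, _ = encode_covariates(birth)
        design_post, _ = encode_covariates(post)
        assert "child_age" not in design_birth.columns
        assert "child_age" in design_post.columns

    def test_all_missing_is_error(self, study_counts_sheet):
        recs = [r for r in study_counts_sheet if r.bmi_category is None][:5]
        with pytest.raises(AnalysisError):
            encode_covariates(recs)
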