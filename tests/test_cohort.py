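"""Cohort statistics: trends, contrasts, latency scoring and splitting."""

import numpy as np
import pandas as pd
import pytest

from placenta_dwr.cohort import (
    cohort_frame,
    ga_trend,
    group_contrast,
    latency_score,
    split_contrast,
    standardise_and_split,
)
from placenta_dwr.synthetic import GeneratorConfig, SubjectRecord, make_cohort


def _case(sid, onset, mri, delivery, **roi):
    return SubjectRecord(subject_id=sid, group="pprom", ga_onset=onset,
                         ga_mri=mri, ga_delivery=delivery, roi_means=roi)


class TestLatencyScore:
    def test_symmetric_interval_gives_unit_ratio(self):
        assert latency_score(_case("a", 24.0, 25.0, 26.0)) == pytest.approx(1.0)

    def test_scan_at_delivery_gives_zero(self):
        assert latency_score(_case("a", 24.0, 26.0, 26.0)) == pytest.approx(0.0)

    def test_decreases_toward_delivery(self):
        far = latency_score(_case("a", 24.0, 25.0, 30.0))
        near = latency_score(_case("b", 24.0, 25.0, 26.0))
        assert far > near
        # strictly decreasing in ga_mri at fixed onset/delivery
        ratios = [latency_score(_case("c", 24.0, m, 30.0)) for m in (25.0, 26.0, 28.0, 29.5)]
        assert all(a > b for a, b in zip(ratios, ratios[1:]))

    def test_mri_at_onset_undefined(self):
        with pytest.raises(ValueError, match="onset"):
            latency_score(_case("a", 25.0, 25.0, 30.0))

    def test_inverted_reading_increases_toward_delivery(self):
        near = latency_score(_case("a", 24.0, 25.0, 26.0), invert=True)
        far = latency_score(_case("b", 24.0, 25.0, 30.0), invert=True)
        assert near > far


class TestStandardiseAndSplit:
    def test_z_scores_have_zero_mean_unit_sd(self, rng):
        cases = [_case(f"c{i}", 22.0, 24.0 + i * 0.3, 30.0) for i in range(10)]
        scores = standardise_and_split(cases)
        z = np.array([s.z for s in scores])
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.std() == pytest.approx(1.0, abs=1e-10)

    def test_known_ratios_sides(self):
        cases = [_case(f"c{i}", 20.0, 25.0, 25.0) for i in range(3)]
        scores = standardise_and_split(cases, ratios=[1.0, 2.0, 3.0])
        assert [s.side for s in scores] == ["below_zero", "above_zero", "above_zero"]
        assert scores[0].z == pytest.approx(-np.sqrt(1.5), abs=1e-12)
        assert scores[1].z == 0.0  # the tie lands on the above-zero side

    def test_zero_variance_rejected(self):
        cases = [_case(f"c{i}", 20.0, 25.0, 30.0) for i in range(3)]
        with pytest.raises(ValueError, match="variance"):
            standardise_and_split(cases, ratios=[2.0, 2.0, 2.0])

    def test_side_matches_z_sign(self):
        cases = [_case(f"c{i}", 22.0, 23.0 + i, 31.0) for i in range(6)]
        for s in standardise_and_split(cases):
            assert (s.side == "below_zero") == (s.z < 0)


class TestGaTrend:
    def test_negative_t2_slope_recovered_in_controls(self):
        df = cohort_frame(make_cohort(seed=2))
        rep = ga_trend(df, "t2_star")
        assert rep.effect < 0
        assert rep.effect_p < 0.05
        assert rep.n == 52

    def test_flat_parameter_shows_no_trend(self):
        df = cohort_frame(make_cohort(seed=2))
        rep = ga_trend(df, "fa")  # generated GA-constant
        assert not (rep.effect_p < 0.05)

    def test_constant_outcome_gives_zero_slope(self):
        recs = make_cohort(seed=0)
        for r in recs:
            r.roi_means["const"] = 42.0
        rep = ga_trend(cohort_frame(recs), "const")
        assert rep.effect == pytest.approx(0.0, abs=1e-12)
        assert not (rep.effect_p < 0.05)

    def test_too_few_controls_rejected(self):
        recs = [r for r in make_cohort(seed=0) if r.group == "control"][:2]
        with pytest.raises(ValueError, match=">= 3 controls"):
            ga_trend(cohort_frame(recs), "t2_star")


class TestGroupContrast:
    def test_injected_t2_reduction_detected(self):
        df = cohort_frame(make_cohort(seed=3))
        rep = group_contrast(df, "t2_star")
        assert rep.effect < 0 and rep.effect_p < 0.05

    def test_null_parameter_near_zero_effect(self):
        df = cohort_frame(make_cohort(cfg=GeneratorConfig().without_effects(), seed=4))
        rep = group_contrast(df, "t2_star")
        assert not (rep.effect_p < 0.01)

    def test_balanced_unadjusted_contrast_equals_mean_difference(self):
        # closed-form oracle: with GA omitted and equal groups, the OLS
        # coefficient is exactly the difference of group means
        recs = make_cohort(n_cases=10, n_pprom=5, n_controls=10, seed=5)
        df = cohort_frame(recs)
        rep = group_contrast(df, "t2_star", adjust_ga=False)
        cases = df[df["group"] != "control"]["t2_star"]
        ctrls = df[df["group"] == "control"]["t2_star"]
        assert rep.effect == pytest.approx(cases.mean() - ctrls.mean(), rel=1e-10)

    def test_subgroups_use_only_named_cases(self):
        df = cohort_frame(make_cohort(seed=3))
        rep_pprom = group_contrast(df, "t2_star", "pprom")
        rep_intact = group_contrast(df, "t2_star", "intact")
        assert rep_pprom.n == 14 + 52
        assert rep_intact.n == 9 + 52
        # PPROM carries the stronger reduction by construction
        assert rep_pprom.effect < rep_intact.effect

    def test_empty_subgroup_named_in_error(self):
        recs = make_cohort(n_cases=3, n_pprom=3, n_controls=5, seed=0)
        with pytest.raises(ValueError, match="intact"):
            group_contrast(cohort_frame(recs), "t2_star", "intact")


class TestSplitContrast:
    def test_injected_near_delivery_f_reduction_detected(self):
        recs = make_cohort(seed=6)
        cases = [r for r in recs if r.is_case]
        rep = split_contrast(cases, "f")
        assert rep.effect < 0
        assert rep.effect_p < 0.05

    def test_identical_sides_give_zero_difference(self):
        cases = [
            _case("a", 22.0, 23.0, 30.0, f=0.2),   # large ratio -> above
            _case("b", 22.0, 23.5, 30.0, f=0.2),
            _case("c", 22.0, 29.0, 30.0, f=0.2),   # small ratio -> below
            _case("d", 22.0, 29.5, 30.0, f=0.2),
        ]
        rep = split_contrast(cases, "f")
        assert rep.effect == pytest.approx(0.0, abs=1e-12)

    def test_one_sided_split_rejected(self):
        cases = [_case("a", 22.0, 23.0, 30.0, f=0.2), _case("b", 22.0, 23.0, 30.0, f=0.3)]
        scores = standardise_and_split(cases, ratios=[1.0, 2.0])
        for s in scores:
            s.side = "above_zero"
        with pytest.raises(ValueError, match="one-sided"):
            split_contrast(cases, "f", scores)


class TestCalibration:
    def test_type_i_error_rate_near_nominal(self):
        # no injected effects: the case indicator should reject ~5% of the time
        cfg = GeneratorConfig().without_effects()
        hits = 0
        n_rep = 150
        for seed in range(n_rep):
            df = cohort_frame(make_cohort(cfg=cfg, seed=seed))
            hits += group_contrast(df, "t2_star").effect_p < 0.05
        rate = hits / n_rep
        band = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < band
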