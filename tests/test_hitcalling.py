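"""Hit calling: tolerance scores, QC, plate normalisation, thresholds, power."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from simplexscreen import (
    ScreenConfig,
    ScreenModel,
    cv,
    detectable_improvement,
    power_curve,
    qc_filter,
    residual_ratio,
    simulate_screen,
)
from simplexscreen.hitcalling import PlateRejectedError


def make_wells(n_samples=20, n_wt=8, wt_pre=100.0, wt_ratio=0.17, cv_noise=0.0,
               seed=0, plate_id="plate1"):
    """Hand-built well table: wild-type controls plus sample wells."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_wt):
        pre = wt_pre * (1 + cv_noise * rng.standard_normal())
        post = wt_pre * wt_ratio * 5.0 * (1 + cv_noise * rng.standard_normal())
        rows.append(dict(plate_id=plate_id, well_id=f"A{i+1}", role="wildtype_control",
                         pre_activity=pre, post_activity=post))
    for i in range(n_samples):
        pre = wt_pre * (1 + cv_noise * rng.standard_normal())
        post = wt_pre * wt_ratio * 5.0 * (1 + cv_noise * rng.standard_normal())
        rows.append(dict(plate_id=plate_id, well_id=f"B{i+1}", role="sample",
                         pre_activity=pre, post_activity=post))
    return pd.DataFrame(rows)


class TestCv:
    def test_hand_computed_example(self):
        assert cv([8.0, 10.0, 12.0]) == pytest.approx(0.2)

    def test_constant_vector(self):
        assert cv([5.0, 5.0, 5.0]) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            cv([1.0])
        with pytest.raises(ValueError):
            cv([-2.0, 2.0])

    def test_estimates_configured_cv_at_replicate_scale(self):
        # 88 replicates at CV 0.17: estimate within 3 SEs
        rng = np.random.default_rng(88)
        sigma = math.sqrt(math.log1p(0.17 ** 2))
        vals = np.exp(rng.normal(0, sigma, 88))
        se = 0.17 / math.sqrt(2 * 88)
        assert abs(cv(vals) - 0.17) < 3 * se


class TestResidualRatio:
    def test_protocol_design_point(self):
        # 20% residual target: 5x product post-exposure, raw reads equal
        assert residual_ratio(10.0, 10.0, 5.0) == pytest.approx(0.2)

    def test_no_deactivation_gives_unity(self):
        assert residual_ratio(7.0, 7.0 * 5.0, 5.0) == pytest.approx(1.0)

    def test_zero_post(self):
        assert residual_ratio(10.0, 0.0) == 0.0

    def test_nonpositive_pre_rejected(self):
        with pytest.raises(ValueError, match="QC"):
            residual_ratio(0.0, 5.0)


class TestQcFilter:
    def test_zero_cutoff_passes_everything_positive(self):
        df = make_wells()
        out = qc_filter(df, 0.0)
        assert out["qc_pass"].all()

    def test_boundary_well_passes(self):
        df = make_wells(n_samples=1)
        df.loc[df["role"] == "sample", "pre_activity"] = 25.0
        out = qc_filter(df, 25.0)
        assert out.loc[out["role"] == "sample", "qc_pass"].all()

    def test_inactive_wells_disqualified_in_simulation(self, small_library):
        # wells whose members are all inactive carry only background signal
        # and must fail the default QC cutoff almost always
        screen = simulate_screen(small_library, 5, seed=21)
        res = ScreenModel(screen.wells).fit()
        merged = res.records.merge(
            screen.truth[["plate_id", "well_id", "true_pre_activity", "n_genes"]],
            on=["plate_id", "well_id"])
        dead = merged[(merged["role"] == "sample")
                      & (merged["n_genes"] > 0)
                      & (merged["true_pre_activity"] == 0.0)]
        assert len(dead) > 30
        assert (~dead["qc_pass"]).mean() >= 0.95

    def test_disqualified_wells_get_no_scores_or_flags(self):
        df = make_wells(n_samples=4)
        df.loc[df["well_id"] == "B1", "pre_activity"] = 0.1
        res = ScreenModel(df).fit()
        row = res.records.set_index("well_id").loc["B1"]
        assert not row["qc_pass"]
        assert np.isnan(row["normalized_tolerance"])
        assert not row["tolerance_hit"] and not row["activity_hit"]


class TestPlateNormalisation:
    def test_wildtype_scores_centre_on_unity(self):
        res = ScreenModel(make_wells(cv_noise=0.05, seed=3)).fit()
        wt = res.records[res.records["role"] == "wildtype_control"]
        assert wt["normalized_tolerance"].mean() == pytest.approx(1.0, abs=1e-12)
        assert wt["normalized_activity"].mean() == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        # rescaling every activity on a plate changes no normalised score,
        # QC decision or hit call
        base = make_wells(cv_noise=0.15, seed=4)
        scaled = base.assign(pre_activity=base["pre_activity"] * scale,
                             post_activity=base["post_activity"] * scale)
        r1 = ScreenModel(base).fit().records
        r2 = ScreenModel(scaled).fit().records
        for col in ("normalized_tolerance", "normalized_activity"):
            np.testing.assert_allclose(r1[col], r2[col], rtol=1e-9)
        assert (r1["qc_pass"] == r2["qc_pass"]).all()
        assert (r1["tolerance_hit"] == r2["tolerance_hit"]).all()
        assert (r1["activity_hit"] == r2["activity_hit"]).all()

    def test_plates_with_different_severity_normalise_identically(self):
        # a plate deactivated 2x harder yields the same normalised scores
        base = make_wells(cv_noise=0.10, seed=5)
        harder = base.assign(post_activity=base["post_activity"] * 0.5)
        r1 = ScreenModel(base).fit().records
        r2 = ScreenModel(harder).fit().records
        np.testing.assert_allclose(r1["normalized_tolerance"],
                                   r2["normalized_tolerance"], rtol=1e-9)

    def test_too_few_wildtype_controls_rejects_plate(self):
        df = make_wells(n_wt=1)
        with pytest.raises(PlateRejectedError, match="wild-type"):
            ScreenModel(df).fit()


class TestCallHits:
    def test_identical_wells_produce_no_hits(self):
        res = ScreenModel(make_wells(cv_noise=0.0)).fit()
        assert len(res.hits("tolerance")) == 0
        assert len(res.hits("activity")) == 0
        assert res.screen_summary.plate_stats[0].degenerate

    def test_planted_fourfold_mutant_is_activity_hit(self, wildtype_library):
        lib = pd.concat([wildtype_library, pd.DataFrame({
            "mutant_id": ["star"], "n_mutations": [2],
            "activity_factor": [4.0], "tolerance_factor": [1.0]})],
            ignore_index=True)
        screen = simulate_screen(lib, 1, ScreenConfig(cv=0.20), seed=30,
                                 planted={("plate1", "B5"): ["star"]})
        res = ScreenModel(screen.wells).fit()
        assert res.records.set_index("well_id").loc["B5", "activity_hit"]

    def test_wildtype_false_positive_rate_near_normal_tail(self, wildtype_library):
        # per-tail FP rate at a 2-SD threshold: the Gaussian oracle says
        # 2.28%; lognormal skew pushes the realised rate slightly above it
        cfg = ScreenConfig(cv=0.20)
        fp, n = 0, 0
        for seed in range(40):
            screen = simulate_screen(wildtype_library, 1, cfg, n_wildtype=40,
                                     seed=100 + seed)
            res = ScreenModel(screen.wells).fit()
            samples = res.records[(res.records["role"] == "sample")
                                  & res.records["qc_pass"]]
            fp += int(samples["tolerance_hit"].sum())
            n += len(samples)
        oracle = stats.norm.sf(2.0)
        assert abs(fp / n - oracle) < 0.02

    def test_summary_reports_cv_and_thresholds(self):
        res = ScreenModel(make_wells(cv_noise=0.15, seed=6)).fit()
        text = res.summary()
        assert "ratio CV" in text and "2 SD" in text


class TestDetectability:
    @pytest.mark.parametrize("cv_value,expected", [
        (0.15, 0.30), (0.25, 0.50), (0.0, 0.0),
    ])
    def test_minimal_detectable_improvement(self, cv_value, expected):
        assert detectable_improvement(cv_value) == pytest.approx(expected)

    def test_threshold_consistency(self):
        # the noise-free expected score at the minimal detectable
        # improvement sits exactly at the hit threshold
        for cv_value in (0.1, 0.17, 0.25):
            mdi = detectable_improvement(cv_value, 2.0)
            assert 1.0 + mdi == pytest.approx(1.0 + 2.0 * cv_value)

    def test_power_at_null_matches_false_positive_rate(self):
        p = power_curve([0.0], 0.2, seed=1, n_draws=40_000)[0]
        assert p == pytest.approx(stats.norm.sf(2.0), abs=0.005)

    def test_power_half_at_detectable_improvement(self):
        for cv_value in (0.15, 0.25):
            mdi = detectable_improvement(cv_value)
            p = power_curve([mdi], cv_value, seed=2, n_draws=10_000)[0]
            assert p == pytest.approx(0.5, abs=0.03)

    def test_power_saturates_at_large_improvement(self):
        # noise is mean-proportional, so at improvement 10xCV the Gaussian
        # oracle gives Phi((1+imp-thr)/(cv(1+imp))) ~ 0.996, approaching
        # Phi(1/cv) in the separation limit
        p10 = power_curve([10 * 0.2], 0.2, seed=3, n_draws=5000)[0]
        p50 = power_curve([50 * 0.2], 0.2, seed=3, n_draws=5000)[0]
        assert p10 > 0.99
        assert p50 > 0.999

    def test_power_monotone_in_improvement(self):
        grid = np.linspace(0.0, 1.0, 11)
        p = power_curve(grid, 0.2, seed=4, n_draws=20_000)
        assert np.all(np.diff(p) > -0.02)  # nondecreasing within MC error

    def test_replicates_sharpen_the_curve(self):
        mdi = 0.4
        p1 = power_curve([mdi * 1.5], 0.2, n_replicates=1, seed=5, n_draws=20_000)[0]
        p4 = power_curve([mdi * 1.5], 0.2, n_replicates=4, seed=5, n_draws=20_000)[0]
        assert p4 > p1

    def test_lognormal_noise_model_available(self):
        p = power_curve([0.4], 0.2, seed=6, n_draws=10_000, noise="lognormal")[0]
        assert 0.3 < p < 0.7
        with pytest.raises(ValueError):
            power_curve([0.1], 0.2, noise="cauchy")
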