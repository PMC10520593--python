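"""Orientation, normative fitting, z-scoring, and deviation profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cognorm import (
    BatterySpec,
    ConfigurationError,
    DegenerateNormativeError,
    NormativeModel,
    TestSpec,
    ValidationError,
    fit_normative,
    orient_scores,
    profile,
    zscore,
)

from .conftest import make_cohort


class TestOrientScores:
    @pytest.mark.parametrize("raw,expected", [(100.0, 0.0), (60.0, 40.0), (0.0, 100.0)])
    def test_lower_better_reversal(self, small_battery, raw, expected):
        cohort = make_cohort(small_battery, [{"RT": raw, "ACC": 17.0, "ERR": 3.0}])
        oriented = orient_scores(cohort)
        assert oriented.data.loc[0, "RT"] == expected
        assert oriented.data.loc[0, "ACC"] == 17.0  # higher_better unchanged

    def test_missing_propagates(self, small_battery):
        cohort = make_cohort(small_battery, [{"ACC": 17.0, "ERR": 3.0}])
        oriented = orient_scores(cohort)
        assert np.isnan(oriented.data.loc[0, "RT"])

    def test_raw_above_reference_names_participant_and_test(self, small_battery):
        cohort = make_cohort(
            small_battery,
            [{"participant_id": "px", "RT": 120.0, "ACC": 1.0, "ERR": 0.0}],
        )
        with pytest.raises(ValidationError, match="px.*RT"):
            orient_scores(cohort)


class TestFitNormative:
    def test_hand_arithmetic(self, small_battery):
        rows = [{"RT": 100 - v, "ACC": v, "ERR": v / 2} for v in (8.0, 10.0, 12.0)]
        model = fit_normative(orient_scores(make_cohort(small_battery, rows)), "HC")
        assert model.entry("ACC") == (10.0, 2.0)  # sample (n-1) denominator
        assert model.stats.loc["ACC", "n_control"] == 3

    def test_zero_variance_is_degenerate(self, small_battery):
        rows = [{"RT": 10.0, "ACC": 5.0, "ERR": 1.0}, {"RT": 20.0, "ACC": 5.0, "ERR": 2.0}]
        with pytest.raises(DegenerateNormativeError, match="ACC"):
            fit_normative(orient_scores(make_cohort(small_battery, rows)), "HC")

    def test_single_control_observation_is_degenerate(self, small_battery):
        rows = [
            {"RT": 10.0, "ACC": 5.0, "ERR": 1.0},
            {"RT": 20.0, "ACC": np.nan, "ERR": 2.0},
        ]
        with pytest.raises(DegenerateNormativeError, match="ACC"):
            fit_normative(orient_scores(make_cohort(small_battery, rows)), "HC")

    def test_absent_control_group(self, small_battery):
        rows = [{"group": "ROP", "RT": 10.0, "ACC": 5.0, "ERR": 1.0}] * 3
        with pytest.raises(ValidationError):
            fit_normative(orient_scores(make_cohort(small_battery, rows)), "HC")

    def test_recovers_generator_parameters(self):
        battery = BatterySpec.from_tests([TestSpec("X", "higher_better")])
        rng = np.random.default_rng(2)
        rows = [{"X": v} for v in rng.normal(50, 10, size=4000)]
        model = fit_normative(make_cohort(battery, rows), "HC")
        mu, sigma = model.entry("X")
        assert mu == pytest.approx(50, abs=3 * 10 / np.sqrt(4000))
        assert sigma == pytest.approx(10, rel=0.05)

    def test_model_file_round_trip(self, tmp_path, small_battery):
        rows = [{"RT": 100 - v, "ACC": v, "ERR": v / 2} for v in (8.0, 10.0, 12.0)]
        model = fit_normative(orient_scores(make_cohort(small_battery, rows)), "HC")
        for name in ("m.yaml", "m.json"):
            model.save(tmp_path / name)
            back = NormativeModel.load(tmp_path / name)
            pd.testing.assert_frame_equal(
                back.stats, model.stats, check_names=False, check_dtype=False
            )


class TestZscore:
    @pytest.mark.parametrize(
        "raw,mu,sigma,expected", [(25, 25, 2, 0.0), (27, 25, 2, 1.0), (30, 25, 2, 2.5)]
    )
    def test_formula(self, raw, mu, sigma, expected):
        assert zscore(raw, mu, sigma) == expected

    def test_missing_propagates(self):
        assert np.isnan(zscore(np.nan, 0.0, 1.0))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(DegenerateNormativeError):
            zscore(1.0, 0.0, 0.0)


class TestProfile:
    def _profiles(self, small_battery, rows, control="HC"):
        oriented = orient_scores(make_cohort(small_battery, rows))
        model = fit_normative(oriented, control)
        return profile(oriented, small_battery, model)

    def test_composite_is_mean_of_z(self, small_battery):
        rng = np.random.default_rng(0)
        rows = [
            {"RT": 100 - rng.normal(40, 5), "ACC": rng.normal(20, 3),
             "ERR": 50 - rng.normal(30, 4)}
            for _ in range(30)
        ]
        profiles = self._profiles(small_battery, rows)
        expected = profiles.z.mean(axis=1)
        pd.testing.assert_series_equal(profiles.composite, expected, check_names=False)

    def test_one_missing_test_kills_composite(self, small_battery):
        rows = [{"RT": 100 - v, "ACC": v, "ERR": 50 - v} for v in (30.0, 40.0, 50.0)]
        rows.append({"RT": 60.0, "ACC": 40.0})  # ERR missing
        profiles = self._profiles(small_battery, rows)
        assert not profiles.complete_battery.iloc[-1]
        assert np.isnan(profiles.composite.iloc[-1])
        assert profiles.complete_battery.iloc[:3].all()
        assert profiles.composite.iloc[:3].notna().all()

    def test_model_must_cover_battery(self, small_battery):
        rows = [{"RT": 100 - v, "ACC": v, "ERR": 50 - v} for v in (30.0, 40.0, 50.0)]
        oriented = orient_scores(make_cohort(small_battery, rows))
        model = fit_normative(oriented, "HC")
        partial = NormativeModel(model.stats.drop(index="ERR"), "HC")
        with pytest.raises(ConfigurationError, match="ERR"):
            profile(oriented, small_battery, partial)

    def test_self_norming(self, small_battery):
        """Controls scored against their own norms: z mean 0, sample SD 1."""
        rng = np.random.default_rng(3)
        rows = [
            {"RT": 100 - rng.normal(40, 6), "ACC": rng.normal(20, 3),
             "ERR": 50 - rng.normal(30, 5)}
            for _ in range(100)
        ]
        profiles = self._profiles(small_battery, rows)
        assert profiles.z.mean().abs().max() < 1e-10
        assert (profiles.z.std(ddof=1) - 1).abs().max() < 1e-10

    def test_composite_between_min_and_max_z(self, small_battery):
        rng = np.random.default_rng(4)
        rows = [
            {"RT": 100 - rng.normal(40, 6), "ACC": rng.normal(20, 3),
             "ERR": 50 - rng.normal(30, 5)}
            for _ in range(50)
        ]
        profiles = self._profiles(small_battery, rows)
        complete = profiles.composite.dropna()
        assert (profiles.z.min(axis=1)[complete.index] <= complete + 1e-12).all()
        assert (profiles.z.max(axis=1)[complete.index] >= complete - 1e-12).all()

    @given(shift=st.floats(-20, 20))
    def test_affine_invariance_of_z(self, shift):
        """Adding a constant to every raw score of a test leaves z unchanged."""
        battery = BatterySpec.from_tests([TestSpec("X", "higher_better")])
        base = np.array([30.0, 35.0, 40.0, 45.0, 55.0])
        rows = [{"X": v} for v in base]
        rows_shifted = [{"X": v + shift} for v in base]
        p1 = profile(make_cohort(battery, rows), battery,
                     fit_normative(make_cohort(battery, rows), "HC"))
        p2 = profile(make_cohort(battery, rows_shifted), battery,
                     fit_normative(make_cohort(battery, rows_shifted), "HC"))
        np.testing.assert_allclose(p1.z.to_numpy(), p2.z.to_numpy(), atol=1e-9)

    def test_orientation_reverses_order_for_lower_better(self, small_battery):
        """On a reaction-time test, slower raw scores must get lower z."""
        rows = [
            {"RT": rt, "ACC": 20.0 + i, "ERR": 10.0 + i}
            for i, rt in enumerate((30.0, 45.0, 60.0, 75.0))
        ]
        profiles = self._profiles(small_battery, rows)
        z_rt = profiles.z["RT"].to_numpy()
        assert (np.diff(z_rt) < 0).all()  # raw ascending -> z descending
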