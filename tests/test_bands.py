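"""Severity bands, multi-test criteria, and prevalence summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cognorm import (
    Band,
    ConfigurationError,
    CriterionSpec,
    band_of,
    band_prevalence,
    criterion_prevalence,
    mean_tests_at_level,
    meets_criterion,
)
from cognorm.bands import assign_bands

from .conftest import profiles_from_z


def _profiles(z_rows, groups=None, columns=None):
    z = pd.DataFrame(z_rows, columns=columns)
    z.index = [f"P{i}" for i in range(len(z))]
    group = pd.Series(groups or ["G"] * len(z), index=z.index)
    return profiles_from_z(z, group)


class TestBandOf:
    @pytest.mark.parametrize(
        "z,band",
        [
            (0.0, Band.AVERAGE),
            (-1.5, Band.MODERATE_IMPAIR),
            (-2.5, Band.SEVERE_IMPAIR),
            (1.5, Band.ABOVE_AVERAGE),
            (2.5, Band.EXTREMELY_HIGH),
            # boundary convention: average is closed, outer bands strict
            (1.0, Band.AVERAGE),
            (-1.0, Band.AVERAGE),
            (-2.0, Band.MODERATE_IMPAIR),
            (2.0, Band.ABOVE_AVERAGE),
        ],
    )
    def test_partition(self, z, band):
        assert band_of(z) is band

    def test_missing_has_no_band(self):
        assert band_of(float("nan")) is None

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(0)
        z = pd.Series(rng.normal(0, 1.5, size=500))
        vec = assign_bands(z)
        assert all(vec.iloc[i] is band_of(z.iloc[i]) for i in range(len(z)))


class TestBandPrevalence:
    def test_counting(self):
        z = [[v] for v in [0.1, -0.3, 0.5, 0.9, -0.8, 0.0, 0.2, -0.5, -1.7, -2.3]]
        profiles = _profiles(z, columns=["T"])
        bp = band_prevalence(profiles)
        cell = bp[(bp.measure == "T")].set_index("band")["percent"]
        assert cell["average"] == 80.0
        assert cell["moderately impaired"] == 10.0
        assert cell["severely impaired"] == 10.0

    def test_percentages_sum_to_100(self, fixture_cohort):
        from cognorm import fit_normative, orient_scores, profile

        oriented = orient_scores(fixture_cohort)
        profiles = profile(oriented, model=fit_normative(oriented, "HC"),
                           battery=fixture_cohort.battery)
        bp = band_prevalence(profiles)
        sums = bp.groupby(["group", "measure"])["percent"].sum()
        assert (abs(sums - 100.0) <= 0.1 + 1e-9).all()

    def test_control_band_masses_match_gaussian(self):
        """Self-normed normal data: band shares approach the Phi masses."""
        rng = np.random.default_rng(7)
        n = 40000
        x = rng.normal(size=n)
        z = (x - x.mean()) / x.std(ddof=1)
        profiles = _profiles([[v] for v in z], columns=["T"])
        bp = band_prevalence(profiles)
        cell = bp[bp.measure == "T"].set_index("band")["percent"] / 100
        expect = {
            "average": stats.norm.cdf(1) - stats.norm.cdf(-1),
            "moderately impaired": stats.norm.cdf(-1) - stats.norm.cdf(-2),
            "above average": stats.norm.cdf(2) - stats.norm.cdf(1),
            "severely impaired": stats.norm.cdf(-2),
            "extremely high": stats.norm.cdf(-2),
        }
        for band, p in expect.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(cell[band] - p) < 3 * se + 0.0005  # 0.05pp rounding grain

    def test_empty_cell_is_undefined_not_zero(self):
        z = pd.DataFrame({"T": [0.5, np.nan]}, index=["a", "b"])
        group = pd.Series(["G1", "G2"], index=z.index)
        bp = band_prevalence(profiles_from_z(z, group))
        g2 = bp[(bp.group == "G2") & (bp.measure == "T")]
        assert g2["percent"].isna().all()
        assert (g2["count"] == 0).all()


class TestCriteria:
    def test_spec_validation(self):
        with pytest.raises(ConfigurationError):
            CriterionSpec(side="both")
        with pytest.raises(ConfigurationError):
            CriterionSpec(level=0)
        with pytest.raises(ConfigurationError):
            CriterionSpec(min_tests=0)
        with pytest.raises(ConfigurationError):
            CriterionSpec(mode="band_exclusive", level=1.5)

    @pytest.mark.parametrize(
        "z,spec_kwargs,expected",
        [
            ([-1.0, -1.2, 0.0], {"level": 1, "min_tests": 2}, True),
            ([-2.5, -2.1, 0.0], {"level": 1, "min_tests": 2}, True),  # severe nests
            ([0.0, 0.0, 0.0], {"level": 1, "min_tests": 1}, False),
            ([-2.5, -2.1, 0.0], {"level": 1, "min_tests": 2,
                                 "mode": "band_exclusive"}, False),
            ([2.1, 1.5, 0.0], {"side": "strength", "level": 1, "min_tests": 2}, True),
            ([-1.5, -1.5, np.nan], {"level": 1, "min_tests": 2}, False),  # not complete
            ([-1.5, -1.5, np.nan], {"level": 1, "min_tests": 2,
                                    "population": "per_test_available"}, True),
        ],
    )
    def test_meets_criterion(self, z, spec_kwargs, expected):
        assert meets_criterion(z, CriterionSpec(**spec_kwargs)) is expected

    def test_counting_three_participants(self):
        z = [
            [-1.2, -1.5, 0.0],   # qualifies on 2 at level 1
            [-1.1, 0.0, 0.0],    # 1 test only
            [-2.5, -2.2, 0.0],   # severe on 2
        ]
        profiles = _profiles(z)
        at1 = criterion_prevalence(profiles, CriterionSpec(level=1, min_tests=2))
        at2 = criterion_prevalence(profiles, CriterionSpec(level=2, min_tests=2))
        assert at1.summary["percent"].iloc[0] == pytest.approx(66.7, abs=0.05)
        assert at2.summary["percent"].iloc[0] == pytest.approx(33.3, abs=0.05)

    def test_distribution_accounts_for_everyone(self):
        rng = np.random.default_rng(1)
        profiles = _profiles(rng.normal(size=(50, 4)))
        prev = criterion_prevalence(profiles, CriterionSpec(level=1, min_tests=2))
        assert prev.distribution.sum(axis=1).iloc[0] == 50
        # percent-meeting equals the tail of the distribution
        tail = prev.distribution.iloc[0, 2:].sum()
        assert prev.summary["count"].iloc[0] == tail

    def test_cumulative_nesting_in_level_and_k(self):
        rng = np.random.default_rng(2)
        profiles = _profiles(rng.normal(-0.5, 1, size=(300, 6)))
        prev = {
            (L, k): criterion_prevalence(
                profiles, CriterionSpec(level=L, min_tests=k)
            ).summary["percent"].iloc[0]
            for L in (1, 2)
            for k in (1, 2, 3)
        }
        for k in (1, 2, 3):
            assert prev[(2, k)] <= prev[(1, k)]
        for L in (1, 2):
            assert prev[(L, 3)] <= prev[(L, 2)] <= prev[(L, 1)]

    def test_single_test_equivalence_with_band_prevalence(self):
        """m=1, k=1: the criterion equals the summed band mass at/beyond L."""
        rng = np.random.default_rng(3)
        profiles = _profiles(rng.normal(0, 1.3, size=(400, 1)), columns=["T"])
        prev = criterion_prevalence(profiles, CriterionSpec(level=1, min_tests=1))
        bp = band_prevalence(profiles)
        cell = bp[bp.measure == "T"].set_index("band")["count"]
        beyond = cell["moderately impaired"] + cell["severely impaired"]
        assert prev.summary["count"].iloc[0] == beyond


class TestMeanTests:
    def test_all_average_gives_zero(self):
        profiles = _profiles(np.zeros((5, 3)))
        mt = mean_tests_at_level(profiles)
        assert mt["mean"].iloc[0] == 0.0
        assert mt["sd"].iloc[0] == 0.0

    def test_hand_counts(self):
        z = [[-1.5, -1.2, 0.0, 0.0], [-1.5, -1.2, -1.1, -2.3]]  # counts 2 and 4
        mt = mean_tests_at_level(_profiles(z))
        assert mt["mean"].iloc[0] == 3.0
        assert mt["n"].iloc[0] == 2

    def test_independent_tests_match_binomial_mean(self):
        """rho=0: E[count] = m * Phi(-L + delta)."""
        rng = np.random.default_rng(4)
        m, n, delta = 6, 20000, 0.5
        profiles = _profiles(rng.normal(-delta, 1, size=(n, m)))
        mt = mean_tests_at_level(profiles, level=1.0)
        p = stats.norm.cdf(-1 + delta)
        se = np.sqrt(m * p * (1 - p) / n)  # conservative for the mean of a sum
        assert mt["mean"].iloc[0] == pytest.approx(m * p, abs=3 * se)
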