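import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from possum_audit import (
    POSSUM,
    band_equal_expected,
    band_equal_width,
    calibration_curve,
    calibration_table,
    default_cohort_spec,
    generate,
    hl_component,
    hl_test,
    oe_ratio,
)
from possum_audit.calibration import merge_degenerate_bands, poisson_exact_ci
from possum_audit.errors import (
    DegenerateBandError,
    StatisticalError,
    ValidationError,
)


class TestHLComponent:
    @pytest.mark.parametrize(
        "n,o,e,expected",
        [
            (1501, 15, 71.96, 47.36),  # lowest-risk band of a deciles table
            (216, 16, 52.36, 33.33),
            (133, 9, 45.64, 44.78),
            (203, 19, 28.64, 3.78),
        ],
    )
    def test_published_band_cells(self, n, o, e, expected):
        assert round(hl_component(n, o, e), 2) == expected

    def test_two_cell_equals_simplified_form(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 5000))
            o = int(rng.integers(0, n + 1))
            e = float(rng.uniform(1e-6, n - 1e-6))
            simplified = (o - e) ** 2 / (e * (1 - e / n))
            assert hl_component(n, o, e) == pytest.approx(simplified, abs=1e-10, rel=1e-10)

    def test_perfectly_calibrated_band_contributes_zero(self):
        assert hl_component(100, 25, 25.0) == 0.0

    @pytest.mark.parametrize("e", [0.0, -1.0, 100.0, 150.0])
    def test_degenerate_expected_rejected(self, e):
        with pytest.raises(DegenerateBandError):
            hl_component(100, 10, e)


class TestHLTest:
    def _bands(self, triples):
        pairs = []
        for n, o, e in triples:
            # build synthetic episodes whose sums reproduce (n, o, e)
            risks = np.full(n, e / n)
            outcomes = np.r_[np.ones(o, int), np.zeros(n - o, int)]
            pairs += list(zip(risks, outcomes))
        return pairs

    def test_statistic_is_sum_of_components_and_df_convention(self, default_cohort):
        bands, hl, _ = calibration_table(POSSUM, default_cohort, "equal_width", 10)
        occupied = [b for b in bands if not b.empty]
        assert hl.statistic == pytest.approx(
            sum(b.hl_component for b in occupied), abs=1e-9
        )
        assert hl.df == len(occupied) - 2

    def test_published_refit_statistic_p_value(self):
        assert chi2.sf(4.503, 8) == pytest.approx(0.81, abs=0.005)

    def test_zero_statistic_gives_p_one(self):
        pairs = self._bands([(50, 10, 10.0), (40, 10, 10.0), (25, 10, 10.0)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bands = band_equal_expected(pairs, 3)
        hl = hl_test(bands)
        assert hl.statistic == pytest.approx(0.0, abs=1e-9)
        assert hl.p_value == pytest.approx(1.0, abs=1e-12)
        assert not hl.poor_fit

    def test_explicit_df_override(self):
        pairs = self._bands([(50, 10, 10.0), (40, 10, 10.0), (25, 10, 10.0)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bands = band_equal_expected(pairs, 3)
        assert hl_test(bands, df=3).df == 3
        with pytest.raises(ValidationError):
            hl_test(bands, df=0)

    def test_too_few_bands_rejected(self):
        pairs = self._bands([(50, 5, 5.0), (50, 10, 10.0)])
        with pytest.raises(StatisticalError, match="3 non-empty"):
            hl_test(band_equal_width(pairs, 2))

    def test_null_rejection_rate_is_nominal_with_external_df(self):
        """Type-I calibration of the HL test for an externally given model.

        Cohorts are drawn from the truth model itself (no distortion), so
        rejections are false positives.  For a model not refitted on the
        data the statistic is chi-square with g (not g - 2) degrees of
        freedom; at that reference the alpha = 0.05 rejection rate is
        nominal.  Run at modest replication here; the acceptance suite
        repeats it at 1000 replicates.
        """
        spec = replace(default_cohort_spec(), n=2000, odds_multiplier=1.0)
        rejections = 0
        n_sim = 200
        for s in range(n_sim):
            cohort = generate(spec.with_seed(500_000 + s))
            from possum_audit import score_cohort

            risks, y = score_cohort(spec.truth_model, cohort)
            bands = merge_degenerate_bands(
                band_equal_width(list(zip(risks, y)), 10)
            )
            occupied = sum(not b.empty for b in bands)
            hl = hl_test(bands, df=occupied)
            rejections += hl.p_value <= 0.05
        assert 0.02 <= rejections / n_sim <= 0.09


class TestBanding:
    def test_equal_width_occupancy_example(self):
        pairs = [(0.05, 0), (0.15, 0), (0.95, 1)]
        bands = band_equal_width(pairs, 10)
        occupancy = [b.n_patients for b in bands]
        assert occupancy == [1, 1, 0, 0, 0, 0, 0, 0, 0, 1]

    def test_half_open_convention_at_band_edge(self):
        bands = band_equal_width([(0.10, 0), (0.1999999, 0), (0.2, 1)], 10)
        assert bands[1].n_patients == 2  # [0.10, 0.20)
        assert bands[2].n_patients == 1  # 0.2 falls in [0.20, 0.30)

    def test_final_band_closed_at_one(self):
        bands = band_equal_width([(0.999999, 1), (0.05, 0)], 10)
        assert bands[-1].n_patients == 1

    @given(st.integers(0, 2**31 - 1), st.integers(2, 12))
    @settings(max_examples=40, deadline=None)
    def test_partition_conservation_both_schemes(self, seed, k):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(k + 5, 400))
        risks = rng.uniform(0.001, 0.999, n)
        outcomes = rng.integers(0, 2, n)
        pairs = list(zip(risks, outcomes))
        for scheme in (band_equal_width, band_equal_expected):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    bands = scheme(pairs, k)
                except StatisticalError:
                    continue  # k exceeded distinct risks (equal_expected)
            assert sum(b.n_patients for b in bands) == n
            assert sum(b.observed_deaths for b in bands) == outcomes.sum()
            assert sum(b.expected_deaths for b in bands) == pytest.approx(risks.sum())

    def test_equal_expected_tie_groups_never_split(self):
        pairs = [(0.1, 0), (0.1, 0), (0.4, 1), (0.4, 0)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bands = band_equal_expected(pairs, 2)
        assert [b.expected_deaths for b in bands] == pytest.approx([0.2, 0.8])
        assert [b.n_patients for b in bands] == [2, 2]

    def test_equal_expected_uniform_risks_balanced(self):
        risks = np.linspace(0.1, 0.9, 12)
        pairs = [(r, 0) for r in risks]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bands = band_equal_expected(pairs, 4)
        # expected deaths per band within one episode's risk of the ideal quarter
        ideal = risks.sum() / 4
        for b in bands:
            assert abs(b.expected_deaths - ideal) < risks.max()

    @pytest.mark.parametrize("scheme", [band_equal_width, band_equal_expected])
    def test_k_below_two_rejected(self, scheme):
        with pytest.raises(ValidationError):
            scheme([(0.1, 0), (0.2, 1), (0.3, 0)], 1)

    def test_equal_expected_k_beyond_distinct_risks_rejected(self):
        with pytest.raises(StatisticalError, match="distinct"):
            band_equal_expected([(0.1, 0), (0.1, 1), (0.2, 0)], 3)

    def test_low_expected_deaths_warns_not_errors(self):
        with pytest.warns(UserWarning, match="5 per band"):
            band_equal_expected([(0.01, 0), (0.02, 0), (0.03, 1), (0.04, 0)], 2)


class TestOERatio:
    @pytest.mark.parametrize(
        "o,e,expected",
        [(88, 350.94, 0.25), (88, 162.35, 0.54), (15, 71.96, 0.21), (19, 28.64, 0.66)],
    )
    def test_published_point_estimates(self, o, e, expected):
        ratio, lo, hi = oe_ratio(o, e)
        assert round(ratio, 2) == expected
        assert lo < ratio < hi

    def test_zero_observed(self):
        ratio, lo, hi = oe_ratio(0, 10.0)
        assert ratio == 0.0 and lo == 0.0 and hi > 0

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(StatisticalError):
            oe_ratio(5, 0.0)

    def test_garwood_interval_inverts_poisson_tails(self):
        # exact interval endpoints satisfy the defining tail equations
        from scipy.stats import poisson

        for o in (3, 30, 88):
            lo, hi = poisson_exact_ci(o)
            assert poisson.sf(o - 1, lo) == pytest.approx(0.025, abs=1e-10)
            assert poisson.cdf(o, hi) == pytest.approx(0.025, abs=1e-10)

    def test_poisson_ci_coverage_nominal(self):
        """Garwood CI covers a true O:E of 1 at close to 95% (200 draws here;
        the acceptance suite uses 1000)."""
        E = 88.0
        rng = np.random.default_rng(99)
        cover = sum(
            (lambda r: r[1] <= 1.0 <= r[2])(oe_ratio(int(rng.poisson(E)), E))
            for _ in range(200)
        )
        assert 0.91 <= cover / 200 <= 0.99


class TestCalibrationTable:
    def test_well_calibrated_cohort_bands_cover_unity(self):
        """With outcomes drawn from the model itself, the per-band O:E CIs
        should cover 1 almost everywhere (binomial sampling error only)."""
        spec = replace(default_cohort_spec(), n=10_000, odds_multiplier=1.0)
        for s in range(3):
            cohort = generate(spec.with_seed(777 + s))
            bands, hl, overall = calibration_table(
                spec.truth_model, cohort, "equal_width", 10
            )
            occupied = [b for b in bands if not b.empty]
            covering = sum(b.oe_ci[0] <= 1.0 <= b.oe_ci[1] for b in occupied)
            assert covering >= len(occupied) - 2
            assert overall.oe_ci[0] <= 1.0 <= overall.oe_ci[1]

    def test_half_odds_distortion_shows_significant_overprediction(self):
        spec = replace(default_cohort_spec(), n=10_000, odds_multiplier=0.5)
        cohort = generate(spec.with_seed(4242))
        _, _, overall = calibration_table(spec.truth_model, cohort, "equal_width", 10)
        assert overall.oe_ratio < 0.75
        assert overall.oe_ci[1] < 1.0  # significantly below unity

    def test_single_band_request_rejected(self, default_cohort):
        with pytest.raises(ValidationError):
            calibration_table(POSSUM, default_cohort, "equal_width", 1)

    def test_unknown_scheme_rejected(self, default_cohort):
        with pytest.raises(ValidationError, match="scheme"):
            calibration_table(POSSUM, default_cohort, "nonsense", 10)

    def test_overall_row_pools_bands(self, default_cohort):
        bands, hl, overall = calibration_table(POSSUM, default_cohort, "equal_width", 10)
        assert overall.n_patients == len(default_cohort)
        assert overall.observed_deaths == default_cohort.n_deaths
        assert overall.expected_deaths == pytest.approx(
            sum(b.expected_deaths for b in bands)
        )
        assert overall.hl_component == pytest.approx(hl.statistic)


class TestCalibrationCurve:
    def test_rates_and_identity(self, default_cohort):
        bands, _, _ = calibration_table(POSSUM, default_cohort, "equal_width", 10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve = calibration_curve(bands)
        occupied = [b for b in bands if not b.empty]
        assert len(curve) == len(occupied)
        for (mean_risk, rate, lo, hi), band in zip(curve, occupied):
            assert rate == pytest.approx(band.observed_deaths / band.n_patients)
            assert 0 <= lo <= rate <= hi <= 1

    def test_all_deaths_band_rate_one(self):
        bands = band_equal_width([(0.95, 1), (0.96, 1), (0.2, 0)], 10)
        curve = calibration_curve([b for b in bands if not b.empty])
        assert curve[-1][1] == 1.0

    def test_example_band_rate(self):
        # 15 deaths among 1501 patients -> 0.00999
        rate = 15 / 1501
        assert rate == pytest.approx(0.00999, abs=5e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            calibration_curve([])
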