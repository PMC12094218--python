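import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cosinorpower import (
    DesignFileError,
    SamplingDesign,
    ValidationError,
    cosinor_variance,
    make_evenly_spaced,
    make_uniform_grid,
    read_design_csv,
    rhythmic_moments,
)
from .conftest import random_design


class TestConstructors:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(n_per_cycle=4, n_cycles=1, period=24, replicates=1, start=0), [0, 6, 12, 18]),
            (dict(n_per_cycle=2, n_cycles=2, period=24, replicates=1, start=0), [0, 12, 24, 36]),
            (
                dict(n_per_cycle=6, n_cycles=1, period=24, replicates=2, start=1),
                np.repeat([1, 5, 9, 13, 17, 21], 2),
            ),
        ],
    )
    def test_evenly_spaced_times(self, kwargs, expected):
        d = make_evenly_spaced(**kwargs)
        np.testing.assert_allclose(d.times, expected)

    @pytest.mark.parametrize("bad", ["n_per_cycle", "n_cycles", "replicates"])
    def test_evenly_spaced_rejects_nonpositive_counts(self, bad):
        kwargs = dict(n_per_cycle=4, n_cycles=1, replicates=1)
        kwargs[bad] = 0
        with pytest.raises(ValidationError):
            make_evenly_spaced(**kwargs)

    def test_uniform_grid_includes_both_endpoints(self):
        d = make_uniform_grid(5, 7, 24, period=24)
        assert d.n == 24
        assert d.times[0] == 5.0 and d.times[-1] == 7.0
        np.testing.assert_allclose(np.diff(d.times), 2.0 / 23.0)

    def test_uniform_grid_degenerate_and_whole_day(self):
        assert make_uniform_grid(0, 0, 1).times.tolist() == [0.0]
        np.testing.assert_allclose(make_uniform_grid(0, 23, 24).times, np.arange(24.0))

    def test_uniform_grid_rejects_reversed_interval(self):
        with pytest.raises(ValidationError):
            make_uniform_grid(7, 5, 24)

    def test_design_validation(self):
        with pytest.raises(ValidationError):
            SamplingDesign([], 24)
        with pytest.raises(ValidationError):
            SamplingDesign([0, 6], 0)
        d = SamplingDesign([0.0, 6.0], 24.0)
        assert d.omega * d.period == pytest.approx(2 * math.pi, abs=1e-15)


class TestMoments:
    def test_evenly_spaced_quarter_day(self, quarter_day):
        m = rhythmic_moments(quarter_day)
        assert m.mu_cos == pytest.approx(0, abs=1e-12)
        assert m.mu_sin == pytest.approx(0, abs=1e-12)
        assert m.sigma2_cos == pytest.approx(0.5, abs=1e-12)
        assert m.sigma2_sin == pytest.approx(0.5, abs=1e-12)
        assert m.sigma_cossin == pytest.approx(0, abs=1e-12)
        assert m.centered and m.phase_invariant

    def test_single_point(self):
        m = rhythmic_moments(SamplingDesign([0.0], 24.0))
        assert (m.mu_cos, m.mu_sin) == (1.0, 0.0)
        assert m.sigma2_cos == m.sigma2_sin == m.sigma_cossin == 0.0

    def test_clustered_grid_not_centered(self, clustered):
        m = rhythmic_moments(clustered)
        # all phases near pi/2, so the sine regressor averages near 1
        assert not m.centered
        assert m.mu_sin > 0.9
        assert not m.phase_invariant

    @pytest.mark.parametrize("n_per_cycle", [3, 4, 5, 7, 12, 24])
    def test_evenly_spaced_moments_are_half(self, n_per_cycle):
        m = rhythmic_moments(make_evenly_spaced(n_per_cycle, n_cycles=2, replicates=2, start=3.7))
        assert m.centered and m.phase_invariant
        assert m.sigma2_cos == pytest.approx(0.5, abs=1e-10)
        assert m.sigma2_sin == pytest.approx(0.5, abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000), k=st.integers(-5, 5))
    def test_shift_invariance_and_pythagoras(self, seed, k):
        """Moments are invariant to whole-period shifts and satisfy cos^2+sin^2=1."""
        d = random_design(np.random.default_rng(seed))
        m, ms = rhythmic_moments(d), rhythmic_moments(d.shifted(k))
        for attr in ("mu_cos", "mu_sin", "sigma2_cos", "sigma2_sin", "sigma_cossin"):
            assert getattr(m, attr) == pytest.approx(getattr(ms, attr), abs=1e-9)
        assert m.sigma2_cos + m.mu_cos**2 + m.sigma2_sin + m.mu_sin**2 == pytest.approx(1.0, abs=1e-12)
        assert abs(m.sigma_cossin) <= math.sqrt(m.sigma2_cos * m.sigma2_sin) + 1e-12


class TestCosinorVariance:
    def test_phase_invariant_design_is_half_for_any_phase(self, quarter_day):
        for phi in np.linspace(-math.pi, math.pi, 17):
            _, s2 = cosinor_variance(quarter_day, phi)
            assert s2 == pytest.approx(0.5, abs=1e-12)

    def test_single_point_zero_variance(self):
        _, s2 = cosinor_variance(SamplingDesign([3.0], 24.0), 1.2)
        assert s2 == 0.0

    def test_clustered_grid_value(self, clustered):
        # brute-force oracle: population variance of cos(w t - pi/2) on the grid
        x = np.cos(2 * np.pi / 24 * clustered.times - np.pi / 2)
        expected = float(np.mean(x**2) - np.mean(x) ** 2)
        _, s2 = cosinor_variance(clustered, np.pi / 2)
        assert s2 == pytest.approx(expected, rel=1e-12)
        assert s2 == pytest.approx(1.21e-4, rel=5e-3)
        assert 24 * 9 * s2 == pytest.approx(0.026, abs=5e-4)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000), phi=st.floats(-math.pi, math.pi))
    def test_decomposition_identity(self, seed, phi):
        """sigma2_cosinor = cos^2(phi) s2_cos + sin^2(phi) s2_sin + 2 cos sin s_cs."""
        d = random_design(np.random.default_rng(seed))
        m = rhythmic_moments(d)
        mu, s2 = cosinor_variance(d, phi)
        composed = (
            math.cos(phi) ** 2 * m.sigma2_cos
            + math.sin(phi) ** 2 * m.sigma2_sin
            + 2 * math.cos(phi) * math.sin(phi) * m.sigma_cossin
        )
        assert s2 == pytest.approx(composed, abs=1e-12)
        # phi = 0 and pi/2 recover the raw cos / sin moments
        assert cosinor_variance(d, 0.0) == pytest.approx((m.mu_cos, m.sigma2_cos), abs=1e-12)
        assert cosinor_variance(d, math.pi / 2) == pytest.approx((m.mu_sin, m.sigma2_sin), abs=1e-12)

    def test_constant_in_phase_iff_phase_invariant(self, quarter_day, clustered):
        grid = np.linspace(-math.pi, math.pi, 181)
        flat = [cosinor_variance(quarter_day, p)[1] for p in grid]
        assert np.ptp(flat) < 1e-12
        varying = [cosinor_variance(clustered, p)[1] for p in grid]
        assert np.ptp(varying) > 1e-3


class TestDesignCsv:
    def test_roundtrip_with_period_comment(self):
        text = "# period=12\ntime\n0\n3\n6\n9\n"
        d = read_design_csv(io.StringIO(text))
        assert d.period == 12.0 and d.n == 4

    def test_explicit_period_wins_over_file(self):
        d = read_design_csv(io.StringIO("# period=12\ntime\n0\n6\n"), period=24.0)
        assert d.period == 24.0

    @pytest.mark.parametrize(
        "text",
        ["", "hours\n1\n2\n", "time\n0\nnot_a_number\n", "# period=24\n"],
    )
    def test_malformed_files_raise(self, text):
        with pytest.raises(DesignFileError):
            read_design_csv(io.StringIO(text))

    def test_missing_period_raises(self):
        with pytest.raises(DesignFileError, match="period"):
            read_design_csv(io.StringIO("time\n0\n6\n"))
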