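import cmath

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repairscape import (
    BinnedSignal,
    DYAD_PERIOD_GRID,
    NUCLEOSOME_PERIOD_GRID,
    permutation_pvalue,
    power_spectrum,
    restrict_downstream,
    snr,
)


def oracle_power(x, period_bins):
    """Independent direct-summation oracle: complex arithmetic term by
    term, no vectorisation shared with the implementation."""
    n = len(x)
    mean = sum(x) / n
    acc = complex(0.0, 0.0)
    for i, v in enumerate(x):
        acc += (v - mean) * cmath.exp(complex(0.0, -2.0 * cmath.pi * i / period_bins))
    return abs(acc) ** 2 / n


class TestPowerSpectrum:
    def test_constant_signal_zero_power(self):
        spec = power_spectrum(np.full(50, 3.7), [100, 160, 200], bin_size=10)
        assert np.allclose(spec.raw_power, 0.0)

    def test_cosine_argmax_at_160(self):
        n = 201
        x = np.cos(2 * np.pi * np.arange(n) / 16.0)
        spec = power_spectrum(x, NUCLEOSOME_PERIOD_GRID, bin_size=10)
        assert spec.argmax_period_bp == 160.0

    def test_relative_power_mean_one(self, rng):
        x = rng.normal(size=80)
        spec = power_spectrum(x, NUCLEOSOME_PERIOD_GRID, bin_size=10)
        assert spec.relative_power.mean() == pytest.approx(1.0)

    def test_matches_direct_sum_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 513))
            x = rng.normal(size=n)
            periods_bins = rng.uniform(2.5, n / 2.0, size=5)
            spec = power_spectrum(x, periods_bins * 10.0, bin_size=10)
            for j, p in enumerate(periods_bins):
                want = oracle_power(list(x), p)
                if want > 1e-12:
                    assert abs(spec.raw_power[j] - want) / want <= 1e-9
                else:
                    assert abs(spec.raw_power[j] - want) <= 1e-12

    def test_sub_nyquist_period_rejected(self):
        with pytest.raises(ValueError):
            power_spectrum(np.arange(50.0), [15.0], bin_size=10)

    def test_missing_bins_mean_imputed(self, rng):
        x = rng.normal(size=60)
        x[10] = np.nan
        spec = power_spectrum(x, [100, 160], bin_size=10)
        assert spec.n_imputed == 1
        x2 = x.copy()
        x2[10] = np.nanmean(x)
        spec2 = power_spectrum(x2, [100, 160], bin_size=10)
        assert np.allclose(spec.raw_power, spec2.raw_power)

    def test_amplitude_equivariance(self, rng):
        x = rng.normal(size=120)
        a = power_spectrum(x, NUCLEOSOME_PERIOD_GRID, bin_size=10)
        b = power_spectrum(3.0 * x, NUCLEOSOME_PERIOD_GRID, bin_size=10)
        assert np.allclose(b.raw_power, 9.0 * a.raw_power)
        assert snr(b, 160) == pytest.approx(snr(a, 160))

    def test_translation_robustness_integer_period(self):
        # circular shift of a cosine with integer bin period leaves the
        # power at its own period unchanged
        n = 160
        x = np.cos(2 * np.pi * np.arange(n) / 16.0)
        p0 = power_spectrum(x, [160.0], bin_size=10).raw_power[0]
        for shift in (1, 5, 11):
            xs = np.roll(x, shift)
            ps = power_spectrum(xs, [160.0], bin_size=10).raw_power[0]
            assert abs(ps - p0) / p0 <= 1e-9


class TestSnr:
    def test_arithmetic(self):
        spec = power_spectrum(
            np.cos(2 * np.pi * np.arange(201) / 16.0),
            NUCLEOSOME_PERIOD_GRID,
            bin_size=10,
        )
        i = list(NUCLEOSOME_PERIOD_GRID).index(160.0)
        manual = spec.raw_power[i] / np.delete(spec.raw_power, i).mean()
        assert snr(spec, 160) == pytest.approx(manual)

    def test_raw_and_relative_identical(self, rng):
        x = rng.normal(size=100)
        spec = power_spectrum(x, NUCLEOSOME_PERIOD_GRID, bin_size=10)
        i = list(NUCLEOSOME_PERIOD_GRID).index(160.0)
        rel = spec.relative_power[i] / np.delete(spec.relative_power, i).mean()
        assert snr(spec, 160) == pytest.approx(rel)

    def test_target_not_in_grid_raises(self, rng):
        spec = power_spectrum(rng.normal(size=50), [100, 200], bin_size=10)
        with pytest.raises(ValueError):
            snr(spec, 160)

    def test_pure_cosine_dominates_all_other_candidates(self):
        x = np.cos(2 * np.pi * np.arange(201) / 16.0)
        spec = power_spectrum(x, NUCLEOSOME_PERIOD_GRID, bin_size=10)
        s160 = snr(spec, 160)
        for p in NUCLEOSOME_PERIOD_GRID:
            if p != 160.0:
                assert s160 > snr(spec, p)

    def test_white_noise_median_snr_near_one(self):
        rng = np.random.default_rng(0)
        snrs = []
        for _ in range(300):
            x = rng.normal(size=201)
            spec = power_spectrum(x, NUCLEOSOME_PERIOD_GRID, bin_size=10)
            snrs.append(snr(spec, 160))
        assert abs(np.median(snrs) - 1.0) < 0.2


class TestPermutationPvalue:
    def test_strong_cosine_gets_p_zero(self):
        rng = np.random.default_rng(1)
        x = np.cos(2 * np.pi * np.arange(201) / 16.0) + rng.normal(0, 0.01, 201)
        t = permutation_pvalue(x, 160, NUCLEOSOME_PERIOD_GRID,
                               n_permutations=1000, seed=3, bin_size=10)
        assert t.empirical_p == 0.0
        assert t.empirical_p_plus_one == pytest.approx(1 / 1001)

    def test_constant_signal_p_one(self):
        t = permutation_pvalue(np.ones(60), 160, NUCLEOSOME_PERIOD_GRID,
                               n_permutations=100, seed=0, bin_size=10)
        assert t.empirical_p == 1.0

    def test_deterministic_under_seed(self, rng):
        x = rng.normal(size=101)
        a = permutation_pvalue(x, 160, NUCLEOSOME_PERIOD_GRID, 200, seed=9,
                               bin_size=10)
        b = permutation_pvalue(x, 160, NUCLEOSOME_PERIOD_GRID, 200, seed=9,
                               bin_size=10)
        assert a.empirical_p == b.empirical_p and a.snr == b.snr

    def test_null_calibration_quick(self):
        """Under iid noise, P(p <= 0.05) stays near 0.05."""
        rng = np.random.default_rng(5)
        hits = 0
        n_sig = 200
        for s in range(n_sig):
            x = rng.normal(size=101)
            t = permutation_pvalue(x, 160, NUCLEOSOME_PERIOD_GRID,
                                   n_permutations=100, seed=s, bin_size=10)
            hits += t.empirical_p <= 0.05
        assert 0.01 <= hits / n_sig <= 0.10


class TestRestrictDownstream:
    @staticmethod
    def _profile(n_bins, bin_size):
        half = (n_bins * bin_size) // 2
        rel = np.arange(n_bins) * bin_size - half
        return BinnedSignal(np.arange(n_bins, dtype=float), float(bin_size),
                            rel_starts=rel)

    def test_summit_window_offset_250(self):
        out = restrict_downstream(self._profile(201, 10), 250)
        assert out.n_bins == 75

    def test_dyad_window_offset_20(self):
        out = restrict_downstream(self._profile(81, 2), 20)
        assert out.n_bins == 30

    def test_offset_zero_gives_downstream_half(self):
        out = restrict_downstream(self._profile(201, 10), 0)
        assert out.n_bins == 100
        assert (out.rel_starts >= 0).all()

    def test_offset_beyond_window_raises(self):
        with pytest.raises(ValueError):
            restrict_downstream(self._profile(201, 10), 5_000)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    st.lists(st.floats(-100, 100), min_size=8, max_size=64),
    st.floats(2.6, 30.0),
)
def test_power_nonnegative_and_scale_equivariant(values, period_bins):
    x = np.asarray(values)
    spec = power_spectrum(x, [period_bins * 10], bin_size=10)
    assert spec.raw_power[0] >= 0
    spec2 = power_spectrum(2.0 * x, [period_bins * 10], bin_size=10)
    assert spec2.raw_power[0] == pytest.approx(4.0 * spec.raw_power[0], abs=1e-9)
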