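import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kardia.io import RRSeries
from kardia.metrics import (
    BANDS,
    PSD,
    band_powers,
    poincare,
    time_domain,
    triangular_index,
    welch_psd,
)
from kardia.preprocess import UniformTachogram


def series_of(values):
    return RRSeries(intervals=np.asarray(values, dtype=float))


rr_lists = st.lists(
    st.floats(min_value=400.0, max_value=1500.0, allow_nan=False),
    min_size=3, max_size=200,
)


class TestTimeDomain:
    def test_two_point_sdnn_closed_form(self):
        p = time_domain(series_of([800.0, 810.0]))
        assert p.sdnn == pytest.approx(7.0711, abs=1e-4)

    @pytest.mark.parametrize("n", [3, 10, 101])
    def test_alternating_rmssd_and_nn50(self, n):
        rr = [800.0 if k % 2 == 0 else 810.0 for k in range(n)]
        p = time_domain(series_of(rr))
        assert p.rmssd == pytest.approx(10.0)
        assert p.nn50 == 0

    def test_nn50_counts_strict_exceedances(self):
        p = time_domain(series_of([800.0, 860.0, 800.0]))
        assert p.nn50 == 2
        assert p.pnn50 == pytest.approx(100.0)
        # exactly 50 ms is not counted (strict inequality)
        p50 = time_domain(series_of([800.0, 850.0, 800.0]))
        assert p50.nn50 == 0

    @settings(max_examples=50, deadline=None)
    @given(rr_lists, st.floats(min_value=-100, max_value=100))
    def test_translation_invariance(self, values, shift):
        base = time_domain(series_of(values))
        arr = np.asarray(values) + shift
        if np.any(arr <= 0):
            return
        moved = time_domain(series_of(arr))
        assert moved.sdnn == pytest.approx(base.sdnn, abs=1e-9)
        assert moved.rmssd == pytest.approx(base.rmssd, abs=1e-9)


class TestTriangularIndex:
    def test_identical_intervals(self):
        assert triangular_index(series_of(np.full(100, 800.0))) == 1.0

    def test_two_equal_bins(self):
        rr = np.concatenate([np.full(50, 800.0), np.full(50, 900.0)])
        assert triangular_index(series_of(rr)) == pytest.approx(2.0)

    def test_four_equal_bins(self):
        width = 1000.0 / 128.0
        centers = [800.0 + (k + 0.5) * width for k in range(4)]
        rr = np.repeat(centers, 25)
        assert triangular_index(series_of(rr)) == pytest.approx(4.0)

    @settings(max_examples=30, deadline=None)
    @given(rr_lists)
    def test_bounds(self, values):
        t = triangular_index(series_of(values))
        assert 1.0 <= t <= len(values)


def make_tacho(signal, fs=4.0):
    return UniformTachogram(values=np.asarray(signal, float), fs=fs)


class TestWelchPSD:
    def test_constant_signal_zero_density(self):
        psd = welch_psd(make_tacho(np.full(1200, 800.0)))
        assert np.all(psd.density < 1e-12)

    def test_sinusoid_parseval(self):
        # amplitude-A sinusoid carries A²/2 total power
        t = np.arange(1200) / 4.0
        sig = 800.0 + 30.0 * np.sin(2 * np.pi * 0.25 * t)
        psd = welch_psd(make_tacho(sig))
        total = np.trapezoid(psd.density, psd.freqs)
        assert total == pytest.approx(450.0, rel=0.05)

    def test_white_noise_variance_conserved(self):
        rng = np.random.default_rng(77)
        sig = 20.0 * rng.standard_normal(1200)
        psd = welch_psd(make_tacho(sig))
        total = np.trapezoid(psd.density, psd.freqs)
        assert total == pytest.approx(np.var(sig), rel=0.10)

    def test_short_tachogram_rejected(self):
        from kardia.preprocess import InsufficientDataError
        with pytest.raises(InsufficientDataError):
            welch_psd(make_tacho(np.full(100, 800.0)))


class TestBandPowers:
    def _psd_with_peak(self, f0, power):
        freqs = np.linspace(0.0, 0.5, 501)
        density = np.zeros_like(freqs)
        idx = int(round(f0 / 0.001))
        # triangular peak integrating to `power`
        density[idx - 1:idx + 2] = [power / 0.002 / 2, power / 0.002,
                                    power / 0.002 / 2]
        return PSD(freqs=freqs, density=density)

    def test_hf_peak_lands_in_hf(self):
        bp = band_powers(self._psd_with_peak(0.25, 100.0))
        assert bp["hf"] == pytest.approx(bp["total_power"])
        assert bp["vlf"] == 0.0 and bp["lf"] == 0.0

    def test_lf_peak_lands_in_lf(self):
        bp = band_powers(self._psd_with_peak(0.10, 100.0))
        assert bp["lf"] == pytest.approx(bp["total_power"])

    def test_equal_lf_hf_unit_ratio(self):
        freqs = np.linspace(0.0, 0.5, 501)
        density = np.zeros_like(freqs)
        lf = (freqs >= BANDS["lf"][0]) & (freqs < BANDS["lf"][1])
        hf = (freqs >= BANDS["hf"][0]) & (freqs < BANDS["hf"][1])
        density[lf] = 1.0 / (0.15 - 0.04)
        density[hf] = 1.0 / (0.40 - 0.15)
        bp = band_powers(PSD(freqs=freqs, density=density))
        assert bp["lf_hf"] == pytest.approx(1.0, rel=0.05)

    def test_total_is_band_sum(self):
        rng = np.random.default_rng(5)
        freqs = np.linspace(0.0, 0.5, 501)
        psd = PSD(freqs=freqs, density=rng.uniform(0, 10, freqs.size))
        bp = band_powers(psd)
        assert bp["total_power"] == pytest.approx(
            bp["vlf"] + bp["lf"] + bp["hf"], rel=1e-12)

    def test_zero_hf_flags_ratio_undefined(self):
        bp = band_powers(self._psd_with_peak(0.10, 100.0))
        assert np.isnan(bp["lf_hf"])


class TestPoincare:
    def test_constant_series_zero_axes(self):
        sd1, sd2 = poincare(series_of(np.full(10, 800.0)))
        assert sd1 == 0.0 and sd2 == 0.0

    def test_alternating_series_matches_rotation_oracle(self):
        # successive differences alternate ±10 ms
        rr = np.array([810.0 if k % 2 else 800.0 for k in range(100)])
        sd1, sd2 = poincare(series_of(rr))
        # oracle: rotate the (RR_k, RR_{k+1}) scatter by 45 degrees and take
        # the sample SD along the short (anti-diagonal) axis
        x, y = rr[:-1], rr[1:]
        u = (y - x) / np.sqrt(2)
        assert sd1 == pytest.approx(np.std(u, ddof=1), rel=1e-12)
        assert sd1 == pytest.approx(10.0 / np.sqrt(2), rel=0.05)

    @settings(max_examples=50, deadline=None)
    @given(rr_lists)
    def test_axis_identity_with_sdnn(self, values):
        """sd1² + sd2² = 2·sdnn² under the sample-variance definitions."""
        s = series_of(values)
        sd1, sd2 = poincare(s)
        sdnn = time_domain(s).sdnn
        if sdnn == 0:
            assert sd1 == sd2 == 0
        elif sd2 > 0:
            assert sd1**2 + sd2**2 == pytest.approx(2 * sdnn**2, rel=1e-6)
        else:
            # strongly anti-correlated series: the long axis clamps at zero
            assert sd1**2 >= 2 * sdnn**2
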