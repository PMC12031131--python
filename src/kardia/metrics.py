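"""Linear HRV indices: time-domain, geometric, spectral and Poincaré.

Conventions (fixed so results are reproducible run-to-run):

* SDNN and RMSSD use sample (N−1) denominators, matching common HRV software.
* NN50 counts successive differences strictly greater than 50 ms.
* Spectral bands follow the short-term standard: VLF [0.0033, 0.04) Hz,
  LF [0.04, 0.15) Hz, HF [0.15, 0.4) Hz, half-open on the right.
* The triangular index bins the RR histogram at multiples of 1/128 s.
* Poincaré SD1/SD2 are the dispersion of the lag-1 return map across and
  along the identity line; under these definitions
  ``sd1² + sd2² = 2·sdnn²`` identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
from scipy import signal

from .io import RRSeries
from .preprocess import InsufficientDataError, UniformTachogram

__all__ = [
    "HRVProfile",
    "PSD",
    "BANDS",
    "time_domain",
    "triangular_index",
    "welch_psd",
    "band_powers",
    "poincare",
    "compute_profile",
]

#: short-term spectral band edges, Hz, half-open [lo, hi)
BANDS: dict[str, tuple[float, float]] = {
    "vlf": (0.0033, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.40),
}

#: triangular-index histogram bin width: 1/128 s in ms
TRI_BIN_MS = 1000.0 / 128.0


@dataclass
class HRVProfile:
    """Per-subject vector of HRV indices.

    Units: sdnn, rmssd, sd1, sd2 in ms; powers in ms²; pnn50 in percent;
    nn50 a count; rr_tri, lf_hf and d2 dimensionless.  ``lf_hf`` is NaN when
    HF power is zero (degenerate input), never infinite.  ``d2`` is filled
    by the nonlinear stage.
    """

    sdnn: float = np.nan
    rmssd: float = np.nan
    nn50: float = np.nan
    pnn50: float = np.nan
    rr_tri: float = np.nan
    vlf: float = np.nan
    lf: float = np.nan
    hf: float = np.nan
    total_power: float = np.nan
    lf_hf: float = np.nan
    sd1: float = np.nan
    sd2: float = np.nan
    d2: float = np.nan
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self) if f.name != "meta"}


@dataclass(frozen=True)
class PSD:
    """One-sided power spectral density of the RR tachogram (ms²/Hz)."""

    freqs: np.ndarray
    density: np.ndarray

    @property
    def resolution(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def time_domain(series: RRSeries) -> HRVProfile:
    """SDNN, RMSSD, NN50 and pNN50 of an RR series.

    sdnn: sample SD (ddof=1).  rmssd: root mean square over the N−1
    successive differences (denominator N−1 for N beats, the canonical
    definition).
    """
    rr = series.intervals
    if rr.size < 2:
        raise InsufficientDataError("time-domain indices need ≥ 2 beats")
    diffs = np.diff(rr)
    sdnn = float(np.std(rr, ddof=1))
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    nn50 = int(np.sum(np.abs(diffs) > 50.0))
    pnn50 = 100.0 * nn50 / diffs.size
    return HRVProfile(sdnn=sdnn, rmssd=rmssd, nn50=nn50, pnn50=pnn50)


def triangular_index(series: RRSeries, bin_width: float = TRI_BIN_MS) -> float:
    """Total beat count over the modal bin height of the RR histogram.

    Bins are aligned at multiples of ``bin_width`` (default 1/128 s), the
    canonical discretisation for this index.
    """
    rr = series.intervals
    if rr.size < 2:
        raise InsufficientDataError("triangular index needs ≥ 2 beats")
    bins = np.floor(rr / bin_width).astype(np.int64)
    counts = np.bincount(bins - bins.min())
    return float(rr.size / counts.max())


def welch_psd(tacho: UniformTachogram, window_s: float = 150.0,
              overlap: float = 0.5) -> PSD:
    """Welch periodogram of the tachogram (Hann window, mean removed).

    Density is scaled so its integral over frequency equals the signal
    variance (up to windowing bias).  Units ms²/Hz.
    """
    if tacho.duration_s < window_s:
        raise InsufficientDataError(
            f"tachogram spans {tacho.duration_s:.0f} s < window {window_s:.0f} s"
        )
    nperseg = int(round(window_s * tacho.fs))
    freqs, density = signal.welch(
        tacho.values,
        fs=tacho.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        detrend="constant",
        scaling="density",
    )
    return PSD(freqs=freqs, density=density)


def band_powers(psd: PSD) -> dict[str, float]:
    """Integrate the PSD over the VLF/LF/HF bands (trapezoidal rule).

    Returns a dict with vlf, lf, hf, total_power (their sum) and lf_hf
    (NaN when hf is zero).
    """
    if psd.freqs[-1] < BANDS["hf"][1]:
        raise ValueError(
            f"PSD covers only up to {psd.freqs[-1]:.3f} Hz; need ≥ 0.4 Hz"
        )
    out: dict[str, float] = {}
    for name, (lo, hi) in BANDS.items():
        mask = (psd.freqs >= lo) & (psd.freqs < hi)
        if mask.sum() < 2:
            out[name] = 0.0
        else:
            out[name] = float(np.trapezoid(psd.density[mask], psd.freqs[mask]))
    out["total_power"] = out["vlf"] + out["lf"] + out["hf"]
    out["lf_hf"] = out["lf"] / out["hf"] if out["hf"] > 0 else float("nan")
    return out


def poincare(series: RRSeries) -> tuple[float, float]:
    """Poincaré short-axis (SD1) and long-axis (SD2) dispersions, ms.

    SD1² = var(ΔRR)/2 with the sample variance of successive differences;
    SD2² = 2·SDNN² − SD1² (floored at zero against round-off).
    """
    rr = series.intervals
    if rr.size < 3:
        raise InsufficientDataError("Poincaré indices need ≥ 3 beats")
    sd1_sq = float(np.var(np.diff(rr), ddof=1)) / 2.0
    sdnn = float(np.std(rr, ddof=1))
    sd2_sq = max(0.0, 2.0 * sdnn**2 - sd1_sq)
    return float(np.sqrt(sd1_sq)), float(np.sqrt(sd2_sq))


def compute_profile(series: RRSeries, tacho: UniformTachogram | None = None,
                    window_s: float = 150.0) -> HRVProfile:
    """All linear indices for one (preprocessed) series.

    When ``tacho`` is omitted the spectral fields stay NaN; ``d2`` is always
    left for the nonlinear stage.
    """
    profile = time_domain(series)
    profile.rr_tri = triangular_index(series)
    profile.sd1, profile.sd2 = poincare(series)
    if tacho is not None:
        powers = band_powers(welch_psd(tacho, window_s=window_s))
        profile.vlf = powers["vlf"]
        profile.lf = powers["lf"]
        profile.hf = powers["hf"]
        profile.total_power = powers["total_power"]
        profile.lf_hf = powers["lf_hf"]
    return profile
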