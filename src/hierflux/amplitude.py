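"""Temporal filtering and per-region fluctuation-amplitude maps.

The low-frequency amplitude of a region's signal can be measured in the
time domain (standard deviation of the band-limited signal) or in the
frequency domain (ALFF, the summed Fourier amplitude inside the band).
By Parseval's theorem the two are monotonically related on band-limited
data, so they produce identical region rankings and an identical
hierarchical index.

Conventions fixed here (they change absolute scales, not rankings):

* the bandpass filter is a 4th-order Butterworth applied
  forward-backward (zero phase) via second-order sections;
* the Fourier decomposition writes the demeaned signal as
  ``x(t) = sum_k [a_k cos(2 pi f_k t) + b_k sin(2 pi f_k t)]`` with
  ``a_k = (2/N) sum x cos``, ``b_k = (2/N) sum x sin`` for
  ``0 < f_k < f_Nyquist``; ALFF sums ``sqrt((a_k^2 + b_k^2)/N)`` over
  in-band bins, excluding DC and Nyquist;
* standard deviations use the sample (N-1) denominator, as does spatial
  z-normalization.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .core import AmplitudeMap, RegionTimeSeries, WindowScheme

__all__ = [
    "bandpass",
    "bandpass_array",
    "sd_map",
    "alff_map",
    "falff_map",
    "znorm",
    "znorm_values",
    "make_windows",
    "DEFAULT_BAND",
]

#: Infra-slow band (Hz) used for BOLD-like signals throughout.
DEFAULT_BAND = (0.01, 0.08)


def _butter_sos(f_lo: float, f_hi: float, fs: float, order: int = 4):
    nyq = fs / 2.0
    if not (0.0 < f_lo < f_hi):
        raise ValueError(f"need 0 < f_lo < f_hi, got ({f_lo}, {f_hi})")
    if f_hi >= nyq:
        raise ValueError(f"f_hi={f_hi} Hz is at or above Nyquist {nyq:.4g} Hz")
    return signal.butter(order, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")


def bandpass_array(
    x: np.ndarray,
    dt: float,
    f_lo: float = DEFAULT_BAND[0],
    f_hi: float = DEFAULT_BAND[1],
    order: int = 4,
    axis: int = 0,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass on a bare array (time along ``axis``)."""
    sos = _butter_sos(f_lo, f_hi, 1.0 / dt, order)
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=axis)


def bandpass(
    ts: RegionTimeSeries,
    f_lo: float = DEFAULT_BAND[0],
    f_hi: float = DEFAULT_BAND[1],
    order: int = 4,
) -> RegionTimeSeries:
    """Band-limit every region's signal with a zero-phase Butterworth filter.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    output has no phase delay and the operation is linear.
    """
    out = bandpass_array(ts.data, ts.dt, f_lo, f_hi, order=order, axis=0)
    return RegionTimeSeries(out, ts.dt, ts.region_ids)


def sd_map(ts: RegionTimeSeries) -> AmplitudeMap:
    """Per-region sample standard deviation across frames.

    Applied to band-limited data this is the low-frequency signal
    variability ("BOLD variability" for fMRI inputs).
    """
    values = ts.data.std(axis=0, ddof=1)
    return AmplitudeMap(values, kind="sd", region_ids=ts.region_ids)


def _fourier_amplitudes(ts: RegionTimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-region one-sided Fourier amplitudes sqrt(a_k^2+b_k^2) and freqs.

    DC is removed by demeaning; the Nyquist bin (even N) is dropped so
    every retained bin follows the same 2/N amplitude convention.
    """
    x = ts.data - ts.data.mean(axis=0)
    n = ts.n_frames
    coef = np.fft.rfft(x, axis=0)
    freqs = np.fft.rfftfreq(n, d=ts.dt)
    amp = 2.0 * np.abs(coef) / n  # sqrt(a_k^2 + b_k^2)
    keep = (freqs > 0) & (freqs < ts.nyquist)
    return amp[keep], freqs[keep]


def alff_map(
    ts: RegionTimeSeries, band: tuple[float, float] = DEFAULT_BAND
) -> AmplitudeMap:
    """Amplitude of low-frequency fluctuation per region.

    Sums ``sqrt((a_k^2 + b_k^2)/N)`` over discrete frequencies inside
    ``band`` (inclusive).  A single in-band sinusoid of amplitude A on an
    exact bin yields ``A/sqrt(N)``.
    """
    amp, freqs = _fourier_amplitudes(ts)
    f_lo, f_hi = band
    in_band = (freqs >= f_lo) & (freqs <= f_hi)
    if not np.any(in_band):
        raise ValueError(
            f"no Fourier bins inside band [{f_lo}, {f_hi}] Hz for "
            f"{ts.n_frames} frames at dt={ts.dt}"
        )
    values = np.sum(amp[in_band] / np.sqrt(ts.n_frames), axis=0)
    return AmplitudeMap(values, kind="alff", band=band, region_ids=ts.region_ids)


def falff_map(
    ts: RegionTimeSeries, band: tuple[float, float] = DEFAULT_BAND
) -> AmplitudeMap:
    """Fractional ALFF: in-band power as a fraction of total power.

    Regions with zero total power get NaN (masked) rather than raising,
    so maps with dead regions still complete.
    """
    amp, freqs = _fourier_amplitudes(ts)
    power = amp**2
    f_lo, f_hi = band
    in_band = (freqs >= f_lo) & (freqs <= f_hi)
    if not np.any(in_band):
        raise ValueError(f"no Fourier bins inside band [{f_lo}, {f_hi}] Hz")
    total = power.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = power[in_band].sum(axis=0) / total
    values[total <= 0] = np.nan
    return AmplitudeMap(values, kind="falff", band=band, region_ids=ts.region_ids)


def znorm_values(values: np.ndarray) -> np.ndarray:
    """Spatially z-score a vector (sample SD); NaNs are preserved."""
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite regions to z-normalize")
    sd = values[finite].std(ddof=1)
    if sd == 0:
        raise ValueError("zero spatial variance: z-normalization undefined")
    out = np.full_like(values, np.nan)
    out[finite] = (values[finite] - values[finite].mean()) / sd
    return out


def znorm(amap: AmplitudeMap) -> AmplitudeMap:
    """Z-normalize an amplitude map across regions (mean 0, sample SD 1).

    Emphasizes spatial heterogeneity over absolute scale; rank order is
    preserved, so rank statistics downstream are unaffected.
    """
    return AmplitudeMap(
        znorm_values(amap.values),
        kind=amap.kind,
        band=amap.band,
        znorm=True,
        region_ids=amap.region_ids,
    )


def make_windows(n_frames: int, window_len: int, stride: int | None = None) -> WindowScheme:
    """Consecutive fixed-length windows starting at frame 0.

    With the default ``stride=window_len`` the windows are nonoverlapping
    and any remainder frames at the run end are dropped (a 1200-frame run
    at length 50 yields 24 windows).  A smaller stride yields the
    overlapping sliding-window variant.
    """
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    if window_len > n_frames:
        raise ValueError("window_len exceeds n_frames")
    if stride is None:
        stride = window_len
    if stride < 1:
        raise ValueError("stride must be >= 1")
    starts = np.arange(0, n_frames - window_len + 1, stride, dtype=int)
    return WindowScheme(window_len=window_len, starts=starts)
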