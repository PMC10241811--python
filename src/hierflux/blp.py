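"""Band-limited power from electrophysiological recordings.

Mirrors the fMRI amplitude pipeline on ECoG-like data: a multitaper
spectrogram (1 s windows, 0.2 s step, 5 DPSS tapers, 1 Hz bins over
1-100 Hz) is converted to decibels and mean-removed per frequency bin;
band-limited power (BLP) is the band average of the normalized
spectrogram; the infra-slow component of gamma BLP plays the role of the
BOLD amplitude in hierarchical-index analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from . import amplitude as amp
from .amplitude import znorm_values
from .hierarchy import hier_index

__all__ = [
    "ChannelRecording",
    "Spectrogram",
    "BLPSeries",
    "BANDS",
    "notch_filter",
    "multitaper_spectrogram",
    "normalize_spectrogram",
    "band_power",
    "blp_filter",
    "blp_hier_index",
    "peak_difference",
]

#: Inclusive integer frequency bands (Hz).
BANDS = {"delta": (1, 4), "alpha_beta": (5, 30), "gamma": (40, 100)}

#: Relative power floor guarding log of zero in the dB transform.
DB_FLOOR = 1e-12


@dataclass
class ChannelRecording:
    """Channel x sample raw recording with its sampling rate."""

    data: np.ndarray
    fs: float
    channel_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs < 250:
            raise ValueError("fs must be >= 250 Hz for 1-100 Hz analysis")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i:03d}" for i in range(self.n_channels)]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Spectrogram:
    """Channel x frequency x time power array on a 1 Hz / step_s grid."""

    power: np.ndarray
    freqs: np.ndarray
    step_s: float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.power.ndim != 3:
            raise ValueError("power must be 3-D (channels x freqs x frames)")
        if self.power.shape[1] != self.freqs.size:
            raise ValueError("frequency axis mismatch")
        if not self.normalized and np.any(self.power < 0):
            raise ValueError("raw power must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.power.shape[2]


@dataclass
class BLPSeries:
    """Channel x time band-limited power at the spectrogram frame rate."""

    data: np.ndarray
    band: str
    step_s: float
    filtered: bool = False
    channel_ids: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


def notch_filter(rec: ChannelRecording, freq: float = 50.0, q: float = 30.0) -> ChannelRecording:
    """Zero-phase IIR notch removing line noise at ``freq`` Hz."""
    b, a = signal.iirnotch(freq, q, fs=rec.fs)
    out = signal.filtfilt(b, a, rec.data, axis=1)
    return ChannelRecording(out, rec.fs, rec.channel_ids)


def multitaper_spectrogram(
    rec: ChannelRecording,
    win_s: float = 1.0,
    step_s: float = 0.2,
    n_tapers: int = 5,
    f_max: float = 100.0,
) -> Spectrogram:
    """Multitaper power spectrogram binned to 1 Hz over 1..f_max Hz.

    DPSS tapers with time-bandwidth NW = 3 (the smallest giving 5
    well-concentrated tapers); power is the taper-average periodogram
    per window.  Periodogram bins are averaged into 1 Hz bins centered
    on the integers.
    """
    if rec.fs < 2 * f_max:
        raise ValueError(f"fs={rec.fs} cannot resolve {f_max} Hz")
    n_win = int(round(win_s * rec.fs))
    n_step = int(round(step_s * rec.fs))
    if n_win < 2 * n_tapers:
        raise ValueError("window too short for the requested taper count")
    if rec.n_samples < n_win:
        raise ValueError("recording shorter than one window")
    nw = (n_tapers + 1) / 2.0
    tapers = signal.windows.dpss(n_win, nw, Kmax=n_tapers)  # (K, n_win)
    n_frames = (rec.n_samples - n_win) // n_step + 1
    freqs_fft = np.fft.rfftfreq(n_win, d=1.0 / rec.fs)
    int_freqs = np.arange(1.0, f_max + 1.0)
    bin_idx = [
        np.where((freqs_fft >= f - 0.5) & (freqs_fft < f + 0.5))[0] for f in int_freqs
    ]
    if any(len(b) == 0 for b in bin_idx):
        raise ValueError("frequency grid too coarse for 1 Hz bins")
    power = np.empty((rec.n_channels, int_freqs.size, n_frames))
    starts = np.arange(n_frames) * n_step
    # (frames, channels, n_win) view of all windows
    wins = np.lib.stride_tricks.sliding_window_view(rec.data, n_win, axis=1)[:, starts]
    for k in range(n_tapers):
        spec = np.fft.rfft(wins * tapers[k], axis=2)
        p = (np.abs(spec) ** 2) / rec.fs
        if k == 0:
            acc = p
        else:
            acc += p
    acc /= n_tapers
    for j, b in enumerate(bin_idx):
        power[:, j, :] = acc[:, :, b].mean(axis=2)
    return Spectrogram(power=power, freqs=int_freqs, step_s=step_s, normalized=False)


def normalize_spectrogram(spec: Spectrogram) -> Spectrogram:
    """dB transform then per-channel, per-frequency temporal mean removal.

    ``10 log10(power + floor)`` followed by subtracting each frequency
    bin's temporal mean; the result is invariant to a global gain on the
    raw recording.
    """
    if spec.normalized:
        return spec
    db = 10.0 * np.log10(spec.power + DB_FLOOR)
    db -= db.mean(axis=2, keepdims=True)
    return Spectrogram(power=db, freqs=spec.freqs, step_s=spec.step_s, normalized=True)


def band_power(spec: Spectrogram, band: str) -> BLPSeries:
    """Average the normalized spectrogram over a named band's bins.

    Bands are inclusive integer ranges: delta 1-4 Hz, alpha_beta 5-30 Hz,
    gamma 40-100 Hz.
    """
    if not spec.normalized:
        raise ValueError("band_power expects a normalized spectrogram")
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; choose from {sorted(BANDS)}")
    lo, hi = BANDS[band]
    sel = (spec.freqs >= lo) & (spec.freqs <= hi)
    data = spec.power[:, sel, :].mean(axis=1)
    return BLPSeries(data=data, band=band, step_s=spec.step_s, filtered=False)


def blp_filter(
    blp: BLPSeries, f_lo: float = 0.01, f_hi: float = 0.08, order: int = 4
) -> BLPSeries:
    """Zero-phase Butterworth bandpass of BLP into the infra-slow band."""
    min_frames = int(np.ceil(2.0 / (f_lo * blp.step_s)))
    if blp.n_frames < min_frames:
        raise ValueError(
            f"record too short to resolve {f_lo} Hz: need >= {min_frames} frames"
        )
    out = amp.bandpass_array(blp.data, blp.step_s, f_lo, f_hi, order=order, axis=1)
    return BLPSeries(
        data=out, band=blp.band, step_s=blp.step_s, filtered=True,
        channel_ids=blp.channel_ids,
    )


def blp_hier_index(blp: BLPSeries, gradient, start: int = 0, length: int | None = None) -> float:
    """Hierarchical index of a BLP fragment's channel SD map.

    Computes the per-channel SD of (filtered) BLP over the fragment
    (e.g. 750 frames = 150 s at a 0.2 s step), z-normalizes it across
    channels and rank-correlates with the channel gradient.
    """
    if length is None:
        length = blp.n_frames - start
    if start < 0 or start + length > blp.n_frames:
        raise ValueError("fragment out of bounds")
    seg = blp.data[:, start : start + length]
    sd = seg.std(axis=1, ddof=1)
    return hier_index(znorm_values(sd), gradient)


def peak_difference(
    event_blp_gamma: np.ndarray,
    event_blp_delta: np.ndarray,
    gradient,
    step_s: float,
    frac: float = 0.2,
    head_s: float = 12.0,
    tail_s: float = 4.0,
    mode: str = "difference_of_max",
) -> tuple[float, float]:
    """Gamma peak difference between hierarchy extremes, plus later delta.

    ``event_blp_gamma``/``event_blp_delta`` are channel x frames arrays
    for one event.  The peak difference contrasts the top-``frac`` and
    bottom-``frac`` gradient-ranked channels' mean gamma BLP inside the
    initial ``head_s`` seconds — as the difference of the per-trace
    maxima (default) or the maximum of the difference trace
    (``mode='max_of_difference'``).  ``later_delta`` is the all-channel
    mean delta BLP over the following ``tail_s`` seconds.
    """
    g = np.asarray(gradient.primary if hasattr(gradient, "primary") else gradient, float)
    gam = np.atleast_2d(np.asarray(event_blp_gamma, dtype=float))
    del_ = np.atleast_2d(np.asarray(event_blp_delta, dtype=float))
    n_head = int(round(head_s / step_s))
    n_tail = int(round(tail_s / step_s))
    if gam.shape[1] < n_head + n_tail:
        raise ValueError("event shorter than head_s + tail_s")
    n_ch = gam.shape[0]
    n_sel = int(frac * n_ch)
    if n_sel < 1:
        raise ValueError("frac selects no channels")
    order = np.argsort(g)
    low, high = order[:n_sel], order[-n_sel:]
    high_tr = gam[high, :n_head].mean(axis=0)
    low_tr = gam[low, :n_head].mean(axis=0)
    if mode == "difference_of_max":
        peak_diff = float(high_tr.max() - low_tr.max())
    elif mode == "max_of_difference":
        peak_diff = float((high_tr - low_tr).max())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    later_delta = float(del_[:, n_head : n_head + n_tail].mean())
    return peak_diff, later_delta
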