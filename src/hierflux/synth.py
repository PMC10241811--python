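"""Synthetic inputs with planted ground truth for every pipeline stage.

Real recordings of the kind this package analyzes (consortium fMRI,
chronic ECoG) are access-restricted, so each analysis stage is exercised
on generated data whose structure is known exactly:

* band-limited (0.01-0.08 Hz) regional noise whose amplitude is
  modulated along a planted gradient by a slow state variable;
* a shared global component with a configurable regional topography;
* injectable ~20 s gradient-ordered propagating wave events;
* discrete sleep-stage-like state trajectories;
* broadband ECoG-like channels: a gamma-band carrier under slow
  amplitude modulation plus a delta oscillation.

The generative model is a test fixture, not a claim about the brain; it
is built with the same zero-phase filter the analysis side uses, so
planted spectral content matches what the analyzers expect.  All
randomness flows through one explicitly passed seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import amplitude as amp
from .core import GradientMap, RegionTimeSeries
from .qpp import QPPTemplate

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "make_gradient",
    "ramp_state",
    "simulate_rest",
    "make_qpp_template",
    "inject_qpp",
    "simulate_stage_traj",
    "simulate_ecog",
    "make_structured_connectome",
    "make_topography_families",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def make_gradient(n_regions: int, seed=None, kind: str = "equispaced") -> GradientMap:
    """Planted per-region hierarchy loading in [-1, 1].

    ``equispaced`` gives a deterministic zero-mean grid; ``random`` draws
    uniform values (shifted to zero mean) from the seeded generator.
    """
    if n_regions < 4:
        raise ValueError("need at least 4 regions")
    if kind == "equispaced":
        g = np.linspace(-1.0, 1.0, n_regions)
    elif kind == "random":
        g = _rng(seed).uniform(-1.0, 1.0, n_regions)
        g = g - g.mean()
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return GradientMap(g)


def ramp_state(n_frames: int, start: float = 0.0, stop: float = 1.0) -> np.ndarray:
    """Linear state trajectory from ``start`` to ``stop`` in [0, 1]."""
    s = np.linspace(start, stop, n_frames)
    if s.min() < 0 or s.max() > 1:
        raise ValueError("state values must stay in [0, 1]")
    return s


@dataclass
class SyntheticSpec:
    """Parameters of the resting-state generator.

    The defaults mirror the acquisition this fixture emulates: 200
    regions, 1200 frames at 0.72 s per frame (a 14.4 min run that splits
    into 24 nonoverlapping 50-frame windows), unit baseline fluctuation
    amplitude, and gradient-state coupling equal to that baseline
    (``beta / sigma0 = 1``).
    """

    n_regions: int = 200
    n_frames: int = 1200
    dt: float = 0.72
    gradient: np.ndarray | None = None  # per-region loading in [-1, 1]
    state_traj: np.ndarray | None = None  # per-frame s(t) in [0, 1]
    beta: float = 1.0
    sigma0: float = 1.0
    gs_weight_low: float = 0.2
    gs_weight_high: float = 0.5
    noise_sd: float = 0.1
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_regions < 4:
            raise ValueError("n_regions must be >= 4")
        if self.n_frames * self.dt < 2.0 / amp.DEFAULT_BAND[0]:
            raise ValueError(
                "run too short to resolve the 0.01 Hz band edge: need "
                f"n_frames >= {2.0 / (amp.DEFAULT_BAND[0] * self.dt):.0f} at dt={self.dt}"
            )
        for name in ("sigma0", "gs_weight_low", "gs_weight_high", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gradient is None:
            self.gradient = make_gradient(self.n_regions).primary
        self.gradient = np.asarray(self.gradient, dtype=float)
        if self.gradient.size != self.n_regions:
            raise ValueError("gradient length must equal n_regions")
        if np.ptp(self.gradient) == 0:
            raise ValueError("gradient must have nonzero variance")
        if self.state_traj is None:
            self.state_traj = ramp_state(self.n_frames)
        self.state_traj = np.asarray(self.state_traj, dtype=float)
        if self.state_traj.size != self.n_frames:
            raise ValueError("state_traj length must equal n_frames")
        if self.state_traj.min() < 0 or self.state_traj.max() > 1:
            raise ValueError("state_traj must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What was planted: state, gradient, envelopes, injected events."""

    state_traj: np.ndarray
    gradient: np.ndarray
    amplitude_schedule: np.ndarray  # frames x regions envelope
    event_onsets: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def _bandpass_gain(n_frames: int, dt: float) -> float:
    """SD of zero-phase-bandpassed unit white noise (deterministic).

    The zero-phase filter applies ``|H(f)|^2`` in magnitude, so the
    output variance of unit white noise is the mean of ``|H|^4`` over
    the DFT grid.  Normalizing by this deterministic gain (rather than
    each realization's sample SD) keeps the process at unit variance
    without pinning every realization's total energy, which would
    induce artifactual long-range anticorrelation between window
    variances.
    """
    from scipy import signal as sps

    sos = sps.butter(4, list(amp.DEFAULT_BAND), btype="bandpass",
                     fs=1.0 / dt, output="sos")
    freqs = np.fft.rfftfreq(n_frames, d=dt)
    _, h = sps.sosfreqz(sos, worN=freqs, fs=1.0 / dt)
    h4 = np.abs(h) ** 4
    # two-sided average (rfft grid: DC and Nyquist counted once)
    weights = np.full(freqs.size, 2.0)
    weights[0] = 1.0
    if n_frames % 2 == 0:
        weights[-1] = 1.0
    return float(np.sqrt((weights * h4).sum() / n_frames))


def _band_limited_noise(
    rng: np.random.Generator, n_frames: int, n_cols: int, dt: float
) -> np.ndarray:
    """Unit-variance noise confined to the analysis passband.

    White noise filtered with the same zero-phase Butterworth used by
    the analyzers, scaled by the filter's deterministic gain so the
    process variance is 1.
    """
    x = rng.standard_normal((n_frames, n_cols))
    x = amp.bandpass_array(x, dt, *amp.DEFAULT_BAND, axis=0)
    return x / _bandpass_gain(n_frames, dt)


def band_limited_regions(
    n_frames: int,
    dt: float,
    amps: np.ndarray,
    band: tuple[float, float] = amp.DEFAULT_BAND,
    seed=None,
) -> RegionTimeSeries:
    """Strictly band-limited regions with a shared spectral magnitude profile.

    Every region carries the same flat in-band DFT magnitude profile
    scaled by its amplitude, with independent random phases.  Time
    courses therefore differ region to region while time-domain SD and
    frequency-domain ALFF depend on the magnitudes alone — the cleanest
    fixture for Parseval-equivalence checks.
    """
    rng = _rng(seed)
    amps = np.asarray(amps, dtype=float)
    freqs = np.fft.rfftfreq(n_frames, d=dt)
    in_band = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    if not np.any(in_band):
        raise ValueError("no DFT bins inside the requested band")
    n_regions = amps.size
    coef = np.zeros((freqs.size, n_regions), dtype=complex)
    phases = rng.uniform(0, 2 * np.pi, (in_band.sum(), n_regions))
    coef[in_band] = np.exp(1j * phases) * amps[None, :]
    x = np.fft.irfft(coef, n=n_frames, axis=0)
    return RegionTimeSeries(x, dt)


def gradient_rank(g: np.ndarray) -> np.ndarray:
    """Normalized rank of the gradient loadings, in [0, 1]."""
    order = np.argsort(np.argsort(g))
    return order / (len(g) - 1)


def simulate_rest(spec: SyntheticSpec) -> tuple[RegionTimeSeries, GroundTruth]:
    """Resting-state-like region x time signals with planted hierarchy drift.

    Each region i follows::

        x_i(t) = [sigma0 + beta * rank(g_i) * s(t)] * eta_i(t)
                 + w_i(t) * G(t) + eps_i(t)

    with ``eta_i`` independent band-limited unit-variance noise, ``G`` a
    shared band-limited component whose loading
    ``w_i(t) = gs_low + (gs_high - gs_low) * rank(g_i) * s(t)``
    interpolates between the low- and high-gradient weights, and
    ``eps_i`` white measurement noise.  Coupling acts on the normalized
    gradient rank so the planted effect is exactly what a rank
    correlation downstream should recover.
    """
    rng = _rng(spec.seed)
    rank = gradient_rank(spec.gradient)
    s = spec.state_traj
    eta = _band_limited_noise(rng, spec.n_frames, spec.n_regions, spec.dt)
    g_t = _band_limited_noise(rng, spec.n_frames, 1, spec.dt)[:, 0]
    envelope = spec.sigma0 + spec.beta * np.outer(s, rank)
    w = spec.gs_weight_low + (spec.gs_weight_high - spec.gs_weight_low) * np.outer(s, rank)
    x = envelope * eta + w * g_t[:, None]
    if spec.noise_sd > 0:
        x = x + spec.noise_sd * rng.standard_normal(x.shape)
    ts = RegionTimeSeries(x, spec.dt)
    truth = GroundTruth(
        state_traj=s.copy(), gradient=spec.gradient.copy(), amplitude_schedule=envelope
    )
    return ts, truth


def make_qpp_template(
    gradient: np.ndarray,
    L: int = 30,
    dt: float = 0.72,
    phase_span: float = np.pi / 2,
) -> QPPTemplate:
    """One-cycle propagating-wave template ordered by gradient rank.

    Region i carries one sinusoid cycle over L frames whose phase lags
    linearly with the gradient rank (total lag ``phase_span`` radians),
    i.e. activity sweeps from the low- to the high-gradient end — an
    analytically checkable stand-in for a gradient-ordered propagating
    event.
    """
    g = np.asarray(gradient, dtype=float)
    rank = gradient_rank(g)
    t = np.arange(L)
    phase = 2.0 * np.pi * t[None, :] / L - phase_span * rank[:, None]
    return QPPTemplate(np.sin(phase), dt=dt)


def inject_qpp(
    ts: RegionTimeSeries,
    template: QPPTemplate,
    onsets: np.ndarray,
    gain: float = 1.0,
) -> RegionTimeSeries:
    """Add the template at given onsets, scaled by ``gain``.

    Onsets must be in bounds and pairwise separated by at least the
    template length (no overlapping events); frames outside events are
    untouched.
    """
    onsets = np.sort(np.asarray(onsets, dtype=int))
    L = template.length
    if ts.n_regions != template.n_regions:
        raise ValueError("template regions do not match the time series")
    if onsets.size:
        if onsets[0] < 0 or onsets[-1] > ts.n_frames - L:
            raise ValueError("onset out of bounds")
        if np.any(np.diff(onsets) < L):
            raise ValueError("overlapping onsets (separation below template length)")
    out = ts.data.copy()
    for o in onsets:
        out[o : o + L] += gain * template.data.T
    return RegionTimeSeries(out, ts.dt, ts.region_ids)


def simulate_stage_traj(
    n_frames: int, dwell_frames: int, levels, seed=None
) -> np.ndarray:
    """Piecewise-constant Markov walk over discrete stage levels.

    Emulates manually scored sleep staging (e.g. wake 0, N1 -1, N2 -2,
    slow-wave -3): the trajectory holds each level for ``dwell_frames``
    frames, then steps to an adjacent level (reflecting at the ends).
    """
    levels = list(levels)
    if not levels:
        raise ValueError("levels must be nonempty")
    if dwell_frames < 1:
        raise ValueError("dwell_frames must be >= 1")
    rng = _rng(seed)
    n_lev = len(levels)
    out = np.empty(n_frames, dtype=int)
    pos = int(rng.integers(n_lev))
    t = 0
    while t < n_frames:
        seg = min(dwell_frames, n_frames - t)
        out[t : t + seg] = levels[pos]
        t += seg
        if n_lev > 1:
            if pos == 0:
                pos = 1
            elif pos == n_lev - 1:
                pos = n_lev - 2
            else:
                pos += int(rng.choice([-1, 1]))
    return out


def simulate_ecog(
    n_channels: int,
    fs: float,
    duration_s: float,
    gradient: np.ndarray,
    mod_traj: np.ndarray,
    seed=None,
    coupling: float = 1.0,
    carrier_band: tuple[float, float] = (55.0, 65.0),
    delta_freq: float = 2.0,
    delta_amp: float = 0.5,
    noise_sd: float = 0.1,
) -> np.ndarray:
    """ECoG-like channels: modulated gamma carrier + delta + white noise.

    Each channel is a unit-variance narrowband carrier (default 55-65 Hz)
    whose slow amplitude envelope is
    ``1 + coupling * rank(g_i) * mod_traj(t)``, plus a ``delta_freq`` Hz
    oscillation with random phase and white noise.  ``mod_traj`` (values
    in [0, 1]) is linearly resampled to the sample grid.
    """
    if fs < 250:
        raise ValueError("fs must be >= 250 Hz to support 1-100 Hz analysis")
    g = np.asarray(gradient, dtype=float)
    if g.size != n_channels:
        raise ValueError("gradient length must equal n_channels")
    rng = _rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    mod = np.asarray(mod_traj, dtype=float)
    mod = np.interp(np.linspace(0, 1, n), np.linspace(0, 1, mod.size), mod)
    rank = gradient_rank(g)
    carrier = rng.standard_normal((n_channels, n))
    carrier = amp.bandpass_array(carrier, 1.0 / fs, *carrier_band, axis=1)
    carrier /= carrier.std(axis=1, keepdims=True)
    env = 1.0 + coupling * rank[:, None] * mod[None, :]
    phases = rng.uniform(0, 2 * np.pi, n_channels)
    delta = delta_amp * np.sin(2 * np.pi * delta_freq * t[None, :] + phases[:, None])
    x = env * carrier + delta
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(x.shape)
    return x


def make_structured_connectome(
    n_regions: int, decay: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Distance-decay connectome on a latent 1-D axis.

    ``C_ij = exp(-decay * |p_i - p_j|)`` for equispaced latent positions
    ``p`` in [0, 1]; symmetric with unit diagonal.  Its principal
    diffusion-embedding component is monotone in ``p``, which makes it
    the standard fixture for embedding tests.  Returns ``(C, p)``.
    """
    if decay <= 0:
        raise ValueError("decay must be positive")
    p = np.linspace(0.0, 1.0, n_regions)
    c = np.exp(-decay * np.abs(p[:, None] - p[None, :]))
    return c, p


def make_topography_families(
    n_windows: int,
    n_regions: int,
    gradient: np.ndarray,
    separation: float = 1.0,
    noise_sd: float = 0.3,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two planted families of global-signal topography maps.

    Family 1 loads positively on the (z-scored) gradient pattern,
    family 0 negatively, around a common random base topography; used to
    validate state clustering and the centroid contrast.  Returns
    ``(topographies, labels)`` with shape (n_windows, n_regions).
    """
    rng = _rng(seed)
    g = np.asarray(gradient, dtype=float)
    gz = (g - g.mean()) / g.std(ddof=1)
    base = rng.standard_normal(n_regions) * 0.5
    labels = rng.integers(0, 2, size=n_windows)
    signs = np.where(labels == 1, 1.0, -1.0)
    topo = (
        base[None, :]
        + 0.5 * separation * signs[:, None] * gz[None, :]
        + noise_sd * rng.standard_normal((n_windows, n_regions))
    )
    return topo, labels
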