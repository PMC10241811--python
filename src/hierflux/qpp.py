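"""Quasiperiodic-pattern (QPP) detection and event-level summaries.

A QPP is a recurring ~20 s spatiotemporal wave of activity that
propagates along the macroscale cortical gradient.  Detection follows
the recursive template-matching scheme: a region x L template is slid
across the run one frame at a time, the Pearson correlation between the
flattened template and each flattened segment is recorded, and local
maxima above a threshold (0.4 by default) mark QPP events.  Template
construction iterates match-and-average from random starting segments
until the event set stabilizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .core import RegionTimeSeries

__all__ = [
    "QPPTemplate",
    "QPPEventSet",
    "sliding_match",
    "detect_events",
    "build_template",
    "phase_align",
    "gradient_projection",
    "event_traces",
    "classify_trajectory",
    "event_network_fc",
]


@dataclass
class QPPTemplate:
    """Region x L spatiotemporal template."""

    data: np.ndarray  # (n_regions, L)
    dt: float
    threshold: float = 0.4
    n_iterations: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("template must be 2-D (regions x frames)")
        if self.data.shape[1] < 5:
            raise ValueError("template must span at least 5 frames")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("template contains non-finite entries")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def length(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.length * self.dt


@dataclass
class QPPEventSet:
    """Detected event onsets with their template-match correlations."""

    onsets: np.ndarray
    correlations: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=int)
        self.correlations = np.asarray(self.correlations, dtype=float)
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if self.correlations.size and np.any(self.correlations < self.threshold):
            raise ValueError("all event correlations must meet the threshold")

    @property
    def n_events(self) -> int:
        return len(self.onsets)


def sliding_match(ts: RegionTimeSeries, template: QPPTemplate) -> np.ndarray:
    """Pearson correlation of the flattened template with every segment.

    Returns one value per start lag tau in ``[0, T - L]``: the
    correlation between the region x L segment starting at tau
    (flattened) and the flattened template.  Computed via FFT
    cross-correlation plus sliding sums, identical to the direct
    per-lag formula.
    """
    if ts.n_regions != template.n_regions:
        raise ValueError("time series and template cover different regions")
    L = template.length
    T = ts.n_frames
    if T < L:
        raise ValueError("time series shorter than the template")
    x = ts.data.T  # regions x T
    tpl = template.data
    nL = tpl.size
    # cross term per lag: sum_i sum_l x[i, tau+l] * tpl[i, l]
    cross = signal.fftconvolve(x, tpl[:, ::-1], mode="valid", axes=1).sum(axis=0)
    ones = np.ones(L)
    seg_sum = signal.fftconvolve(x, ones[None, :], mode="valid", axes=1).sum(axis=0)
    seg_sq = signal.fftconvolve(x**2, ones[None, :], mode="valid", axes=1).sum(axis=0)
    t_sum = tpl.sum()
    t_sq = (tpl**2).sum()
    num = cross - seg_sum * t_sum / nL
    var_seg = seg_sq - seg_sum**2 / nL
    var_tpl = t_sq - t_sum**2 / nL
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / np.sqrt(np.clip(var_seg, 0, None) * var_tpl)
    r[~np.isfinite(r)] = 0.0
    return np.clip(r, -1.0, 1.0)


def detect_events(
    corr_series: np.ndarray, threshold: float = 0.4, min_sep: int | None = None
) -> QPPEventSet:
    """Local maxima of the match series at or above the threshold.

    A local maximum is strictly greater than both neighbors (a plateau
    counts at its leftmost frame); maxima closer than ``min_sep`` frames
    keep the higher correlation.  ``min_sep`` defaults to nothing
    (callers typically pass the template length to forbid overlaps).
    """
    r = np.asarray(corr_series, dtype=float)
    n = r.size
    if n == 0:
        return QPPEventSet(np.empty(0, int), np.empty(0), threshold)
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and r[j + 1] == r[i]:
            j += 1
        left_ok = i == 0 or r[i] > r[i - 1]
        right_ok = j == n - 1 or r[i] > r[j + 1]
        if left_ok and right_ok and r[i] >= threshold:
            peaks.append(i)  # leftmost frame of a plateau
        i = j + 1
    if min_sep is not None and min_sep > 0 and len(peaks) > 1:
        kept: list[int] = []
        for p in sorted(peaks, key=lambda q: -r[q]):
            if all(abs(p - q) >= min_sep for q in kept):
                kept.append(p)
        peaks = sorted(kept)
    onsets = np.asarray(peaks, dtype=int)
    return QPPEventSet(onsets=onsets, correlations=r[onsets], threshold=threshold)


def build_template(
    ts: RegionTimeSeries,
    L: int,
    threshold: float = 0.4,
    max_iter: int = 20,
    n_seeds: int = 20,
    seed: int | np.random.Generator | None = None,
) -> tuple[QPPTemplate, QPPEventSet]:
    """Recursive match-and-average template construction.

    From each of ``n_seeds`` random starting segments: correlate the
    current template with all lags, collect super-threshold local maxima
    (separated by at least L frames), average the corresponding segments
    into a new template, and iterate until the event set repeats or
    ``max_iter`` is reached.  Among converged candidates the one with
    the highest summed event correlation wins.
    """
    T = ts.n_frames
    if T < 3 * L:
        raise ValueError("need at least 3 template lengths of data")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    starts = rng.integers(0, T - L + 1, size=n_seeds)
    best: tuple[float, QPPTemplate, QPPEventSet] | None = None
    for s0 in starts:
        tpl = ts.data[s0 : s0 + L].T.copy()
        prev_onsets: np.ndarray | None = None
        events = None
        qtpl = None
        for n_it in range(1, max_iter + 1):
            qtpl = QPPTemplate(tpl, ts.dt, threshold=threshold, n_iterations=n_it)
            r = sliding_match(ts, qtpl)
            events = detect_events(r, threshold=threshold, min_sep=L)
            if events.n_events == 0:
                break
            if prev_onsets is not None and np.array_equal(events.onsets, prev_onsets):
                break
            prev_onsets = events.onsets
            tpl = np.mean([ts.data[o : o + L].T for o in events.onsets], axis=0)
        if events is None or events.n_events == 0:
            continue
        score = float(events.correlations.sum())
        if best is None or score > best[0]:
            best = (score, qtpl, events)
    if best is None:
        raise ValueError("no super-threshold events found from any starting segment")
    return best[1], best[2]


def phase_align(
    template_a: QPPTemplate, template_b: QPPTemplate, max_shift: int = 5
) -> tuple[int, QPPTemplate]:
    """Circularly shift template b to best match template a.

    Searches shifts in ``[-max_shift, max_shift]``, maximizing the
    flattened Pearson correlation; ties prefer the smaller |shift|, then
    the negative one.  Returns the chosen shift and the shifted copy.
    """
    if template_a.data.shape != template_b.data.shape:
        raise ValueError("templates must have the same shape")
    a = template_a.data.ravel()
    best_shift, best_r = 0, -np.inf
    shifts = sorted(range(-max_shift, max_shift + 1), key=lambda s: (abs(s), s))
    for s in shifts:
        b = np.roll(template_b.data, s, axis=1).ravel()
        r = stats.pearsonr(a, b).statistic
        if r > best_r + 1e-15:
            best_shift, best_r = s, r
    aligned = QPPTemplate(
        np.roll(template_b.data, best_shift, axis=1),
        template_b.dt,
        template_b.threshold,
        template_b.n_iterations,
    )
    return best_shift, aligned


def gradient_projection(frame_values: np.ndarray, gradient) -> float:
    """Dot product of a spatial frame with the gradient loadings."""
    g = np.asarray(gradient.primary if hasattr(gradient, "primary") else gradient, float)
    v = np.asarray(frame_values, dtype=float).ravel()
    if v.size != g.size:
        raise ValueError("frame and gradient cover different regions")
    return float(v @ g)


def _extreme_sets(gradient, frac: float, n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    g = np.asarray(gradient.primary if hasattr(gradient, "primary") else gradient, float)
    if g.size != n_regions:
        raise ValueError("gradient length mismatch")
    n_sel = int(frac * n_regions)
    if n_sel < 1:
        raise ValueError("frac too small: selects no regions")
    order = np.argsort(g)
    return order[:n_sel], order[-n_sel:]


def event_traces(
    ts: RegionTimeSeries,
    events: QPPEventSet,
    gradient,
    L: int,
    frac: float = 0.2,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Bottom-/top-gradient mean time courses within each event.

    For each event, averages the signal over the bottom ``frac`` and top
    ``frac`` gradient-ranked regions across the L event frames; a
    gradient-ordered propagating wave shows the high-order (top) trace
    lagging the low-order one.
    """
    low_idx, high_idx = _extreme_sets(gradient, frac, ts.n_regions)
    out = []
    for o in events.onsets:
        if o + L > ts.n_frames:
            raise ValueError("event extends past the end of the run")
        seg = ts.data[o : o + L]
        out.append((seg[:, low_idx].mean(axis=1), seg[:, high_idx].mean(axis=1)))
    return out


def classify_trajectory(
    event_trace: np.ndarray, template_trace: np.ndarray, r_thresh: float = 0.5
) -> str:
    """Label an event 'typical' or 'atypical' by trace similarity.

    Typical iff the Pearson correlation between the event's high-order
    trace and the template's is at least ``r_thresh`` (boundary value
    counts as typical).  Constant traces are atypical by convention.
    """
    a = np.asarray(event_trace, dtype=float).ravel()
    b = np.asarray(template_trace, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("traces must have equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return "atypical"
    r = stats.pearsonr(a, b).statistic
    # boundary counts as typical; tolerate float error in the comparison
    return "typical" if r >= r_thresh - 1e-12 else "atypical"


def event_network_fc(
    ts: RegionTimeSeries,
    events: QPPEventSet,
    network_labels: np.ndarray,
    L: int,
    events_b: QPPEventSet | None = None,
) -> dict[str, np.ndarray]:
    """Within-event network x network functional connectivity.

    Each event contributes the Pearson FC of network-mean time series
    over its L frames; the output is the event-average matrix.  When a
    second event group is given, an edgewise two-sided two-sample t map
    (group A minus group B) is added.
    """
    labels = np.asarray(network_labels)
    if labels.size != ts.n_regions:
        raise ValueError("one network label per region required")
    nets = np.unique(labels)
    idx = [np.where(labels == net)[0] for net in nets]
    if any(len(i) == 0 for i in idx):
        raise ValueError("network with no regions")

    def group_fcs(ev: QPPEventSet) -> np.ndarray:
        fcs = []
        for o in ev.onsets:
            seg = ts.data[o : o + L]
            net_ts = np.column_stack([seg[:, i].mean(axis=1) for i in idx])
            fcs.append(np.corrcoef(net_ts, rowvar=False))
        return np.asarray(fcs)

    fcs_a = group_fcs(events)
    out = {"networks": nets, "mean_fc": fcs_a.mean(axis=0)}
    if events_b is not None:
        if events.n_events < 2 or events_b.n_events < 2:
            raise ValueError("need at least 2 events per group for the t contrast")
        fcs_b = group_fcs(events_b)
        t, p = stats.ttest_ind(fcs_a, fcs_b, axis=0)
        # identical degenerate groups: a zero contrast, not an undefined one
        same = (fcs_a.std(axis=0) == 0) & (fcs_b.std(axis=0) == 0) & (
            fcs_a.mean(axis=0) == fcs_b.mean(axis=0)
        )
        t = np.where(same, 0.0, t)
        p = np.where(same, 1.0, p)
        out["t_map"] = t
        out["p_map"] = p
    return out
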