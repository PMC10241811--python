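"""The hierarchical index and its windowed dynamics.

The hierarchical index is the Spearman rank correlation between a
spatial fluctuation-amplitude map and the principal connectome gradient.
It summarizes, in one scalar per time window, how strongly spontaneous
fluctuations are concentrated at the transmodal (high-gradient) versus
unimodal (low-gradient) end of the cortical hierarchy — the marker used
to track global states such as wakefulness, sedation and sleep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import amplitude as amp
from .core import AmplitudeMap, GradientMap, RegionTimeSeries, WindowScheme

__all__ = [
    "hier_index",
    "hier_trajectory",
    "trend_test",
    "paired_t_map",
    "state_corr_map",
    "window_pairs",
    "HierIndexTrajectory",
    "StateContrastMap",
]


@dataclass
class HierIndexTrajectory:
    """Per-window hierarchical-index values with their window scheme."""

    rho: np.ndarray
    windows: WindowScheme

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        finite = self.rho[np.isfinite(self.rho)]
        if finite.size and (np.any(finite < -1) or np.any(finite > 1)):
            raise ValueError("rho values outside [-1, 1]")

    @property
    def n_windows(self) -> int:
        return len(self.rho)


@dataclass
class StateContrastMap:
    """Per-region contrast statistic (paired-t or state correlation)."""

    values: np.ndarray
    statistic: str  # "paired_t" | "spearman"
    n_obs: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_obs < 3:
            raise ValueError("need at least 3 observations")


def _as_values(m) -> np.ndarray:
    if isinstance(m, AmplitudeMap):
        return m.values
    if isinstance(m, GradientMap):
        return m.primary
    return np.asarray(m, dtype=float).ravel()


def hier_index(amp_map, gradient) -> float:
    """Spearman correlation between an amplitude map and the gradient.

    Ties get average ranks; regions that are NaN in either map are
    dropped pairwise.  Returns NaN (flagged, not raised) when either map
    is constant over the valid regions.
    """
    x = _as_values(amp_map)
    g = _as_values(gradient)
    if x.size != g.size:
        raise ValueError("maps cover different numbers of regions")
    ok = np.isfinite(x) & np.isfinite(g)
    if ok.sum() < 4:
        raise ValueError("need at least 4 jointly valid regions")
    x, g = x[ok], g[ok]
    if np.ptp(x) == 0 or np.ptp(g) == 0:
        return float("nan")
    return float(stats.spearmanr(x, g).statistic)


def hier_trajectory(
    ts: RegionTimeSeries,
    gradient,
    window_len: int = 50,
    prefiltered: bool = False,
    band: tuple[float, float] = amp.DEFAULT_BAND,
) -> HierIndexTrajectory:
    """Windowed hierarchical-index trajectory.

    The run is band-limited once (unless ``prefiltered``), cut into
    nonoverlapping ``window_len``-frame windows, and each window's
    per-region SD map is rank-correlated with the gradient.  Filtering
    the full run first avoids per-window filter transients.
    """
    if window_len < 10:
        raise ValueError("window_len must be >= 10")
    filt = ts if prefiltered else amp.bandpass(ts, *band)
    scheme = amp.make_windows(ts.n_frames, window_len)
    g = _as_values(gradient)
    rho = np.empty(scheme.n_windows)
    for w, (a, b) in enumerate(scheme):
        sd = filt.data[a:b].std(axis=0, ddof=1)
        rho[w] = hier_index(sd, g)
    return HierIndexTrajectory(rho=rho, windows=scheme)


def trend_test(traj) -> tuple[float, float]:
    """Pearson trend of a trajectory against window index, with two-sided p.

    Returns ``(nan, nan)`` (flagged) for a constant trajectory.
    """
    rho = traj.rho if isinstance(traj, HierIndexTrajectory) else np.asarray(traj, float)
    rho = rho[np.isfinite(rho)]
    n = rho.size
    if n < 5:
        raise ValueError("need at least 5 windows for a trend test")
    if np.ptp(rho) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(np.arange(n, dtype=float), rho)
    return float(res.statistic), float(res.pvalue)


def paired_t_map(maps_a: np.ndarray, maps_b: np.ndarray) -> StateContrastMap:
    """Per-region paired t statistic between two conditions (A - B).

    ``maps_a`` and ``maps_b`` are (n_subjects, n_regions) stacks with
    matched rows (the same subject in both conditions).  Regions where
    the paired differences have zero variance are flagged: +/-inf if the
    mean difference is nonzero, NaN if it is zero too.
    """
    a = np.atleast_2d(np.asarray(maps_a, dtype=float))
    b = np.atleast_2d(np.asarray(maps_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("condition stacks must have matching shapes (paired design)")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subject pairs")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[(sd == 0) & (mean == 0)] = np.nan
    return StateContrastMap(values=t, statistic="paired_t", n_obs=n)


def state_corr_map(window_maps: np.ndarray, state_values: np.ndarray) -> StateContrastMap:
    """Per-region Spearman correlation of amplitude with a state code.

    ``window_maps`` is (n_windows, n_regions); ``state_values`` assigns
    each window a state code (sleep stage depth, pairwise time interval,
    ...).  Constant regions get NaN; a constant state vector is an error.
    """
    m = np.atleast_2d(np.asarray(window_maps, dtype=float))
    s = np.asarray(state_values, dtype=float).ravel()
    if m.shape[0] != s.size:
        raise ValueError("one state value per window row required")
    if s.size < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(s) == 0:
        raise ValueError("state vector is constant: correlation undefined")
    s_rank = stats.rankdata(s)
    s_rank = s_rank - s_rank.mean()
    s_norm = np.linalg.norm(s_rank)
    ranks = np.apply_along_axis(stats.rankdata, 0, m)
    ranks = ranks - ranks.mean(axis=0)
    norms = np.linalg.norm(ranks, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (s_rank @ ranks) / (s_norm * norms)
    rho[norms == 0] = np.nan
    return StateContrastMap(values=rho, statistic="spearman", n_obs=s.size)


def window_pairs(n_windows: int) -> list[tuple[int, int, int]]:
    """All unordered window pairs ``(i, j, j - i)`` with ``i < j``.

    For 24 windows this yields 276 pairs with intervals 1..23; the
    interval is a proxy for elapsed time (vigilance drop) between the
    paired amplitude maps.
    """
    if n_windows < 2:
        raise ValueError("need at least 2 windows")
    return [
        (i, j, j - i) for i in range(n_windows) for j in range(i + 1, n_windows)
    ]
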