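"""Global-signal topography, brain-state clustering, and entropy measures.

The global signal (GS) is the unweighted mean signal over regions.  Its
per-window spatial correlation pattern ("GS topography") captures which
systems dominate global coordination in that window; k-means over the
window topographies decomposes a run into discrete brain states.  Two
complexity measures accompany the states: the normalized Shannon entropy
of each node's binned connectivity distribution, and the sample entropy
of region time courses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .core import RegionTimeSeries, WindowScheme
from .hierarchy import hier_index

__all__ = [
    "StateClustering",
    "global_signal",
    "gs_topography",
    "window_topographies",
    "cluster_states",
    "centroid_contrast",
    "node_strength",
    "connectivity_entropy",
    "sample_entropy",
    "state_entropy_summary",
]


@dataclass
class StateClustering:
    """K-means state decomposition of window topographies."""

    labels: np.ndarray
    centroids: np.ndarray
    k: int
    silhouettes: dict[int, float]
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.labels.min() < 0 or self.labels.max() >= self.k:
            raise ValueError("labels must lie in [0, k)")
        if len(np.unique(self.labels)) != self.k:
            raise ValueError("every cluster must be nonempty")


def global_signal(ts: RegionTimeSeries) -> np.ndarray:
    """Per-frame unweighted mean across regions."""
    return ts.data.mean(axis=1)


def gs_topography(ts_window: RegionTimeSeries) -> np.ndarray:
    """Per-region Pearson correlation with the window's global signal.

    Constant regions get NaN (flagged missing).
    """
    if ts_window.n_frames < 3:
        raise ValueError("need at least 3 frames")
    gs = global_signal(ts_window)
    x = ts_window.data - ts_window.data.mean(axis=0)
    g = gs - gs.mean()
    denom = np.linalg.norm(x, axis=0) * np.linalg.norm(g)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (g @ x) / denom
    r = np.where(np.linalg.norm(x, axis=0) == 0, np.nan, r)
    return r


def window_topographies(ts: RegionTimeSeries, windows: WindowScheme) -> np.ndarray:
    """Stack of GS topography maps, one row per window."""
    out = np.empty((windows.n_windows, ts.n_regions))
    for w, (a, b) in enumerate(windows):
        out[w] = gs_topography(ts.window(a, b - a))
    return out


def cluster_states(
    topographies: np.ndarray,
    k_range: range = range(2, 11),
    k_select: int | None = None,
    seed: int | None = None,
    n_init: int = 50,
) -> StateClustering:
    """Euclidean k-means over window topography vectors.

    Silhouette coefficients are computed for every k in ``k_range``; the
    returned clustering uses ``k_select`` when given, otherwise the k
    with the largest silhouette (a two-cluster solution on typical
    resting data).
    """
    x = np.atleast_2d(np.asarray(topographies, dtype=float))
    if np.any(~np.isfinite(x)):
        raise ValueError("topographies contain non-finite values")
    if np.allclose(x, x[0]):
        raise ValueError("all topographies identical: clustering degenerate")
    sil: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in k_range:
        if x.shape[0] < 2 * k:
            break
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
        fits[k] = km
        sil[k] = float(silhouette_score(x, km.labels_, metric="euclidean"))
    if not fits:
        raise ValueError("too few windows for the requested k range")
    k = k_select if k_select is not None else max(sil, key=sil.get)
    if k not in fits:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    else:
        km = fits[k]
    return StateClustering(
        labels=km.labels_, centroids=km.cluster_centers_, k=k, silhouettes=sil, seed=seed
    )


def centroid_contrast(clustering: StateClustering, gradient) -> np.ndarray:
    """State-1-minus-state-2 centroid map for a two-state solution.

    State 1 is defined as the state whose centroid has the higher
    hierarchical similarity (Spearman) with the gradient, so the
    contrast's sign convention is fixed by the hierarchy reference.
    """
    if clustering.k != 2:
        raise ValueError("centroid contrast requires a two-state clustering")
    g = np.asarray(gradient.primary if hasattr(gradient, "primary") else gradient, float)
    rho = [hier_index(c, g) for c in clustering.centroids]
    hi, lo = (0, 1) if rho[0] >= rho[1] else (1, 0)
    return clustering.centroids[hi] - clustering.centroids[lo]


def node_strength(c: np.ndarray) -> np.ndarray:
    """Sum of each node's link weights (diagonal excluded)."""
    c = np.asarray(c, dtype=float)
    n = c.shape[0]
    if c.shape != (n, n):
        raise ValueError("expected a square matrix")
    if not np.allclose(c, c.T, equal_nan=True):
        raise ValueError("matrix must be symmetric")
    return c.sum(axis=1) - np.diag(c)


def connectivity_entropy(fc_row: np.ndarray, n_bins: int = 10) -> float:
    """Normalized Shannon entropy of a node's connectivity distribution.

    The node's FC values (self-connection excluded by the caller) are
    binned into ``n_bins`` equal-width bins spanning their observed
    range; ``H = -sum p_i log(p_i) / log(n_bins)`` with ``0 log 0 = 0``,
    so H lies in [0, 1].  A constant row returns 0 by convention.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    v = np.asarray(fc_row, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite connectivity values")
    if np.ptp(v) == 0:
        return 0.0
    counts, _ = np.histogram(v, bins=n_bins, range=(v.min(), v.max()))
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(n_bins))


def sample_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.5) -> float:
    """Sample entropy ``-log(A/B)`` under the Chebyshev metric.

    Templates are all overlapping subsequences of length ``m`` (for B)
    and ``m + 1`` (for A); two templates match when their Chebyshev
    distance is at most ``r = r_factor * SD(x)``.  Self-matches are
    excluded (the standard Richman-Moorman convention).  Returns 0 for a
    constant series (A = B) and inf when no (m+1)-matches exist.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if m < 1 or r_factor <= 0:
        raise ValueError("need m >= 1 and r_factor > 0")
    if n < m + 2:
        raise ValueError("series too short for the requested m")
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0
    r = r_factor * sd

    def count_matches(mm: int) -> int:
        n_t = n - mm + 1
        tpl = np.lib.stride_tricks.sliding_window_view(x, mm)
        total = 0
        for i in range(n_t - 1):
            d = np.max(np.abs(tpl[i + 1 :] - tpl[i]), axis=1)
            total += int(np.sum(d <= r))
        return total

    b = count_matches(m)
    a = count_matches(m + 1)
    if b == 0:
        return float("nan")
    if a == 0:
        return float("inf")
    return float(-np.log(a / b))


def state_entropy_summary(
    ts: RegionTimeSeries,
    windows: WindowScheme,
    clustering: StateClustering | None = None,
    n_bins: int = 10,
    m: int = 2,
    r_factor: float = 0.5,
) -> dict[str, np.ndarray]:
    """Per-window mean connectivity entropy and sample entropy.

    For each window, a Pearson FC network is built over regions; the
    connectivity entropy is averaged over nodes (self-connections
    excluded) and the sample entropy over region time courses.  When a
    clustering is supplied its labels are attached for state contrasts.
    """
    n_w = windows.n_windows
    conn_h = np.empty(n_w)
    samp_h = np.empty(n_w)
    for w, (a, b) in enumerate(windows):
        seg = ts.data[a:b]
        c = np.corrcoef(seg, rowvar=False)
        n = c.shape[0]
        h = np.empty(n)
        for i in range(n):
            row = np.delete(c[i], i)
            h[i] = connectivity_entropy(row, n_bins=n_bins)
        conn_h[w] = h.mean()
        se = [sample_entropy(seg[:, i], m=m, r_factor=r_factor) for i in range(n)]
        se = np.asarray(se)
        samp_h[w] = np.nanmean(se[np.isfinite(se)]) if np.any(np.isfinite(se)) else np.nan
    out = {"connectivity_entropy": conn_h, "sample_entropy": samp_h}
    if clustering is not None:
        if clustering.labels.size != n_w:
            raise ValueError("clustering labels do not align with windows")
        out["labels"] = clustering.labels
    return out
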