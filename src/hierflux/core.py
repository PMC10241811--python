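"""Core data containers shared across the pipeline.

All containers are thin, validated wrappers around numpy arrays.  Frame
indexing is 0-based and windows are half-open ``[start, start + len)``
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RegionTimeSeries",
    "AmplitudeMap",
    "GradientMap",
    "WindowScheme",
    "default_region_ids",
]


def default_region_ids(n: int, prefix: str = "r") -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(n)]


@dataclass
class RegionTimeSeries:
    """A frames x regions signal matrix with a fixed sampling interval.

    Parameters
    ----------
    data : ndarray, shape (n_frames, n_regions)
        Signal values; rows are time frames.
    dt : float
        Seconds per frame (the repetition time for fMRI-like data).
    region_ids : list of str, optional
        Region labels; autogenerated when omitted.
    """

    data: np.ndarray
    dt: float
    region_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (frames x regions)")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite entries")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.region_ids is None:
            self.region_ids = default_region_ids(self.n_regions)
        elif len(self.region_ids) != self.n_regions:
            raise ValueError("region_ids length does not match data columns")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist(self) -> float:
        return 0.5 / self.dt

    def window(self, start: int, length: int) -> "RegionTimeSeries":
        """Extract frames ``[start, start + length)`` as a new series."""
        if start < 0 or start + length > self.n_frames:
            raise ValueError("window out of bounds")
        return RegionTimeSeries(self.data[start : start + length], self.dt, self.region_ids)


@dataclass
class AmplitudeMap:
    """Per-region fluctuation-amplitude values (SD, ALFF or fALFF).

    ``values`` may contain NaN for regions where the statistic is
    undefined (e.g. zero-power regions for fALFF); those regions are
    excluded from downstream rank statistics.
    """

    values: np.ndarray
    kind: str = "sd"
    band: tuple[float, float] | None = None
    znorm: bool = False
    region_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.kind not in ("sd", "alff", "falff"):
            raise ValueError(f"unknown amplitude kind {self.kind!r}")
        if self.region_ids is None:
            self.region_ids = default_region_ids(len(self.values))
        elif len(self.region_ids) != len(self.values):
            raise ValueError("region_ids length mismatch")
        finite = self.values[np.isfinite(self.values)]
        if not self.znorm and finite.size and np.any(finite < 0):
            raise ValueError("non-normalized amplitude values must be >= 0")

    @property
    def n_regions(self) -> int:
        return len(self.values)


@dataclass
class GradientMap:
    """Diffusion-embedding components (or an external reference map).

    ``components`` is (n_regions, K) ordered by descending eigenvalue;
    component 0 is the principal gradient.  A bare per-region vector is
    accepted and treated as a single-component map.
    """

    components: np.ndarray
    eigenvalues: np.ndarray | None = None
    alpha: float | None = None
    sparsity: float | None = None
    region_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.ndim == 1:
            self.components = self.components[:, None]
        if self.components.ndim != 2:
            raise ValueError("components must be 1-D or 2-D")
        if not np.all(np.isfinite(self.components)):
            raise ValueError("components contain non-finite entries")
        if self.eigenvalues is not None:
            self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
            if self.eigenvalues.size != self.components.shape[1]:
                raise ValueError("one eigenvalue per component required")
        if self.region_ids is None:
            self.region_ids = default_region_ids(self.n_regions)
        elif len(self.region_ids) != self.n_regions:
            raise ValueError("region_ids length mismatch")

    @property
    def n_regions(self) -> int:
        return self.components.shape[0]

    @property
    def primary(self) -> np.ndarray:
        """The principal gradient (component 0)."""
        return self.components[:, 0]


@dataclass
class WindowScheme:
    """Half-open frame windows of fixed length.

    Windows built by :func:`hierflux.amplitude.make_windows` are
    nonoverlapping (the default stride equals the window length); a
    smaller stride yields the overlapping sliding-window variant.
    """

    window_len: int
    starts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.window_len < 2:
            raise ValueError("window_len must be >= 2")
        self.starts = np.asarray(self.starts, dtype=int)
        if self.starts.ndim != 1:
            raise ValueError("starts must be 1-D")
        if np.any(np.diff(self.starts) <= 0):
            raise ValueError("starts must be strictly increasing")
        if self.starts.size and self.starts[0] < 0:
            raise ValueError("starts must be nonnegative")

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def __iter__(self):
        for s in self.starts:
            yield int(s), int(s) + self.window_len
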