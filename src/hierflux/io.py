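"""Text-based interchange formats: TSV matrices with JSON sidecars.

The canonical containers are plain TSV (diffable, portable) with a JSON
sidecar carrying metadata that the matrix itself cannot (sampling
interval, seed, band, eigenvalues).  Neuroimaging formats are adapters
on top of this core, not the data model, so the package runs with no
imaging dependency installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AmplitudeMap, GradientMap, RegionTimeSeries

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_map",
    "read_map",
    "write_gradient",
    "read_gradient",
    "read_matrix",
    "write_json",
    "read_json",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_timeseries(ts: RegionTimeSeries, path) -> None:
    """Write frames x regions TSV (header = region ids) + dt sidecar."""
    path = Path(path)
    pd.DataFrame(ts.data, columns=ts.region_ids).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
    write_json(_sidecar(path), {"dt": ts.dt, "n_frames": ts.n_frames})


def read_timeseries(path, dt: float | None = None) -> RegionTimeSeries:
    """Read a frames x regions TSV; dt from the sidecar unless given."""
    path = Path(path)
    df = _read_tsv(path)
    if dt is None:
        sc = _sidecar(path)
        if not sc.exists():
            raise ValueError(f"no dt given and no sidecar at {sc}")
        dt = float(read_json(sc)["dt"])
    return RegionTimeSeries(df.to_numpy(), dt, list(df.columns))


def _read_tsv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as e:  # ragged rows etc.
        raise ValueError(f"malformed TSV {path}: {e}") from e
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0][0]) + 2  # 1-based + header
        raise ValueError(f"non-numeric cell in {path} at line {row}")
    return numeric


def write_map(amap: AmplitudeMap, path) -> None:
    """Write a per-region map as two-column TSV + metadata sidecar."""
    path = Path(path)
    pd.DataFrame({"region_id": amap.region_ids, "value": amap.values}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
    write_json(
        _sidecar(path),
        {"kind": amap.kind, "band": list(amap.band) if amap.band else None,
         "znorm": amap.znorm},
    )


def read_map(path) -> AmplitudeMap:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = read_json(_sidecar(path)) if _sidecar(path).exists() else {}
    band = meta.get("band")
    return AmplitudeMap(
        df["value"].to_numpy(),
        kind=meta.get("kind", "sd"),
        band=tuple(band) if band else None,
        znorm=bool(meta.get("znorm", False)),
        region_ids=list(df["region_id"].astype(str)),
    )


def write_gradient(grad: GradientMap, path) -> None:
    """Write gradient components as TSV + eigenvalue/parameter sidecar."""
    path = Path(path)
    cols = {"region_id": grad.region_ids}
    for j in range(grad.components.shape[1]):
        cols[f"component_{j + 1}"] = grad.components[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.10g")
    write_json(
        _sidecar(path),
        {
            "eigenvalues": None if grad.eigenvalues is None else grad.eigenvalues.tolist(),
            "alpha": grad.alpha,
            "sparsity": grad.sparsity,
        },
    )


def read_gradient(path) -> GradientMap:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    comp_cols = [c for c in df.columns if c.startswith("component_")]
    if not comp_cols:
        # two-column reference-map form: region_id, loading
        value_cols = [c for c in df.columns if c != "region_id"]
        if len(value_cols) != 1:
            raise ValueError(f"cannot identify gradient columns in {path}")
        comp_cols = value_cols
    meta = read_json(_sidecar(path)) if _sidecar(path).exists() else {}
    ev = meta.get("eigenvalues")
    return GradientMap(
        df[comp_cols].to_numpy(),
        eigenvalues=None if ev is None else np.asarray(ev),
        alpha=meta.get("alpha"),
        sparsity=meta.get("sparsity"),
        region_ids=list(df["region_id"].astype(str)) if "region_id" in df else None,
    )


def read_matrix(path, dt: float | None = None):
    """Read a TSV as a RegionTimeSeries (with dt) or a bare array.

    Convenience entry point for the CLI: if a dt is available (argument
    or sidecar) the result is a :class:`RegionTimeSeries`, otherwise the
    raw 2-D array is returned.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_tsv(path)
    if dt is None and _sidecar(path).exists():
        meta = read_json(_sidecar(path))
        dt = meta.get("dt")
    if dt is not None:
        return RegionTimeSeries(df.to_numpy(), float(dt), list(df.columns))
    return df.to_numpy()
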