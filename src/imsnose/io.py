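"""Data model and I/O for 2D MCC-IMS maps.

An MCC-IMS e-nose measurement is a matrix of ion-current intensities over a
retention-time axis (rows, seconds; the chromatographic dimension) and a
drift-time axis (columns, milliseconds; the ion-mobility dimension).  This
module defines the in-memory containers (:class:`IMSMap`,
:class:`IMSDataset`, :class:`FeatureMatrix`), plain-text CSV and HDF5
readers/writers, and the row-major flattening used by the full-matrix
modelling approach, where every pixel of the corrected 2D map is a feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import MalformedInputError

__all__ = [
    "IMSMap",
    "IMSDataset",
    "FeatureMatrix",
    "read_map",
    "write_map",
    "read_dataset",
    "write_dataset",
    "read_manifest",
    "flatten_dataset",
    "unflatten",
]

_CSV_CORNER = "retention_s\\drift_ms"


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise MalformedInputError(f"{name} must be one-dimensional")
    return arr


@dataclass
class IMSMap:
    """One MCC-IMS sample: intensity matrix plus its two time axes.

    Parameters
    ----------
    intensity : (n_ret, n_drift) array
        Signal intensity (arbitrary units). Rows are drift spectra acquired
        at successive retention times.
    drift_time : (n_drift,) array
        Drift-time axis in milliseconds, strictly increasing.
    retention_time : (n_ret,) array
        Retention-time axis in seconds, strictly increasing.
    sample_id : str
        Identifier used for HDF5 group names and error messages.
    label : str or None
        Class label (e.g. olive-oil grade), if known.
    meta : dict
        Free-form string metadata.
    """

    intensity: np.ndarray
    drift_time: np.ndarray
    retention_time: np.ndarray
    sample_id: str = ""
    label: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.drift_time = _as_1d_float(self.drift_time, "drift_time")
        self.retention_time = _as_1d_float(self.retention_time, "retention_time")
        if self.intensity.ndim != 2:
            raise MalformedInputError("intensity must be a 2D matrix")
        if self.intensity.shape != (self.retention_time.size, self.drift_time.size):
            raise MalformedInputError(
                f"intensity shape {self.intensity.shape} does not match axes "
                f"({self.retention_time.size}, {self.drift_time.size})"
            )
        for name, ax in (("drift_time", self.drift_time),
                         ("retention_time", self.retention_time)):
            if ax.size == 0:
                raise MalformedInputError(f"{name} is empty")
            if not np.all(np.isfinite(ax)):
                raise MalformedInputError(f"{name} contains non-finite values")
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise MalformedInputError(f"{name} must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise MalformedInputError("intensity contains non-finite values")

    @property
    def n_ret(self) -> int:
        return self.retention_time.size

    @property
    def n_drift(self) -> int:
        return self.drift_time.size

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def replace(self, **kwargs) -> "IMSMap":
        """Return a copy with some fields replaced (arrays are copied)."""
        data = dict(
            intensity=self.intensity.copy(),
            drift_time=self.drift_time.copy(),
            retention_time=self.retention_time.copy(),
            sample_id=self.sample_id,
            label=self.label,
            meta=dict(self.meta),
        )
        data.update(kwargs)
        return IMSMap(**data)


@dataclass
class IMSDataset:
    """An ordered collection of maps sharing one classification problem."""

    maps: list[IMSMap]
    class_names: list[str]

    def __post_init__(self) -> None:
        self.maps = list(self.maps)
        self.class_names = list(self.class_names)
        if len(set(self.class_names)) != len(self.class_names):
            raise MalformedInputError("class_names must be unique")
        known = set(self.class_names)
        for m in self.maps:
            if m.label is not None and m.label not in known:
                raise MalformedInputError(
                    f"label {m.label!r} of sample {m.sample_id!r} not in class_names"
                )

    @classmethod
    def from_maps(cls, maps, class_names=None) -> "IMSDataset":
        maps = list(maps)
        if class_names is None:
            seen: list[str] = []
            for m in maps:
                if m.label is not None and m.label not in seen:
                    seen.append(m.label)
            class_names = seen
        return cls(maps=maps, class_names=list(class_names))

    def __len__(self) -> int:
        return len(self.maps)

    def __iter__(self):
        return iter(self.maps)

    @property
    def labels(self) -> list[str | None]:
        return [m.label for m in self.maps]

    def is_aligned(self, rtol: float = 1e-9, atol: float = 1e-12) -> bool:
        """True when every map shares the first map's axes."""
        if not self.maps:
            return True
        ref = self.maps[0]
        for m in self.maps[1:]:
            if m.shape != ref.shape:
                return False
            if not np.allclose(m.drift_time, ref.drift_time, rtol=rtol, atol=atol):
                return False
            if not np.allclose(m.retention_time, ref.retention_time,
                               rtol=rtol, atol=atol):
                return False
        return True


@dataclass
class FeatureMatrix:
    """Flattened dataset for modelling: one row per sample, one column per pixel."""

    X: np.ndarray
    y: np.ndarray
    shape_info: tuple[int, int]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n_ret, n_drift = self.shape_info
        if self.X.shape[1] != n_ret * n_drift:
            raise MalformedInputError(
                f"feature count {self.X.shape[1]} != n_ret*n_drift "
                f"{n_ret * n_drift}"
            )
        if len(self.y) != self.X.shape[0]:
            raise MalformedInputError("y length must equal the number of rows")


def flatten_dataset(ds: IMSDataset, *, require_labels: bool = True,
                    check_aligned: bool = True) -> FeatureMatrix:
    """Unroll every map row-major (retention-major, drift-minor) into a matrix.

    Row i of ``X`` is ``ds.maps[i].intensity.ravel(order="C")``, so the
    retention index is the slow axis — this makes reshaping a feature-space
    vector (e.g. a VIP score vector) back into map coordinates a single
    ``reshape(shape_info)``.
    """
    if not ds.maps:
        raise MalformedInputError("dataset is empty")
    if check_aligned and not ds.is_aligned():
        raise MalformedInputError(
            "maps do not share common axes; align the dataset first"
        )
    shape = ds.maps[0].shape
    for m in ds.maps:
        if m.shape != shape:
            raise MalformedInputError(
                f"sample {m.sample_id!r} has shape {m.shape}, expected {shape}"
            )
    if require_labels and any(m.label is None for m in ds.maps):
        missing = [m.sample_id for m in ds.maps if m.label is None]
        raise MalformedInputError(f"samples without labels: {missing}")
    X = np.stack([m.intensity.ravel(order="C") for m in ds.maps])
    y = np.array([m.label if m.label is not None else "" for m in ds.maps],
                 dtype=object)
    return FeatureMatrix(X=X, y=y, shape_info=shape)


def unflatten(v: np.ndarray, shape_info: tuple[int, int]) -> np.ndarray:
    """Inverse of the row-major unrolling used by :func:`flatten_dataset`."""
    v = np.asarray(v)
    return v.reshape(shape_info, order="C")


# ---------------------------------------------------------------------------
# CSV (single map)
# ---------------------------------------------------------------------------

def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "hdf5"):
            raise MalformedInputError(f"unknown format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    return "csv"


def _read_map_csv(path) -> IMSMap:
    try:
        df = pd.read_csv(path, index_col=0)
        drift = df.columns.to_numpy(dtype=float)
        ret = df.index.to_numpy(dtype=float)
        body = df.to_numpy(dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise MalformedInputError(f"cannot parse CSV map {path}: {exc}") from exc
    return IMSMap(intensity=body, drift_time=drift, retention_time=ret,
                  sample_id=Path(path).stem)


def _write_map_csv(m: IMSMap, path) -> None:
    df = pd.DataFrame(m.intensity, index=m.retention_time, columns=m.drift_time)
    df.to_csv(path, index_label=_CSV_CORNER)


# ---------------------------------------------------------------------------
# HDF5 container: /samples/<id> with intensity, drift_time_ms,
# retention_time_s, and a `label` attribute; sample order kept in a root
# attribute so datasets round-trip in acquisition order.
# ---------------------------------------------------------------------------

def _write_sample_group(root: h5py.Group, m: IMSMap) -> None:
    grp = root.create_group(m.sample_id)
    grp.create_dataset("intensity", data=m.intensity)
    grp.create_dataset("drift_time_ms", data=m.drift_time)
    grp.create_dataset("retention_time_s", data=m.retention_time)
    if m.label is not None:
        grp.attrs["label"] = m.label
    for k, v in m.meta.items():
        grp.attrs[f"meta:{k}"] = str(v)


def _read_sample_group(grp: h5py.Group, sample_id: str) -> IMSMap:
    meta = {k[5:]: str(v) for k, v in grp.attrs.items() if k.startswith("meta:")}
    label = grp.attrs.get("label")
    return IMSMap(
        intensity=grp["intensity"][()],
        drift_time=grp["drift_time_ms"][()],
        retention_time=grp["retention_time_s"][()],
        sample_id=sample_id,
        label=None if label is None else str(label),
        meta=meta,
    )


def write_map(m: IMSMap, path, fmt: str | None = None) -> None:
    """Write one map as CSV (drift axis = header row, retention = first column)
    or as a single-sample HDF5 container."""
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        _write_map_csv(m, path)
        return
    sid = m.sample_id or "sample"
    with h5py.File(path, "w") as f:
        samples = f.create_group("samples")
        _write_sample_group(samples, m.replace(sample_id=sid))
        f.attrs["sample_order"] = [sid]


def read_map(path, fmt: str | None = None) -> IMSMap:
    """Read one map from CSV or a single-sample HDF5 file."""
    fmt = _infer_format(path, fmt)
    if not Path(path).exists():
        raise FileNotFoundError(path)
    if fmt == "csv":
        return _read_map_csv(path)
    with h5py.File(path, "r") as f:
        ids = list(f.attrs.get("sample_order", list(f["samples"].keys())))
        if len(ids) != 1:
            raise MalformedInputError(
                f"{path} holds {len(ids)} samples; use read_dataset"
            )
        sid = str(ids[0])
        return _read_sample_group(f["samples"][sid], sid)


def write_dataset(ds: IMSDataset, path) -> None:
    """Write a dataset to one HDF5 file (one group per sample)."""
    ids = []
    with h5py.File(path, "w") as f:
        samples = f.create_group("samples")
        for i, m in enumerate(ds.maps):
            sid = m.sample_id or f"sample_{i:04d}"
            ids.append(sid)
            _write_sample_group(samples, m.replace(sample_id=sid))
        f.attrs["sample_order"] = ids
        f.attrs["class_names"] = list(ds.class_names)


def read_dataset(path) -> IMSDataset:
    """Read a dataset written by :func:`write_dataset`."""
    with h5py.File(path, "r") as f:
        ids = [str(s) for s in f.attrs.get("sample_order",
                                           list(f["samples"].keys()))]
        maps = [_read_sample_group(f["samples"][sid], sid) for sid in ids]
        class_names = [str(c) for c in f.attrs.get("class_names", [])]
    if class_names:
        return IMSDataset(maps=maps, class_names=class_names)
    return IMSDataset.from_maps(maps)


def read_manifest(path) -> IMSDataset:
    """Read a JSON manifest listing per-sample CSV files and labels.

    Format: ``{"class_names": [...], "samples": [{"path": ..., "label": ...,
    "id": ...}, ...]}``; relative paths resolve against the manifest location.
    """
    path = Path(path)
    with open(path) as fh:
        spec = json.load(fh)
    maps = []
    for entry in spec["samples"]:
        p = Path(entry["path"])
        if not p.is_absolute():
            p = path.parent / p
        m = read_map(p)
        maps.append(m.replace(label=entry.get("label"),
                              sample_id=entry.get("id", m.sample_id)))
    class_names = spec.get("class_names")
    if class_names is None:
        return IMSDataset.from_maps(maps)
    return IMSDataset(maps=maps, class_names=class_names)
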