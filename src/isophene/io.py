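"""Reading and writing of on-disk artifacts.

Formats
-------
Ion stacks
    One multi-page TIFF per mass channel (``<label>.tif``) plus a
    ``stack.yaml`` sidecar carrying channel labels, dwell time, raster size
    and free-form session metadata.
ROI masks
    Single-page 16-bit unsigned label TIFF (0 = background).
ROI count tables
    UTF-8 TSV with header ``session region roi_id c12 c13 nc14 nc15 s32 s33
    s34 centroid_x centroid_y area_px n_planes``; extra columns are
    preserved as opaque annotations.
FISH label tables
    CSV with header ``session,region,roi_id,taxon,morphology``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .isotope import COUNT_COLUMNS, KEY_COLUMNS

#: Canonical seven-mass channel set, in collector order.
CHANNEL_LABELS = ("12C", "13C", "14N12C", "15N12C", "32S", "33S", "34S")

#: Mass label -> count-table column name.
CHANNEL_COLUMNS = dict(zip(CHANNEL_LABELS, COUNT_COLUMNS))

_NOMINAL_MASS = {"12C": 12, "13C": 13, "14N12C": 26, "15N12C": 27,
                 "32S": 32, "33S": 33, "34S": 34}

TAXA = ("gamma", "delta", "unknown")
MORPHOLOGIES = ("filament", "coccus", "rod", "unknown")

ROI_TABLE_COLUMNS = KEY_COLUMNS + COUNT_COLUMNS + [
    "centroid_x", "centroid_y", "area_px", "n_planes"]


class FormatError(ValueError):
    """A file or directory does not match the expected on-disk layout."""


@dataclass(frozen=True)
class MassChannel:
    """A secondary-ion species collected in parallel (e.g. 14N12C−)."""

    label: str
    nominal_mass: int = 0

    def __post_init__(self):
        if self.nominal_mass == 0 and self.label in _NOMINAL_MASS:
            object.__setattr__(self, "nominal_mass", _NOMINAL_MASS[self.label])


@dataclass
class IonImageStack:
    """Multi-channel, multi-plane ion count images with acquisition metadata.

    ``counts`` is indexed (channel, plane, row, col).  Raw counts are
    nonnegative integers; dead-time-corrected stacks hold real values.
    """

    channels: list[MassChannel]
    counts: np.ndarray
    dwell_time: float
    raster_size: float
    session_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.counts.ndim != 4:
            raise ValueError("counts must be (channel, plane, row, col)")
        if len(self.channels) != self.counts.shape[0]:
            raise ValueError("channel list does not match counts array")
        if self.raster_size <= 0:
            raise ValueError("raster_size must be > 0")
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        if np.issubdtype(self.counts.dtype, np.integer) and (self.counts < 0).any():
            raise ValueError("raw counts must be >= 0")

    @property
    def n_planes(self) -> int:
        return self.counts.shape[1]

    def channel_index(self, label: str) -> int:
        for i, c in enumerate(self.channels):
            if c.label == label:
                return i
        raise KeyError(f"channel {label!r} not in stack")


def write_ion_stack(stack: IonImageStack, path) -> None:
    """Write one TIFF per channel plus the ``stack.yaml`` sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    integral = np.issubdtype(stack.counts.dtype, np.integer) or np.allclose(
        stack.counts, np.round(stack.counts))
    dtype = np.uint32 if integral else np.float32
    for i, ch in enumerate(stack.channels):
        tifffile.imwrite(path / f"{ch.label}.tif", stack.counts[i].astype(dtype),
                         photometric="minisblack")
    sidecar = {
        "channels": [c.label for c in stack.channels],
        "dwell_time": float(stack.dwell_time),
        "raster_size": float(stack.raster_size),
        "session_meta": dict(stack.session_meta),
    }
    with open(path / "stack.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)


def read_ion_stack(path) -> IonImageStack:
    """Read a per-channel TIFF directory written by :func:`write_ion_stack`."""
    path = Path(path)
    sidecar_path = path / "stack.yaml"
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        meta = yaml.safe_load(fh)
    arrays = []
    for label in meta["channels"]:
        f = path / f"{label}.tif"
        if not f.exists():
            raise FormatError(f"missing channel file for {label!r}: {f}")
        arr = tifffile.imread(f)
        if arr.ndim == 2:
            arr = arr[None]
        arrays.append(arr)
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise FormatError(f"plane-count/shape mismatch across channels: {shapes}")
    counts = np.stack(arrays)
    channels = [MassChannel(label) for label in meta["channels"]]
    return IonImageStack(channels=channels, counts=counts,
                         dwell_time=float(meta["dwell_time"]),
                         raster_size=float(meta["raster_size"]),
                         session_meta=dict(meta.get("session_meta") or {}))


def write_roi_mask(labels: np.ndarray, path) -> None:
    """Write an ROI label image as a single-page 16-bit unsigned TIFF."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("ROI ids must fit in uint16")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_roi_mask(path) -> np.ndarray:
    """Read an ROI label image written by :func:`write_roi_mask`."""
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise FormatError("ROI mask must be a single-page 2-D label image")
    return arr.astype(np.int64)


def _validate_roi_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ROI_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"ROI table missing columns: {missing}")
    for col in COUNT_COLUMNS:
        bad = table.index[table[col] < 0]
        if len(bad):
            raise ValueError(f"negative counts in column {col} at row {bad[0]}")
    if (table["area_px"] < 1).any():
        raise ValueError("area_px must be >= 1")
    dup = table.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        key = table.loc[dup.idxmax(), KEY_COLUMNS].tolist()
        raise ValueError(f"duplicate ROI key {key}")
    ordered = ROI_TABLE_COLUMNS + [c for c in table.columns if c not in ROI_TABLE_COLUMNS]
    return table[ordered]


def read_roi_table(path) -> pd.DataFrame:
    """Read and validate a per-ROI accumulated-count TSV."""
    table = pd.read_csv(Path(path), sep="\t")
    return _validate_roi_table(table)


def write_roi_table(table: pd.DataFrame, path) -> None:
    """Write a per-ROI accumulated-count TSV with a deterministic column order."""
    table = _validate_roi_table(table.reset_index() if isinstance(table.index, pd.MultiIndex)
                                else table)
    table.to_csv(Path(path), sep="\t", index=False)


def read_fish_table(path) -> pd.DataFrame:
    """Read a FISH taxon label CSV; taxa are validated against the vocabulary."""
    table = pd.read_csv(Path(path))
    missing = [c for c in KEY_COLUMNS + ["taxon"] if c not in table.columns]
    if missing:
        raise FormatError(f"FISH table missing columns: {missing}")
    bad = set(table["taxon"]) - set(TAXA)
    if bad:
        raise ValueError(f"unknown taxa {sorted(bad)}; allowed: {TAXA}")
    if "morphology" in table.columns:
        badm = set(table["morphology"].dropna()) - set(MORPHOLOGIES)
        if badm:
            raise ValueError(f"unknown morphologies {sorted(badm)}")
    else:
        table["morphology"] = "unknown"
    return table


def write_fish_table(table: pd.DataFrame, path) -> None:
    cols = KEY_COLUMNS + ["taxon"] + (["morphology"] if "morphology" in table.columns else [])
    table[cols].to_csv(Path(path), index=False)


def write_ratio_table(ratios: pd.DataFrame, path) -> None:
    """Write a ratio matrix (indexed by ROI key) as TSV."""
    ratios.reset_index().to_csv(Path(path), sep="\t", index=False)


def read_ratio_table(path) -> pd.DataFrame:
    t = pd.read_csv(Path(path), sep="\t")
    return t.set_index(KEY_COLUMNS)


def write_report(tables: dict[str, pd.DataFrame], path, figures: dict | None = None) -> list[Path]:
    """Write named summary tables (TSV) and optional figures into a directory.

    ``figures`` maps filename -> matplotlib Figure.  Returns written paths.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        f = path / f"{name}.tsv"
        table.to_csv(f, sep="\t")
        written.append(f)
    for name, fig in (figures or {}).items():
        f = path / name
        fig.savefig(f, dpi=150)
        written.append(f)
    return written
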