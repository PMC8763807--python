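"""File boundary: multi-channel z-stack TIFFs, run configs, result tables.

Conventions fixed here for the whole package: images are (slices, rows,
cols); coordinates are 0-based (row, col) with 0-based slice indices; 8- and
16-bit unsigned TIFFs are accepted and promoted to a common numeric type
in memory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .overlap import CountResult, OverlapParams
from .preprocess import SegmentationParams
from .quantify import AggregationRecord

__all__ = [
    "ZStack",
    "RunConfig",
    "read_zstack",
    "write_zstack",
    "load_config",
    "write_results",
    "read_aggregation_records",
    "count_results_frame",
]


@dataclass
class ZStack:
    """One image's intensity volume(s), one (S, H, W) array per channel.

    All channels share a shape; intensities are non-negative.  ``pixel_size_xy``
    and ``slice_spacing`` are optional physical calibrations (default 1,
    unitless) carried along for reporting.
    """

    channels: dict[str, np.ndarray]
    pixel_size_xy: float = 1.0
    slice_spacing: float = 1.0
    image_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ZStack needs at least one channel")
        shapes = {name: v.shape for name, v in self.channels.items()}
        first = next(iter(shapes.values()))
        if len(first) != 3 or first[0] < 1:
            raise ValueError(f"channel volumes must be (S>=1, H, W); got {first}")
        for name, shape in shapes.items():
            if shape != first:
                raise ValueError(f"channel {name!r} shape {shape} != {first}")
        for name, v in self.channels.items():
            if np.issubdtype(v.dtype, np.signedinteger) and v.min() < 0:
                raise ValueError(f"channel {name!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def n_slices(self) -> int:
        return self.shape[0]


@dataclass
class RunConfig:
    """Everything a counting run needs besides the images themselves."""

    nucleus_channel: str = "dapi"
    marker_channels: tuple[str, ...] = ()
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    overlap: OverlapParams = field(default_factory=OverlapParams)
    mode: str = "3D"
    aggregation_columns: tuple[str, ...] = (
        "genotype", "differentiation_id", "well_id", "image_id")
    seed: int = 0

    def __post_init__(self) -> None:
        mode = self.mode.upper()
        if mode not in ("2D", "3D"):
            raise ValueError(f"mode must be 2D or 3D, got {self.mode!r}")
        self.mode = mode
        if not self.nucleus_channel:
            raise ValueError("exactly one nucleus channel is required")


def read_zstack(
    path: str | Path,
    channel_map: list[str] | dict[str, int],
    axis_order: str = "zc",
    image_id: str | None = None,
) -> ZStack:
    """Read a multi-page TIFF into a ZStack.

    ``channel_map`` names the channels in index order (list) or maps
    name -> channel index (dict).  When the TIFF carries OME-style axis
    metadata with explicit Z/C axes, that layout is honored; otherwise the
    flat page sequence is deinterleaved according to ``axis_order``:

    * ``"zc"`` — slices outermost, channels cycling fastest
      (page p holds slice ``p // C``, channel ``p % C``);
    * ``"cz"`` — channel blocks, slices cycling fastest
      (page p holds channel ``p // S``, slice ``p % S``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if axis_order not in ("zc", "cz"):
        raise ValueError("axis_order must be 'zc' or 'cz'")
    if isinstance(channel_map, dict):
        names = [name for name, _ in sorted(channel_map.items(), key=lambda kv: kv[1])]
    else:
        names = list(channel_map)
    n_channels = len(names)
    if n_channels == 0:
        raise ValueError("channel_map must declare at least one channel")

    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        axes = series.axes.upper()
        data = series.asarray()

    if "C" in axes and "Z" in axes:
        # OME-style explicit axes: move to (C, Z, H, W)
        perm = [axes.index("C"), axes.index("Z")] + [
            i for i, a in enumerate(axes) if a not in ("C", "Z")]
        arr = np.transpose(data, perm)
        if arr.ndim != 4:
            raise ValueError(f"cannot interpret TIFF axes {axes!r}")
        if arr.shape[0] != n_channels:
            raise ValueError(
                f"TIFF has {arr.shape[0]} channels, {n_channels} declared")
        per_channel = [arr[c] for c in range(n_channels)]
    else:
        if data.ndim == 2:
            data = data[np.newaxis]
        if data.ndim != 3:
            raise ValueError(f"cannot interpret TIFF of shape {data.shape}")
        n_pages = data.shape[0]
        if n_pages % n_channels != 0:
            raise ValueError(
                f"{n_pages} pages not divisible by {n_channels} channels")
        n_slices = n_pages // n_channels
        if axis_order == "zc":
            arr = data.reshape(n_slices, n_channels, *data.shape[1:])
            per_channel = [arr[:, c] for c in range(n_channels)]
        else:
            arr = data.reshape(n_channels, n_slices, *data.shape[1:])
            per_channel = [arr[c] for c in range(n_channels)]

    channels = {}
    for name, vol in zip(names, per_channel):
        vol = np.ascontiguousarray(vol)
        if not np.issubdtype(vol.dtype, np.unsignedinteger):
            vol = np.asarray(vol)
        channels[name] = vol
    return ZStack(channels=channels, image_id=image_id or path.stem)


def write_zstack(stack: ZStack, path: str | Path, axis_order: str = "zc") -> Path:
    """Write a ZStack as a flat multi-page TIFF (inverse of :func:`read_zstack`)."""
    path = Path(path)
    names = list(stack.channels)
    volumes = [stack.channels[n] for n in names]
    n_slices = stack.n_slices
    if axis_order == "zc":
        pages = [volumes[c][s] for s in range(n_slices) for c in range(len(names))]
    elif axis_order == "cz":
        pages = [volumes[c][s] for c in range(len(names)) for s in range(n_slices)]
    else:
        raise ValueError("axis_order must be 'zc' or 'cz'")
    tifffile.imwrite(path, np.stack(pages))
    return path


_CONFIG_KEYS = {"nucleus_channel", "marker_channels", "segmentation", "overlap",
                "mode", "aggregation_columns", "seed"}
_SEG_KEYS = {f.name for f in dataclasses.fields(SegmentationParams)}
_OVL_KEYS = {f.name for f in dataclasses.fields(OverlapParams)}


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run config; unknown keys are rejected, missing keys
    take the documented defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("config must be a mapping")
    unknown = set(doc) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    seg_doc = doc.pop("segmentation", {}) or {}
    ovl_doc = doc.pop("overlap", {}) or {}
    bad = set(seg_doc) - _SEG_KEYS
    if bad:
        raise ValueError(f"unknown segmentation keys: {sorted(bad)}")
    bad = set(ovl_doc) - _OVL_KEYS
    if bad:
        raise ValueError(f"unknown overlap keys: {sorted(bad)}")
    kwargs = dict(doc)
    if "marker_channels" in kwargs:
        kwargs["marker_channels"] = tuple(kwargs["marker_channels"])
    if "aggregation_columns" in kwargs:
        kwargs["aggregation_columns"] = tuple(kwargs["aggregation_columns"])
    return RunConfig(segmentation=SegmentationParams(**seg_doc),
                     overlap=OverlapParams(**ovl_doc), **kwargs)


def count_results_frame(results: list[CountResult]) -> pd.DataFrame:
    """Tabulate CountResults, one row per result, with a params snapshot."""
    rows = []
    for r in results:
        rows.append({
            "image_id": r.image_id, "channel": r.channel, "mode": r.mode,
            "count": r.count,
            "threshold": r.seg_params.threshold,
            "threshold_mode": r.seg_params.threshold_mode,
            "min_particle_size": r.seg_params.min_particle_size,
            "watershed_value": r.seg_params.watershed_value,
            "connectivity": r.seg_params.connectivity,
            "area_diff_max": r.overlap_params.area_diff_max,
            "centroid_diff_max": r.overlap_params.centroid_diff_max,
            "window": r.overlap_params.window,
        })
    return pd.DataFrame(rows)


def write_results(
    records: list[AggregationRecord] | list[CountResult],
    path: str | Path,
    allow_empty: bool = False,
) -> Path:
    """Write records to CSV, one row per record (losslessly re-readable for
    aggregation records via :func:`read_aggregation_records`)."""
    path = Path(path)
    if not records:
        if not allow_empty:
            raise ValueError("no records to write (pass allow_empty=True)")
        cols = [f.name for f in dataclasses.fields(AggregationRecord)]
        pd.DataFrame(columns=cols).to_csv(path, index=False)
        return path
    if isinstance(records[0], CountResult):
        df = count_results_frame(records)  # type: ignore[arg-type]
    else:
        df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    df.to_csv(path, index=False)
    return path


def read_aggregation_records(path: str | Path) -> list[AggregationRecord]:
    """Read back a CSV written by :func:`write_results`."""
    df = pd.read_csv(path, dtype={k: str for k in
                                  ("genotype", "differentiation_id",
                                   "well_id", "image_id", "marker")})
    return [AggregationRecord(
        genotype=row["genotype"], differentiation_id=row["differentiation_id"],
        well_id=row["well_id"], image_id=row["image_id"],
        marker=row["marker"], value=float(row["value"]),
    ) for _, row in df.iterrows()]
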