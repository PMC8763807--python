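"""Confocal-like z-stack phantoms with exact ground truth.

Nuclei are rendered as bright ellipsoids: each cell occupies a run of
consecutive slices and appears on each as a disk whose radius shrinks toward
the z caps (the shrink-then-grow footprint the overlap-correction stage
assumes).  A nuclear channel contains every cell; marker channels contain
configurable fractions of cells, with a controlled co-expressing subset.
Volumes are Gaussian-blurred in-plane, offset by a background level, and
corrupted with additive Gaussian read noise, then clipped to the dtype range.

Placement is rejection-sampled with a minimum in-plane center separation;
``min_separation = 0`` allows touching/overlapping cells (the stress regime),
while ``min_separation >= 2 * r_max + 2`` guarantees cells that are disjoint
even after blur (the oracle-exact regime, where the true count is exactly
the number of 3D connected components).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import ZStack

__all__ = ["SyntheticSpec", "GroundTruth", "generate_stack",
           "generate_validation_suite", "NUCLEUS_CHANNEL", "MARKER_CHANNELS"]

NUCLEUS_CHANNEL = "dapi"
MARKER_CHANNELS = ("marker1", "marker2")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one phantom z-stack.

    Intensities are in raw camera units of the output dtype; ``noise_sigma``
    is the standard deviation of the additive Gaussian read noise.
    ``marker_fraction`` is the fraction of cells positive in *each* marker
    channel and ``coexpression_fraction`` the fraction positive in both
    (must not exceed ``marker_fraction``).
    """

    n_cells: int = 120
    shape: tuple[int, int, int] = (12, 512, 512)
    radius_range: tuple[float, float] = (5.0, 8.0)
    z_extent_range: tuple[int, int] = (3, 7)
    min_separation: float = 14.0
    intensity: float = 200.0
    blur_sigma: float = 1.0
    noise_sigma: float = 16.0
    background: float = 10.0
    marker_fraction: float = 0.5
    coexpression_fraction: float = 0.1
    n_marker_channels: int = 2
    dtype: str = "uint8"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range must be ordered")
        if self.z_extent_range[0] > self.z_extent_range[1]:
            raise ValueError("z_extent_range must be ordered")
        if not (0 <= self.marker_fraction <= 1 and 0 <= self.coexpression_fraction <= 1):
            raise ValueError("fractions must be in [0, 1]")
        if self.coexpression_fraction > self.marker_fraction:
            raise ValueError("coexpression_fraction must be <= marker_fraction")
        if self.n_marker_channels not in (0, 1, 2):
            raise ValueError("n_marker_channels must be 0, 1, or 2")


@dataclass
class GroundTruth:
    """Exact inventory of a phantom's cells.

    ``cells`` has one row per cell: centroid (z, row, col), radius, z_extent,
    first slice z0, and boolean marker memberships.  ``totals`` maps channel
    name -> true cell count; ``per_slice`` counts, per channel, the cells
    whose z-run covers each slice.
    """

    cells: pd.DataFrame
    totals: dict[str, int]
    per_slice: pd.DataFrame


def _place_cells(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Rejection-sample cell geometries honoring the in-plane separation."""
    S, H, W = spec.shape
    rows: list[dict] = []
    centers: list[tuple[float, float]] = []
    max_attempts = max(1000, 400 * max(spec.n_cells, 1))
    attempts = 0
    while len(rows) < spec.n_cells:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {spec.n_cells} cells with min_separation="
                f"{spec.min_separation} in {H}x{W} after {max_attempts} attempts")
        attempts += 1
        r = rng.uniform(*spec.radius_range)
        ze_lo, ze_hi = spec.z_extent_range
        ze = int(rng.integers(min(ze_lo, S), min(ze_hi, S) + 1))
        z0 = int(rng.integers(0, S - ze + 1))
        margin = r + 2.0
        if H - margin <= margin or W - margin <= margin:
            raise ValueError("volume too small for the requested radii")
        row = rng.uniform(margin, H - margin)
        col = rng.uniform(margin, W - margin)
        if spec.min_separation > 0 and centers:
            d2 = [(row - a) ** 2 + (col - b) ** 2 for a, b in centers]
            if min(d2) < spec.min_separation ** 2:
                continue
        centers.append((row, col))
        rows.append({"cell_id": len(rows), "z": z0 + (ze - 1) / 2.0,
                     "row": row, "col": col, "radius": r,
                     "z_extent": ze, "z0": z0})
    columns = ["cell_id", "z", "row", "col", "radius", "z_extent", "z0"]
    return pd.DataFrame(rows, columns=columns)


def _assign_markers(spec: SyntheticSpec, cells: pd.DataFrame,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Deterministic marker membership: exact rounded counts, random identity."""
    n = len(cells)
    n_marker = int(round(spec.marker_fraction * n))
    n_co = int(round(spec.coexpression_fraction * n))
    n_co = min(n_co, n_marker)
    for ch in MARKER_CHANNELS:
        cells[ch] = False
    if spec.n_marker_channels >= 1 and n:
        perm = rng.permutation(n)
        co = perm[:n_co]
        only1 = perm[n_co:n_marker]
        cells.loc[cells.index[co], MARKER_CHANNELS[0]] = True
        cells.loc[cells.index[only1], MARKER_CHANNELS[0]] = True
        if spec.n_marker_channels == 2:
            cells.loc[cells.index[co], MARKER_CHANNELS[1]] = True
            only2 = perm[n_marker:2 * n_marker - n_co]
            if len(only2) < n_marker - n_co:
                raise ValueError(
                    "marker_fraction/coexpression_fraction combination needs "
                    "more cells than available for disjoint single-positives")
            cells.loc[cells.index[only2], MARKER_CHANNELS[1]] = True
    return cells


def _render(spec: SyntheticSpec, cells: pd.DataFrame,
            rng: np.random.Generator) -> np.ndarray:
    """Render a subset of cells into one noisy intensity volume."""
    S, H, W = spec.shape
    vol = np.zeros((S, H, W), dtype=np.float64)
    for cell in cells.itertuples(index=False):
        # z semi-axis (ze+1)/2: the ellipsoid poles lie between sampling
        # planes, so the outermost of the ze intersected sections is interior
        # to the cell rather than grazing the pole
        half = (cell.z_extent + 1) / 2.0
        for s in range(cell.z0, cell.z0 + cell.z_extent):
            rel = (s - cell.z) / half
            rs = cell.radius * np.sqrt(max(0.0, 1.0 - rel * rel))
            if rs < 0.5:
                continue
            r_lo = max(0, int(np.floor(cell.row - rs)) - 1)
            r_hi = min(H, int(np.ceil(cell.row + rs)) + 2)
            c_lo = max(0, int(np.floor(cell.col - rs)) - 1)
            c_hi = min(W, int(np.ceil(cell.col + rs)) + 2)
            rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
            disk = (rr - cell.row) ** 2 + (cc - cell.col) ** 2 <= rs * rs
            patch = vol[s, r_lo:r_hi, c_lo:c_hi]
            np.maximum(patch, np.where(disk, spec.intensity, 0.0), out=patch)
    if spec.blur_sigma > 0:
        vol = ndi.gaussian_filter(vol, sigma=(0, spec.blur_sigma, spec.blur_sigma))
    vol += spec.background
    if spec.noise_sigma > 0:
        vol += rng.normal(0.0, spec.noise_sigma, size=vol.shape)
    dtype = np.dtype(spec.dtype)
    info = np.iinfo(dtype)
    return np.clip(np.rint(vol), info.min, info.max).astype(dtype)


def generate_stack(spec: SyntheticSpec,
                   image_id: str = "phantom") -> tuple[ZStack, GroundTruth]:
    """Generate one phantom z-stack and its exact ground truth.

    Deterministic for a given spec (including its seed): the same spec always
    produces a bit-identical stack.
    """
    rng = np.random.default_rng(spec.seed)
    cells = _place_cells(spec, rng)
    cells = _assign_markers(spec, cells, rng)

    channel_cells = {NUCLEUS_CHANNEL: cells}
    for i in range(spec.n_marker_channels):
        ch = MARKER_CHANNELS[i]
        channel_cells[ch] = cells[cells[ch]] if len(cells) else cells

    channels = {name: _render(spec, sub, rng)
                for name, sub in channel_cells.items()}
    stack = ZStack(channels=channels, image_id=image_id)

    totals = {name: int(len(sub)) for name, sub in channel_cells.items()}
    S = spec.shape[0]
    per_slice_rows = []
    for s in range(S):
        row = {"slice": s}
        for name, sub in channel_cells.items():
            if len(sub):
                covered = (sub["z0"] <= s) & (s < sub["z0"] + sub["z_extent"])
                row[name] = int(covered.sum())
            else:
                row[name] = 0
        per_slice_rows.append(row)
    truth = GroundTruth(cells=cells, totals=totals,
                        per_slice=pd.DataFrame(per_slice_rows))
    return stack, truth


def generate_validation_suite(
    n_images: int,
    spec_template: SyntheticSpec,
    seed: int,
    count_range: tuple[int, int] | None = None,
) -> list[tuple[ZStack, GroundTruth]]:
    """Generate ``n_images`` independent phantoms from one template.

    Each image gets a derived seed; when ``count_range`` is given, the true
    cell count of each image is drawn uniformly from it (inclusive).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = np.random.default_rng(seed)
    suite = []
    for i in range(n_images):
        image_seed = int((seed * 100003 + 7919 * (i + 1)) % (2 ** 31 - 1))
        spec = replace(spec_template, seed=image_seed)
        if count_range is not None:
            n = int(rng.integers(count_range[0], count_range[1] + 1))
            spec = replace(spec, n_cells=n)
        suite.append(generate_stack(spec, image_id=f"phantom_{i + 1:03d}"))
    return suite
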