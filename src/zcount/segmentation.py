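"""Stage 2: split each slice's foreground into labeled cell regions.

Touching nuclei are separated by a watershed on the negated Euclidean
distance transform of the binary mask.  A single "watershed value" parameter
controls how aggressively regions are merged: it is the ``h`` of h-maxima
suppression applied to the distance transform before flooding, so raising it
monotonically yields fewer, larger regions.  ``watershed_value = 0``
degenerates to one region per distance-transform basin; a very large value
degenerates to plain connected-components labeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import local_maxima, reconstruction
from skimage.segmentation import watershed as _skimage_watershed

from .preprocess import connectivity_structure

__all__ = [
    "LabelSlice",
    "DetectedObject",
    "label_components",
    "watershed_split",
    "extract_objects",
]


@dataclass
class LabelSlice:
    """Integer label image of one slice: 0 = background, 1..n = regions."""

    labels: np.ndarray  # (H, W) int
    slice_index: int = 0
    n_labels: int = 0


@dataclass(frozen=True)
class DetectedObject:
    """One segmented region on one slice.

    ``centroid`` is the unweighted mean (row, col) of the region's pixels,
    0-based; ``bbox`` is (min_row, min_col, max_row, max_col) half-open.
    """

    slice_index: int
    label: int
    area: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]


def _relabel_raster(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Renumber labels 1..n in raster order of each region's first pixel."""
    flat = labels.ravel()
    nz = np.flatnonzero(flat)
    if nz.size == 0:
        return np.zeros_like(labels), 0
    seen = flat[nz]
    # order of first appearance in raster scan
    _, first_idx = np.unique(seen, return_index=True)
    order = seen[np.sort(first_idx)]
    mapping = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
    mapping[order] = np.arange(1, order.size + 1)
    return mapping[labels], int(order.size)


def label_components(binary_slice: np.ndarray, connectivity: int = 8,
                     slice_index: int = 0) -> LabelSlice:
    """Connected-components labeling of one binary slice.

    Labels are enumerated in raster order of each component's first pixel,
    so output is deterministic.
    """
    binary_slice = np.asarray(binary_slice, dtype=bool)
    if binary_slice.ndim != 2:
        raise ValueError("binary_slice must be 2D")
    labels, n = ndi.label(binary_slice, structure=connectivity_structure(connectivity))
    return LabelSlice(labels=labels, slice_index=slice_index, n_labels=int(n))


def watershed_split(binary_slice: np.ndarray, watershed_value: float = 0.0,
                    connectivity: int = 8, slice_index: int = 0) -> LabelSlice:
    """Split touching blobs by watershed on the negated distance transform.

    ``watershed_value`` (h) suppresses distance-transform maxima shallower
    than h before flooding, merging spurious sub-regions.  Every foreground
    pixel is assigned to exactly one region (no watershed-line pixels are
    dropped), and labels are renumbered in raster order of first pixel.
    """
    if watershed_value < 0:
        raise ValueError("watershed_value must be >= 0")
    binary_slice = np.asarray(binary_slice, dtype=bool)
    if binary_slice.ndim != 2:
        raise ValueError("binary_slice must be 2D")
    if not binary_slice.any():
        return LabelSlice(labels=np.zeros(binary_slice.shape, dtype=np.int32),
                          slice_index=slice_index, n_labels=0)

    structure = connectivity_structure(connectivity)
    skimage_conn = 1 if connectivity == 4 else 2
    edt = ndi.distance_transform_edt(binary_slice)
    if watershed_value > 0:
        # grayscale reconstruction by dilation of (edt - h) under edt:
        # regional maxima of the result are the h-maxima domains of edt
        surface = reconstruction(edt - watershed_value, edt, method="dilation")
    else:
        surface = edt
    peaks = local_maxima(surface, connectivity=skimage_conn) & binary_slice
    # A component whose distance-transform dynamic is below watershed_value
    # loses all its maxima under suppression; give it one marker (raster-first
    # EDT argmax) so no foreground component can disappear.
    comps, ncomp = ndi.label(binary_slice, structure=structure)
    if ncomp:
        has_peak = ndi.sum_labels(peaks.astype(np.int64), comps,
                                  np.arange(1, ncomp + 1)) > 0
        for comp_id in np.flatnonzero(~has_peak) + 1:
            in_comp = comps == comp_id
            flat = np.where(in_comp.ravel(), edt.ravel(), -1.0)
            peaks.ravel()[int(np.argmax(flat))] = True
    markers, _ = ndi.label(peaks, structure=structure)
    labels = _skimage_watershed(-surface, markers=markers, mask=binary_slice,
                                connectivity=skimage_conn)
    labels, n = _relabel_raster(labels.astype(np.int32))
    return LabelSlice(labels=labels, slice_index=slice_index, n_labels=n)


def extract_objects(label_slice: LabelSlice) -> list[DetectedObject]:
    """Measure area, centroid and bbox of every labeled region on a slice."""
    labels = label_slice.labels
    n = label_slice.n_labels
    if n == 0:
        return []
    idx = np.arange(1, n + 1)
    areas = ndi.sum_labels(np.ones_like(labels, dtype=np.int64), labels, idx)
    centroids = ndi.center_of_mass(np.ones_like(labels, dtype=np.float64), labels, idx)
    objects: list[DetectedObject] = []
    slices = ndi.find_objects(labels, max_label=n)
    for i, lab in enumerate(idx):
        sl = slices[i]
        bbox = (sl[0].start, sl[1].start, sl[0].stop, sl[1].stop)
        objects.append(DetectedObject(
            slice_index=label_slice.slice_index,
            label=int(lab),
            area=int(areas[i]),
            centroid=(float(centroids[i][0]), float(centroids[i][1])),
            bbox=bbox,
        ))
    return objects
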