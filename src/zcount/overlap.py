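"""Stage 3: counting with z-overlap correction, plus the 2D collapsed mode.

A nucleus typically appears in several consecutive optical sections, so naive
per-slice counting over-counts.  The correction walks the stack in increasing
z and, for each object on the current slice ("slice A"), looks for a matching
region on the previous slice ("slice B"):

1.  A *logical overlap matrix* — pixels foreground in both slices — is
    intersected with slice A's label image, transferring A's labels onto the
    regions of slice B they touch.
2.  The matched B region's full area and centroid are compared with the A
    object's.  The object is a *repeat* (already counted) only if the relative
    area difference and the centroid displacement are both within their gates;
    exceeding either gate makes it a new cell.

Objects flagged as repeats are not counted; every cell is represented by the
object on the earliest slice where it appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .preprocess import (
    BinaryStack,
    SegmentationParams,
    binarize,
    connectivity_structure,
    remove_small_particles,
)
from .segmentation import DetectedObject, LabelSlice, extract_objects, watershed_split

__all__ = [
    "OverlapParams",
    "RepeatDecision",
    "CountResult",
    "logical_overlap",
    "transfer_labels",
    "flag_repeats",
    "count_stack_3d",
    "count_projection_2d",
]


@dataclass(frozen=True)
class OverlapParams:
    """Sensitivity gates of the overlap-correction method.

    area_diff_max : maximum relative area difference, |aA - aB| / max(aA, aB).
    centroid_diff_max : maximum centroid displacement in pixels (Euclidean).
    window : how many previous slices are examined (nearest first).
    """

    area_diff_max: float = 0.5
    centroid_diff_max: float = 5.0
    window: int = 1

    def __post_init__(self) -> None:
        if self.area_diff_max < 0 or self.centroid_diff_max < 0:
            raise ValueError("overlap gates must be >= 0")
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass(frozen=True)
class RepeatDecision:
    """Audit record of one object's repeat/new decision."""

    object: DetectedObject
    matched: bool
    matched_area: int = 0
    matched_centroid: tuple[float, float] | None = None
    area_diff: float = float("nan")
    centroid_diff: float = float("nan")
    is_repeat: bool = False
    matched_slice: int | None = None


@dataclass
class CountResult:
    """Cell count of one image channel, with the evidence behind it."""

    image_id: str
    channel: str
    mode: str  # "2D" | "3D"
    count: int
    objects_retained: list[DetectedObject] = field(default_factory=list)
    decisions: list[RepeatDecision] = field(default_factory=list)
    seg_params: SegmentationParams = field(default_factory=SegmentationParams)
    overlap_params: OverlapParams = field(default_factory=OverlapParams)


def logical_overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Pixels foreground in both slices (elementwise AND)."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"shape mismatch: {mask_a.shape} vs {mask_b.shape}")
    return mask_a & mask_b


def transfer_labels(
    overlap: np.ndarray,
    labels_a: LabelSlice,
    mask_b: np.ndarray | LabelSlice,
    connectivity: int = 8,
) -> dict[int, tuple[int, tuple[float, float]]]:
    """Assign slice-A labels to the slice-B regions they overlap.

    Each region of slice B that overlaps at least one A label is assigned the
    A label with the largest pixel overlap (ties to the lower label).
    ``mask_b`` may be a binary mask — B regions are then its connected
    components — or an already-segmented :class:`LabelSlice` (as in the 3D
    counting pipeline, where slice B has been watershed-split so that a
    touching pair of cells is two regions, not one merged blob).  Returns
    ``{a_label: (full B-region area, B-region centroid)}``; A labels with no
    overlapping B region are absent.  When two B regions are claimed by the
    same A label, the one with the larger overlap wins.
    """
    overlap = np.asarray(overlap, dtype=bool)
    la = labels_a.labels
    if isinstance(mask_b, LabelSlice):
        b_labels, nb = mask_b.labels, mask_b.n_labels
    else:
        b_labels, nb = ndi.label(np.asarray(mask_b, dtype=bool),
                                 structure=connectivity_structure(connectivity))
    if overlap.shape != la.shape or b_labels.shape != la.shape:
        raise ValueError("overlap, labels_a and mask_b must share one shape")
    if nb == 0 or labels_a.n_labels == 0 or not overlap.any():
        return {}

    sel = overlap & (la > 0) & (b_labels > 0)
    if not sel.any():
        return {}
    pairs_a = la[sel].astype(np.int64)
    pairs_b = b_labels[sel].astype(np.int64)
    na = labels_a.n_labels
    joint = np.bincount(pairs_b * (na + 1) + pairs_a,
                        minlength=(nb + 1) * (na + 1)).reshape(nb + 1, na + 1)

    b_idx = np.arange(1, nb + 1)
    b_areas = ndi.sum_labels(np.ones_like(b_labels, dtype=np.int64), b_labels, b_idx)
    b_cents = ndi.center_of_mass(np.ones(b_labels.shape), b_labels, b_idx)

    result: dict[int, tuple[int, tuple[float, float]]] = {}
    claimed: dict[int, int] = {}  # a_label -> winning overlap size
    for b in range(1, nb + 1):
        row = joint[b, 1:]
        best = int(row.max())
        if best == 0:
            continue
        a = int(np.argmax(row)) + 1  # argmax returns first (lowest label) on ties
        if a in result and claimed[a] >= best:
            continue
        result[a] = (int(b_areas[b - 1]),
                     (float(b_cents[b - 1][0]), float(b_cents[b - 1][1])))
        claimed[a] = best
    return result


def flag_repeats(
    objects_a: list[DetectedObject],
    matches: dict[int, tuple[int, tuple[float, float]]],
    params: OverlapParams,
    matched_slice: int | None = None,
) -> list[RepeatDecision]:
    """Decide repeat/new for each slice-A object against its matched B region.

    ``area_diff = |area_A - area_B| / max(area_A, area_B)``;
    ``centroid_diff`` is the Euclidean distance between centroids.  An object
    is a repeat iff it matched and both differences are within their gates.
    """
    decisions: list[RepeatDecision] = []
    for obj in objects_a:
        match = matches.get(obj.label)
        if match is None:
            decisions.append(RepeatDecision(object=obj, matched=False))
            continue
        m_area, m_cent = match
        area_diff = abs(obj.area - m_area) / max(obj.area, m_area)
        centroid_diff = float(np.hypot(obj.centroid[0] - m_cent[0],
                                       obj.centroid[1] - m_cent[1]))
        is_repeat = (area_diff <= params.area_diff_max
                     and centroid_diff <= params.centroid_diff_max)
        decisions.append(RepeatDecision(
            object=obj, matched=True, matched_area=m_area, matched_centroid=m_cent,
            area_diff=area_diff, centroid_diff=centroid_diff,
            is_repeat=is_repeat, matched_slice=matched_slice,
        ))
    return decisions


def _segment_stack(volume: np.ndarray, seg: SegmentationParams,
                   channel: str) -> tuple[np.ndarray, list[LabelSlice], list[list[DetectedObject]]]:
    binary = binarize(volume, seg, channel_name=channel)
    binary = remove_small_particles(binary)
    mask = binary.mask if binary.mask.ndim == 3 else binary.mask[np.newaxis]
    label_slices = [
        watershed_split(mask[s], seg.watershed_value, seg.connectivity, slice_index=s)
        for s in range(mask.shape[0])
    ]
    objects = [extract_objects(ls) for ls in label_slices]
    return mask, label_slices, objects


def count_stack_3d(
    volume: np.ndarray,
    seg: SegmentationParams | None = None,
    ovl: OverlapParams | None = None,
    *,
    image_id: str = "",
    channel: str = "",
) -> CountResult:
    """Count cells in a z-stack with slice-overlap correction.

    Slices are processed in increasing z.  All objects on the first slice are
    new; on later slices an object flagged as a repeat of any of the previous
    ``window`` slices (nearest first) is not counted.
    """
    seg = seg or SegmentationParams()
    ovl = ovl or OverlapParams()
    volume = np.asarray(volume)
    if volume.ndim == 2:
        volume = volume[np.newaxis]
    if volume.size == 0:
        return CountResult(image_id=image_id, channel=channel, mode="3D", count=0,
                           seg_params=seg, overlap_params=ovl)

    mask, label_slices, objects = _segment_stack(volume, seg, channel)
    n_slices = mask.shape[0]

    retained: list[DetectedObject] = list(objects[0])
    all_decisions: list[RepeatDecision] = [
        RepeatDecision(object=o, matched=False) for o in objects[0]
    ]
    for s in range(1, n_slices):
        objs_a = objects[s]
        if not objs_a:
            continue
        # nearest previous slice first; an object is a repeat as soon as one
        # window slice says so
        final: dict[int, RepeatDecision] = {}
        pending = list(objs_a)
        for offset in range(1, min(ovl.window, s) + 1):
            if not pending:
                break
            b = s - offset
            ov = logical_overlap(mask[s], mask[b])
            matches = transfer_labels(ov, label_slices[s], label_slices[b],
                                      seg.connectivity)
            decisions = flag_repeats(pending, matches, ovl, matched_slice=b)
            still_pending = []
            for obj, dec in zip(pending, decisions):
                if dec.is_repeat:
                    final[obj.label] = dec
                else:
                    if obj.label not in final or (dec.matched and not final[obj.label].matched):
                        final[obj.label] = dec
                    still_pending.append(obj)
            pending = still_pending
        for obj in objs_a:
            dec = final[obj.label]
            all_decisions.append(dec)
            if not dec.is_repeat:
                retained.append(obj)

    return CountResult(image_id=image_id, channel=channel, mode="3D",
                       count=len(retained), objects_retained=retained,
                       decisions=all_decisions, seg_params=seg, overlap_params=ovl)


def count_projection_2d(
    volume: np.ndarray,
    seg: SegmentationParams | None = None,
    *,
    image_id: str = "",
    channel: str = "",
    reduction: str = "max",
) -> CountResult:
    """Count cells on the z-collapsed image (no overlap correction).

    The stack is reduced along z (maximum-intensity projection by default,
    ``reduction="mean"`` also supported), then thresholded, size-filtered and
    watershed-split exactly like a single slice.
    """
    seg = seg or SegmentationParams()
    volume = np.asarray(volume)
    if volume.ndim == 2:
        volume = volume[np.newaxis]
    if volume.size == 0:
        return CountResult(image_id=image_id, channel=channel, mode="2D", count=0,
                           seg_params=seg)
    if reduction == "max":
        proj = volume.max(axis=0)
    elif reduction == "mean":
        proj = volume.mean(axis=0)
    else:
        raise ValueError(f"unknown reduction {reduction!r}")

    _, label_slices, objects = _segment_stack(proj[np.newaxis], seg, channel)
    objs = objects[0]
    decisions = [RepeatDecision(object=o, matched=False) for o in objs]
    return CountResult(image_id=image_id, channel=channel, mode="2D",
                       count=len(objs), objects_retained=objs,
                       decisions=decisions, seg_params=seg)
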