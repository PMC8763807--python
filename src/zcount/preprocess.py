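"""Stage 1 of the counting pipeline: binarization and small-particle filtering.

Each slice of a fluorescence z-stack is converted to a foreground mask by an
intensity threshold, then connected components smaller than a minimum pixel
area are discarded as debris/noise.  Both steps are strictly 2D (per slice);
structure along z is handled later by the overlap-correction stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import remove_small_objects

__all__ = [
    "SegmentationParams",
    "BinaryStack",
    "binarize",
    "remove_small_particles",
    "connectivity_structure",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the per-slice thresholding/segmentation stages.

    Parameters
    ----------
    threshold : float
        Intensity cutoff.  In ``"absolute"`` mode, a pixel is foreground iff
        its intensity is strictly greater than this value.  In ``"fraction"``
        mode, ``threshold`` is a fraction in [0, 1] resolved per slice as
        ``threshold * slice_max``.
    threshold_mode : {"absolute", "fraction"}
    min_particle_size : int
        Connected components (per slice) with area strictly below this many
        pixels are removed.
    watershed_value : float
        Merge scale of the watershed splitting stage; larger values yield
        fewer, larger regions.  See :mod:`zcount.segmentation`.
    connectivity : {4, 8}
        In-slice pixel connectivity used for components and watershed.
    blur_sigma : float
        Optional Gaussian pre-blur (pixels) applied before thresholding.
        Default 0 (off).
    """

    threshold: float = 60.0
    threshold_mode: str = "absolute"
    min_particle_size: int = 30
    watershed_value: float = 2.0
    connectivity: int = 8
    blur_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("absolute", "fraction"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.threshold_mode == "fraction" and self.threshold > 1:
            raise ValueError("fraction-mode threshold must be <= 1")
        if self.min_particle_size < 0:
            raise ValueError("min_particle_size must be >= 0")
        if self.watershed_value < 0:
            raise ValueError("watershed_value must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class BinaryStack:
    """A binarized z-stack: boolean mask plus provenance."""

    mask: np.ndarray  # (S, H, W) bool
    channel: str = ""
    params: SegmentationParams = field(default_factory=SegmentationParams)


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3 structuring element for 4- or 8-connectivity."""
    if connectivity == 4:
        return ndi.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndi.generate_binary_structure(2, 2)
    raise ValueError("connectivity must be 4 or 8")


def _as_volume(a: np.ndarray) -> tuple[np.ndarray, bool]:
    a = np.asarray(a)
    if a.ndim == 2:
        return a[np.newaxis], True
    if a.ndim == 3:
        return a, False
    raise ValueError(f"expected 2D slice or 3D volume, got ndim={a.ndim}")


def binarize(
    channel: np.ndarray,
    params: SegmentationParams | None = None,
    *,
    channel_name: str = "",
) -> BinaryStack:
    """Threshold an intensity volume slice by slice.

    A pixel is foreground iff its intensity is *strictly* greater than the
    effective threshold (ties go to background, so threshold 0 still excludes
    true-zero background).  In fraction mode the effective threshold is
    ``params.threshold * max(slice)``; an all-zero slice therefore yields an
    all-false mask rather than an error.
    """
    params = params or SegmentationParams()
    volume, squeezed = _as_volume(channel)
    volume = volume.astype(np.float64, copy=False)
    if params.blur_sigma > 0:
        volume = ndi.gaussian_filter(volume, sigma=(0, params.blur_sigma, params.blur_sigma))
    if params.threshold_mode == "absolute":
        mask = volume > params.threshold
    else:
        slice_max = volume.max(axis=(1, 2), keepdims=True)
        mask = volume > params.threshold * slice_max
        # all-zero slice: threshold 0 * 0 = 0, and 0 > 0 is false everywhere
    if squeezed:
        mask = mask[0]
    return BinaryStack(mask=mask, channel=channel_name, params=params)


def remove_small_particles(
    binary: BinaryStack | np.ndarray,
    min_particle_size: int | None = None,
    connectivity: int | None = None,
) -> BinaryStack:
    """Remove per-slice connected components with area < ``min_particle_size``.

    Components are strictly 2D; a voxel cluster spanning slices is filtered
    slice by slice.  ``min_particle_size`` of 0 or 1 is the identity.
    """
    if isinstance(binary, BinaryStack):
        params = binary.params
        mask = binary.mask
        channel = binary.channel
    else:
        params = SegmentationParams()
        mask = np.asarray(binary, dtype=bool)
        channel = ""
    if min_particle_size is None:
        min_particle_size = params.min_particle_size
    if connectivity is None:
        connectivity = params.connectivity
    if min_particle_size < 0:
        raise ValueError("min_particle_size must be >= 0")

    volume, squeezed = _as_volume(mask)
    out = np.empty_like(volume)
    skimage_conn = 1 if connectivity == 4 else 2
    for s in range(volume.shape[0]):
        if min_particle_size <= 1:
            out[s] = volume[s]
            continue
        out[s] = remove_small_objects(volume[s], max_size=min_particle_size - 1,
                                      connectivity=skimage_conn)
    if squeezed:
        out = out[0]
    return BinaryStack(mask=out, channel=channel, params=params)
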