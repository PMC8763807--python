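"""Versioned ground-truth validation of the counting modes.

The original tool was validated against hand counts on real confocal images;
those images are not available, so validation here runs the pipeline on
synthetic phantoms with exact ground truth and reports the same statistic:
the mean over images of the per-image percent error,
``100 * |auto - truth| / truth``.

The phantom conditions below are fixed ("versioned") so that validation runs
are comparable across machines and versions: true counts uniform in 50-300
per 512x512 field, cell radii 5-8 px, each cell spanning 3-7 consecutive
slices of a 12-slice stack, in-plane center separation >= 14 px (so touching
cells occur at the upper densities), Gaussian read noise with sigma = 8% of
the peak intensity.  The 2D mode is validated on 11 images and the 3D mode
on 9, mirroring the sizes of the original hand-counted validation sets.
"""

from __future__ import annotations

from zcount.overlap import (CountResult, OverlapParams, count_projection_2d,
                            count_stack_3d)
from zcount.preprocess import SegmentationParams
from zcount.quantify import ValidationResult, mean_percent_error
from zcount.synthdata import (NUCLEUS_CHANNEL, SyntheticSpec,
                              generate_validation_suite)

__all__ = [
    "VALIDATION_TEMPLATE",
    "VALIDATION_COUNT_RANGE",
    "N_IMAGES_2D",
    "N_IMAGES_3D",
    "run_validation",
]

#: Fixed phantom conditions of the validation suite (see module docstring).
VALIDATION_TEMPLATE = SyntheticSpec(
    shape=(12, 512, 512),
    radius_range=(5.0, 8.0),
    z_extent_range=(3, 7),
    min_separation=14.0,
    intensity=200.0,
    blur_sigma=1.0,
    noise_sigma=16.0,      # 0.08 x peak intensity
    background=10.0,
    n_marker_channels=0,   # counting validation uses the nuclear channel only
)

#: True cell counts are drawn uniformly from this range (inclusive).
VALIDATION_COUNT_RANGE = (50, 300)

N_IMAGES_2D = 11
N_IMAGES_3D = 9


def run_validation(
    mode: str,
    seed: int,
    n_images: int | None = None,
    seg: SegmentationParams | None = None,
    ovl: OverlapParams | None = None,
) -> tuple[ValidationResult, list[CountResult], list[int]]:
    """Count the validation phantoms and score them against ground truth.

    Returns the percent-error summary, the per-image CountResults, and the
    true counts.  ``mode`` is ``"2D"`` (z-collapsed counting, 11 images by
    default) or ``"3D"`` (overlap-corrected counting, 9 images by default).
    """
    mode = mode.upper()
    if mode not in ("2D", "3D"):
        raise ValueError("mode must be '2D' or '3D'")
    if n_images is None:
        n_images = N_IMAGES_2D if mode == "2D" else N_IMAGES_3D
    seg = seg or SegmentationParams()
    ovl = ovl or OverlapParams()

    suite = generate_validation_suite(
        n_images, VALIDATION_TEMPLATE, seed, count_range=VALIDATION_COUNT_RANGE)
    results: list[CountResult] = []
    truths: list[int] = []
    for stack, truth in suite:
        volume = stack.channels[NUCLEUS_CHANNEL]
        if mode == "2D":
            res = count_projection_2d(volume, seg, image_id=stack.image_id,
                                      channel=NUCLEUS_CHANNEL)
        else:
            res = count_stack_3d(volume, seg, ovl, image_id=stack.image_id,
                                 channel=NUCLEUS_CHANNEL)
        results.append(res)
        truths.append(truth.totals[NUCLEUS_CHANNEL])
    vr = mean_percent_error([r.count for r in results], truths)
    return vr, results, truths
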