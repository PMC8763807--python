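"""Stage 4: marker percentages, co-expression, nested aggregation, validation.

The experimental arithmetic downstream of counting:

* percent of marker-positive cells relative to the nuclear (DAPI) count,
* two-channel co-expression by one-to-one centroid matching,
* the nested averaging hierarchy image -> well -> differentiation -> genotype
  with the genotype SEM taken over differentiation replicates,
* mean percent error of automated counts against reference (hand) counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import DetectedObject

__all__ = [
    "AggregationRecord",
    "SummaryStat",
    "ValidationResult",
    "HIERARCHY",
    "positive_percent",
    "coexpression_count",
    "aggregate",
    "mean_percent_error",
]

#: Nesting order of the averaging hierarchy, outermost first.
HIERARCHY = ("genotype", "differentiation_id", "well_id", "image_id")


@dataclass(frozen=True)
class AggregationRecord:
    """One per-image value (a count or a percentage) with its hierarchy keys."""

    genotype: str
    differentiation_id: str
    well_id: str
    image_id: str
    marker: str
    value: float

    def __post_init__(self) -> None:
        for key in (*HIERARCHY, "marker"):
            if not str(getattr(self, key)):
                raise ValueError(f"hierarchy key {key!r} must be non-empty")
        if self.value < 0:
            raise ValueError("value must be >= 0")


@dataclass(frozen=True)
class SummaryStat:
    """Mean +/- SEM at one level of the hierarchy.

    ``sem`` is the standard error over the units one level down (sample
    standard deviation / sqrt(n)); it is None when fewer than two units exist.
    """

    level: str
    keys: tuple[str, ...]
    marker: str
    mean: float
    sem: float | None
    n_units: int


@dataclass(frozen=True)
class ValidationResult:
    """Per-image percent errors of automated vs reference counts."""

    per_image_percent_error: tuple[float, ...]
    mean_percent_error: float
    n: int


def positive_percent(marker_count: int, nucleus_count: int) -> float:
    """Percent of nuclei positive for a marker: 100 * marker / nuclei."""
    if nucleus_count <= 0:
        raise ValueError("nucleus_count must be > 0")
    return 100.0 * marker_count / nucleus_count


def coexpression_count(
    objects_c1: list[DetectedObject],
    objects_c2: list[DetectedObject],
    match_radius: float = 5.0,
    max_slice_diff: int = 1,
) -> int:
    """Number of cells positive in both channels, by centroid matching.

    Retained (post-dedup) objects from the two channels are paired greedily by
    ascending in-plane centroid distance; a pair counts as one co-expressing
    cell when its distance is within ``match_radius`` and its slice indices
    differ by at most ``max_slice_diff``.  Matching is one-to-one, so the
    result never exceeds the smaller list, and the operation is symmetric.
    """
    if match_radius < 0:
        raise ValueError("match_radius must be >= 0")
    candidates = []
    for i, o1 in enumerate(objects_c1):
        for j, o2 in enumerate(objects_c2):
            if abs(o1.slice_index - o2.slice_index) > max_slice_diff:
                continue
            d = float(np.hypot(o1.centroid[0] - o2.centroid[0],
                               o1.centroid[1] - o2.centroid[1]))
            if d <= match_radius:
                # tie-break on the unordered centroid pair so the count is
                # symmetric in the two channels even with tied distances
                k1 = (o1.slice_index, *o1.centroid)
                k2 = (o2.slice_index, *o2.centroid)
                candidates.append((d, min(k1, k2), max(k1, k2), i, j))
    candidates.sort(key=lambda c: c[:3])
    used1: set[int] = set()
    used2: set[int] = set()
    n_pairs = 0
    for _, _, _, i, j in candidates:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        n_pairs += 1
    return n_pairs


def _sem(values: np.ndarray) -> float | None:
    if values.size < 2:
        return None
    return float(np.std(values, ddof=1) / np.sqrt(values.size))


def aggregate(records: list[AggregationRecord]) -> dict[str, list[SummaryStat]]:
    """Nested unweighted averaging: image -> well -> differentiation -> genotype.

    Per-image values are averaged to one value per well, well values to one
    per differentiation, and differentiation values to one per genotype; the
    genotype SEM is computed over the differentiation-level values (and each
    level's SEM over the units one level down).  Returns summaries keyed by
    level name: ``{"well": [...], "differentiation": [...], "genotype": [...]}``.
    """
    if not records:
        return {"well": [], "differentiation": [], "genotype": []}
    df = pd.DataFrame([{
        "genotype": r.genotype, "differentiation_id": r.differentiation_id,
        "well_id": r.well_id, "image_id": r.image_id,
        "marker": r.marker, "value": float(r.value),
    } for r in records])

    out: dict[str, list[SummaryStat]] = {}
    level_names = {3: "well", 2: "differentiation", 1: "genotype"}
    current = df
    for depth in (3, 2, 1):
        keys = list(HIERARCHY[:depth])
        grouped = current.groupby(keys + ["marker"], sort=True)["value"]
        summary = grouped.agg(["mean", "count"]).reset_index()
        sems = grouped.apply(lambda v: _sem(v.to_numpy())).reset_index(drop=True)
        stats = []
        for (_, row), sem in zip(summary.iterrows(), sems):
            stats.append(SummaryStat(
                level=level_names[depth],
                keys=tuple(str(row[k]) for k in keys),
                marker=str(row["marker"]),
                mean=float(row["mean"]),
                sem=sem,
                n_units=int(row["count"]),
            ))
        out[level_names[depth]] = stats
        current = summary.rename(columns={"mean": "value"})[keys + ["marker", "value"]]
    return out


def mean_percent_error(auto: list[float], reference: list[float]) -> ValidationResult:
    """Mean of per-image percent errors, 100 * |auto - reference| / reference."""
    if len(auto) != len(reference) or len(auto) == 0:
        raise ValueError("auto and reference must be equal-length, non-empty")
    reference_arr = np.asarray(reference, dtype=float)
    if np.any(reference_arr <= 0):
        raise ValueError("reference counts must be > 0")
    auto_arr = np.asarray(auto, dtype=float)
    pe = 100.0 * np.abs(auto_arr - reference_arr) / reference_arr
    return ValidationResult(
        per_image_percent_error=tuple(float(x) for x in pe),
        mean_percent_error=float(pe.mean()),
        n=len(auto),
    )
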