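# Methods

## Pipeline model and assumptions

`zcount` treats a confocal z-stack as a sequence of optical sections through
a field of roughly ellipsoidal nuclei.  The pipeline is slice-based: all
segmentation happens in 2D, and the third dimension is handled exclusively by
the overlap-correction stage.  This matches the acquisition physics — a
nucleus produces a run of consecutive footprints that grow toward its
equator and shrink toward its poles — and keeps every stage auditable: the
output records every per-object decision (matched area, centroid
displacement, repeat verdict).

**Thresholding.**  Foreground is `intensity > t`, strictly, so `t = 0`
still excludes true-zero background.  `t` may be absolute (global across
slices) or a fraction of each slice's maximum; the fraction mode adapts to
per-slice brightness variation but is sensitive to hot pixels, so absolute
is the default.  An all-zero slice in fraction mode yields an empty mask
rather than an error.

**Particle filter.**  Per-slice connected components with area below
`min_particle_size` are removed.  The filter is deliberately 2D — a small
cap footprint of a large nucleus may be removed on one slice yet the nucleus
survives on its equatorial slices, where it is counted.

**Watershed.**  Touching nuclei are split by flooding the negated Euclidean
distance transform (EDT).  The single tuning parameter is the `h` of
h-maxima suppression applied to the EDT before flooding: maxima whose
dynamic (height above the saddle connecting them to a higher maximum) is
below `h` are merged, so the number of regions is monotone non-increasing in
`h`.  `h = 0` gives one region per EDT basin; `h → ∞` degenerates to plain
connected components (a component whose whole dynamic falls below `h` keeps
one injected marker at its EDT argmax, so no foreground is ever lost).
Every foreground pixel is assigned to a region (conservation), and labels
are renumbered in raster order of first pixel so runs are bit-reproducible.

**Overlap correction (3D mode).**  Walking slices in increasing z, each
object on the current slice A is matched against the previous slice B
through the logical overlap matrix — pixels foreground in *both* slices.
The matrix is the foreground AND, not pixel-value equality: shared
background carries no cell identity, and only the AND restricts attention
to cellular regions.  A labels are transferred to the B regions they
overlap (largest pixel overlap wins; ties to the lower label).  The B
regions are the *watershed-segmented* regions of slice B — the same
segmentation that counts slice B — not raw connected components; with
touching cells a raw component merges neighbours and inflates the matched
area, which would defeat the area gate precisely in the dense fields the 3D
mode exists for.  The matched B region contributes its full area and
centroid (the cell on slice B, not merely the intersection).  An object is
a repeat iff its relative area difference `|aA − aB| / max(aA, aB)` and its
centroid displacement are both within their gates; exceeding either makes
it a new cell.  Each cell is represented by its earliest-slice object.
A `window > 1` matches against up to that many previous slices, nearest
first, to bridge a dropped or empty slice.

**2D mode.**  Maximum-intensity projection over z (mean projection is
available), then the same threshold → filter → watershed chain, no
correction.  Appropriate for thin cultures; in thick or dense stacks the
projection fuses z-separated cells.

**Quantification.**  Marker percentages use the same-field nucleus (DAPI)
count from the same counting mode as denominator; a zero nucleus count is an
error, never 0%.  Co-expression pairs the *retained* (post-dedup) objects of
two channels greedily by ascending in-plane centroid distance, one-to-one,
within a match radius (default = the centroid gate) and a slice tolerance;
centroid matching is robust to area mismatch between stains, where pixel
overlap is not.  The greedy matching is symmetric in its arguments (ties are
broken on the unordered centroid pair) and is never smaller than half the
maximum matching.  The experimental hierarchy averages unweighted at each
level — images to a well value, wells to a differentiation value,
differentiations to a genotype mean — with the SEM at each level computed
over the units one level down (sample SD / √n, reported as missing when
n < 2).  The genotype SEM over n = 3 independent differentiations mirrors
standard practice for iPSC differentiation experiments.

**Percent error.**  Validation uses the per-image absolute percent error
`100·|auto − reference| / reference`, averaged over images.  The absolute
form keeps over- and under-counts from cancelling in the mean.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `threshold` | 60 (absolute) | intensity cutoff; suited to 8-bit stacks with peak ≈ 200 and background ≪ 60 |
| `min_particle_size` | 30 px | debris floor ≈ 40% of the smallest expected nuclear cross-section (r ≈ 5 px at 20×) |
| `watershed_value` | 2.0 | EDT merge scale; merges ragged-edge maxima (dynamic ≲ 2 px) while preserving true necks between touching nuclei |
| `connectivity` | 8 | in-slice pixel connectivity |
| `area_diff_max` | 0.5 | relative area gate of the repeat test (size-invariant across magnifications) |
| `centroid_diff_max` | 5 px | centroid gate; nuclei drift little between adjacent sections |
| `window` | 1 | previous slices examined |

All defaults are config-exposed (YAML) and every `CountResult` row snapshots
the parameters that produced it.

## The phantom generator

Phantoms emulate DAPI-dense confocal fields: `n_cells` ellipsoidal nuclei
with in-plane radius 5–8 px, each spanning 3–7 consecutive slices of a
12 × 512 × 512 stack, rendered at peak 200 on background 10, blurred in-plane
(σ = 1 px, a modest PSF at 20×), with additive Gaussian read noise
σ = 16 (8% of peak), 8-bit output.  A cell spanning `ze` slices has z
semi-axis `(ze + 1)/2`, placing the sampling planes strictly interior to the
ellipsoid: optical sections sample the interior of a slab and essentially
never graze a pole, and under this convention consecutive-slice area ratios
of the rendered footprints (0.58–0.75 for `ze` 3–7) are comfortably inside
the default area gate, which is what makes a single area-gate default
coherent across the z-extent range.  Placement is rejection-sampled with a
minimum in-plane centre separation; 14 px (the validation default) permits
touching pairs at the upper densities, while `≥ 2·r_max + 2` guarantees
disjoint cells — the *oracle-exact regime*, in which the true count equals
the 3D connected-components count of the binarized volume and the pipeline
is required to match it exactly.  Marker membership is assigned by exact
rounded counts (`round(fraction · n)`) with randomized identity, so marker
and co-expression percentages are recoverable to one-cell granularity.

What phantoms do **not** emulate: realistic PSF anisotropy and z-blur,
Poisson shot noise, intensity heterogeneity within and between nuclei,
non-ellipsoidal morphologies, staining artifacts, and the subjectivity of
the hand counts real validations are scored against.  Passing the phantom
validation therefore demonstrates the algorithmic correctness of the
pipeline (segmentation, dedup bookkeeping, arithmetic) under controlled
geometry and noise — not image-quality robustness on real microscopy, where
errors are dominated by exactly the factors held clean here.  That is also
why the phantom percent errors (≈ 0–0.2%) sit well below the few-percent
errors reported for validations against hand counts on real images.

## Validation suites and problem sizes

The versioned suite (`zcount.validation`) fixes the conditions above and
draws true counts uniformly from 50–300 per image: 11 images for the 2D mode
and 9 for the 3D mode, with per-image seeds derived from one base seed.
These sizes keep a full validation run under half a minute on one CPU while
spanning sparse to dense (touching) fields.  `scripts/acceptance.py --seed N
--out results/acceptance.json` writes both mean percent errors as JSON.

## Numerical choices and degenerate inputs

* Binarization ties go to background (strict `>`).
* Watershed ties: every masked pixel is flooded from the nearest marker;
  label order is raster-deterministic, so identical inputs give
  bit-identical results.
* Label transfer ties (equal pixel overlap) go to the lower label; when two
  B regions claim one A label the larger overlap wins.
* Empty volume → count 0; empty slice inside a stack is skipped and
  `window = 2` can bridge it.
* `sem` is undefined (not 0) for a single unit.
* Border-clipped objects are retained; phantoms keep cells `r + 2` px from
  the xy borders so ground truth is unambiguous.
* Infeasible phantom packing fails with an explicit error after a bounded
  number of rejection-sampling attempts rather than looping forever.

## Known limitations

* No true 3D watershed; a cell whose footprint drifts more than the centroid
  gate between sections (e.g. strongly tilted elongated nuclei) is split.
* The dedup window matches single cells, not trajectories; it cannot follow
  a cell through more than `window` consecutive dropout slices.
* Distance metrics are isotropic in-plane pixels; slice spacing is carried
  as metadata but not used to scale the centroid gate.
* Automatic threshold selection (Otsu and friends) is intentionally out of
  scope: thresholds are user-set and recorded.
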