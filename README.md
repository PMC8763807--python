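# zcount

Automated cell counting in confocal immunofluorescence z-stacks.

A nucleus imaged as a confocal z-stack appears in several consecutive optical
sections, so counting objects slice by slice over-counts, while counting a
z-collapsed projection under-counts dense fields where nuclei overlap in
xy.  `zcount` implements a slice-based counting pipeline for both situations,
aimed at quantifying marker-positive fractions (e.g. OLIG2+, NKX2.2+ of
DAPI) in stem-cell-derived neural cultures:

1. **Threshold** — each slice is binarized (pixel intensity strictly greater
   than an absolute cutoff, or a per-slice fraction of the maximum) and
   connected components below a minimum area are discarded as debris.
2. **Segment** — touching nuclei on a slice are split by a watershed on the
   negated Euclidean distance transform; a single *watershed value* `h`
   (h-maxima suppression of the distance transform) controls the merge scale,
   so larger values give fewer, larger regions.
3. **Overlap correction (3D mode)** — for each object on slice *A*, the
   logical overlap matrix `mask_A ∧ mask_B` with the previous slice *B*
   transfers *A*'s labels onto *B*'s segmented regions.  An object whose
   matched B cell satisfies *both* gates

   ```
   |area_A − area_B| / max(area_A, area_B) ≤ area_diff_max      (default 0.5)
   ‖centroid_A − centroid_B‖              ≤ centroid_diff_max   (default 5 px)
   ```

   is a *repeat* and is not counted again; exceeding either gate makes it a
   new cell.  The 2D mode instead counts a maximum-intensity projection with
   no correction.
4. **Quantify** — marker-positive percentages (`100 · marker / nuclei`),
   two-channel co-expression by greedy one-to-one centroid matching, and the
   experimental averaging hierarchy image → well → differentiation → genotype
   with the genotype mean ± SEM taken over independent differentiations.

Because validating a counter needs images with known truth, the package ships
a phantom generator: nuclei as bright ellipsoids spanning several consecutive
slices (per-slice disks that shrink toward the z caps), with configurable
count, density, marker/co-expression fractions, blur and read noise — and an
exact ground-truth inventory.

## Worked example

Simulate a two-marker phantom (60 nuclei at moderate density, 50% positive
for each marker, 10% co-expressing), then count it in 3D mode:

```sh
$ zcount simulate --spec demo_spec.yaml --out-tiff demo.tif --out-truth demo_truth.csv
wrote demo.tif (dapi+marker1+marker2, 10 slices) and demo_truth.csv ({'dapi': 60, 'marker1': 30, 'marker2': 30})

$ zcount count demo.tif --channels dapi,marker1,marker2 --mode 3d
image_id,channel,mode,count,threshold,threshold_mode,min_particle_size,watershed_value,connectivity,area_diff_max,centroid_diff_max,window
demo,dapi,3D,60,60.0,absolute,30,2.0,8,0.5,5.0,1
demo,marker1,3D,30,60.0,absolute,30,2.0,8,0.5,5.0,1
demo,marker2,3D,30,60.0,absolute,30,2.0,8,0.5,5.0,1
```

Every row carries the full parameter snapshot that produced its count.  The
same from Python, including percentages:

```python
from zcount import (read_zstack, count_stack_3d, positive_percent,
                    coexpression_count)

stack = read_zstack("demo.tif", ["dapi", "marker1", "marker2"])
res = {name: count_stack_3d(vol, channel=name)
       for name, vol in stack.channels.items()}
n = res["dapi"].count                                   # 60 nuclei
positive_percent(res["marker1"].count, n)               # 50.0 (%)
coexpression_count(res["marker1"].objects_retained,
                   res["marker2"].objects_retained,
                   match_radius=5.0, max_slice_diff=10)  # 6 co-expressing
```

All values match the generative truth (60 nuclei, 50% per marker, 6 = 10% of
60 co-expressing cells).

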