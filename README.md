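# wingasym

Landmark-free morphometry and fluctuating-asymmetry analysis of paired
insect wing images.

Insect wings are partitioned by their vein network into membrane *cells*.
Comparing the left and right wing of one individual — without having to
place homologous landmarks — gives a rich read-out of developmental
stability: small random left/right deviations (fluctuating asymmetry) show
up in cell sizes and shapes, vein-junction positions, and whole-wing
dimensions. `wingasym` implements that pipeline for pairs of binarizable
wing scans (dark veins on light membranes):

1. **Binarize** each image at a fixed threshold (default 0.54 on [0, 1]
   intensities) and mirror the left wing so both share chirality.
2. **Segment** every membrane cell by 8-connected region growing and
   measure it: area *A* (pixel count), length *L* (maximum pairwise
   distance between its boundary pixels), width *W = A/L*, and circularity

   *C* = 4π·*A* / *P*²,

   where *P* is the traced-contour perimeter. The wing silhouette provides
   the outline and whole-wing area/length/width/perimeter.
3. **Skeletonize** the vein network (morphological thinning) and detect
   vein **junctions** as skeleton branch points: pixels with ≥ 3 skeleton
   neighbors whose crossing number (0→1 transitions around the
   8-neighborhood cycle) is ≥ 3, clustered per anatomical junction.
4. **Superimpose** the wings with a rigid transform (x, y, θ) — translation
   plus rotation, deliberately *no scaling* so genuine size asymmetry
   survives — found by global-best Particle Swarm Optimization (30
   particles, 40 iterations, inertia 1.0 damped by 0.95, cognitive and
   social coefficients 1.2) minimizing the mean nearest-point distance
   between the resampled wing outlines, after centroid pre-alignment.
5. **Match** cells and junctions by nearest centroid, once with each wing
   as reference (bidirectional, so extra or merged cells on either side are
   still covered), and **quantify asymmetry**: per metric and direction an
   OLS regression (slope, intercept, r²) of target on reference and the
   NRMSE = RMSE / (max − min of the reference); mean ± SD of centroid,
   junction and outline distances; and signed differences in counts and
   whole-wing dimensions. Cells can be grouped into up to five *cell sets*
   (≥ 3 cells each) for localized comparisons.

A synthetic-wing generator (`wingasym.synth`) renders Voronoi-tessellated
wing pairs with exact polygonal ground truth and controllable left/right
perturbations (area scaling, vertex jitter, rigid offset, salt-and-pepper
noise, Gaussian blur), so the whole pipeline is testable without any image
downloads.

## Worked example

Generate a synthetic pair whose left wing is 10 % larger in every cell and
rigidly displaced, then run the full analysis:

```python
import numpy as np
import wingasym as wa

cfg = wa.SynthConfig(seed=42, area_scale=1.10, offset_x=8, offset_y=-5,
                     offset_theta=np.deg2rad(4))
left, right, truth = wa.generate_pair(cfg)
out = wa.analyze_pair(right, left, wa.PairOptions(mirror2=True, seed=0))

t = out.transform
print(f"recovered transform: x={t.x:.2f} y={t.y:.2f} "
      f"theta={np.rad2deg(t.theta):.2f} deg")
for m, st in out.result.comparisons[1].items():
    print(f"{m:<12} slope={st.slope:.3f}  r2={st.r2:.4f}  nrmse={st.nrmse:.4f}")
for cat, (mean, sd) in out.result.distances.items():
    print(f"{cat} distance: mean={mean:.2f} px  sd={sd:.2f} px")
```

prints

```
recovered transform: x=-11.22 y=5.12 theta=-4.31 deg
area         slope=1.103  r2=0.9974  nrmse=0.1487
length       slope=1.036  r2=0.9953  nrmse=0.1681
width        slope=1.039  r2=0.9955  nrmse=0.1054
circularity  slope=1.039  r2=0.9849  nrmse=0.0371
centroid distance: mean=7.52 px  sd=3.68 px
junction distance: mean=7.66 px  sd=3.81 px
outline distance: mean=8.47 px  sd=2.55 px
```

Read-out: the PSO undid the configured 4° rotation (θ ≈ −4.3° recovers it
about the moved centroid); the area regression slope ≈ 1.10 reports the
built-in 10 % size asymmetry; r² near 1 says cell-to-cell correspondence is
clean; circularity stays symmetric (slope ≈ 1.04, low NRMSE) because the
perturbation changed size, not shape; and the residual distances reflect
the unremovable size mismatch under a rigid (non-scaling) superimposition.

## Command line

```sh
# synthesize a pair with ground truth
wingasym synth --seed 3 --cells 20 --out-dir demo/

# analyze a pair (first image is the left wing and gets mirrored)
wingasym run --pair demo/left.png demo/right.png --label demo --out reports/

# batch projects: YAML listing pairs and options
wingasym project project.yaml --out reports/
```

Reports are CSV (per-wing cell tables, wing summaries, per-direction
comparison tables, distances/deltas, per-set tables, cross-pair aggregate)
plus a human-readable TXT block per pair.

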