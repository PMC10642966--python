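# unfoldreg

Topology-preserving, surface-based registration of hippocampal subfield
segmentations.

The hippocampus is a folded cortical sheet whose cytoarchitectonic
subfields (subicular complex, CA1–CA4) occupy consistent positions *on*
the sheet while the sheet's folding varies grossly between individuals.
Conventional 3D volumetric registration aligns outer shape, not sheet
topology: propagated subfield labels can jump across the vestigial sulcus,
producing anatomically impossible maps (CA1 islands, CA1 directly
bordering CA3). `unfoldreg` instead:

1. **unfolds** each segmented hippocampus into a standardized 2D
   rectangle by solving Laplace's equation between anatomical boundary
   labels — anterior/posterior termini (A-P axis), proximal/distal edges
   (P-D axis), and SRLM/outer surface (laminar axis);
2. computes per-vertex **morphometric features** on the mid-thickness
   surface — thickness (mm), gyrification index (native/unfolded area
   ratio), and mean curvature (mm⁻¹) — that are contrast-agnostic and
   associated with subfield boundaries;
3. **registers** samples in unfolded space with a multi-channel
   diffeomorphic (stationary-velocity) engine and groupwise template
   building, so homologous sheet positions, not absolute 3D positions,
   are brought into correspondence;
4. **propagates** subfield labels between samples through the
   concatenated transforms and evaluates alignment (Dice overlap, border
   distances, topology checks) against unfolding alone and against an
   idealized 3D volumetric control on binarized masks.

Because histological ground truth cannot be redistributed, the package
ships a first-class **phantom generator**: folded-sheet labelmaps with
analytically known intrinsic coordinates, subfield boundaries, and
morphometry, plus seeded inter-sample variability (folding configuration,
subfield proportions, hemisphere). Every stage of the pipeline can be
validated against these analytic oracles.

Intended users: researchers in hippocampal morphometry and segmentation
who want a testable, self-contained implementation of unfolded-space
registration, and method developers who need a controlled benchmark for
surface-based vs volumetric label propagation.

## The model in brief

Unfolding solves three harmonic fields over the gray-matter domain Ω:

    ∇²φ = 0 on Ω,  φ = 0 / 1 on opposing boundary labels

for φ ∈ {ap, pd, io}, giving each voxel intrinsic coordinates
(ap, pd, io) ∈ [0,1]³. The io = 0.5 level set sampled on a regular
(A-P × P-D) lattice turns the sheet into a flat 2D image. Registration
minimizes the mean per-channel SSD of z-scored feature images under a
stationary velocity field v (displacement = scaling-and-squaring of v,
guaranteeing a positive-Jacobian, invertible warp; the rectangle has four
true edges — nothing wraps). Groupwise alignment iterates
average → register-all → re-average four times. Labels move only by
nearest-neighbor/majority resampling; subfield label propagation from
sample *i* to the reference runs through

    ref → (template ← ref)⁻¹ → (template ← sample i)

## Worked example

```bash
unfoldreg benchmark --n 7 --seed 42 --grid 64x32 --ablation --out report/
```

generates a seven-sample phantom cohort (four left, three right
hemispheres, jittered folding and subfield proportions), runs the three
conditions and writes `report/report.json`. On this cohort the headline
numbers are:

```
mean native-space Dice   volumetric control   0.641
                         unfolding alone      0.743
                         unfolded registration 0.766
one-tailed paired t (reg > unfolding alone)   p = 0.042
one-tailed paired t (unfolding > volumetric)  p = 7e-07
topology violations (unfolded registration)   0 breaks, 0 reorderings
```

Reading: unfolding alone already aligns subfields far better than
idealized volumetric registration (it factors out folding), and
feature-driven registration in unfolded space improves every subfield
further while preserving sheet topology exactly. `report/dice.csv` holds
the per-sample × per-subfield values behind the means; `ablation.csv`
compares all seven feature subsets.

The same pipeline is scriptable from Python:

```python
from unfoldreg import (PhantomParams, CohortVariation, generate_cohort,
                       run_benchmark)

cohort = generate_cohort(7, PhantomParams(grid_shape=(64, 32)),
                         CohortVariation(), seed=42)
report = run_benchmark(cohort, ref_index=0, grid_shape=(64, 32))
print(report.mean_dice("unfolded_reg", "native"))
```

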