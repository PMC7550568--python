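# voxelfd

Box-counting fractal dimension of 3-D binary segmentation volumes, with
principled selection of the interval of fractal spatial scales, and the
statistical machinery to evaluate the resulting morphometric feature as a
marker of brain aging.

## The problem

The cerebral cortex is a folded sheet whose structural complexity is not
well captured by Euclidean descriptors. Over a limited range of spatial
scales it is *statistically self-similar*, and its space-filling capacity
can be summarized by a single unit-less number, the fractal dimension (FD):
between 2 (a flat sheet) and 3 (a space-filling solid) for a cortical
ribbon mask. Box counting estimates FD by covering the binary object
`I(x,y,z)` with grids of cubic boxes of side `s` and counting the occupied
boxes `N(s)`; for a fractal,

```
N(s) = C · s^(−FD)        ⇔        log10 N(s) = log10 C − FD · log10 s
```

so FD is the absolute slope of an ordinary least-squares line in the
log–log plane. Real objects obey this power law only between a minimum and
a maximum fractal scale (`mfs`, `Mfs`), and the choice of that interval
changes the estimate substantially — which is exactly what this package
lets you study. It is aimed at neuroimaging researchers who already have
binary masks (e.g. a FreeSurfer cortical ribbon exported as NIfTI) and at
anyone needing a well-tested, oracle-validated 3-D box counter.

## What it does

- **Counting** (`voxelfd.boxcount`): occupied-box counts at dyadic scales
  `s = 2^k` voxels, `k = 0..8`, each scale averaged over 20 random integer
  grid-origin offsets (seeded, reproducible) to remove grid-placement bias;
  an exact zero-offset mode for analytic work.
- **Scaling-range selection** (`voxelfd.scaleselect`), four strategies:
  - `apriori1` — fixed `[4, 256]` mm;
  - `apriori2` — 5% and 40% of the shortest foreground bounding-box side,
    rounded to powers of two;
  - `marzi2018` — exhaustive window search maximizing the adjusted
    coefficient of determination `R²_adj` (≥ 4 points);
  - `fractalbrain` — window search ranked by `R²_adj` *rounded to 3
    decimals*, ties broken toward the widest interval (≥ 5 points, hence
    ≥ 1.2 decades), so non-effective decimal places never drive selection.
- **Phantoms** (`voxelfd.phantoms`): solid cube (FD 3), one-voxel plane
  (FD 2), Menger sponge (FD = log 20 / log 3 ≈ 2.7268, exactly recovered on
  its native triadic scales), perturbed spherical shells, and synthetic
  age-linked cohorts — every downstream stage is testable without MRI data.
- **Evaluation** (`voxelfd.agepredict`): Pearson feature–age association;
  individual age prediction with OLS on (feature, eTIV, sex) in a repeated
  5-fold cross-validation loop with training-set-only standardization,
  scored by mean absolute error (MAE), with label-permutation significance.

## Worked example

```sh
$ voxelfd phantom shell --radius 24 --amplitude 5 --seed 3 --out shell.nii.gz
$ voxelfd fd --input shell.nii.gz --strategy fractalbrain --offsets 20 --seed 42
FD = 1.9140  [2, 32] mm  (1.2 decades, R2_adj = 0.9996)
```

The folded-shell phantom is a thin 2-D sheet, and the estimator reports a
dimension just below 2 over an automatically selected interval of 1.2
decades with an excellent log–log fit — exactly what one expects for a
mildly folded surface at this resolution.

```sh
$ voxelfd phantom cohort --n 150 --seed 7 --out cohort.csv
$ voxelfd agepredict --features cohort.csv --feature-col FD --reps 20 --perms 199 --seed 42
r = -0.897 (p = 2.1e-54); mean MAE = 6.898 y (permutation p = 0.005)
```

The simulated cohort has an FD that declines linearly with age; the
association is strongly negative, and the cross-validated age-prediction
error (6.9 years over a 19–85 year range) beats every one of the 199
permuted-label null models (the permutation p-value 0.005 is the floor
`1/(199+1)` of the add-one estimator).

The same functionality is available as a library:

```python
import voxelfd as v
report = v.estimate_fd(v.generate_menger(4), "fractalbrain", n_offsets=20, seed=1)
print(report.fd, report.mfs_mm, report.Mfs_mm)
```

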