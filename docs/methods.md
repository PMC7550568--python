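# Methods

## Model

A binary volume `I(x,y,z)` with isotropic voxel spacing is treated as a
bounded set whose box-counting (Minkowski–Bouligand) dimension is estimated
from the covering counts `N(s)`: the number of cells of an `s`-voxel cubic
grid that contain at least one foreground voxel. For a statistically
self-similar object, `N(s) = C·s^(−FD)` over a limited interval of scales,
so FD is the absolute slope of the OLS fit of `log10 N(s)` on `log10 s`
restricted to that interval. Base 10 is used on both axes; the estimate is
invariant to the base as long as both axes share it (property-tested).

Assumptions: the mask is binary (nonzero → foreground), voxels are
isotropic (max/min spacing ratio ≤ 1 + 1e-3; strict by default, because an
anisotropic grid silently rescales one axis of the log–log plot), and the
object is non-empty. All internal geometry is in voxel units; physical
units (mm) enter only through the isotropic spacing when reporting
`mfs`/`Mfs`, so a 1 mm-spacing volume has scales 1–256 mm.

## Counting

Scales are dyadic, `s = 2^k` voxels for `k = 0..8` (9 points, uniform on
the log axis). At each scale the count is averaged over `n_offsets = 20`
random integer offsets of the grid origin, drawn uniformly and
independently from `{0,…,s−1}³` per scale. Design notes:

- *Integer offsets.* For binary voxel data a sub-voxel grid shift cannot
  change which voxels share a cell, so integer shifts span the full set of
  distinct grids at scale `s` (there are exactly `s³`), keep the count
  exact, and make the sampled average checkable against the exhaustive mean
  over all offsets (the test suite verifies < 2% deviation at 500 draws).
- *Cell convention.* Voxel `v` maps to cell `floor((v + offset)/s)`; the
  grid conceptually extends past the volume so no voxel is ever lost, and
  `1 ≤ N(s) ≤ #foreground` always holds.
- *Seeding.* One master seed; each scale uses a substream keyed on
  `(seed, s)`, so adding or removing scales never perturbs the draws of the
  others. `n_offsets = 0` selects the single aligned grid — exact,
  deterministic, used by the analytic phantom checks.
- Scales larger than the volume are permitted; their counts saturate near 1
  and the selection stage, not the counter, decides whether they are used.

## Scaling-interval selection

`R²_adj = 1 − (1 − R²)(n − 1)/(n − 2)` is the one-predictor adjustment for
the number of points `n`. When the counts in a window are constant, the
zero-slope line fits with zero residual and the window is scored `R² = 1`
(FD 0); such flat windows are never wider than 3 points on the default
scale set and therefore cannot win either automated strategy.

- `apriori1`: fixed `[4, 256]` mm. Both bounds must be sampled scales. Its
  width is log10(256/4) ≈ 1.8 decades; note that a commonly quoted value
  for this interval is 1.5 decades, which corresponds to `[4, 128]` or any
  other 6-point dyadic window — this package reports the arithmetic truth
  for the bounds actually used.
- `apriori2`: 5% and 40% of the shortest side of the foreground bounding
  box (in mm), each rounded to a power of two, then clipped to the sampled
  scales. "Nearest" rounding is geometric (nearest exponent in log2 space,
  ties up); the alternative "next power up" behaviour is available as
  `rounding="next"` since both conventions appear in the literature.
- `marzi2018`: fit every contiguous window of ≥ 4 points, return the
  highest unrounded `R²_adj`. Exact ties (measure-zero except on synthetic
  exact power laws) keep the first window in enumeration order (by start,
  then end index).
- `fractalbrain`: fit every window of ≥ 5 points, rank by `R²_adj` rounded
  to 3 decimal places (descending), then width in decades (descending),
  then `mfs` (ascending). Rounding uses the tie-away-from-zero rule
  implemented arithmetically as `floor(|x|·10³ + 0.5)`; it differs from
  banker's rounding only on exact `.0005` boundaries. The 3-decimal choice
  follows the view of `R²` as a percentage reported to one decimal place.
  Five dyadic points guarantee `Mfs/mfs ≥ 16`, i.e. ≥ 1.204 decades — the
  smallest dyadic span above one decade, a common minimum for claiming
  fractal behaviour. The final `mfs` tie-break is a determinism guarantee;
  it also matches the empirical preference of automated selection for
  small minimum scales.

Both automated strategies are verified against an independent brute-force
enumerate–fit–rank oracle on 200 random curves.

## Phantoms and what they do (not) show

- Cube and plane: exact power laws on aligned grids; the estimator must
  return 3 and 2 to machine precision (it does, asserted at 1e-9).
- Menger sponge (level `L`, `3^L` side, exactly `20^L` voxels, built by the
  base-3 digit test): on its native triadic scales `{1,3,9,27,81}` the
  counter reproduces `N(3^k) = 20^(4−k)` exactly and the fit returns
  log 20/log 3 to machine precision. On the default *dyadic* scales the
  estimate is systematically low (≈ 2.35 at level 4, ≈ 2.55 at level 5):
  boxes of side `2^k` never align with triadic holes, the `s=1→2` step
  probes sub-hole structure (local slope ≈ 2.1), and mid scales partially
  saturate the 81³ bounding box. This is a property of dyadic sampling of
  a triadic fractal at finite depth, not of the implementation — the
  cross-checks above isolate it. Consequence for practice: box-counting FD
  values are comparable only under a fixed scale-sampling scheme.
- Perturbed shell: thin spherical shell with three seeded sinusoidal
  harmonics modulating the radius — deterministic, scale-spanning
  roughness. It emulates a folded sheet's geometry only; it does not
  emulate cortical topology, thickness variation, or segmentation noise,
  so passing shell tests supports the estimator's geometric behaviour, not
  anatomical validity.
- Cohort simulator: ages uniform on a range (default 19–85 y), feature
  linear in age with Gaussian noise (defaults: slope −0.002/y, intercept
  2.6, sd 0.02 — an FD-like feature declining over the adult lifespan),
  sex Bernoulli(0.5), eTIV Gaussian (1.5 L ± 0.15 L, typical adult values).
  Real cohorts have non-uniform age distributions and heteroscedastic,
  non-linear trends; the simulator establishes correctness of the
  machinery, not realism of effect sizes.

## Age-prediction evaluation

OLS of age on (feature, eTIV, sex), all standardized with the *training*
fold's mean/sd only (no peeking — property-tested by corrupting test rows).
Folds: uniform random shuffle, contiguous split, remainder spread one per
fold. The per-repetition MAE pools all test predictions of that repetition
(equivalent to fold-size-weighted averaging); the reported score is the
mean over repetitions (default 1000; the large-cohort calibration test uses
50 repetitions at n = 2000, where the repetition variance is negligible).
Significance: ages are permuted and one CV score computed per permutation
(default 5000; `perm_reps` exposes repeated CV per permutation for
sensitivity checks, but one score per permutation is the standard,
proportionate choice), and `p = (1 + #{null ≤ observed})/(1 + n_perm)` —
the add-one estimator, never exactly zero, floor 1/5001 < 0.0002 at the
default. Under a null feature the p-values are uniform (KS-tested over 500
seeds).

Degenerate inputs: constant features standardize to zero (sd guarded to 1)
and drop out of the fit; constant vectors are rejected for correlation;
cohorts smaller than twice the fold count are rejected.

## Known limitations

- Dyadic-vs-triadic sampling bias on the Menger phantom (above).
- FD estimates above 3 are possible on degenerate objects with offset
  averaging; values above 3.1 trigger a warning, not an error.
- No surface-based FD, no lobar/regional parcellation, no multi-segment
  scaling-regime detection, and no resampling of anisotropic inputs —
  anisotropy is rejected, not corrected.
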