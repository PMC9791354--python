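# Methods

## Benefit-transfer model

The package values a landscape by unit-value transfer: every mapped
land-cover class is assigned an *equivalent biome* whose per-hectare
coefficient, estimated elsewhere, stands in for local valuation.  With
class areas A_k (ha) and coefficients VC_k (USD · ha⁻¹ · yr⁻¹),

    ESV   = Σ_k A_k · VC_k
    ESV_f = Σ_k A_k · VC_fk          (f = 1 … 17 service functions)

Assumptions inherited from the method, stated so users know what the
numbers mean:

* coefficients are constant over time — no inflation, price or
  productivity adjustment; differences between dates therefore reflect
  area change only;
* value is proportional to area — no spatial heterogeneity within a
  class, no interaction between neighbouring covers;
* the proxy-biome assignment is imperfect by construction (shrubland and
  open forest both borrow the tropical-forest coefficient; built-up land
  borrows the urban biome's coefficient of 0).  The sensitivity module
  exists to quantify the exposure to these choices.

Values are computed and stored in USD · yr⁻¹ at full precision; report
helpers print in 10⁶ USD rounded to two decimals, and percent shares are
computed on unrounded values before rounding.  Zero-coefficient classes
are kept in every report (value 0) so totals and shares span the full
landscape.

## The built-in Guna tables

The shipped legend maps five classes onto four biomes — cropland →
cropland (225.56), forest and shrubland → tropical forest (986.69),
grassland → grass/rangelands (293.25), built-up → urban (0), all in
USD · ha⁻¹ · yr⁻¹.  The per-function table decomposes each biome's total
over 17 functions in four groups.

The published per-function source leaves a few cells' biome ownership
ambiguous.  The shipped file (`data/guna_coefficients.csv`) resolves them
under one hard constraint: **every biome column must sum exactly to its
published total**, because only column-consistent tables keep the
class-based and function-based valuations mutually consistent.  Under
that constraint the tropical-forest and grass/rangelands columns are
fully determined by published cells; the cropland column requires exactly
one unpublished cell of 14.00, assigned to pollination (the classic
global cropland pollination coefficient) and flagged as reconstructed in
the file's comment header.  Consequences, stated plainly: per-function
*changes* between dates are robust (they depend only on unambiguous
cells for the headline functions), while per-function *levels* for
several functions differ from the published ones by a near-constant
≈0.09 × 10⁶ USD in 1995 — the published levels evidently include
coefficient mass that was never printed.  `validate_column_sums` reports
(never enforces) column consistency for user-supplied tables, default
tolerance 0.01 USD · ha⁻¹ · yr⁻¹.

Published change-matrix margins carry the 10-ha granularity of their
cells; comparisons against them use ±10 ha.

## Change accounting

Transition matrices are exact pixel cross-tabulations (nodata at either
date excludes the pixel), so their marginals equal the re-tabulated area
tables to machine precision — a conservation law the tests assert.  Two
annual rates are reported because both circulate in the literature and
they answer different questions: the absolute rate net/years
(ha · yr⁻¹) and the simple percent rate (period percent ÷ years,
% · yr⁻¹).  Compound (geometric) rates are deliberately not implemented;
with 12–13-year gaps between maps the simple rate is what the reference
tables use.  Period lengths are the caller's responsibility (label
arithmetic is not attempted): the Guna periods are 13, 12 and 25 years.

## Sensitivity

CS = (%ΔESV)/(%ΔVC_k) for a single-biome adjustment.  The adjustment
scales the biome's total *and* all its per-function cells by the same
factor, so both valuation routes stay consistent under perturbation.
Linearity makes CS equal to the biome's baseline value share, hence
independent of the adjustment's size and sign; the default sweep still
runs both +50% and −50% to make that property visible in output rather
than asserted in prose.  Urban (coefficient 0) is skipped with a logged
notice: a relative change of a zero coefficient is undefined.

## Accuracy

Orientation is **rows = mapped, columns = reference**; user's accuracy is
row-wise, producer's column-wise.  This is stated prominently because the
transposed convention also circulates; transposing the matrix swaps the
two per-class statistics but leaves overall accuracy and kappa unchanged.
Degenerate inputs: classes never mapped (zero row) or never referenced
(zero column) get missing per-class accuracy rather than 0; kappa is
missing when chance agreement p_e = 1 (all mass in one row×column cell).
No area-weighted (error-adjusted) estimation is attempted — the counts
are treated as a plain sample.

## Spectral indices

One operator, (a − b)/(a + b), over configurable band pairs.  Cells with
a + b = 0 are masked, not clipped: no physical index exists there, and
propagating a sentinel value would poison downstream statistics
silently.

## Synthetic generator

The generator emulates the *statistical* structure of a two-date mapping
study: initial class proportions, a row-stochastic per-pixel Markov
transition matrix, a mapped→reference confusion matrix, and per-class
Gaussian band reflectances (truncated at 0).  Pixels are independent;
an optional 3×3 majority filter (k passes, ties keep the centre pixel)
adds visual patchiness.  It does **not** emulate spatial
autocorrelation, patch-size distributions, or sensor radiometry — so
passing tests demonstrate correct counting, valuation and accuracy
arithmetic on realistically composed data, not robustness to spatially
structured classification error.

Shipped defaults (`data/guna_generator.yaml`) are the study conditions:
the 1995 composition (cropland 0.457, shrubland 0.300, grassland 0.195,
forest 0.042, built-up 0.006), the observed 1995→2020 transition areas
row-normalized into probabilities, a 0.87-diagonal confusion matrix
(the overall-accuracy magnitude reported for maps of this kind, off-
diagonal mass spread uniformly), 30 m pixels, and band means ordering
NDVI as forest > shrubland > grassland > cropland > built-up.
Transition rows in the YAML are given as *weights* (the observed
hectares) and normalized at load, so the file stays exactly consistent
with the published matrix without hand-rounded probabilities.

Sampling design for reference samples: n positions are apportioned to
classes by the largest-remainder rule on pixel counts (class sample
sizes proportional to areas within one sample) and drawn without
replacement within classes.  All randomness flows through
`numpy.random.default_rng(seed)`; a fixed seed reproduces every grid and
sample bit-for-bit.

## Problem sizes and tolerances

Stochastic checks use 1000×1000 landscapes (10⁶ pixels) and 10⁵
reference samples, sizes at which the binomial/multinomial standard
errors (≈0.0005–0.0016 for class fractions, ≈0.001–0.01 for transition
rows, ≈0.1 percentage point for overall accuracy) sit comfortably inside
the asserted bounds of ±0.003, ±0.02 and ±0.5 respectively.  Monetary
comparisons against the published tables use the tables' own printed
precision (0.01 × 10⁶ USD); property tests use 1e-9 relative for
linearity/additivity and 1e-12 for kappa against the brute-force oracle.

## Known limitations

* No reprojection, resampling or vector support; multi-date rasters must
  already share a grid for transition analysis.
* No discounting, currency conversion or uncertainty propagation beyond
  the single-coefficient elasticity; no Monte-Carlo over coefficients.
* No spatially explicit per-pixel value maps — the method is an area
  aggregate by design.
* The published Guna reference tables contain small internal
  inconsistencies (10-ha rounding in the change matrix, unprinted
  per-function coefficient mass); the package computes from its inputs
  at full precision and does not attempt to reconcile a source table
  with itself.
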