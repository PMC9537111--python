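# Methods

## The problem

The MMSE and the MoCA are both 30-point cognitive screens, but they weight
domains differently and their totals are not interchangeable: the MoCA is
harder, so the same patient typically scores several points lower on it,
and in impaired populations the MoCA shows a floor effect.  Pooling or
comparing cohorts assessed with different screens therefore needs a score
crosswalk — an equating function mapping each MMSE total to an equivalent
MoCA total.  Classical equipercentile equating needs large samples;
clinical cohorts are small.  The circle-arc method is a small-sample
observed-score equating technique that determines the whole conversion
from just three anchor points.

## The circle-arc model

Given anchor points — nadir `(x1, y1)`, midpoint `(x2, y2)`, zenith
`(x3, y3)` with `x1 < x2 < x3`, all on the 0–30 score scale — the
conversion decomposes into:

1. **Linear component** (chord through the endpoints):
   `L(x) = y1 + (y3 − y1)/(x3 − x1) · (x − x1)`.
2. **Arc component.** Subtracting `L` sends the endpoints to `(x1, 0)`,
   `(x3, 0)` and the midpoint to `(x2, y2*)` with `y2* = y2 − L(x2)`.
   The unique circle through those three points has closed-form
   parameters

   ```
   xc = (x3² − x1²) / (2(x3 − x1))              # = (x1+x3)/2
   yc = [x1²(x3−x2) − (x2²+y2*²)(x3−x1) + x3²(x2−x1)] / (2·y2*·(x1−x3))
   r  = sqrt((xc − x1)² + yc²)
   ```

3. **Recomposition.** The converted score is
   `ŷ(x) = L(x) + yc + sign(y2*)·sqrt(r² − (x − xc)²)`.
   The branch sign follows the midpoint deviation: the arc bends toward
   the midpoint anchor, the only choice that interpolates it.  With
   collinear anchors (`y2* = 0`) the model degenerates to `L` itself.

The published sources for this method give the decomposition and the
circle parameters but never write the recomposed conversion explicitly;
`ŷ = L + Y*` is adopted here because it interpolates all three anchors
and reproduces the published conversion tables from the published
parameters (see Reproduction below).

**Validity regime.** The three transformed points lie on a single
function branch only for a *minor* arc — center on the opposite side of
the baseline from the midpoint bulge, `sign(yc) ≠ sign(y2*)`,
equivalently `y2*² < (xc−x1)² − (x2−xc)²`.  Score crosswalks deviate
mildly from linearity and sit deep inside this regime (the fitted sags
here are 0.2–2.2 points against radii of 37–264); property tests enforce
the regime bound explicitly because outside it the endpoint anchors fall
on the other branch.  Near collinearity (`|y2*| → 0`) the radius grows
like `(x3−x1)²/(8|y2*|)` and the arc converges pointwise to the chord;
`|y2*| < 1e−12` is treated as exactly collinear.

## Conversion tables

Clinicians use an integer lookup table over source scores 0..30.  Each
integer `s` is converted with the arc formula when `s` lies in the arc's
x-domain `[xc − r, xc + r]` — including beyond the zenith, where the
published tables keep following the arc — and with the chord `L(s)`
otherwise; the result is rounded half-away-from-zero and clamped to
[0, 30].  Rounding half-away-from-zero (not banker's rounding) matches
the published tables at every checkable cell.

## Anchor selection

How the anchors were chosen from data is not standardized.  Automatic
extraction here uses: midpoint = the rounded sample means of the two
scales; nadir/zenith x = the minimum/maximum observed source score;
nadir/zenith y = the rounded median target score among records sharing
that extreme source score (a deterministic tie rule — the extreme source
score is often attained by several patients).  Explicit mode accepts an
externally published anchor set verbatim, which is how the published
parameter sets are reproduced exactly.  Medians are used at the extremes
because a single aberrant companion should not relocate an anchor;
nevertheless extreme-score anchors remain the dominant noise source in
refits (see Parameter recovery).

## Study pipeline

`run_equating_study` mirrors the standard conversion/validation design:

1. Stratify by education years (cut points 6 and 9: low ≤6, medium 7–9,
   high ≥10) and split A/B at random within strata.  The split shuffles
   with a seeded generator and alternates A, B, … with parity carried
   across strata, so group sizes differ by at most one within every
   stratum and overall.
2. Independently for the total group and each stratum: extract anchors
   from group A, fit, tabulate 0..30.
3. Consistency: Spearman and Pearson correlation of the two scales in
   group A, and of observed vs. table-converted target scores in group B.
   Both coefficients are always reported; Spearman is primary for
   bounded integer scores with floors, Pearson secondary.
4. Baseline comparability of A vs B per block: chi-square (2×2, no Yates
   correction by default) for sex; for age and the two scales, a t-test
   when both groups pass Shapiro–Wilk at α = 0.05, otherwise
   Mann–Whitney U (exact p for combined n ≤ 20 without ties, normal
   approximation with continuity correction otherwise).  The rule applied
   is recorded in each output row.

Per-block failures (e.g. a stratum with fewer than three distinct source
scores) are recorded with a status and do not abort the run.  Every run
writes `anchors.csv`, `model_params.csv`, per-block conversion tables,
`consistency.csv`, `group_comparison.csv` and a `run_log.txt` with the
seed, parameters and SHA-256 of each artifact, so a result is auditable
and byte-reproducible from (config, seed).

## Synthetic cohorts

No patient-level MMSE/MoCA dataset of this design is publicly deposited,
so the pipeline is exercised on synthetic cohorts.

* **Bivariate mode** (`generate_cohort`): per education stratum, latent
  scores are bivariate normal with stratum-specific means/SDs and a
  shared correlation ρ, then rounded half-away-from-zero and clamped to
  [0, 30].  Defaults emulate a memory-clinic dementia cohort: n = 322,
  ρ = 0.9, stratum mix 66:48:84 (low:medium:high), score moments per
  stratum of (MMSE mean ± SD / MoCA mean ± SD) low 11.42 ± 7.08 /
  6.82 ± 5.37, medium 15.54 ± 6.91 / 8.54 ± 4.92, high 15.48 ± 6.67 /
  9.62 ± 5.49; education uniform within the stratum band (0–6, 7–9,
  10–16 years), age normal(69.7, 11.1) clamped to [40, 95], 42% male.
  Setting the MoCA means below the MMSE means makes clamping at 0
  produce the MoCA floor effect.  Rounding+clamping a latent Gaussian is
  the simplest mechanism consistent with the available information
  (means, SDs, ranges, correlation level); no higher moments are
  targeted.
* **Model-driven mode** (`generate_from_model`): source scores are
  sampled (default: discretized normal at the total-group moments
  12.11/6.82, clamped), target = conversion of source + N(0, noise_sd),
  rounded and clamped; default noise_sd = 2 score points.  This provides
  known-truth inputs for round-trip and recovery tests.

A root seed spawns independent substreams (stratum assignment, scores,
education, age, sex), so adding a field never perturbs other draws and
cohorts are byte-identical across re-runs.

**What the generator does not emulate:** item-level subscores, the true
empirical joint distribution beyond first moments and rank correlation,
education-dependent test bias, and any non-Gaussian skew.  Passing tests
demonstrate the machinery is correct under these idealized conditions,
not that a particular clinical cohort satisfies them.

## Reproduction and known limitations

* From the published anchor sets, the closed forms reproduce the
  published circle parameters exactly at printed precision for the total
  group (15, 34.75, 37.09895), the high stratum (14.5, 46.13, 47.79476)
  and the low stratum (14, −263.91, 264.1382), and the integer tables
  reproduce 91 of the 93 published total/high/low cells.  The two
  deviating cells (high column at source 1: computed 0.52 → 1 vs
  printed 0; low column at source 13: computed 7.59 → 8 vs printed 7)
  cannot be produced by the stated formulas with the stated parameters
  under any nearest-integer rounding and are treated as typographical.
* The medium-education anchor set is internally inconsistent as
  published: its printed center abscissa (14) contradicts the xc formula
  applied to its printed anchors ((2+23)/2 = 12.5), and its printed
  table does not return the zenith value at the zenith.  The medium
  block is therefore fitted from its printed anchors like any other
  input but is not a reproduction target.
* Parameter recovery from noisy data is limited by the extreme-score
  anchors: at n = 161 and noise SD 2 the median (over 50 seeds) worst-
  score deviation of a refit table is ≤ 2 points, but roughly one seed
  in five exceeds ±2 somewhere, almost always because the zenith's
  target value rests on one or two patients.  Larger samples at the
  extremes, or explicit anchors, remove this failure mode.
* No standard error or confidence band accompanies the equating
  function, and no equipercentile/kernel alternatives are provided; the
  linear conversion appears only as the degenerate collinear case.
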