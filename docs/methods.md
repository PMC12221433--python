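# Methods

## The statistic

`ordimirror` summarizes one individual's composite set of ordinal
assessment scores — e.g. the answers `[2, 3, 3, 3, 3, 3, 3, 3, 3, 4]` to
ten 5-point Likert items — by its *statistical proximity to the highest
positive scale point*, rather than by the sum, mean or median of the raw
codes.

The scores are first put on **whole-number encoding**: an n-point scale
with common interval k admits `{0, k, ..., (n_s−1)k}`, so the most
negative category is exactly 0 and the most positive is
`p = (n_s−1)k`.  Natural-number input (`{k, ..., n_s·k}`, the usual
1..5 coding with k = 1) is shifted down by one interval.  The interval is
derived from the declared scale: `k = max_scale / point_scale` for
natural encoding and `k = max_scale / (point_scale − 1)` for whole
encoding.  The whole-number derivation is this package's documented
convention — the upstream interface examples only exercise natural-number
input.

The n whole-encoded scores, sorted ascending, are paired *isoreflectively*
with a **statistical mirror** — n copies of the top scale point p — about
a central element δ = 0:

```
d = (x(1), ..., x(n), 0, p, ..., p)        length 2n + 1
R = (1, 2, ..., 2n+1),  r_c = n + 1        the "optiscale"
```

Sorting ascending with the mirror on the high-index side realizes
head-to-head pairing: the lowest response sits maximally distant from the
mirror's far end.  The **Kabirian coefficient of positive ordinal
assessment** is the ratio of the center-weighted to the position-weighted
mass of this construct,

```
KC1 = r_c · Σ d_i / Σ R_i d_i
    = (n+1)(s + np) / (Σ i·x(i) + 3pn(n+1)/2),   s = Σ x_i ,
```

which lies in [2/3, 1] for data in [0, p]: 1 iff every response is at the
top of the scale, 2/3 iff every response is at the bottom.  The
bi-coefficient of the inverse operation is KC2 = 1/KC1.  KC1 is translated
to a probability of positive assessment by

```
PSprox = ((2n+1)·KC1 − (n+1)) / ((n+1) − KC1),    PSdev = 1 − PSprox.
```

PSprox is monotone increasing in KC1, equals 1 at KC1 = 1 and
(n−1)/(3n+1) at KC1 = 2/3.  Because both numerator and denominator of KC1
are homogeneous of degree 1 in (x, p), all three statistics are invariant
to a common rescaling of the data and the scale top — the source of the
scale-robustness property — and they depend on the data only through the
sorted multiset, hence are permutation-invariant and strictly increasing
in every single response.

The displayed equations in the source material are typographically
unrecoverable; the formulas above are a reconstruction that is
regression-locked against every legible printed worked-example value
(30 five-point response sets and 11 rescaled seven-point sets:
coefficients to 6 decimal places, probabilities to 4).  The test suite
treats those tables as ground truth, and `ordimirror reproduce` recomputes
them cell by cell.

### Known divergences in the locked tables

* The printed *median* column of the two 15-item blocks equals the printed
  mean (2.40 and 3.33) rather than the sample median of the rows (2, and
  3 or 4).  The package computes the median by the standard order-statistic
  rule; those cells are reported as known divergences, not locked.
* As a consequence, the printed "0 % sensitivity" for the median in the
  third block does not hold under the correct median: the true medians of
  that block alternate between 3 and 4, giving ≈ 29.2 % relative entropy.
  One acceptance case asserts the published claim and is expected to fail;
  it is retained deliberately rather than reproducing the defect.

### Alternative coefficients

The upstream interface names three additional outputs (`kcalt1`,
`kcalt2`, `kcalt`) without defining them.  This package's provisional
definitions — kcalt1 = KC1 itself, kcalt2 = the coefficient whose
translation equals PSdev (the closed-form inverse
`(n+1)(1+PSdev)/((2n+1)+PSdev)`), kcalt = 1/KC1 — are emitted only on
request and tagged `"provisional semantics"` in the result metadata.

## Generalized mirroring and SAMD

`mirroring_engine.stat_mirroring` exposes the construct with configurable
centering (`never`, absolute deviations `bymeanR+`, signed deviations
`bymeanR±`), principal mirror value (`mean`, `max`, or a custom number),
ordering and pairing.  SM-based ordinalysis is exactly the
`{p, never, ascend, H_H}` specialization, verified bit-for-bit on the
locked tables.

The **statistical absolute meanic deviation** (SAMD) used as the
efficiency criterion is the probability of deviation of the construct
that mirrors `a_i = |x_i − mean(x)|` against `q = mean(a)`.  Its cited
construct is not restated by the source; this definition is a documented
reconstruction chosen to match the name, to reuse the verified
coefficient/translation machinery, and to satisfy the stated contract:
`samd(c·x + b) = samd(x)` for any c ≠ 0 and any b ("scaloc" invariance,
held to 1e-12 in tests), with samd = 0 iff x is constant.  With the
mirror equal to the mean of the mirrored values, the Chebyshev sum
inequality gives KC ≤ 1, and KC ≥ 2(n+1)/(2.5n+1.5) > 2/3, so the
standard translation branch always applies even though individual
deviations may exceed the mirror value (the engine therefore skips the
ordinalysis-specific [0, p] bound).  Signed centering (`bymeanR±`)
usually produces a zero mirror (mean of signed deviations) or an
out-of-model coefficient; the engine rejects both diagnosably, which is
why SAMD uses the absolute variant.  A fully degenerate 0/0 construct
(constant data) is defined as zero deviation.  Without the upstream raw
food-sensory data the reconstruction cannot be checked against the
published bracketed SAMD percentages; this is the main open limitation.

## Synthetic data generators

Three families emulate the validation study's response structures; their
defaults are the study conditions, not tuning knobs.

* **Categorical** — i.i.d. 5-category draws with 30 preset probability
  vectors: a dominant category of mass 1.00, 0.92, 0.84, 0.76, 0.68 or
  0.60 swept across the five positions, the remainder spread evenly.
  (One preset family is labeled upstream with intensity "0.78" but prints
  0.76 vectors; the printed vectors are used.)
* **Rounded normal** — Gaussian(μ, σ) rounded half-away-from-zero and
  clipped to {1..5}.  The rounding convention is documented here because
  the source says only "rounded to fit"; half-away-from-zero keeps the
  cut points at half-integers.
* **Gaussian copula ordinal** — latent equicorrelated standard normals
  mapped through Φ and binned by cumulative cut points.  Five base
  marginal presets (3 cuts → 4 categories, kept as published even where
  that diverges from the 5-point scale used elsewhere) and six base 2×2
  correlation templates; the marginal list is expanded cyclically to d
  items and the correlation as the d×d equicorrelation matrix.  An
  expansion with ρ < −1/(d−1) is not positive semidefinite and raises,
  with an explicit opt-in that shrinks ρ just inside the bound — the
  negative template therefore cannot be used beyond d = 2 without it.

What these generators do **not** emulate: respondent-level heterogeneity,
item-specific difficulty, missingness, or polarity errors.  Passing tests
show that the statistic behaves as designed under clean i.i.d. and
equicorrelated response processes, not that it is robust to messy survey
data.

## Evaluation metrics

Per design cell, each estimator (classical sum/average/median of the raw
natural scores; KCSprox/PSprox/PSdev of the whole-encoded scores) is
applied to every simulated dataset, and the estimate series is summarized
by its mean, median, Shannon entropy in bits and percent relative entropy
(entropy / log2(n) × 100, the sensitivity score; distinctness is judged
after rounding to 9 decimals because exact float equality is meaningless),
and SAMD as the efficiency criterion.  Relative efficiency is
RE = Eff(reference)/Eff(proposed), so RE > 1 favors the proposed
estimator; a 0/0 cell (both series constant) is reported as RE = 1 with a
degenerate flag, and 0 in the denominator alone as +inf with a warning.
SAMD's scaloc-invariance is what makes efficiencies comparable across
estimators of different magnitudes.

## Problem sizes and numerical choices

* The benchmark grids reconstruct the study layout — normal:
  N ∈ {5,10,15,20,25} × μ ∈ {1..5} × σ ∈ {0.5,...,2.5} (125 cells);
  categorical: 5 N-values × 30 probability vectors (150 cells) — at
  20 iterations per cell, this package's scaled-down condition for the
  relative-efficiency replication (the study's full runs used three
  orders of magnitude more datasets; the claim checked here is the
  qualitative one, median RE ≈ 1).
* Construct sums are accumulated term by term in Python scalars, so
  integer inputs stay exact and the 6-decimal table lock is free of float
  drift; scale membership is tested to 1e-9 relative tolerance to admit
  decimal ladders such as a 0.01-step scale.
* Coefficients slightly outside [2/3, 1] from float arithmetic
  (≤ 1e-9) are clamped before translation; anything farther out raises an
  out-of-model error.
* Reported rounding follows the published convention (coefficients
  6 d.p., probabilities 4 d.p.); full precision is retained internally
  and available via `--precision full`.
* Per-cell simulation seeds are `base_seed + cell index` over a fixed
  Cartesian ordering, making every grid byte-reproducible.

## Limitations

* The SAMD construct is a reconstruction (above) pending the upstream
  definition or raw data to adjudicate it.
* The alternative-coefficient semantics are provisional.
* Probability translation is only defined on the proximity branch
  [2/3, 1]; general mirroring configurations that leave it are rejected
  rather than extended.
* The statistic requires a declared finite scale top and homogeneous
  scores; heterogeneous instruments must be aligned or reverse-coded
  first (`AlignmentMap`, `reverse_code`).
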