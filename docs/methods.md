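# Methods

## Model and assumptions

The estimator treats a bulk tumor transcriptome as a mixture whose
immune component leaves a rank fingerprint: genes specifically expressed
by an infiltrating cell type rise in the within-sample ordering relative
to a cancer-cell baseline, and the amount they rise is monotone in the
cell type's fraction. Everything downstream of the raw matrices uses
only strict within-sample ordering comparisons, so the method assumes
nothing about the measurement scale beyond monotonicity — microarray
intensities, FPKM and counts are all acceptable, and any per-sample
monotone normalization is a no-op by construction. Ties (exact equality
of two genes' values) are treated as evidence for neither ordering,
everywhere.

Three reference resources are required per cancer type: cancer-cell
profiles (the ordering background), per-cell-type immune profiles (for
signature derivation and calibration), and normal-tissue "control"
profiles (the non-cancer, non-immune compartment of the calibration
mixtures). Gene identifiers are opaque strings; callers must supply
consistent identifiers across all inputs.

## Pipeline stages and key parameters

**Stable pairs** (`pairs.find_stable_pairs`). A directed pair
(greater, lesser) qualifies when the strict ordering holds in at least
`threshold` (default 0.99) of the reference samples; the qualifying test
is `count >= ceil(threshold * n)` on integers, so floating-point edge
cases cannot flip a pair. The search universe defaults to
candidate-marker × all-genes (the only pairs downstream scoring ever
consults), with `all_pairs=True` available for fidelity checks.
Thresholds at or below 0.5 are rejected because both directions could
then qualify.

**Individual up-calls** (`signatures.call_updegs`). Per sample and
candidate gene, the 2×2 table (background above/below counts vs sample
above/below counts over the same partners) is tested one-sided by
Fisher's exact test, implemented as the upper hypergeometric tail; BH
adjustment is per sample across its candidates (`individual_fdr`
default 0.05). A directional gate requires the sample's
above-fraction to exceed the background's — "upregulated" is a
directional claim and the 2×2 test alone is not. The one-pass test is
the default; `max_rounds > 1` enables an iterative refinement that
excludes already-up partner genes from the null background and re-tests
until a fixed point (capped at the supplied round budget). Partners
absent from the query matrix are excluded from both background and
sample counts, since their orderings cannot be evaluated.

**Population filter** (`signatures.build_signatures`). A gene up in k of
n samples of a cell type is retained when the upper binomial tail
P(X ≥ k), X ~ Bin(n, P0), survives BH within the cell type at
`population_fdr` (default 0.05); `P0 = 0.5` is the chance probability of
an up call in one sample. Genes retained for two or more cell types are
then deleted from all of them, which makes the final signature lists
pairwise disjoint and reduces coupling between closely related types
(CD4+/CD8+ T cells being the canonical offenders).

**UpScore** (`scoring`). Counts are pooled over all stable pairs
touching any signature gene of one cell type; a pair joining two
signature genes contributes once per endpoint, with direction taken
relative to that endpoint, identically in background and sample. The
score is −log10 of the one-sided Fisher p, floored at 1e-300 so scores
are finite (cap 300). A two-sided variant exists for sensitivity
analysis only and is never used in the default path.

**Calibration** (`calibration`). The spike-in grid runs X from 0.008 to
0.256 in steps of 0.008 (32 points) — the range where the cell types of
interest actually live in tumors. Mixtures are formed on the linear
scale from median profiles: 0.60·cancer + X·immune + (0.40−X)·control.
Because linear-scale mixing is sensitive to gross platform-scale
differences, each reference cohort is first rescaled by a single
constant bringing its global median to the median of the cohorts'
global medians; this touches no within-sample ordering. Callers with
properly batch-corrected references can pass `harmonize=False`.

The transform F = V1·(S − S_min)^V2 is fitted with S_min the grid's
minimal UpScore. Grid points whose shifted score is exactly zero anchor
the shift but carry no shape information (0^V2 ≡ 0) and are excluded
from the fit; the lowest spike-in is such a point by construction — it
barely produces reversal significance, which is precisely why it defines
the origin. The loss is ordinary least squares in linear F-space,
initialized from the OLS line of log F on log(S − S_min) (which is the
exact solution on noiseless data); V1, V2 are constrained positive.
Fewer than four usable points or a flat grid raise a calibration error
rather than returning a degenerate transform.

Applying the transform clamps scores below S_min to 0 (flagged
`below_calibration_range`); estimates above the top grid fraction are
extrapolations and flagged `above_calibration_range`. Estimates are not
renormalized to a simplex: they are calibrated reversal significances,
comparable across cell types and samples, not a composition vector.

## Synthetic data: what it emulates and what it does not

`synthetic` stands in for the reference compendia and the single-cell
benchmark. The expression model is multiplicative log-normal: a shared
per-gene baseline `exp(N(baseline_log_mean=2.0, baseline_log_sd=1.0))`,
a `marker_fold` (default 6) multiplier on each cell type's planted
markers in that type only, and per-sample noise `exp(N(0, noise_sd))`
with `noise_sd = 0.2`. Defaults: 2,000 genes, 8 cell types, 40 markers
per type, 30 samples per reference cohort. These effect sizes are in the
range of well-measured lineage markers (several-fold specific
overexpression, ~20% multiplicative measurement noise); baselines
spanning ~2 orders of magnitude mimic the dynamic range of
microarray/FPKM data.

Bulk mixtures follow the infiltration scenario the estimator targets:
100 samples of 1,000 cells, cancer fraction uniform on [0.5, 0.99], the
remainder split across immune types by a uniform (symmetric Dirichlet)
simplex draw, fractions converted to integer counts by
largest-remainder rounding (counts always sum exactly to the cell
budget), and cells drawn from the pool with replacement whenever a pool
is smaller than its demand. All randomness flows from explicit seeds;
identical configurations are bit-reproducible.

The generator does *not* emulate: correlated marker programs shared
between related cell types (real CD4/CD8 signatures overlap far more
than disjoint planted markers), cancer-cell heterogeneity between cell
lines, platform artifacts (probe saturation, single-cell dropout), or
compositional distortions of library size. Passing tests therefore
demonstrate correctness of the machinery and recoverability under
realistic noise — not that the accuracy numbers transfer to real
tumors, where signature quality is the binding constraint.

## Numerical choices

- Fisher one-sided p-values are upper hypergeometric tails via scipy's
  `hypergeom.sf`, which agrees with exact rational enumeration to
  ~1e-15 relative error even for p ~ 1e-59; the test suite enforces
  1e-10 on tables with margins up to 200.
- The binomial tail uses `binom.sf`; BH uses statsmodels.
- Stable-pair qualification and mixture cell counts are integer
  arithmetic; fractions reported as n/total may differ from an exact
  simplex sum by one ulp.
- Ties break toward "no evidence" at every stage (neither pair
  direction, neither contingency cell); AUC ties count one half;
  samples exactly at the median-truth cutoff are negatives.
- Degenerate inputs fail loudly: empty matrices, all-zero contingency
  tables, flat calibration grids, one-class AUC labels, missing
  transform parameters.

## Design choices where the design was open

- The UpScore's scale is −log10 of the one-sided p: the calibration fit
  needs a non-negative score growing with infiltration, and the log
  scale makes "shift by the minimum" meaningful.
- Pseudo-bulk aggregation sums barcode columns (any per-donor constant
  is invisible to rank scoring).
- The power fit's loss is linear-space least squares; the log-log OLS
  used for initialization is available as a fit in its own right by
  taking the initial values (noiseless data makes them identical).
- The correlation-deviation summary uses the RMS form
  sqrt(mean((1 − r)²)); a no-root variant is exposed for comparison.
- Problem sizes in tests and the acceptance script match the generator
  defaults above (the full pipeline runs in seconds at that scale).

## Known limitations

- Signature quality is inherited from the candidate marker lists; no
  de-novo marker discovery is attempted.
- Estimates are not a composition: they need not sum to one and can
  exceed the calibrated range (flagged, not clipped).
- The low end of the calibration grid saturates — spike-ins below ~1–4%
  (fixture-dependent) may produce no ordering reversals at all, and all
  such samples map to an estimate of exactly 0.
- Median-profile calibration ignores within-cohort heterogeneity; the
  grid is deterministic given the references.
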