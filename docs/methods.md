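# Methods

## Model and conventions

Counts are negative binomial, `Var(y) = mu + phi * mu^2`, with a common
dispersion `phi` shared across features (a per-feature estimate shrunk
toward the common value by a weighted-likelihood prior equivalent to 10
residual degrees of freedom is available but not used by the default
pipeline). All abundance statements use

    CPM(f, s) = count(f, s) * 1e6 / effective_library_size(s)

with no prior count; log-CPM is `log2(CPM + 0.5)`. The 0.5 prior on the CPM
scale keeps log fold changes finite at zero counts while leaving column sums
of plain CPM exactly 1e6. Fold changes between groups are computed from
prior-moderated group-mean CPM, so they are defined for every feature.

Filtering (CPM > 4, strictly, in at least 3 samples) runs on library-size
CPM *before* normalization; TMM factors are then computed on the retained
features only. The threshold comparison is strict because the rule is
"greater than four"; the filter is idempotent, and samples emptied by a
previous filtering round contribute no CPM evidence rather than dividing by
zero.

### TMM

The reference sample is the one whose 75th-percentile count fraction is
closest to the mean of those quantiles (ties: first in input order). For
each other sample, M-values (log2 ratio of count fractions vs the
reference) and A-values (mean log2 abundance) are formed over features
nonzero in both; the M-values are trimmed 30% on each side by M-rank and 5%
by A-rank (ranks average ties), and the surviving M-values are averaged with
inverse delta-method-variance weights `(N-y)/(Ny)` summed over the two
samples. `2^` of that mean is the factor; factors are rescaled to geometric
mean 1 so effective library sizes are comparable across runs. A sample
sharing no nonzero feature with the reference is an error. This is the
standard published TMM recipe; agreement with edgeR's implementation to
1e-10 (factors) is asserted in the test suite.

## Exact test

Because the conditional construction requires exchangeable totals, counts
are first scaled linearly to the geometric mean of the effective library
sizes and rounded half-to-even ("pseudo-counts"). For a feature with group
sums `(s_A, s_B)` and total `t = s_A + s_B`, the null conditional law of
`s_A` given `t` is beta-binomial with shape parameters `n_A/phi` and
`n_B/phi` — the distribution of an NB split given its total — degenerating
to `Binomial(t, n_A/(n_A+n_B))` as `phi -> 0`. The two-sided p-value is the
total probability of all splits no more probable than the observed one
(minimum-likelihood rule, with a relative tie tolerance of 1e-12 so exact
mirror splits are always included). This rule, rather than tail doubling,
makes p exactly 1 at the conditional mode and monotone in the distance from
it.

The enumeration over all `t + 1` splits is evaluated with a one-step
probability-ratio recurrence accumulated by a segmented cumulative sum (one
logarithm per split instead of four log-gamma calls), normalized per feature
after subtracting the per-feature maximum. Features are processed in chunks
of at most 2e6 enumerated splits to bound memory. Accumulated rounding in
the cumulative sum stays orders of magnitude below the tie tolerance at the
totals the pipeline encounters; agreement with full scipy-based enumeration
is at machine precision in the tests, and with edgeR's
`exactTest(rejection.region="smallp")` to 5e-15 on an equal-library fixture.
A feature with zero total is defined, not an error: p = 1, log2FC = 0.

## Dispersion estimation

The common `phi` maximizes the conditional NB log-likelihood of the
within-group replicate splits (all groups with ≥ 2 replicates, on
pseudo-counts; conditioning on each group total removes the mean
parameters). The likelihood is scanned on a 30-point log-spaced grid over
[1e-6, 10] and the best interior point refined by golden-section search in
log10-space; a boundary optimum returns the boundary value, which is how
Poisson-like data yield estimates below 0.01.

## Trend modules

A log2FC maps to `up` if above 0.33, `down` if below −0.33, else `same` —
boundaries inclusive into `same` because the gate is written as a strict
inequality on the fold change. The first axis is 3 h vs untreated; the
second axis is 8 h **vs 3 h** (the previous time point), which makes
`up-down` the transient early wave and `same-up` the delayed response. The
same 0.33 threshold serves both axes, and labels use the moderated log2FCs
from the DE stage, not raw count ratios, for consistency with DEM calling.
The nominal "33%" bound and the log2 threshold differ slightly
(2^0.33 ≈ 1.26); the log2 form is the operational definition used
throughout.

## Temporal DEMs

T-DEMs come from the direct 8 h-vs-3 h exact test restricted to activated
samples (untreated excluded), BH-adjusted across tested features, gated at
`q ≤ 0.05` and `|log2FC| > 0.33`. Phase is determined by the sign alone:
negative log2FC (higher at 3 h) = `early`, positive = `late`. No additional
requirement that a T-DEM also be a DEM versus untreated is imposed; callers
can intersect with the 3 h / 8 h contrasts if they want that stricter set.

## Target integration

A gene becomes a record when it is significant in the mRNA table
(FDR ≤ 0.05), substantially changed between the time points, expressed at
≥ 10 CPM, and has ≥ 1 validated pairing to a T-DEM. The temporal-change
gate is `|log2FC| ≥ 1` — inclusive at the boundary, because reported fold
changes are rounded (a gene printed at exactly 2.00-fold must not fall out
of its own table). Pairs referencing genes absent from the DEG table are
skipped with a warning. One record aggregates all partners of a gene; the
abundant flag marks any partner miRNA above 200 average CPM. The bipartite
network reports per-node degrees and the maximum-degree miRNA(s) as hub.
Overrepresentation uses the one-sided hypergeometric upper tail
`P[X ≥ k]` with BH across sets; the universe defaults to the DEG table's
gene list and is a parameter.

The packaged reference table (21 genes, 23 pairs) carries printed
statistics; the per-miRNA CPMs behind its abundant flags are known only for
miR-7a-5p (16738) and miR-146a-5p (11147) — the others are nominal synthetic
stand-ins consistent with the flags and are used for nothing else.

## Synthetic data

The generator emulates the structure the analysis assumes:

- **Baseline abundances** — log-normal on the log10 scale (sd 1.3, a
  five-decade spread), renormalized to sum to 1e6 CPM (a CPM profile is
  compositional), with any single feature capped at 16.2% of the library
  (real small-RNA libraries are dominated by a few mature miRNAs, but the
  top one holds only ~16% of reads).
- **Counts** — gamma-Poisson draws at `mu = lib_size * CPM * 2^effect /
  1e6`; library sizes log-normal around 5e6 reads (typical small-RNA depth)
  with CV 0.1; biological triplicates per group by default.
- **Effects** — each of the nine modules receives a rounded fraction of
  features (defaults echo the observed occupancies: ~57% unchanged, ~18% up
  at 3 h mostly as a transient wave, 14% delayed, 11% down); the sign
  pattern of a module is applied with a single magnitude `effect_log2fc`
  (default 1.0) multiplicatively on the mean, never by resampling, so the
  stored ground truth is exact. `spike_min_cpm` restricts spiked modules to
  features above a baseline abundance, as the recovery studies require.
- **Drug arm** — optional activated+drug groups at 3 h and 8 h sharing the
  activation effects plus per-feature deltas, by default four miRNAs
  upregulated 1.27–1.93-fold at 8 h only.
- **Companion tables** — an mRNA DEG table (7970 genes, 2% with substantial
  temporal change, one Tnf-like gene at 5250.7 average CPM) and a validated
  pair table in which every spiked temporal miRNA receives ≥ 1 target and a
  designated hub receives 11.

What it does **not** emulate: isomiRs and arm-switching, compositional
competition between miRNAs during library preparation, ligation or
GC biases, correlated (feature-specific) dispersions, batch structure, or
exosomal compartments. Passing tests therefore demonstrate correctness of
the statistics under a clean NB world, not robustness to those artifacts.

## Calibration studies and what they show

Five studies (in `mirtempo.studies`) fix their conditions once and are run
identically by the test suite and `scripts/acceptance.py`: a global-null
error-control study (2000 features, 3 vs 3, dispersion 0.1, 20 seeds), a
power study (2000 features, 20% of features spiked ±1 log2 unit at baseline
≥ 100 CPM, 10 seeds), nine-module recovery and temporal recovery studies
(372 features, effect 1.0 at ≥ 100 CPM, dispersion 0.1, 10 seeds; the
temporal study spikes 10 late and 5 early effects), and a
dispersion-recovery study (2000 features).

At dispersion 0.1 with triplicates, the error-control side is excellent
(null q ≤ 0.05 fraction ~4e-5; observed false-discovery proportion ~0.03)
and the dispersion estimate is essentially unbiased. Detection, however, is
overdispersion-limited: the standard deviation of an estimated log2FC is
roughly `sqrt(2*phi/n)/ln 2 ≈ 0.38`, independent of abundance, so the
exact-test z-statistic for a 2-fold change saturates near 2.6. The studies
measure the consequences directly: DEM sensitivity after BH ~0.49, spiked
nine-module accuracy ~0.70 (a null axis stays inside the ±0.33 band only
~62% of the time), and ~2.5 of 15 spiked temporal effects recovered. High
recovery targets (≥ 0.8 sensitivity, ≥ 90% module accuracy, ≥ 12/15
T-DEMs) are attainable only at dispersions around 0.02 or below — the
regime of very reproducible culture triplicates — as the README's demo run
(dispersion 0.02, all 15 temporal spikes recovered with correct phase)
illustrates. The demo configuration is deliberately low-noise so the
showcase visibly recovers its own ground truth; the studies keep dispersion
at 0.1.

## Numerical and design choices

- Pseudo-count rounding is half-to-even; fixed for determinism.
- FDR gates are inclusive (`q ≤ 0.05`), fold-change trend gates strict
  (`|log2FC| > 0.33`), the integration temporal gate inclusive
  (`|log2FC| ≥ 1`); each boundary choice is stated at its definition above.
- The exact-test tie tolerance is relative (1e-12); enumeration chunk size
  2e6 splits.
- PCA QC centers `log2(CPM + 0.5)` per feature and decomposes samples by
  SVD; variance fractions are reported non-increasing.
- Study seeds derive as `base_seed * 1000 + i (mod 2^31 - 1)`.
- The pipeline's contrast set is fixed: 3 h vs untreated, 8 h vs untreated,
  8 h vs 3 h, plus the same three for the drug arm when present.

## Known limitations

- The exact test assumes a common dispersion; strong feature-specific
  overdispersion will inflate calls on those features (the tagwise
  estimator exists but is not wired into the default pipeline).
- The conditional construction needs near-equal effective libraries;
  extreme depth imbalance makes pseudo-count rounding a larger relative
  perturbation for low-count features.
- Trend classification is a hard threshold on a noisy estimate; near the
  ±0.33 boundary, assignments are unstable by construction (no fuzzy or
  significance-gated variant is provided).
- Enrichment treats gene sets as unordered memberships; no topology or
  abundance weighting.
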