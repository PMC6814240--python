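# Methods

This note records the models behind each module, the defaults and why,
and the choices made where the underlying protocol leaves the numerics
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Noise statistic

Noise is the Fano factor of the log-transformed fluorescence readout,
`F = 100 · Var(log₁₀ x) / Mean(log₁₀ x)` in percent. Pinned choices the
protocol leaves open:

- **Log base**: log₁₀. Any fixed base works, but the base rescales the
  mean linearly and the variance quadratically, so it must be pinned for
  Fano values to be comparable across analyses.
- **Variance denominator**: the sample (n−1) variance. Above the
  recommended 5,000 cells the difference from the population variance is
  negligible, but the estimator must be fixed.
- **Non-positive signals** are dropped before the log transform and
  counted in the estimate (`n_dropped_nonpositive`); these are
  cytometer baseline artifacts for which the log is undefined.
- A population below `min_cells = 5000` triggers a warning, not an
  error; a non-positive mean of the log signal marks the estimate
  invalid rather than returning a negative Fano.

Replicate-level comparisons use the one-sided Wilcoxon rank-sum test:
exact enumeration when both groups have ≤ 12 tie-free replicates,
otherwise the normal approximation with mid-rank tie correction
(delegated to `scipy.stats.mannwhitneyu`; the test suite checks the
exact branch against full enumeration).

## Gate hierarchy

Gates operate on a boolean mask over the original event table and
compose by intersection, so each stage's retained set is a subset of the
previous stage's.

- **Trigger threshold** (default FSC ≥ 2,570): strict exclusion below
  the threshold; an event at exactly the threshold is retained.
- **Constant band** ("relatively constant pulse width / FSC-W along
  FSC"): no numeric rule exists for this phrase, so it is
  operationalized as quantile-binning on FSC (default 32 bins) and
  retaining events within k = 3.0 median absolute deviations of the bin
  median. Per-bin medians/MADs are reported for audit. Fewer events
  than bins falls back to a single bin with a warning. k and the bin
  count are configurable.
- **Percentile box** (5–95% on FSC and SSC): percentile rank uses
  mid-ranks for ties, bounds inclusive.
- **Density contour** (60% of the second-gated population): density is
  a fixed 64×64 histogram whose axes span the 0.1–99.9 percentile range
  of each channel (outliers clipped into edge bins); events are ranked
  by their bin count and exactly `round(keep_frac · n)` are retained,
  ties broken by bin count then original event index. A histogram
  rather than a KDE keeps the gate deterministic and O(n). The
  tie-break makes the retained count an exact contract.
- **Tail selection** (top/bottom 5% for sorting): exactly
  `round(frac · n)` events, ties broken by event index. The fraction is
  taken of the *gated* population.

## Synthetic flow events

Singlet log₁₀ fluorescence is Normal(mu_log, fano_pct·mu_log/100), i.e.
the Fano target is imposed directly on the log scale because that is the
scale the statistic is computed on; raw values are 10^(log value).
Scatter is log-normal with configurable FSC–SSC correlation
(independent of fluorescence by default — the correlation structure
between scatter and signal is not constrained by any measurement we
emulate, so independence is the default and both are configurable).
Pulse-shape channels are affine in FSC plus bounded instrument noise.
Contaminants give the gates something real to remove:

- **Doublets**: sums of two independent singlets (scatter and
  fluorescence), with both width channels inflated ×1.8 — far outside
  the 3-MAD constant band.
- **Debris**: scatter at 3% of the singlet scale (mostly below the
  trigger threshold; stragglers fall below the 5th FSC percentile) and
  fluorescence at an autofluorescence baseline two decades below the
  signal.

What the generator does *not* emulate: spectral spillover,
instrument drift within a run, signal saturation, cell-cycle structure
in the fluorescence distribution, or scatter–fluorescence correlation
(off by default). Passing tests therefore show the pipeline's
statistical correctness on the stated model, not robustness to every
instrument artifact.

## Cross, screen and pooled reads

F1 haploid segregants inherit each marker allele with probability ½;
under a genetic map, adjacent markers recombine with the stated fraction
(Markov chain along the marker order; "unlinked" = ½ everywhere). The
noise phenotype is `base + Σ causal effects + N(0, residual_sd)`, in
Fano-percent units; each measurement run redraws the environmental term,
emulating independent cytometry sessions.

The iterative screen keeps, per run, segregants in the top/bottom 20%
of that run's measured set whose mean signal is within 3 control SDs
(excluding mean-shift alleles); survivors of run r are the only
segregants measured in run r+1, exactly as on the bench. Ties in the
noise ranking are broken by table order; when both tails collapse onto
the same tied ids, the evolved-like track claims them.

Pooled sequencing: per marker and pool, coverage ~ Poisson(mean
coverage) truncated at 1 — a coverage *range* rather than a constant is
what pooled libraries actually deliver — and alt reads ~
Binomial(coverage, pool allele frequency). Control-clone alt reads
default to 0 (markers private to the evolved line) and can be supplied
per marker.

Background-mutation annotation classes default to the
nonsynonymous/synonymous/intergenic mix of an EMS-mutagenized evolved
yeast genome (494:256:271 of 1,022, the remainder being one mutation of
another class), apportioned deterministically by largest remainder.
Substitutions carry the EMS G:C→A:T signature. Positions are drawn
without replacement from a 16-chromosome, 12-Mb layout.

## Enrichment thresholds

A neutral SNP's observed pooled frequency follows the two-stage
binomial: k ~ Bin(pool, ½) carriers, r ~ Bin(coverage, k/pool) alt
reads, frequency r/coverage. Thresholds are empirical quantiles of
200,000 Monte-Carlo replicates by default, using the **nearest-rank**
definition (smallest order statistic whose cumulative fraction reaches
the level) so that simulated quantiles can be compared exactly against
the enumeration oracle `exact_pool_threshold`.

The default settings — upper 90th percentile for a pool of 10, lower
5th percentile (95% one-sided) for a pool of 20 — are the one-sided
reading of the published confidence levels; it is the reading that
reproduces both published threshold values under the stated simulation,
and it is a configuration default, not hard-coded. The pool sizes 10
and 20 are likewise the simulated sizes as published, although the
sequenced pools held 16 and 20 segregants; both parameterizations are
available, and the calibration calculator (`neutral_pass_rate`) accepts
the actual pool sizes.

With the default margins (0.70 upper, 0.32 lower) the difference
criterion (> 0.38) is implied by the margins (0.701 − 0.319 > 0.38), so
it only binds under non-default settings; it is implemented as a
separate, disableable filter because its provenance relative to the
margins is ambiguous. All frequency comparisons are strict and computed
from read counts at call time, never pre-rounded.

`neutral_pass_rate` computes the exact joint probability that a neutral
marker passes all frequency filters, using the independence of the two
disjoint pools (product lattice). It predicts the neutral
false-positive count per candidate list; the parameter-recovery test
checks the observed median against a central Poisson interval around
this prediction.

## Selection-regime simulator

Lineage-based Wright–Fisher-style forward simulation. Per cycle:

1. deterministic proportional growth to the census entering mutagenesis
   (`n_mutagenized`, default 10⁶) with largest-remainder rounding —
   growth is modeled without death or drift because the sorting
   bottleneck dominates drift at these sizes;
2. mutagenesis: mutation events per genotype ~ Poisson(count · rate),
   each converting one cell into a new genotype with one extra mutation
   (at realistic per-cell rates the chance of two hits in one cell in
   one cycle is negligible, so the per-event formulation is equivalent
   to per-lineage Poisson draws);
3. each cell draws `log-signal ~ Normal(mu_g, var_g)` with
   `var_g = max(base_fano + Σ fano effects, 0) · mu_g / 100`; the floor
   triggers a warning if it binds for > 1% of cells;
4. the top (odd cycles) or bottom (even cycles) `tail_frac` of
   phenotypes is sorted and `n_sorted` (default 5,000) cells seed the
   next cycle.

No quantitative model exists for how mutations move expression noise,
so the effect distribution is the simplest testable choice: additive on
the Fano percentage, exponential magnitude (default scale 5 Fano
points), 50% sign split, plus a configurable fraction of mean-shifting
mutations (default 0). The default `mutation_rate` of 10⁻⁴
noise-affecting mutations per cell per cycle reflects that only a small
minority of EMS hits should touch noise regulation; it is a free
parameter, not a measured one. De-novo mutation frequencies are only
tracked when `track_de_novo=True` (bookkeeping cost); standing variants
are always tracked.

`generations_per_phase` defaults to 13.4 — the value obtained by
inverting `2/Nₑ = 1/(N₀₁·g) + 1/(N₀₂·g)` at the reported Nₑ = 1.33×10⁵
with N₀₁ = 10⁶ and N₀₂ = 5×10³; it is a derived default, not a printed
one. The formula uses a single g for both phases. EMS survival
(60–80%) and mitochondria-defective subpopulations are not modeled.

## Problem sizes in the tests

The acceptance-level checks use 20,000 flow events (noise recovery),
10,000 neutral markers (calibration), 100 seeds of the
360-segregant / 1,001-marker cross (parameter recovery) and 200,000
Monte-Carlo replicates per threshold; the regime simulator's property
tests run reduced censuses (2×10⁴ cells, 10–15 cycles) since its
guarantees are distributional, not scale-dependent. These sizes give
3-SE Monte-Carlo resolution well below the tolerances being asserted.

## Known limitations

- FCS binary files are not parsed; event tables are CSV. Channel
  naming follows the documented `FSC, SSC, PW, FSC_W, <signal>` schema.
- The upstream variant caller's 10% frequency cut-off for the
  ancestral-like pool is an ingestion assumption, not re-implemented;
  the package consumes variant frequency tables, not reads.
- The exact thresholds under the default settings are 0.7133 and
  0.3067 (enumeration); published rounded values (0.70 / 0.32) are
  reproduced within their printed precision by the same simulation but
  the package reports the unrounded quantiles.
- The screen models measurement runs as exchangeable; day effects or
  drift between runs are not simulated.
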