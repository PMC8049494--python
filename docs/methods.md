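# Methods

## The multiplicative interaction model

The analysis treats a quantitative phenotype score (positive, right-skewed,
higher = more severe) as a multiplicative trait. Scores for every genotype are
first expressed as *percentage of control*: `100 * raw / mean(control)`,
where the control is the genotype carrying the same genetic background
(different RNAi construct libraries have different background genotypes, so
each background keeps its own matched control). The arithmetic mean is used
as the control summary and as the single-knockdown effect estimate, because
the no-interaction expectation is defined as a product of averages; medians
appear only in enhancer/suppressor direction calls.

For a double knockdown of genes A and B with single-knockdown percent-of-
control means `m_A`, `m_B`, the no-interaction expectation is
`E = m_A * m_B / 100`, and the interaction score is `log2(observed mean / E)`.
The deviation test is a two-tailed one-sample Wilcoxon signed-rank test of the
normalised pairwise scores against `E`, BH-corrected; a significant deviation
with positive score is a negative (aggravating) interaction, with negative
score a positive (alleviating) one. Enhancer/suppressor status relative to the
focal single knockdown is assessed independently with a two-tailed
Mann-Whitney test so that a pair can, e.g., enhance the focal phenotype yet be
consistent with the multiplicative expectation ("combined independent
effects").

Assumptions worth stating: scores are positive with finite mean; effects
combine multiplicatively on the raw scale; the expected value `E` is treated
as a known constant by the signed-rank test even though it is estimated from
the single-knockdown and control samples. The last assumption is the model's
main fragility — see *Calibration* below.

### Rank tests

Both rank tests switch between an exact null distribution and a tie-corrected
normal approximation with continuity correction at a configurable combined
sample size (default 25, `DEFAULT_EXACT_MAX_N`). The Mann-Whitney exact branch
enumerates labellings (via scipy); the one-sample signed-rank exact branch is
a dynamic program over doubled midranks, so tied absolute differences are
handled exactly, with two-sided p defined as `min(1, 2*min(P(W<=w), P(W>=w)))`.
Zero differences are discarded (classic Wilcoxon treatment); an all-zero
sample returns p = 1. Identical Mann-Whitney samples return p = 1 because the
continuity correction shrinks |U − mean| toward zero.

### Multiple testing and validation

BH correction is applied per family, by default one family per focal gene and
test type, mirroring per-screen corrections; `bh_family="global"` pools the
whole table into one family (used when all tested pairs form a single planned
family, e.g. calibration experiments). Significance is strict: `p_adj < alpha`
with alpha = 0.05 by default.

A gene pair tested with one line combination is a *potential* interaction and
keeps its line-level class. With two or more combinations the observed trend
must be reproduced: at least two significant concordant calls validate the
pair; a single significant call among several is *not validated*; significant
calls with conflicting signs are *discordant* (both aggregate to class
`none`); no significant call at all is a validated no-interaction. Requiring
two concordant significant calls (rather than merely the absence of
contradiction) is the package's reading of "reproduced by multiple lines";
it sharply reduces pair-level false calls at a negligible power cost for
|interaction score| near 1.

### Category comparisons

Interaction rates between two gene categories are compared with a two-sided
Fisher's exact test on the 2x2 table (category x interacting/non-interacting),
the p-value summing all tables at the observed margins whose probability does
not exceed the observed one. Two-sided is assumed throughout; the printed
reference values are two-sided to the stated precision.

## The synthetic screen generator

The generator emulates the statistical structure of a batched modifier
screen, not any organism-level biology:

* **Noise** — mean-preserving multiplicative lognormal noise with coefficient
  of variation `noise_cv` (default 0.15): scores stay positive and
  right-skewed, and percent-of-control normalisation is always defined. The
  dispersion is an operational choice; screens report per-genotype sample
  sizes but not within-genotype CVs.
* **Single effects** — each construct line draws its own log2 effect from
  `single_effect_log2_range` (default 0.25–1.5, i.e. 1.2x to 2.8x of
  control), modelling the line-to-line variability the validation rule
  exists to absorb. Lines are assigned backgrounds in rotation.
* **Controls** — one control genotype per background, offset from the nominal
  control mean by a small lognormal background effect
  (`background_log2_offset_sd`, default 0.05), because controls must be
  background-matched.
* **Two-hit construction** — the raw-scale mean of a pairwise genotype is
  `control_mean_bg * 2**(eff_A + eff_B + IS)`, so `IS = 0` *is* the
  multiplicative null and the injected score is exactly the quantity the
  caller estimates.
* **Batching** — reference genotypes (controls and single knockdowns) recur
  alongside every batch of pairwise crosses in a real screen, so the
  generator scores them in `reference_batches` batches (default 4) of
  `replicates_per_genotype` flies each, while each pairwise cross is scored
  once. With 15 flies per cross this gives 60 reference observations — the
  expected values the caller treats as constants are then estimated well
  enough for the test to hold its nominal level.

What the generator does *not* emulate: image-derived score artefacts, batch
drift over time, unequal per-genotype sample sizes, lethal crosses and
missing data, or realistic genome-wide network topology (edges are uniform
random; planted modules are cliques). Passing tests therefore demonstrate the
statistical machinery, not robustness to those real-data features.

## Calibration

Because the signed-rank test treats the expected value as exact, sampling
error in the reference means inflates the false-call rate. Quantitatively:
with all genotypes at 15 observations and CV 0.15, the reference error adds
roughly the same variance again to the test statistic and the BH-significant
rate under the null rises to ~0.1–0.15; with references pooled over four
batches (the default) the per-pair false-call rate measured over 500
independently simulated pairs is ≤ 0.01–0.02 at alpha 0.05, and the correct
interaction sign is recovered in ~100% of pairs at |IS| = 1 with 15 flies per
cross. These numbers are computed by `tests/test_acceptance.py` and
`scripts/acceptance.py`. Two caveats: (i) when many tested pairs share the
same reference crosses, their calls are positively correlated and the
realised false-call count in a single screen is more variable than the rate
suggests; (ii) users analysing real screens with small reference samples
should expect anticonservative behaviour and rely on the multi-line
validation rule, which is the design's mitigation.

## Network connectivity

The gene network is undirected with positive functional-interaction weights;
only edges with weight strictly above the cutoff are kept (absolute cutoff,
or the top fraction `q` of weights via the empirical `1-q` quantile, matching
the strict "greater than" form of an absolute cutoff). Edge cost is the
inverse weight; pair connectivity is the inverse of the Dijkstra shortest-path
cost, 0 for disconnected pairs (the natural limit); connector genes are the
interior nodes of the shortest path. Among equal-cost paths the
lexicographically smallest node sequence is chosen (deterministic), with an
optional mode returning the union of connectors over all tied paths; ties are
compared with a 1e-9 relative tolerance. Genes absent from the thresholded
network are excluded from set statistics with a logged warning.

Set-level connectivity (median by default, mean optional) is tested against
two seeded nulls: uniform random same-size gene sets from the network, and
contiguous blocks of genomically adjacent genes with blocks touching flagged
CNV regions rejected and redrawn (so known multi-gene CNVs do not contaminate
the null). The summary reports a z-score using the null's n−1 standard
deviation, a one-tailed normal p in the stated direction, and a percentile
counting null values strictly below the observed statistic — with this
convention an observed value smaller than 99.6% of the null sits at the 0.4th
percentile. A degenerate null (zero variance) is flagged and yields an
undefined z rather than a fabricated p.

Connector-set intolerance comparisons use two-tailed Mann-Whitney tests on
RVIS percentiles (missing scores dropped and counted) plus the fraction of
genes at or below the 20th RVIS percentile.

## Numerical and design choices

* Determinism: every stochastic stage takes a seed; the pipeline derives
  per-stage seeds from one run seed by hashing, so stages are independently
  reproducible and re-runs are byte-identical.
* Problem sizes in the shipped tests and acceptance script (500-pair
  calibration, 200-pair sign recovery, 100 oracle graphs of ≤ 12 nodes, 1000
  permutations) were chosen so each check completes in seconds while keeping
  Monte-Carlo error well inside the asserted margins.
* The calibration and sign-recovery runs simulate each tested pair with its
  own focal gene, interactor, line and background-matched control, making the
  500 calls independent draws from the caller — the quantity being measured
  is a per-pair error rate, and shared references would correlate the
  outcomes and inflate the variance of the estimate.
* Degenerate inputs are errors, not silent defaults: empty controls or
  samples, non-positive means/weights, unknown backgrounds or genes, empty
  thresholded networks, oversized block lengths.

## Known limitations

* The multiplicative model addresses only mean severity; distributional
  interactions (variance or shape changes) are invisible to it.
* The one-sample deviation test treats the multiplicative expectation as a
  known constant, as is standard modifier-screen practice; calibration
  therefore relies on well-estimated references.
* Contiguous-block sampling draws uniformly over admissible block positions,
  which weights chromosomes by length; gene density differences are not
  modelled.
* The union-of-connectors mode enumerates tie-optimal nodes by distance
  equality and can include nodes of paths tied only within the numerical
  tolerance.
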