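# Methods

This note documents the models implemented in `isosim`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic data does
and does not emulate.

## Scope and simulation procedure

The framework operates on an isoform-by-cell matrix of nonnegative integer
counts plus a transcript-to-gene map. It deliberately models *isoform
detection*, not isoform quantification: the simulated unit of observation is
the set of isoforms called expressed in a cell, and the reported statistics
are the mean number of detected isoforms per gene per cell and the mean
overlap fraction with the ground truth. Read-level simulation (FASTQ,
mapping, PCR) is out of scope.

One simulation round, given the set of genes with exactly four detected
isoforms:

1. for each gene and cell, draw per-isoform choice probabilities from the
   configured choice model and sample `i` distinct isoforms (the ground
   truth for that gene/cell);
2. drop each chosen isoform's reads with its dropout probability;
3. call each isoform with reads expressed with probability 1 − pFN, and each
   isoform without reads expressed with probability pFP;
4. per gene, average the detected count and the overlap fraction
   |GroundTruth ∩ Detected| / |GroundTruth| over cells.

`n_rounds` (default 100) independent rounds are run per scenario
i ∈ {1, 2, 3, 4}. Per-round values are retained, so both pooled
distributions and per-gene means are available; pooling across rounds is the
default input to the mixture model, with per-round fits available.

### Detection filters

The dataset-level filter defining a "detected isoform" is strict: more than
5 counts in at least 2 cells. The per-cell detection probability that feeds
the inferred-probability model uses count > 0 by default — the dropout
machinery treats any zero as a dropout, so nonzero = detected is the
consistent cell-level notion — and the threshold is exposed
(`compute_isoform_stats(..., detection_min_count=...)`) because the two
definitions are genuinely distinct. Under the default, p_detection and
dropout_rate are exact complements.

## Isoform choice models

| model | probability of isoform (rank k of M) | scope |
|---|---|---|
| `weibull` (default) | ∝ exp[−(1 + k/M)²] | fixed per gene |
| `inferred` | normalized P(Choice) from the detection decomposition | fixed per gene |
| `cell_variability` | Beta draw around each isoform's P(Choice), σ = 0.002 | per cell |
| `random` | uniform(0,1) weight, normalized | per gene per round (per-cell switch) |
| `normal` | truncated-normal(0.25, 0.06) weight on [0,1], normalized | per cell |
| `bernoulli` | Bernoulli(0.25) weight, normalized; all-zero → uniform | per cell |
| `constant` | 0.25 each | fixed |

**Weibull parameterization.** The extreme-value splicing model defines a
median frequency mf(k, M) = exp[−(1 + k/M)²] / (k·H_M) with H_M the
generalised harmonic normaliser. Self-normalizing that expression (keeping
the 1/k factor) yields [0.742, 0.187, 0.055, 0.016] at M = 4, which
contradicts the reference probability vector [0.55, 0.28, 0.12, 0.05] — the
latter is exactly the normalization *without* the 1/k factor. The package
treats the reference vector as authoritative: `weibull_choice_probs(M)`
normalizes exp[−(1 + k/M)²], and the median-frequency form is retained
behind `include_rank_factor=True` rather than silently reconciled.

**Inferred probabilities.** P(Choice) = |P(Detection) − pFP| /
|P(¬Dropout)(1 − pFN) − pFP|, with absolute values guarding against negative
intermediates from imperfect estimates and results above 1 clamped to 1.
A denominator of exactly zero has no defined answer and raises. Per-gene
vectors are normalized over the gene's isoforms.

**Cell variability.** Each isoform's per-cell probability is drawn from a
Beta moment-matched to mean P(Choice) and σ = 0.002, sampled independently
per isoform and then normalized within the cell (the alternative — perturbing
the normalized vector directly — would not keep per-isoform means at their
inferred values). When the moments are infeasible (σ² ≥ μ(1 − μ), including
the clamped extremes μ ∈ {0, 1}) the isoform falls back to the constant
probability μ. As σ → 0 the model provably collapses onto the inferred
model, which the tests check by total-variation distance.

**Random model scope.** The random model's weights are drawn once per gene
per simulation round and held constant across cells; only the normal and
Bernoulli models are explicitly per-cell. A `random_per_cell` switch flips
this reading.

**Truncated normal.** Sampled by inverse CDF on the truncated interval
[0, 1], not by clip-after-draw, so the distribution shape is exact.

### Sampling i isoforms without replacement

`choose_isoforms` performs sequential weighted draws with renormalization
after each draw — the Plackett–Luce distribution over ordered draws.
Zero-probability isoforms are chosen (uniformly) only after all
positive-probability isoforms are exhausted. The vectorized simulator path
(`choose_isoforms_many`) realizes the *same* distribution as an exponential
race (key E_t/p_t, keep the i smallest — successive sampling proportional to
weight is exactly Gumbel-top-k in disguise), which the test suite verifies
against the exact two-draw Plackett–Luce probabilities alongside the
sequential route. When i = M the probabilities are irrelevant and the
simulator skips choice sampling entirely; this is also what makes i = 4
output bit-identical across choice models under a shared seed.

## Noise models

**Dropouts.** P(Dropout) = 1 − S/(K_M + S) with S the isoform's mean CPM
across cells (zeros included). K_M is estimated by maximum likelihood
treating each isoform's zero-cell tally as Binomial(n_cells, d(S; K_M)) —
the simplest observation model consistent with the curve; the likelihood is
unimodal in one dimension, so a bounded scalar search on
log₁₀ K_M ∈ [−3, 6] (CPM scale, tolerance 1e−6) suffices. Isoforms with
S = 0 are excluded (d ≡ 1 regardless of K_M carries no information).
Dropout events are independent across isoforms and cells; no covariance
structure is modelled.

**Beta-sampled dropouts.** To emulate sequencing depths, per-isoform dropout
probabilities can be drawn from Beta(α, β) once per isoform per round
(mirroring the per-isoform Michaelis–Menten assignment, not per cell).
Presets: (α, β) = (1.31, 0.74) for ~1M reads/cell and (0.72, 1.03) for ~4M
reads/cell. The five-point sweep `BETA_SWEEP` = (2.0, 0.5), (1.31, 0.74),
(1.0, 0.88), (0.72, 1.03), (0.4, 1.3) spans high to low mean dropout
(0.80 → 0.24) around those presets with α strictly decreasing and β strictly
increasing, making the family likelihood-ratio ordered. Draws use the
inverse CDF of shared uniforms, so sweep runs sharing a seed are coupled:
dropout draws are *pointwise* ordered across presets, and the monotone
effect of dropout on detection is a deterministic property of a coupled run
rather than a statistical tendency.

**Quantification errors.** Constant event probabilities pFP = 0.01 and
pFN = 0.04 (defaults estimated for Kallisto on full-length scRNA-seq data).
An isoform whose reads all dropped out but which is nonetheless called
expressed counts as a false positive ("rescued" dropout). Constancy across
isoforms is an acknowledged simplification: no GC-content, length, or
expression dependence. The closed-form oracle
E[detected] = Σ_chosen [(1 − d_t)(1 − pFN) + d_t·pFP] + (M − |chosen|)·pFP
backs the property tests for the stochastic path.

## Distribution comparison

Scenario output distributions are compared with the k-sample
Anderson–Darling test (delegated to `scipy.stats.anderson_ksamp`). Note the
implementation floors the reported significance level at 0.001 and caps it
at 0.25, so "indistinguishable" results report 0.25.

## Mixture model

Each scenario's pooled mean-detected distribution is approximated by a
log-normal fitted by maximum likelihood on natural logs (σ with ddof = 0).
EM then estimates the mixing fractions of the four scenario components in an
observed distribution, with component parameters frozen — only
k_c = Σ_i r_ic / n is updated. EM runs a fixed 100 iterations with no early
stopping, and the full fraction trajectory is the primary output. Numerical
choices: zeros in the data (genes never detected) have no log-normal density
and are excluded with a logged count — the least-assumption option, reported
rather than silent; a density floor of 1e−300 in the responsibility
denominator keeps extreme outliers finite without materially changing
responsibilities. The observed-data log-likelihood is non-decreasing across
iterations (standard EM guarantee), asserted in the tests at every step.

## Synthetic data generator

The generator emulates the *statistical* structure the analysis assumes of a
full-length scRNA-seq quantification, with full ground truth:

* gene mean expression ~ log-normal (log-sd 1.5 by default), split across
  four isoforms by `rank_proportions` (default: the Weibull M = 4 vector, so
  the synthetic major/minor hierarchy matches the default choice model);
  by default gene means are rescaled so isoform means sum to 1e6, putting
  nominal means on the same CPM scale the pipeline computes from the matrix
  (without rescaling, the random total would decouple the two scales and
  K_M would not be recoverable in CPM units);
* each isoform's *marginal* mean S (zeros included) is that nominal CPM, its
  true dropout probability is d = 1 − S/(K_M + S), and conditional on
  surviving dropout, counts are negative-binomial (overdispersion φ = 0.1;
  variance m + φm²) around S/(1 − d) = S + K_M scaled by the cell's library
  size (log-normal, mean 1e6 counts, log-sd 0.2, roughly a deeply sequenced
  full-length protocol);
* dropout is explicit zero-inflation on top of the negative binomial rather
  than relying on sampling zeros, so the true dropout probability is exactly
  the Michaelis–Menten value and K_M recovery from the generated output is a
  clean end-to-end test (recovery within 10% at 2000 isoforms × 200 cells is
  part of the acceptance checks). Inflating the conditional mean by K_M
  keeps the observed mean equal to the nominal S, so the fitted curve sees
  consistent (S, d) pairs.

Default problem sizes — a 50-gene × 100-cell fixture for pipeline runs and a
500-gene × 200-cell matrix for K_M recovery — were chosen so a complete
simulate-plus-mixture pass runs in seconds while leaving all Monte-Carlo
checks with comfortable 3-standard-error margins.

**What the generator does not emulate.** Biological (bursty-expression)
dropouts, gene–gene and isoform–isoform correlation, PCR amplification bias,
GC/length-dependent error rates, batch structure, and genes with other than
exactly four isoforms. Counts are conditionally independent given the truth.
Consequently, passing tests demonstrate that the pipeline's estimators and
simulations are internally correct and mutually consistent — not that real
tissues satisfy the Michaelis–Menten dropout law or any particular choice
model. On real data, all of this machinery conditions on the observed matrix
and the fitted K_M, and its conclusions inherit those assumptions.

## Reproducibility and numerical conventions

* All randomness flows through `numpy.random.Generator`; a scenario's master
  seed spawns one independent substream per round (`SeedSequence.spawn`), so
  results are bit-reproducible and rounds are individually reproducible.
* Expression ranks break ties lexicographically by isoform id; gene lists
  are sorted by gene id — output is invariant to input row/column order.
* CPM uses per-cell totals over all isoforms in the matrix; all-zero cells
  are flagged and contribute zero columns.
* Probability vectors are validated to sum to 1 within 1e−9; all-zero weight
  rows (possible under the Bernoulli model) fall back to uniform.

## Known limitations

* The binomial likelihood for K_M assumes independent cells; overdispersed
  dropout would widen the estimator's error beyond the tested 10%.
* The inferred-probability model inherits the noise of its inputs; with
  near-saturated detection probabilities the clamp at 1 makes it (and the
  cell-variability model built on it) collapse toward uniform within a gene.
* The error model is isoform-feature-blind by construction.
* The mixture model fixes four log-normal components; it performs no model
  selection and will misattribute mass if the observed data deviate from
  log-normality (e.g. heavy zero-inflation, which is excluded from the fit
  and reported separately).
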