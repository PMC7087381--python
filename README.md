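# isosim

How well can full-length single-cell RNA-seq detect splice isoforms?

Single-cell RNA-seq suffers a high rate of *dropouts* — expressed transcripts
that yield no reads in a cell — and isoform quantification adds its own false
positives and false negatives. `isosim` is a simulation framework for asking
how these technical confounders, together with the unknown mechanism of
*isoform choice* (which of a gene's isoforms each cell actually expresses),
limit our ability to count isoforms per gene per cell. It is aimed at
single-cell methods developers and analysts who want to quantify, on their own
isoform-by-cell count matrices or on synthetic data with known ground truth,
how far observed isoform counts sit from the truth.

## The model

Starting from genes with exactly four detected isoforms (an isoform is
*detected* if it has more than 5 counts in at least 2 cells), one simulation
round iterates over every gene and cell:

1. **Choice** — choose *i* ∈ {1, 2, 3, 4} isoforms to be expressed, with
   per-isoform probabilities from one of seven models. The default Weibull
   model assigns rank *k* of *M* isoforms probability ∝ exp[−(1 + k/M)²]
   (for M = 4: **[0.55, 0.28, 0.12, 0.05]**). Alternatives: probabilities
   inferred from observed detection rates by inverting
   P(Detection) = P(Choice)·P(¬Dropout)(1 − pFN) + P(¬Choice)·pFP;
   a cell-variability variant that redraws the inferred probability per cell
   from a moment-matched Beta (σ ≈ 0.002); and random, truncated-normal(0.25,
   0.06), Bernoulli(0.25), and constant-0.25 models.
2. **Dropout** — each chosen isoform's reads survive with probability
   S/(K_M + S), the Michaelis–Menten curve in its mean expression S (CPM);
   K_M is fitted to the whole transcriptome by maximum likelihood. Dropout
   probabilities can instead be drawn from Beta(α, β) distributions to
   emulate different sequencing depths (presets fitted at ~1M and ~4M
   reads/cell), or disabled as a negative control.
3. **Quantification errors** — isoforms with surviving reads are called with
   probability 1 − pFN (default pFN = 0.04); isoforms without reads are
   falsely called with probability pFP (default 0.01).

Per gene and round the framework records the mean number of detected isoforms
per cell and the mean *overlap fraction* |GroundTruth ∩ Detected| /
|GroundTruth|. Scenario distributions are compared with the k-sample
Anderson–Darling test, and a log-normal mixture model with EM over the mixing
fractions only (component parameters frozen) estimates how much each scenario
contributes to an observed distribution.

A synthetic-data generator produces count matrices with full ground truth:
major/minor isoform rank structure, negative-binomial counts, and explicit
Michaelis–Menten zero-inflation with a known K_M.

## Worked example

```python
import isosim as iso

spec = iso.SyntheticSpec(n_genes=50, n_cells=100, K_M_true=10.0, seed=1)
matrix, truth = iso.generate_counts(spec)
genes = iso.select_four_isoform_genes(matrix)
stats = iso.compute_isoform_stats(matrix)
km = iso.fit_km_mle(stats, matrix.n_cells)
print(f"selected {len(genes)} four-isoform genes; fitted K_M = {km:.2f} CPM")

dropout = iso.DropoutModel.michaelis_menten(km, stats)
for i in (1, 2, 3, 4):
    scen = iso.SimulationScenario(i=i, n_cells=matrix.n_cells, dropout=dropout,
                                  n_rounds=30, seed=10 + i)
    res = iso.run_scenario(genes, stats, scen)
    print(f"i={i}: mean detected = {res.pooled_detected().mean():.3f}, "
          f"mean overlap = {res.pooled_overlap().mean():.3f}")
```

prints

```
selected 50 four-isoform genes; fitted K_M = 10.22 CPM
i=1: mean detected = 0.978, mean overlap = 0.948
i=2: mean detected = 1.913, mean overlap = 0.946
i=3: mean detected = 2.839, mean overlap = 0.943
i=4: mean detected = 3.750, mean overlap = 0.938
```

The fitted K_M (10.22 CPM) recovers the generator's true constant (10). In
every scenario the mean detected count sits *below* the true i and the
overlap below 1: dropouts and errors systematically bias isoform counts
downward, and the bias grows with i. On this synthetic matrix expression is
high relative to K_M, so dropout rates are mild; beta-sampled dropout
(e.g. `iso.DropoutModel.from_preset("1M")`) emulates the much harsher
regimes of shallow sequencing.

The same pipeline is scriptable from the shell:

```sh
isosim synth --genes 50 --cells 100 --km 10 --seed 1 --out-dir fix/
isosim select-genes --counts fix/counts.tsv --t2g fix/t2g.tsv --out genes.tsv
isosim fit-dropout  --counts fix/counts.tsv --t2g fix/t2g.tsv --out km.json
isosim simulate --counts fix/counts.tsv --t2g fix/t2g.tsv --i 1 --rounds 100 \
    --seed 2 --out sim1.tsv          # ... likewise for --i 2, 3, 4
isosim mixture --observed obs.tsv --sim sim1.tsv --sim sim2.tsv \
    --sim sim3.tsv --sim sim4.tsv --out mix.tsv
```

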