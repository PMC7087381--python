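"""Synthetic isoform-by-cell count matrices with known ground truth.

The generator emulates the statistical structure the analysis assumes of a
full-length scRNA-seq quantification: integer counts; a pronounced
major/minor isoform hierarchy within each gene (rank-1 isoforms far more
highly expressed than rank-4); and a dropout-rate-versus-mean-expression
relationship following the Michaelis-Menten curve with a known constant.

Construction per isoform (nominal values are on the CPM scale of the emitted
matrix):

* gene mean expression is drawn log-normally, and isoform means are the gene
  mean split by ``rank_proportions`` (default: the Weibull M = 4 vector);
  by default gene means are rescaled so isoform means sum to 1e6, putting
  nominal means and the fitted K_M on the same CPM scale;
* the *marginal* mean S of each isoform (zeros included) is that nominal
  value, and its true dropout probability is d = 1 - S/(K_M + S);
* conditional on surviving dropout, counts are negative-binomial around
  S/(1 - d) = S + K_M scaled by the cell's log-normal library size, then
  zeroed with probability d (explicit zero-inflation, so the true dropout
  probability is exactly the Michaelis-Menten value and the constant can be
  recovered cleanly from the output).

Everything is deterministic given the seed, and the emitted matrix always
passes :func:`isosim.data_io.read_count_matrix` validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import IsoformCountMatrix
from .isoform_choice import weibull_choice_probs
from .noise_models import mm_dropout_prob

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate_counts", "generate_scenario_fixture"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic count-matrix generator.

    ``gene_mean_log_mu``/``gene_mean_log_sd`` parameterize the log-normal
    gene-level mean expression (natural-log scale); with
    ``normalize_total=True`` only the spread matters because means are
    rescaled to sum to 1e6 nominal CPM.  ``dispersion`` is the
    negative-binomial overdispersion phi (variance = m + phi m^2).
    ``library_size_sd`` is the log-scale standard deviation of per-cell
    total counts.
    """

    n_genes: int = 50
    isoforms_per_gene: int = 4
    n_cells: int = 100
    K_M_true: float = 10.0
    rank_proportions: np.ndarray | None = None
    gene_mean_log_mu: float = 8.0
    gene_mean_log_sd: float = 1.5
    dispersion: float = 0.1
    library_size_mean: float = 1e6
    library_size_sd: float = 0.2
    seed: int = 0
    dropout_enabled: bool = True
    normalize_total: bool = True

    def __post_init__(self) -> None:
        if self.rank_proportions is None:
            self.rank_proportions = weibull_choice_probs(self.isoforms_per_gene)
        self.rank_proportions = np.asarray(self.rank_proportions, dtype=float)
        if self.rank_proportions.shape != (self.isoforms_per_gene,):
            raise ValueError("rank_proportions must have one entry per isoform")
        if (self.rank_proportions <= 0).any() or abs(self.rank_proportions.sum() - 1) > 1e-9:
            raise ValueError("rank_proportions must be positive and sum to 1")
        if self.K_M_true <= 0:
            raise ValueError("K_M_true must be > 0")
        if self.n_cells < 2 or self.n_genes < 1:
            raise ValueError("need at least 1 gene and 2 cells")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.library_size_mean <= 0 or self.library_size_sd <= 0:
            raise ValueError("library size parameters must be > 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for a generated matrix.

    ``dropout_prob[t]`` equals ``mm_dropout_prob(mean_cpm[t], K_M_true)``
    when dropout injection is enabled, else 0.
    """

    mean_cpm: dict[str, float]
    dropout_prob: dict[str, float]
    rank_of: dict[str, int]
    gene_of: dict[str, str]
    K_M_true: float


def generate_counts(spec: SyntheticSpec) -> tuple[IsoformCountMatrix, SyntheticTruth]:
    """Generate a count matrix plus its ground truth, deterministically."""
    rng = np.random.default_rng(spec.seed)
    G, P, n_cells = spec.n_genes, spec.isoforms_per_gene, spec.n_cells

    gene_means = rng.lognormal(spec.gene_mean_log_mu, spec.gene_mean_log_sd, size=G)
    iso_means = np.outer(gene_means, spec.rank_proportions).ravel()  # gene-major
    if spec.normalize_total:
        iso_means *= 1e6 / iso_means.sum()

    if spec.dropout_enabled:
        d = mm_dropout_prob(iso_means, spec.K_M_true)
    else:
        d = np.zeros_like(iso_means)
    cond_mean_cpm = iso_means / (1.0 - d)  # = S + K_M under the MM curve

    lib_mu = np.log(spec.library_size_mean) - spec.library_size_sd**2 / 2.0
    lib = rng.lognormal(lib_mu, spec.library_size_sd, size=n_cells)

    m = cond_mean_cpm[:, None] * lib[None, :] / 1e6
    r = 1.0 / spec.dispersion  # NB shape: variance = m + dispersion * m^2
    lam = rng.gamma(r, m / r)
    counts = rng.poisson(lam)
    if spec.dropout_enabled:
        counts = np.where(rng.random(counts.shape) < d[:, None], 0, counts)
    counts = counts.astype(np.int64)

    width = max(4, len(str(G)))
    gene_ids = [f"G{g + 1:0{width}d}" for g in range(G)]
    isoform_ids = [f"{gid}.I{k + 1}" for gid in gene_ids for k in range(P)]
    gene_of = {t: t.split(".")[0] for t in isoform_ids}

    matrix = IsoformCountMatrix(
        isoform_ids=isoform_ids,
        cell_ids=[f"cell{c + 1}" for c in range(n_cells)],
        counts=counts,
        gene_of=gene_of,
    )
    truth = SyntheticTruth(
        mean_cpm=dict(zip(isoform_ids, iso_means.tolist())),
        dropout_prob=dict(zip(isoform_ids, d.tolist())),
        rank_of={t: (j % P) + 1 for j, t in enumerate(isoform_ids)},
        gene_of=gene_of,
        K_M_true=spec.K_M_true,
    )
    return matrix, truth


def generate_scenario_fixture(
    i: int,
    spec: SyntheticSpec,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a complete pipeline fixture: counts TSV, t2g TSV, truth JSON.

    ``i`` is the true isoforms-per-gene-per-cell the fixture is meant to be
    simulated at; it is recorded in the truth file.  Byte-identical for a
    given spec (seed included).
    """
    if not 1 <= i <= spec.isoforms_per_gene:
        raise ValueError(f"i must be in 1..{spec.isoforms_per_gene}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate_counts(spec)

    from .data_io import write_count_matrix

    paths = {
        "counts": out_dir / "counts.tsv",
        "t2g": out_dir / "t2g.tsv",
        "truth": out_dir / "truth.json",
    }
    write_count_matrix(matrix, paths["counts"], paths["t2g"])
    payload = {
        "true_i": i,
        "K_M_true": truth.K_M_true,
        "seed": spec.seed,
        "mean_cpm": truth.mean_cpm,
        "dropout_prob": truth.dropout_prob,
        "rank": truth.rank_of,
        "gene_of": truth.gene_of,
    }
    paths["truth"].write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return paths
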