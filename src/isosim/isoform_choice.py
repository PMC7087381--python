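"""Isoform-choice models: which isoforms a gene expresses in a given cell.

Seven probabilistic models assign each of a gene's M detected isoforms a
probability of being "chosen" for expression in a cell:

``weibull``
    Rank-based probabilities derived from an extreme-value (type III Weibull)
    model of alternative splicing.  For M = 4 the vector is
    [0.55, 0.28, 0.12, 0.05].  The default model.
``inferred``
    Back-calculates P(Choice) per isoform from its empirical detection
    probability, its dropout probability, and the quantification error rates:
    P(Choice) = |P(Detection) - pFP| / |P(not Dropout)(1 - pFN) - pFP|,
    clamped to 1; the vector is then normalized within the gene.
``cell_variability``
    Same as ``inferred`` but the per-isoform probability is redrawn per cell
    from a Beta distribution moment-matched to (P(Choice), sigma).
``random``
    One uniform(0, 1) weight per isoform, drawn once per gene per simulation
    round (optionally per cell), normalized.
``normal``
    Per-cell truncated-normal(0.25, 0.06) weight on [0, 1] per isoform,
    normalized.
``bernoulli``
    Per-cell Bernoulli(0.25) 0/1 weight per isoform, normalized; if every
    weight is zero the probabilities fall back to uniform (0.25 at M = 4).
``constant``
    A fixed probability (0.25 at M = 4) per isoform.

Choosing ``i`` isoforms without replacement uses sequential weighted draws
with renormalization after each draw (the Plackett–Luce distribution); the
vectorized path in :func:`choose_isoforms_many` realizes the same
distribution as an exponential race.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .data_io import GeneIsoformSet, IsoformStats

__all__ = [
    "CHOICE_MODELS",
    "ChoiceModelSpec",
    "ChoiceProbabilities",
    "weibull_choice_probs",
    "weibull_median_frequencies",
    "inferred_choice_prob",
    "beta_params_from_moments",
    "GeneChoiceContext",
    "cell_choice_probs",
    "choose_isoforms",
    "choose_isoforms_many",
]

CHOICE_MODELS = (
    "weibull",
    "inferred",
    "cell_variability",
    "random",
    "normal",
    "bernoulli",
    "constant",
)


@dataclass
class ChoiceModelSpec:
    """Which isoform-choice model to use, and its parameters.

    ``sigma`` is the between-cell standard deviation of the choice
    probability in the cell-variability model (default 0.002).  The normal
    model's truncated-normal has mean 0.25 and standard deviation 0.06; the
    Bernoulli and constant models default to probability 0.25.
    """

    model: str = "weibull"
    sigma: float = 0.002
    normal_mean: float = 0.25
    normal_sd: float = 0.06
    bernoulli_p: float = 0.25
    constant_p: float = 0.25
    random_per_cell: bool = False
    weibull_rank_factor: bool = False

    def __post_init__(self) -> None:
        if self.model not in CHOICE_MODELS:
            raise ValueError(f"unknown choice model {self.model!r}; one of {CHOICE_MODELS}")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        for name in ("normal_mean", "bernoulli_p", "constant_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.normal_sd <= 0:
            raise ValueError("normal_sd must be > 0")


@dataclass(frozen=True)
class ChoiceProbabilities:
    """A gene's per-isoform choice probability vector for one cell.

    ``scope`` records whether the vector is fixed per gene ("gene") or
    resampled per cell ("cell").  Entries are nonnegative and sum to 1.
    """

    gene_id: str
    isoforms: tuple[str, ...]
    p: np.ndarray
    scope: str

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (len(self.isoforms),):
            raise ValueError("probability vector length must equal the gene's M")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "p", p)


def weibull_median_frequencies(M: int) -> tuple[np.ndarray, float]:
    """Median frequency mf(k, M) per rank and the generalised harmonic
    normaliser H_M of the Weibull splicing model:

    mf(k, M) = exp[-(1 + k/M)^2] / (k * H_M),
    H_M = sum_m exp[-(1 + m/M)^2] / m.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    k = np.arange(1, M + 1, dtype=float)
    raw = np.exp(-((1.0 + k / M) ** 2))
    H = float(np.sum(raw / k))
    return raw / (k * H), H


def weibull_choice_probs(M: int, include_rank_factor: bool = False) -> np.ndarray:
    """Weibull-model choice probabilities over ranks 1..M.

    The default normalizes exp[-(1 + k/M)^2] over ranks, which at M = 4 gives
    [0.55, 0.28, 0.12, 0.05].  ``include_rank_factor=True`` instead
    normalizes the median-frequency form with its extra 1/k factor (at M = 4:
    [0.742, 0.187, 0.055, 0.016]); the two parameterizations disagree and the
    former is the reference behaviour.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    k = np.arange(1, M + 1, dtype=float)
    raw = np.exp(-((1.0 + k / M) ** 2))
    if include_rank_factor:
        raw = raw / k
    return raw / raw.sum()


def inferred_choice_prob(
    p_detection: float,
    p_not_dropout: float,
    pfp: float,
    pfn: float,
) -> float:
    """P(Choice) back-calculated from a detection-probability decomposition.

    Solves P(Detection) = P(Choice) P(notDropout)(1 - pFN) + P(notChoice) pFP
    for P(Choice), taking absolute values of numerator and denominator to
    guard against negative intermediates from imperfect estimates, and
    clamping results above 1 to 1.
    """
    for name, v in (("p_detection", p_detection), ("p_not_dropout", p_not_dropout),
                    ("pfp", pfp), ("pfn", pfn)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    denom = abs(p_not_dropout * (1.0 - pfn) - pfp)
    if denom == 0.0:
        raise ZeroDivisionError(
            "P(notDropout)(1 - pFN) == pFP: the choice probability is undefined"
        )
    return min(1.0, abs(p_detection - pfp) / denom)


def beta_params_from_moments(mu: float, sigma: float) -> tuple[float, float] | None:
    """Beta shape parameters matching mean ``mu`` and standard deviation ``sigma``.

    alpha = ((1 - mu)/sigma^2 - 1/mu) mu^2 and beta = alpha (1/mu - 1).
    Returns ``None`` when the moments are infeasible (alpha or beta would be
    nonpositive, i.e. sigma^2 >= mu(1 - mu)); callers then fall back to the
    constant probability ``mu``.
    """
    if not 0.0 < mu < 1.0:
        raise ValueError("mu must be strictly inside (0, 1)")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    alpha = ((1.0 - mu) / sigma**2 - 1.0 / mu) * mu**2
    beta = alpha * (1.0 / mu - 1.0)
    if alpha <= 0 or beta <= 0:
        return None
    return alpha, beta


def _as_prob_array(
    dropout_probs: Mapping[str, float] | Sequence[float] | np.ndarray | None,
    gene: GeneIsoformSet,
) -> np.ndarray | None:
    if dropout_probs is None:
        return None
    if isinstance(dropout_probs, Mapping):
        return np.array([float(dropout_probs[t]) for t in gene.isoforms])
    arr = np.asarray(dropout_probs, dtype=float)
    if arr.shape != (gene.M,):
        raise ValueError("dropout probabilities must cover every isoform of the gene")
    return arr


def _normalize_rows(W: np.ndarray) -> np.ndarray:
    """Row-normalize nonnegative weights; all-zero rows become uniform."""
    W = np.asarray(W, dtype=float)
    sums = W.sum(axis=1, keepdims=True)
    zero = sums[:, 0] <= 0
    if zero.any():
        W[zero] = 1.0
        sums = W.sum(axis=1, keepdims=True)
    return W / sums


class GeneChoiceContext:
    """Per-gene (per simulation round) choice-probability state.

    Fixed-scope models (weibull, inferred, constant, and random unless
    ``random_per_cell``) compute one vector at construction; per-cell models
    (cell_variability, normal, bernoulli) sample fresh weights from
    :meth:`cell_probs` for every cell.
    """

    def __init__(
        self,
        spec: ChoiceModelSpec,
        gene: GeneIsoformSet,
        stats: Mapping[str, IsoformStats] | None = None,
        dropout_probs: Mapping[str, float] | Sequence[float] | None = None,
        pfp: float = 0.01,
        pfn: float = 0.04,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.spec = spec
        self.gene = gene
        M = gene.M
        self._fixed: np.ndarray | None = None
        model = spec.model

        if model == "weibull":
            self._fixed = weibull_choice_probs(M, spec.weibull_rank_factor)
        elif model == "constant":
            self._fixed = _normalize_rows(np.full((1, M), max(spec.constant_p, 1e-12)))[0]
        elif model == "random" and not spec.random_per_cell:
            if rng is None:
                raise ValueError("the random model needs an rng at construction")
            self._fixed = _normalize_rows(rng.random((1, M)))[0]
        elif model in ("inferred", "cell_variability"):
            if stats is None or dropout_probs is None:
                raise ValueError(f"the {model} model needs stats and dropout probabilities")
            d = _as_prob_array(dropout_probs, gene)
            mu = np.array([
                inferred_choice_prob(stats[t].p_detection, 1.0 - d[j], pfp, pfn)
                for j, t in enumerate(gene.isoforms)
            ])
            if model == "inferred":
                self._fixed = _normalize_rows(mu[None, :])[0]
            else:
                self._cv_mu = mu
                self._cv_params = [
                    beta_params_from_moments(m, spec.sigma) if 0.0 < m < 1.0 else None
                    for m in mu
                ]
        elif model == "normal":
            self._tn_a = (0.0 - spec.normal_mean) / spec.normal_sd
            self._tn_b = (1.0 - spec.normal_mean) / spec.normal_sd
        # bernoulli and per-cell random need no gene-level state

    @property
    def scope(self) -> str:
        return "gene" if self._fixed is not None else "cell"

    def cell_probs(self, rng: np.random.Generator, n_cells: int = 1) -> np.ndarray:
        """Choice-probability vectors for ``n_cells`` cells, shape (n_cells, M)."""
        M = self.gene.M
        spec = self.spec
        if self._fixed is not None:
            return np.broadcast_to(self._fixed, (n_cells, M)).copy()
        if spec.model == "random":
            return _normalize_rows(rng.random((n_cells, M)))
        if spec.model == "normal":
            # inverse-CDF sampling keeps the truncated shape exact on [0, 1]
            u = rng.random((n_cells, M))
            w = sps.truncnorm.ppf(u, self._tn_a, self._tn_b,
                                  loc=spec.normal_mean, scale=spec.normal_sd)
            return _normalize_rows(w)
        if spec.model == "bernoulli":
            w = (rng.random((n_cells, M)) < spec.bernoulli_p).astype(float)
            return _normalize_rows(w)
        if spec.model == "cell_variability":
            w = np.empty((n_cells, M))
            for j, params in enumerate(self._cv_params):
                if params is None:
                    w[:, j] = self._cv_mu[j]
                else:
                    a, b = params
                    w[:, j] = rng.beta(a, b, size=n_cells)
            return _normalize_rows(w)
        raise AssertionError(f"unhandled model {spec.model!r}")  # pragma: no cover


def cell_choice_probs(
    spec: ChoiceModelSpec,
    gene: GeneIsoformSet,
    stats: Mapping[str, IsoformStats] | None = None,
    dropout_probs: Mapping[str, float] | Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
    pfp: float = 0.01,
    pfn: float = 0.04,
) -> ChoiceProbabilities:
    """One cell's choice-probability vector under ``spec``."""
    rng = rng if rng is not None else np.random.default_rng()
    ctx = GeneChoiceContext(spec, gene, stats, dropout_probs, pfp, pfn, rng=rng)
    p = ctx.cell_probs(rng, 1)[0]
    return ChoiceProbabilities(gene.gene_id, tuple(gene.isoforms), p, ctx.scope)


def choose_isoforms(
    probs: ChoiceProbabilities | Sequence[float] | np.ndarray,
    i: int,
    rng: np.random.Generator,
) -> set:
    """Sample ``i`` distinct isoforms by sequential weighted draws.

    After each draw the remaining probabilities are renormalized.  Isoforms
    with probability zero are chosen (uniformly) only once every
    positive-probability isoform is exhausted.  Returns isoform ids when
    given :class:`ChoiceProbabilities`, otherwise indices.
    """
    if isinstance(probs, ChoiceProbabilities):
        p = probs.p.copy()
        labels: Sequence = probs.isoforms
    else:
        p = np.asarray(probs, dtype=float).copy()
        labels = range(len(p))
    M = len(p)
    if not 1 <= i <= M:
        raise ValueError(f"i must be in 1..{M}, got {i}")

    available = np.ones(M, dtype=bool)
    chosen: list[int] = []
    for _ in range(i):
        weights = np.where(available, p, 0.0)
        total = weights.sum()
        idx_avail = np.flatnonzero(available)
        if total > 0:
            j = rng.choice(M, p=weights / total)
        else:
            j = idx_avail[rng.integers(len(idx_avail))]
        chosen.append(int(j))
        available[j] = False
    return {labels[j] for j in chosen}


def choose_isoforms_many(P: np.ndarray, i: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized i-subset sampling for many cells at once.

    ``P`` has one probability row per cell.  Each row's subset follows the
    same Plackett–Luce distribution as :func:`choose_isoforms` (sequential
    weighted draws without replacement), realized as an exponential race:
    isoform t gets key E_t / p_t with E_t ~ Exp(1), and the ``i`` smallest
    keys win.  Zero-probability isoforms receive effectively infinite keys in
    a random order, so they are selected only after all positive-probability
    isoforms.  Returns a boolean chosen mask of the same shape as ``P``.
    """
    P = np.asarray(P, dtype=float)
    n, M = P.shape
    if not 1 <= i <= M:
        raise ValueError(f"i must be in 1..{M}, got {i}")
    if i == M:
        return np.ones((n, M), dtype=bool)
    with np.errstate(divide="ignore"):
        keys = rng.exponential(size=(n, M)) / P
    zero = P <= 0
    if zero.any():
        keys[zero] = 1e300 * (1.0 + rng.random(int(zero.sum())))
    part = np.argpartition(keys, i - 1, axis=1)[:, :i]
    mask = np.zeros((n, M), dtype=bool)
    np.put_along_axis(mask, part, True, axis=1)
    return mask
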