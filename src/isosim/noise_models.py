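"""Technical-noise models: dropouts and isoform-quantification errors.

Dropouts follow the Michaelis-Menten relationship between an isoform's mean
expression S (in CPM) and its probability of yielding no reads in a cell:

    P(Dropout) = 1 - S / (K_M + S)

with K_M estimated per dataset by maximum likelihood over the transcriptome's
observed dropout rates.  Alternatively, dropout probabilities can be drawn
from a Beta(alpha, beta) distribution per isoform per simulation round — the
mechanism used to emulate datasets of different sequencing depths — or
disabled entirely for negative controls.

Quantification errors are two constant per-isoform event probabilities: a
false positive (``pFP``, default 0.01) calls an isoform with no surviving
reads as expressed (this includes "rescued" dropouts), and a false negative
(``pFN``, default 0.04) misses an isoform that has reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .data_io import IsoformStats

__all__ = [
    "BETA_PRESETS",
    "BETA_SWEEP",
    "DropoutModel",
    "ErrorModel",
    "mm_dropout_prob",
    "fit_km_mle",
    "sample_dropout_probs_beta",
    "apply_dropouts",
    "apply_quantification_errors",
    "expected_detected",
]

# Beta shapes fitted to the per-isoform dropout-probability distributions of
# the H1 human embryonic stem cells sequenced at ~1M and ~4M reads per cell.
BETA_PRESETS: dict[str, tuple[float, float]] = {
    "1M": (1.31, 0.74),
    "4M": (0.72, 1.03),
}

# Five-point sweep of beta shapes ordered from high to low mean dropout
# probability.  Alpha strictly decreases and beta strictly increases along the
# sweep, so the five distributions are likelihood-ratio (hence stochastically)
# ordered; the two fitted presets above sit inside the sweep.
BETA_SWEEP: tuple[tuple[float, float], ...] = (
    (2.0, 0.5),
    (1.31, 0.74),
    (1.0, 0.88),
    (0.72, 1.03),
    (0.4, 1.3),
)


def mm_dropout_prob(S, K_M: float):
    """Michaelis-Menten dropout probability 1 - S/(K_M + S).

    Strictly decreasing in mean expression ``S`` (CPM); 1 at S = 0 and 0 in
    the high-expression limit.  Accepts scalars or arrays.
    """
    S = np.asarray(S, dtype=float)
    if K_M <= 0:
        raise ValueError("K_M must be > 0")
    if (S < 0).any():
        raise ValueError("mean expression S must be nonnegative")
    out = 1.0 - S / (K_M + S)
    return float(out) if out.ndim == 0 else out


def fit_km_mle(stats: Mapping[str, IsoformStats], n_cells: int) -> float:
    """Maximum-likelihood Michaelis-Menten constant from observed dropout rates.

    Each isoform's zero-count cell tally is modelled as
    Binomial(n_cells, d(S; K_M)), giving the log-likelihood
    sum_t [z_t log d(S_t) + (n_cells - z_t) log(1 - d(S_t))].  Isoforms with
    S = 0 are excluded (their dropout probability is 1 regardless of K_M).
    The 1-D likelihood is maximized by bounded search on log10 K_M in
    [-3, 6] (CPM scale).
    """
    S = np.array([st.S for st in stats.values()])
    z = np.rint(np.array([st.dropout_rate for st in stats.values()]) * n_cells)
    keep = S > 0
    S, z = S[keep], z[keep]
    if S.size < 1:
        raise ValueError("no isoforms with positive mean expression")
    if np.all(z == 0) or np.all(z == n_cells):
        raise ValueError("all dropout rates are 0 or all are 1: K_M is unidentifiable")

    def neg_loglik(log10_km: float) -> float:
        d = np.clip(1.0 - S / (10.0**log10_km + S), 1e-12, 1.0 - 1e-12)
        return -float(np.sum(z * np.log(d) + (n_cells - z) * np.log1p(-d)))

    res = optimize.minimize_scalar(
        neg_loglik, bounds=(-3.0, 6.0), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(10.0 ** res.x)


def sample_dropout_probs_beta(
    alpha: float,
    beta: float,
    isoforms: Iterable[str],
    rng: np.random.Generator,
) -> dict[str, float]:
    """One independent Beta(alpha, beta) dropout probability per isoform.

    Sampled by inverse CDF of uniform draws, so two samplers sharing an RNG
    stream but using different shapes are coupled through the same uniforms
    (the coupling the sequencing-depth sweep relies on).
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("beta shape parameters must be > 0")
    isoforms = list(isoforms)
    u = rng.random(len(isoforms))
    return dict(zip(isoforms, sps.beta.ppf(u, alpha, beta)))


@dataclass
class DropoutModel:
    """Dropout configuration: Michaelis-Menten, beta-sampled, or disabled.

    ``per_isoform_p`` holds the fixed per-isoform dropout probabilities for
    the Michaelis-Menten mode; the beta mode resamples them every round via
    :meth:`round_probs`.
    """

    mode: str = "michaelis_menten"
    K_M: float | None = None
    beta_alpha: float | None = None
    beta_beta: float | None = None
    per_isoform_p: dict[str, float] = field(default_factory=dict)

    _MODES = ("michaelis_menten", "beta_sampled", "disabled")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"unknown dropout mode {self.mode!r}; one of {self._MODES}")
        if self.mode == "michaelis_menten" and self.K_M is not None and self.K_M <= 0:
            raise ValueError("K_M must be > 0")
        if self.mode == "beta_sampled":
            if self.beta_alpha is None or self.beta_beta is None:
                raise ValueError("beta_sampled mode needs beta_alpha and beta_beta")
            if self.beta_alpha <= 0 or self.beta_beta <= 0:
                raise ValueError("beta shape parameters must be > 0")
        bad = [t for t, p in self.per_isoform_p.items() if not 0.0 <= p <= 1.0]
        if bad:
            raise ValueError(f"dropout probability out of [0, 1] for {bad[0]!r}")

    @classmethod
    def disabled(cls) -> "DropoutModel":
        """Negative control: no dropouts at all."""
        return cls(mode="disabled")

    @classmethod
    def michaelis_menten(cls, K_M: float, stats: Mapping[str, IsoformStats]) -> "DropoutModel":
        """Fixed per-isoform probabilities from the fitted curve at each S."""
        p = {t: float(mm_dropout_prob(st.S, K_M)) for t, st in stats.items()}
        return cls(mode="michaelis_menten", K_M=K_M, per_isoform_p=p)

    @classmethod
    def beta_sampled(cls, alpha: float, beta: float) -> "DropoutModel":
        return cls(mode="beta_sampled", beta_alpha=alpha, beta_beta=beta)

    @classmethod
    def from_preset(cls, name: str) -> "DropoutModel":
        """Beta dropout at a named sequencing-depth preset ("1M" or "4M")."""
        alpha, beta = BETA_PRESETS[name]
        return cls.beta_sampled(alpha, beta)

    def round_probs(
        self,
        isoforms: Sequence[str],
        rng: np.random.Generator | None = None,
    ) -> dict[str, float]:
        """Per-isoform dropout probabilities for one simulation round."""
        if self.mode == "disabled":
            return {t: 0.0 for t in isoforms}
        if self.mode == "michaelis_menten":
            missing = [t for t in isoforms if t not in self.per_isoform_p]
            if missing:
                raise KeyError(f"no dropout probability for isoform {missing[0]!r}")
            return {t: self.per_isoform_p[t] for t in isoforms}
        if rng is None:
            raise ValueError("beta_sampled mode needs an rng to draw round probabilities")
        return sample_dropout_probs_beta(self.beta_alpha, self.beta_beta, isoforms, rng)


@dataclass
class ErrorModel:
    """Constant quantification-error probabilities (pFP, pFN)."""

    pFP: float = 0.01
    pFN: float = 0.04
    enabled: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.pFP <= 1.0 and 0.0 <= self.pFN <= 1.0):
            raise ValueError("pFP and pFN must be in [0, 1]")

    @classmethod
    def disabled(cls) -> "ErrorModel":
        return cls(pFP=0.0, pFN=0.0, enabled=False)


def apply_dropouts(
    chosen: set,
    dropout: DropoutModel,
    rng: np.random.Generator,
    round_probs: Mapping[str, float] | None = None,
) -> set:
    """Isoforms surviving with reads: each chosen isoform independently
    survives with probability 1 - P(Dropout).  Unchosen isoforms never gain
    reads here.  ``round_probs`` supplies this round's beta-sampled
    probabilities; otherwise they are taken from the model."""
    if dropout.mode == "disabled":
        return set(chosen)
    probs = round_probs if round_probs is not None else dropout.round_probs(sorted(chosen), rng)
    return {t for t in chosen if rng.random() >= probs[t]}


def apply_quantification_errors(
    surviving: set,
    all_isoforms: Sequence[str],
    errors: ErrorModel,
    rng: np.random.Generator,
) -> set:
    """Detected set after error injection.

    Isoforms with surviving reads are detected with probability 1 - pFN;
    isoforms without reads (unchosen, or chosen but dropped — rescued
    dropouts count as false positives) are detected with probability pFP.
    Events are independent across isoforms.
    """
    if not set(surviving) <= set(all_isoforms):
        raise ValueError("surviving isoforms must be a subset of all isoforms")
    if not errors.enabled:
        return set(surviving)
    detected = set()
    for t in all_isoforms:
        u = rng.random()
        if t in surviving:
            if u >= errors.pFN:
                detected.add(t)
        elif u < errors.pFP:
            detected.add(t)
    return detected


def expected_detected(
    dropout_probs_chosen: Sequence[float],
    M: int,
    errors: ErrorModel,
) -> float:
    """Closed-form expectation of the detected-isoform count.

    For chosen isoforms with dropout probabilities d_t and M total isoforms:
    sum_t [(1 - d_t)(1 - pFN) + d_t pFP] + (M - |chosen|) pFP.  This is the
    analytic oracle the stochastic noise path is tested against.
    """
    d = np.asarray(dropout_probs_chosen, dtype=float)
    if ((d < 0) | (d > 1)).any():
        raise ValueError("dropout probabilities must be in [0, 1]")
    if len(d) > M:
        raise ValueError("more chosen isoforms than M")
    pfp, pfn = (errors.pFP, errors.pFN) if errors.enabled else (0.0, 0.0)
    per_chosen = (1.0 - d) * (1.0 - pfn) + d * pfp
    return float(per_chosen.sum() + (M - len(d)) * pfp)
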