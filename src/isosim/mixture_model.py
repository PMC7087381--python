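"""Log-normal mixture modelling of mean-detected-isoform distributions.

Each simulated scenario's pooled distribution of mean detected isoforms per
gene per cell is approximated by a log-normal component.  Expectation
maximisation then estimates how much each scenario contributes to an
observed distribution — but only the mixing fractions are updated; the
component means and standard deviations stay frozen at their fitted values.

E step:  r_ic = k_c LN(x_i | mu_c, sigma_c) / sum_j k_j LN(x_i | mu_j, sigma_j)
M step:  k_c = sum_i r_ic / n

EM runs for a fixed number of iterations (default 100) and the whole mixing
fraction trajectory is returned, since the trajectory itself — not just the
endpoint — is the quantity of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "LogNormalComponent",
    "MixtureFit",
    "fit_lognormal",
    "em_mixing_fractions",
    "mixture_report",
]

# floor on mixture densities so extreme outliers cannot zero a denominator
_DENSITY_FLOOR = 1e-300


@dataclass(frozen=True)
class LogNormalComponent:
    """One scenario's fitted log-normal: mu and sigma of the natural logs."""

    mu: float
    sigma: float
    label: object = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        logx = np.log(x)
        return sps.norm.logpdf(logx, self.mu, self.sigma) - logx


def fit_lognormal(values: Sequence[float], label: object = None) -> LogNormalComponent:
    """Maximum-likelihood log-normal fit: mu and sigma of the natural logs.

    Non-positive values carry no log-normal density; they are excluded with a
    logged count.  Raises if fewer than two positive values remain or if the
    positive values are all equal (sigma would be zero).
    """
    v = np.asarray(values, dtype=float).ravel()
    pos = v[v > 0]
    n_excluded = v.size - pos.size
    if n_excluded:
        logger.info("excluded %d non-positive values from the log-normal fit", n_excluded)
    if pos.size < 2:
        raise ValueError("need at least two positive values to fit a log-normal")
    logs = np.log(pos)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))
    if sigma == 0.0:
        raise ValueError("all values equal: degenerate (sigma = 0) log-normal")
    return LogNormalComponent(mu=mu, sigma=sigma, label=label)


@dataclass
class MixtureFit:
    """EM output: the full mixing-fraction trajectory plus final responsibilities.

    ``fractions`` has shape (n_iter + 1, C): row 0 is the initialization and
    each subsequent row one EM update.  ``log_likelihoods`` is evaluated at
    every row of the trajectory and is non-decreasing (standard EM guarantee
    with frozen component parameters).
    """

    fractions: np.ndarray
    responsibilities: np.ndarray
    log_likelihoods: np.ndarray
    n: int
    n_excluded: int
    components: tuple[LogNormalComponent, ...]

    @property
    def final_fractions(self) -> np.ndarray:
        return self.fractions[-1]

    @property
    def n_iter(self) -> int:
        return self.fractions.shape[0] - 1

    def trajectory_frame(self) -> pd.DataFrame:
        """Trajectory as a table with columns (iteration, k_<label>...)."""
        cols = [f"k_{c.label if c.label is not None else j + 1}"
                for j, c in enumerate(self.components)]
        df = pd.DataFrame(self.fractions, columns=cols)
        df.insert(0, "iteration", np.arange(self.fractions.shape[0]))
        return df


def em_mixing_fractions(
    data: Sequence[float],
    components: Sequence[LogNormalComponent],
    n_iter: int = 100,
    init_fractions: Sequence[float] | None = None,
) -> MixtureFit:
    """EM over mixing fractions only, for exactly ``n_iter`` iterations.

    Component parameters are frozen; fractions start uniform unless
    ``init_fractions`` is given.  A density floor keeps responsibilities
    defined for datapoints far outside every component's support.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    components = tuple(components)
    C = len(components)
    if C < 1:
        raise ValueError("need at least one component")
    v = np.asarray(data, dtype=float).ravel()
    x = v[v > 0]
    n_excluded = v.size - x.size
    if n_excluded:
        logger.info("excluded %d non-positive datapoints from EM", n_excluded)
    if x.size == 0:
        raise ValueError("no positive datapoints")
    n = x.size

    dens = np.exp(np.stack([c.logpdf(x) for c in components], axis=1))  # (n, C)

    if init_fractions is None:
        k = np.full(C, 1.0 / C)
    else:
        k = np.asarray(init_fractions, dtype=float)
        if k.shape != (C,) or (k < 0).any() or abs(k.sum() - 1.0) > 1e-9:
            raise ValueError("init_fractions must be a probability vector over the components")

    def loglik(frac: np.ndarray) -> float:
        return float(np.sum(np.log(np.maximum(dens @ frac, _DENSITY_FLOOR))))

    traj = [k.copy()]
    lls = [loglik(k)]
    resp = np.empty_like(dens)
    for _ in range(n_iter):
        weighted = dens * k
        denom = np.maximum(weighted.sum(axis=1, keepdims=True), _DENSITY_FLOOR)
        resp = weighted / denom
        k = resp.sum(axis=0) / n
        traj.append(k.copy())
        lls.append(loglik(k))

    return MixtureFit(
        fractions=np.asarray(traj),
        responsibilities=resp,
        log_likelihoods=np.asarray(lls),
        n=n,
        n_excluded=n_excluded,
        components=components,
    )


def mixture_report(fit: MixtureFit) -> dict:
    """Dominant component and final fractions of a completed fit.

    Exact ties are reported as ties, lowest label first.
    """
    final = fit.final_fractions
    best = final.max()
    labels = [c.label if c.label is not None else j + 1
              for j, c in enumerate(fit.components)]
    winners = sorted(
        (labels[j] for j in range(len(labels)) if final[j] == best),
        key=lambda lab: str(lab),
    )
    return {
        "dominant": winners[0],
        "dominant_components": winners,
        "tie": len(winners) > 1,
        "final_fractions": {labels[j]: float(final[j]) for j in range(len(labels))},
        "trajectory": fit.trajectory_frame(),
        "n": fit.n,
        "n_excluded": fit.n_excluded,
    }
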