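"""Bayesian bootstrap with uniform Dirichlet observation weights.

Rather than resampling with replacement (the classical bootstrap), each
replicate draws a weight vector w ~ Dirichlet(1, ..., 1) over the n data
rows and evaluates the statistic under those weights, simulating the
posterior distribution of the statistic.  A resampling mode is also
provided: rows are redrawn n times with probabilities w and the statistic
sees the resample unweighted; it layers multinomial noise on top of the
weights, so the two modes agree approximately (same center, slightly
wider spread for resampling).
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .errors import PsybayesError, ValidationError
from .fits import BayesFit

__all__ = [
    "BootstrapResult",
    "bayesian_bootstrap",
    "weighted_mean",
    "weighted_median",
    "weighted_sd",
    "weighted_quantile",
    "builtin_statistic",
]


class BootstrapResult(BayesFit):
    """Statistic draws from the Bayesian bootstrap; comparable like a fit.

    ``group`` holds the draws under the parameter name ``statistic`` (one
    chain); ``statistic_draws`` gives them as a flat vector (or matrix for
    vector-valued statistics).
    """

    @property
    def statistic_draws(self) -> np.ndarray:
        values = self.group.values[0]  # (n_draws, k)
        return values[:, 0] if values.shape[1] == 1 else values


def weighted_mean(data, weights):
    return float(np.sum(np.asarray(data, float) * weights))


def weighted_median(data, weights):
    return weighted_quantile(data, weights, 0.5)


def weighted_sd(data, weights):
    x = np.asarray(data, float)
    m = np.sum(x * weights)
    return float(np.sqrt(np.sum(weights * (x - m) ** 2)))


def weighted_quantile(data, weights, q: float):
    x = np.asarray(data, float)
    order = np.argsort(x)
    cum = np.cumsum(weights[order])
    return float(x[order][np.searchsorted(cum, q, side="left").clip(0, x.size - 1)])


def builtin_statistic(name: str) -> Callable:
    """Resolve a named statistic: mean, median, sd, or quantile:q."""
    if name == "mean":
        return weighted_mean
    if name == "median":
        return weighted_median
    if name == "sd":
        return weighted_sd
    if name.startswith("quantile:"):
        q = float(name.split(":", 1)[1])
        if not 0 < q < 1:
            raise ValidationError("quantile level must be in (0, 1)")
        return lambda data, weights: weighted_quantile(data, weights, q)
    raise ValidationError(f"unknown statistic {name!r}; use mean, median, sd or quantile:q")


def bayesian_bootstrap(
    data,
    statistic: Callable,
    n_draws: int = 4000,
    seed: int = 1,
    use_weights: bool = True,
) -> BootstrapResult:
    """Draw the statistic's posterior via Dirichlet-weighted replicates.

    ``statistic(data, weights)`` when ``use_weights``; otherwise the data
    are resampled (n rows, probabilities w) and ``statistic`` receives the
    resample with uniform weights.
    """
    if int(n_draws) < 1:
        raise ValidationError("n_draws must be a positive integer")
    n_draws = int(n_draws)
    arr = np.asarray(data)
    n = arr.shape[0]
    if n < 1:
        raise ValidationError("bootstrap needs at least one data row")
    rng = np.random.default_rng(seed)
    if n == 1:  # the one-dimensional Dirichlet is degenerate at exactly 1
        weights = np.ones((n_draws, 1))
    else:
        weights = rng.dirichlet(np.ones(n), size=n_draws)
    out = []
    for i in range(n_draws):
        if use_weights:
            value = statistic(arr, weights[i])
        else:
            take = rng.choice(n, size=n, replace=True, p=weights[i])
            resample = arr[take]
            value = statistic(resample, np.full(n, 1.0 / n))
        value = np.atleast_1d(np.asarray(value, dtype=float))
        if not np.all(np.isfinite(value)):
            raise PsybayesError(f"statistic returned a non-finite value at draw {i}")
        out.append(value)
    values = np.stack(out)  # (n_draws, k)
    k = values.shape[1]
    names = ["statistic"] if k == 1 else [f"statistic[{j}]" for j in range(1, k + 1)]
    from .draws import DrawMatrix

    group = DrawMatrix(values[None, :, :], names)
    return BootstrapResult(
        model="bootstrap",
        group=group,
        data=arr,
        extra={"seed": seed, "n_draws": n_draws, "use_weights": use_weights},
    )
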