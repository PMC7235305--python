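"""Bayesian t-test on a scaled and shifted Student-t distribution.

Each group is modelled independently as y_i ~ StudentT(nu, mu, sigma) with
degrees of freedom nu > 0, location mu and scale sigma > 0; the heavy tails
make the location estimate robust to outliers.  Groups are compared
afterwards through their mu draws (see :mod:`psybayes.compare`).
"""

from __future__ import annotations

import numpy as np
from scipy import special

from .errors import ValidationError
from .fits import BayesFit
from .priors import Prior
from .sampler import (
    POSITIVE,
    REAL,
    ModelSpec,
    ParameterBlock,
    SamplerSettings,
    sample_posterior,
)

__all__ = ["TTestFit", "student_t_log_density", "fit_ttest"]


class TTestFit(BayesFit):
    """Posterior draws for nu, mu, sigma; ``mu`` is the comparison currency."""


def student_t_log_density(y, nu, mu, sigma):
    """Log density of the location-scale Student-t at ``y`` (vectorized)."""
    nu = np.asarray(nu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(nu <= 0) or np.any(sigma <= 0):
        raise ValidationError("student_t_log_density needs nu > 0 and sigma > 0")
    z = (np.asarray(y, dtype=float) - np.asarray(mu, dtype=float)) / sigma
    out = (
        special.gammaln((nu + 1.0) / 2.0)
        - special.gammaln(nu / 2.0)
        - 0.5 * np.log(nu * np.pi)
        - np.log(sigma)
        - (nu + 1.0) / 2.0 * np.log1p(z * z / nu)
    )
    return out if out.shape else float(out)


def _validate_vector(y) -> np.ndarray:
    y = np.asarray(y, dtype=float).reshape(-1)
    if y.size < 2:
        raise ValidationError("the t-test needs at least 2 observations")
    if not np.all(np.isfinite(y)):
        raise ValidationError("t-test data must be finite")
    if np.ptp(y) == 0.0:
        raise ValidationError("constant data: the scale parameter is not identified")
    return y


def fit_ttest(
    y,
    priors: dict[str, Prior] | None = None,
    settings: SamplerSettings | None = None,
) -> TTestFit:
    """Fit the Student-t model to a numeric vector.

    Default priors are flat on mu and flat on log(sigma) and log(nu); pass
    ``priors={"mu": Prior("normal", (120, 20)), ...}`` to override.
    """
    y = _validate_vector(y)
    settings = settings or SamplerSettings()
    priors = dict(priors or {})
    unknown = set(priors) - {"mu", "sigma", "nu"}
    if unknown:
        raise ValidationError(f"unknown t-test prior targets: {sorted(unknown)}")

    loc, scale = float(np.mean(y)), float(np.std(y))

    def log_likelihood(params):
        mu = params["mu"]  # (batch, 1)
        sigma = params["sigma"]
        nu = params["nu"]
        z = (y[None, :] - mu) / sigma
        ll = (
            special.gammaln((nu + 1.0) / 2.0)
            - special.gammaln(nu / 2.0)
            - 0.5 * np.log(nu * np.pi)
            - np.log(sigma)
        ) * y.size - (nu + 1.0) / 2.0 * np.log1p(z * z / nu).sum(axis=1, keepdims=True)
        return ll[:, 0]

    model = ModelSpec(
        blocks=[
            ParameterBlock("mu", 1, REAL),
            ParameterBlock("sigma", 1, POSITIVE),
            ParameterBlock("nu", 1, POSITIVE),
        ],
        log_likelihood=log_likelihood,
        priors=priors,
        init=lambda rng: {"mu": np.array([loc]), "sigma": np.array([scale]), "nu": np.array([10.0])},
    )
    draws = sample_posterior(model, settings)
    return TTestFit(model="ttest", group=draws, data=y, settings=settings)


def posterior_predictive(fit: TTestFit, n_per_draw: int, rng: np.random.Generator) -> np.ndarray:
    """One Student-t datum block per posterior draw, concatenated."""
    nu = np.repeat(fit.group_draws("nu"), n_per_draw)
    mu = np.repeat(fit.group_draws("mu"), n_per_draw)
    sigma = np.repeat(fit.group_draws("sigma"), n_per_draw)
    return mu + sigma * rng.standard_t(nu)
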