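"""Hierarchical exGaussian model for reaction times.

Each subject's reaction times follow an exponentially modified normal
distribution with parameters (mu_i, sigma_i, lambda_i): the sum of a
Normal(mu_i, sigma_i) component and an independent Exponential tail with
*rate* lambda_i, so a subject's expected reaction time is mu_i + 1/lambda_i.
Subject parameters are partially pooled through group-level normal
distributions N(mu_mu, sigma_mu), N(mu_sigma, sigma_sigma) and
N(mu_lambda, sigma_lambda), the latter two truncated to positive support.
The group-level expected reaction time E = mu_mu + 1/mu_lambda is the
comparison currency for this model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .errors import PsybayesError, ValidationError
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

__all__ = [
    "ReactionTimeData",
    "ReactionTimeFit",
    "exgaussian_log_density",
    "fit_reaction_time",
    "rt_group_mean_draws",
]

_LOG_HALF = np.log(0.5)


def _log_erfcx(u):
    """log(erfcx(u)) without overflow: erfcx(u) ~ 2*exp(u^2) as u -> -inf."""
    u = np.asarray(u, dtype=float)
    with np.errstate(over="ignore", divide="ignore"):
        direct = np.log(special.erfcx(np.where(u < -5.0, 0.0, u)))
        tail = u * u + np.log(special.erfc(np.maximum(u, -30.0)))
    return np.where(u < -5.0, tail, direct)


def exgaussian_log_density(t, mu, sigma, lam):
    """Stable log density of the exGaussian (normal + exponential) at ``t``.

    Uses the scaled complementary error function erfcx to avoid overflow:
    log f = log(lambda/2) + log erfcx(u) - (t - mu)^2 / (2 sigma^2) with
    u = (mu + lambda sigma^2 - t) / (sqrt(2) sigma).
    """
    sigma = np.asarray(sigma, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(sigma <= 0) or np.any(lam <= 0):
        raise ValidationError("exgaussian_log_density needs sigma > 0 and lambda > 0")
    t = np.asarray(t, dtype=float)
    mu = np.asarray(mu, dtype=float)
    u = (mu + lam * sigma**2 - t) / (np.sqrt(2.0) * sigma)
    out = np.log(lam) + _LOG_HALF + _log_erfcx(u) - (t - mu) ** 2 / (2.0 * sigma**2)
    return out if out.shape else float(out)


def _truncated_normal_logpdf(x, mean, sd):
    """N(mean, sd) log density truncated to x > 0, normalization included."""
    z = (x - mean) / sd
    log_norm = special.log_ndtr(mean / sd)  # log P(X > 0) = log Phi(mean/sd)
    return -0.5 * np.log(2.0 * np.pi) - np.log(sd) - 0.5 * z * z - log_norm


@dataclass
class ReactionTimeData:
    """Validated (t, s) pairs: reaction times in seconds, 1-based subject ids.

    Subjects must be indexed contiguously from 1 to n; re-index raw ids
    first (e.g. ``pd.factorize(ids)[0] + 1``).
    """

    t: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float).reshape(-1)
        self.s = np.asarray(self.s).reshape(-1)
        if self.t.size != self.s.size or self.t.size == 0:
            raise ValidationError("t and s must be equally long and non-empty")
        if not np.all(np.isfinite(self.t)) or np.any(self.t <= 0):
            raise ValidationError("reaction times must be finite and positive (seconds)")
        s = self.s
        if not np.all(s == np.floor(np.asarray(s, dtype=float))):
            raise ValidationError("subject ids must be integers")
        self.s = s = np.asarray(s, dtype=int)
        present = np.unique(s)
        n = present.max() if present.size else 0
        if present[0] != 1 or not np.array_equal(present, np.arange(1, n + 1)):
            raise ValidationError(
                "subject ids must run contiguously from 1 to n; "
                "re-index your ids onto the interval [1, n] before fitting"
            )

    @property
    def n_subjects(self) -> int:
        return int(self.s.max())

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, correct_only: bool = False) -> "ReactionTimeData":
        """Build from a frame with columns subject, rt and optionally correct."""
        if correct_only:
            if "correct" not in frame.columns:
                raise ValidationError("correct_only requested but no 'correct' column present")
            frame = frame[frame["correct"] == 1]
        return cls(frame["rt"].to_numpy(), frame["subject"].to_numpy())


class ReactionTimeFit(BayesFit):
    """Hierarchical exGaussian fit; subject params mu, sigma, lambda."""


_GROUP_BLOCKS = [
    ParameterBlock("mu_mu", 1, REAL),
    ParameterBlock("sigma_mu", 1, POSITIVE),
    ParameterBlock("mu_sigma", 1, POSITIVE),
    ParameterBlock("sigma_sigma", 1, POSITIVE),
    ParameterBlock("mu_lambda", 1, POSITIVE),
    ParameterBlock("sigma_lambda", 1, POSITIVE),
]

GROUP_PARAMETERS = [b.name for b in _GROUP_BLOCKS]
SUBJECT_PARAMETERS = ["mu", "sigma", "lambda"]


def fit_reaction_time(
    data: ReactionTimeData | pd.DataFrame,
    priors: dict[str, Prior] | None = None,
    settings: SamplerSettings | None = None,
) -> ReactionTimeFit:
    """Fit the hierarchical exGaussian reaction-time model.

    Custom priors may target the group parameters (mu_mu, sigma_mu,
    mu_sigma, sigma_sigma, mu_lambda, sigma_lambda); hyper-scales default to
    flat on their positive support.
    """
    if isinstance(data, pd.DataFrame):
        data = ReactionTimeData.from_frame(data)
    settings = settings or SamplerSettings()
    n = data.n_subjects
    t = data.t
    idx = data.s - 1

    # flat on the positive support (not on the log scale) for every positive
    # group parameter: a 1/x-improper default would pile mass at zero
    prior_map: dict[str, Prior] = {
        "sigma_mu": Prior("flat"),
        "mu_sigma": Prior("flat"),
        "sigma_sigma": Prior("flat"),
        "mu_lambda": Prior("flat"),
        "sigma_lambda": Prior("flat"),
    }
    prior_map.update(priors or {})
    unknown = set(prior_map) - set(GROUP_PARAMETERS)
    if unknown:
        raise ValidationError(f"unknown reaction-time prior targets: {sorted(unknown)}")

    def log_likelihood(params):
        mu_i = params["mu"][:, idx]
        sigma_i = params["sigma"][:, idx]
        lam_i = params["lambda"][:, idx]
        u = (mu_i + lam_i * sigma_i**2 - t[None, :]) / (np.sqrt(2.0) * sigma_i)
        ll = (
            np.log(lam_i)
            + _LOG_HALF
            + _log_erfcx(u)
            - (t[None, :] - mu_i) ** 2 / (2.0 * sigma_i**2)
        ).sum(axis=1)
        # hierarchical priors on subject parameters
        ll += (
            -0.5 * ((params["mu"] - params["mu_mu"]) / params["sigma_mu"]) ** 2
            - np.log(params["sigma_mu"])
        ).sum(axis=1)
        ll += _truncated_normal_logpdf(
            params["sigma"], params["mu_sigma"], params["sigma_sigma"]
        ).sum(axis=1)
        ll += _truncated_normal_logpdf(
            params["lambda"], params["mu_lambda"], params["sigma_lambda"]
        ).sum(axis=1)
        return ll

    # data-scaled initialization: per-subject moments
    mu0 = np.zeros(n)
    sd0 = np.zeros(n)
    for j in range(n):
        tj = t[idx == j]
        mu0[j] = tj.min() if tj.size == 1 else np.quantile(tj, 0.2)
        sd0[j] = max(tj.std(), 1e-3 * max(tj.mean(), 1e-3))
    mean_tail = np.maximum(t.mean() - mu0.mean(), 1e-3)
    lam0 = 1.0 / mean_tail

    def init(rng):
        return {
            "mu": mu0,
            "sigma": sd0,
            "lambda": np.full(n, lam0),
            "mu_mu": np.array([mu0.mean()]),
            "sigma_mu": np.array([max(mu0.std(), 1e-2)]),
            "mu_sigma": np.array([max(sd0.mean(), 1e-2)]),
            "sigma_sigma": np.array([max(sd0.std(), 1e-2)]),
            "mu_lambda": np.array([lam0]),
            "sigma_lambda": np.array([max(0.2 * lam0, 1e-2)]),
        }

    model = ModelSpec(
        blocks=[
            ParameterBlock("mu", n, REAL),
            ParameterBlock("sigma", n, POSITIVE, jacobian=True),
            ParameterBlock("lambda", n, POSITIVE, jacobian=True),
            *_GROUP_BLOCKS,
        ],
        log_likelihood=log_likelihood,
        priors=prior_map,
        init=init,
    )
    all_draws = sample_posterior(model, settings)
    # block layout: mu(n), sigma(n), lambda(n), then the six group parameters
    subj_labels = [f"{p}[{i}]" for p in SUBJECT_PARAMETERS for i in range(1, n + 1)]
    from .draws import DrawMatrix

    return ReactionTimeFit(
        model="reaction_time",
        group=DrawMatrix(all_draws.values[:, :, 3 * n :], GROUP_PARAMETERS),
        subject=DrawMatrix(all_draws.values[:, :, : 3 * n], subj_labels),
        n_subjects=n,
        data=data,
        settings=settings,
    )


def rt_group_mean_draws(fit: ReactionTimeFit) -> np.ndarray:
    """Group-level expected reaction time per draw: E = mu_mu + 1/mu_lambda."""
    mu_mu = fit.group_draws("mu_mu")
    mu_lambda = fit.group_draws("mu_lambda")
    if np.any(mu_lambda <= 0):
        raise PsybayesError("internal inconsistency: non-positive mu_lambda draw")
    return mu_mu + 1.0 / mu_lambda
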