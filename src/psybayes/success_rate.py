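"""Hierarchical Bernoulli-Beta model for binary task outcomes.

Subject i succeeds with probability p_i; the subject rates are partially
pooled through a reparameterized Beta prior Beta(p*tau, (1-p)*tau), where p
is the group-level success rate and tau the concentration (larger tau means
less between-subject dispersion).  The group p carries a Beta(1, 1) prior
by default and tau a flat prior on its positive support; the group p draws
are the comparison currency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .errors import ValidationError
from .fits import BayesFit
from .priors import Prior
from .sampler import (
    POSITIVE,
    UNIT_INTERVAL,
    ModelSpec,
    ParameterBlock,
    SamplerSettings,
    sample_posterior,
)

__all__ = [
    "SuccessRateData",
    "SuccessRateFit",
    "reparam_beta_log_density",
    "fit_success_rate",
]


def reparam_beta_log_density(x, p, tau):
    """Log Beta density with shapes (p*tau, (1-p)*tau) at x in (0, 1)."""
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any((x <= 0) | (x >= 1)) or np.any((p <= 0) | (p >= 1)) or np.any(tau <= 0):
        raise ValidationError("need 0 < x < 1, 0 < p < 1 and tau > 0")
    a = p * tau
    b = (1.0 - p) * tau
    out = (
        (a - 1.0) * np.log(x)
        + (b - 1.0) * np.log1p(-x)
        - special.betaln(a, b)
    )
    return out if out.shape else float(out)


@dataclass
class SuccessRateData:
    """Validated (r, s) pairs: 0/1 outcomes linked to 1-based subject ids."""

    r: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r)
        s = np.asarray(self.s)
        if r.size != s.size or r.size == 0:
            raise ValidationError("r and s must be equally long and non-empty")
        rf = np.asarray(r, dtype=float)
        if not np.all(np.isin(rf, (0.0, 1.0))):
            raise ValidationError("outcomes must be binary 0/1")
        self.r = rf.astype(int)
        if not np.all(np.asarray(s, dtype=float) == np.floor(np.asarray(s, dtype=float))):
            raise ValidationError("subject ids must be integers")
        self.s = s = np.asarray(s, dtype=int)
        present = np.unique(s)
        if present[0] != 1 or not np.array_equal(present, np.arange(1, present.max() + 1)):
            raise ValidationError(
                "subject ids must run contiguously from 1 to n; re-index before fitting"
            )

    @property
    def n_subjects(self) -> int:
        return int(self.s.max())

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SuccessRateData":
        return cls(frame["result"].to_numpy(), frame["subject"].to_numpy())


class SuccessRateFit(BayesFit):
    """Hierarchical Bernoulli-Beta fit; subject parameter p, group p and tau."""


def fit_success_rate(
    data: SuccessRateData | pd.DataFrame,
    priors: dict[str, Prior] | None = None,
    settings: SamplerSettings | None = None,
) -> SuccessRateFit:
    """Fit the hierarchical success-rate model; group ``p`` draws compare groups."""
    if isinstance(data, pd.DataFrame):
        data = SuccessRateData.from_frame(data)
    settings = settings or SamplerSettings()
    n = data.n_subjects
    idx = data.s - 1
    successes = np.bincount(idx, weights=data.r, minlength=n)
    counts = np.bincount(idx, minlength=n).astype(float)

    # tau must be bounded: the subject rates can collapse onto the group
    # rate while tau grows without limit, so an unbounded flat prior would
    # leave the posterior improper.  Flat on (0, 500] is the default.
    prior_map: dict[str, Prior] = {
        "p": Prior("beta", (1.0, 1.0)),
        "tau": Prior("uniform", (0.0, 500.0)),
    }
    prior_map.update(priors or {})
    unknown = set(prior_map) - {"p", "tau"}
    if unknown:
        raise ValidationError(f"unknown success-rate prior targets: {sorted(unknown)}")

    def log_likelihood(params):
        p_i = params["p_subject"]  # (batch, n)
        p = params["p"]
        tau = params["tau"]
        ll = (successes[None, :] * np.log(p_i) + (counts - successes)[None, :] * np.log1p(-p_i)).sum(axis=1)
        a = p * tau
        b = (1.0 - p) * tau
        ll += (
            (a - 1.0) * np.log(p_i)
            + (b - 1.0) * np.log1p(-p_i)
            - special.betaln(a, b)
        ).sum(axis=1)
        return ll

    rate0 = np.clip((successes + 1.0) / (counts + 2.0), 0.02, 0.98)

    def init(rng):
        return {
            "p_subject": rate0,
            "p": np.array([float(np.clip(data.r.mean(), 0.05, 0.95))]),
            "tau": np.array([10.0]),
        }

    model = ModelSpec(
        blocks=[
            ParameterBlock("p_subject", n, UNIT_INTERVAL, jacobian=True),
            ParameterBlock("p", 1, UNIT_INTERVAL),
            ParameterBlock("tau", 1, POSITIVE),
        ],
        log_likelihood=log_likelihood,
        priors={"p_subject": None, **prior_map},
        init=init,
    )
    draws = sample_posterior(model, settings)
    from .draws import DrawMatrix

    # block layout: p_subject(n), then group p and tau
    subj_labels = [f"p[{i}]" for i in range(1, n + 1)]
    return SuccessRateFit(
        model="success_rate",
        group=DrawMatrix(draws.values[:, :, n : n + 2], ["p", "tau"]),
        subject=DrawMatrix(draws.values[:, :, :n], subj_labels),
        n_subjects=n,
        data=data,
        settings=settings,
    )
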