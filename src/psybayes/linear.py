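"""Hierarchical linear normal model for sequential tasks.

Responses of subject i follow y = alpha_i + beta_i * x + Normal(0, sigma_i)
with x the trial index (or time).  Subject intercepts, slopes and residual
scales are partially pooled through group-level normals N(mu_alpha,
sigma_alpha), N(mu_beta, sigma_beta) and N(mu_sigma, sigma_sigma), the last
truncated to positive support.  The comparison currency is selectable:
"intercept" (mu_alpha), "slope" (mu_beta) or "sigma" (mu_sigma).

x is used as given (no internal centering) so the intercept keeps its
interpretation at x = 0 / the start of the sequence; pass ``center_x=True``
to subtract the grand mean of x before fitting.
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
    REAL,
    ModelSpec,
    ParameterBlock,
    SamplerSettings,
    sample_posterior,
)

__all__ = ["SequentialData", "LinearFit", "fit_linear"]


@dataclass
class SequentialData:
    """Validated (x, y, s) triples with contiguous 1-based subject ids.

    Every subject needs at least two distinct x values so a subject-level
    slope is identified.
    """

    x: np.ndarray
    y: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).reshape(-1)
        self.y = np.asarray(self.y, dtype=float).reshape(-1)
        s = np.asarray(self.s).reshape(-1)
        if not (self.x.size == self.y.size == s.size) or self.x.size == 0:
            raise ValidationError("x, y and s must be equally long and non-empty")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValidationError("x and y must be finite")
        if not np.all(np.asarray(s, dtype=float) == np.floor(np.asarray(s, dtype=float))):
            raise ValidationError("subject ids must be integers")
        self.s = s = np.asarray(s, dtype=int)
        present = np.unique(s)
        if present[0] != 1 or not np.array_equal(present, np.arange(1, present.max() + 1)):
            raise ValidationError(
                "subject ids must run contiguously from 1 to n; re-index before fitting"
            )
        for j in present:
            xs = np.unique(self.x[s == j])
            if xs.size < 2:
                raise ValidationError(
                    f"subject {j} needs at least 2 distinct x values for a slope"
                )

    @property
    def n_subjects(self) -> int:
        return int(self.s.max())

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SequentialData":
        return cls(
            frame["sequence"].to_numpy(),
            frame["response"].to_numpy(),
            frame["subject"].to_numpy(),
        )


class LinearFit(BayesFit):
    """Hierarchical linear fit; subject params alpha, beta, sigma."""


GROUP_PARAMETERS = [
    "mu_alpha",
    "sigma_alpha",
    "mu_beta",
    "sigma_beta",
    "mu_sigma",
    "sigma_sigma",
]
SUBJECT_PARAMETERS = ["alpha", "beta", "sigma"]


def _truncated_normal_logpdf(x, mean, sd):
    z = (x - mean) / sd
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * z * z - special.log_ndtr(mean / sd)


def fit_linear(
    data: SequentialData | pd.DataFrame,
    priors: dict[str, Prior] | None = None,
    settings: SamplerSettings | None = None,
    center_x: bool = False,
) -> LinearFit:
    """Fit the hierarchical linear model to sequential-task data."""
    if isinstance(data, pd.DataFrame):
        data = SequentialData.from_frame(data)
    settings = settings or SamplerSettings()
    n = data.n_subjects
    idx = data.s - 1
    x = data.x - data.x.mean() if center_x else data.x
    y = data.y

    # flat on positive support for all positive group parameters (a flat
    # default on the log scale would be improper at zero)
    prior_map: dict[str, Prior] = {
        "sigma_alpha": Prior("flat"),
        "sigma_beta": Prior("flat"),
        "mu_sigma": Prior("flat"),
        "sigma_sigma": Prior("flat"),
    }
    prior_map.update(priors or {})
    unknown = set(prior_map) - set(GROUP_PARAMETERS)
    if unknown:
        raise ValidationError(f"unknown linear-model prior targets: {sorted(unknown)}")

    def log_likelihood(params):
        a_i = params["alpha"][:, idx]
        b_i = params["beta"][:, idx]
        s_i = params["sigma"][:, idx]
        resid = y[None, :] - a_i - b_i * x[None, :]
        ll = (-np.log(s_i) - 0.5 * (resid / s_i) ** 2).sum(axis=1)
        ll += (
            -np.log(params["sigma_alpha"])
            - 0.5 * ((params["alpha"] - params["mu_alpha"]) / params["sigma_alpha"]) ** 2
        ).sum(axis=1)
        ll += (
            -np.log(params["sigma_beta"])
            - 0.5 * ((params["beta"] - params["mu_beta"]) / params["sigma_beta"]) ** 2
        ).sum(axis=1)
        ll += _truncated_normal_logpdf(
            params["sigma"], params["mu_sigma"], params["sigma_sigma"]
        ).sum(axis=1)
        return ll

    # per-subject least-squares starting values
    a0 = np.zeros(n)
    b0 = np.zeros(n)
    s0 = np.zeros(n)
    for j in range(n):
        m = idx == j
        coef = np.polyfit(x[m], y[m], 1)
        b0[j], a0[j] = coef[0], coef[1]
        resid = y[m] - np.polyval(coef, x[m])
        s0[j] = max(float(resid.std()), 1e-3 * max(abs(y[m]).mean(), 1.0))

    def init(rng):
        return {
            "alpha": a0,
            "beta": b0,
            "sigma": s0,
            "mu_alpha": np.array([a0.mean()]),
            "sigma_alpha": np.array([max(a0.std(), 1e-2)]),
            "mu_beta": np.array([b0.mean()]),
            "sigma_beta": np.array([max(b0.std(), 1e-2)]),
            "mu_sigma": np.array([max(s0.mean(), 1e-2)]),
            "sigma_sigma": np.array([max(s0.std(), 1e-2)]),
        }

    model = ModelSpec(
        blocks=[
            ParameterBlock("alpha", n, REAL),
            ParameterBlock("beta", n, REAL),
            ParameterBlock("sigma", n, POSITIVE, jacobian=True),
            ParameterBlock("mu_alpha", 1, REAL),
            ParameterBlock("sigma_alpha", 1, POSITIVE),
            ParameterBlock("mu_beta", 1, REAL),
            ParameterBlock("sigma_beta", 1, POSITIVE),
            ParameterBlock("mu_sigma", 1, POSITIVE),
            ParameterBlock("sigma_sigma", 1, POSITIVE),
        ],
        log_likelihood=log_likelihood,
        priors=prior_map,
        init=init,
    )
    draws = sample_posterior(model, settings)
    from .draws import DrawMatrix

    subj_labels = [f"{p}[{i}]" for p in SUBJECT_PARAMETERS for i in range(1, n + 1)]
    return LinearFit(
        model="linear",
        group=DrawMatrix(draws.values[:, :, 3 * n :], GROUP_PARAMETERS),
        subject=DrawMatrix(draws.values[:, :, : 3 * n], subj_labels),
        n_subjects=n,
        data=data,
        settings=settings,
        extra={"centered": center_x},
    )
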