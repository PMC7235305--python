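"""Prior distributions attachable to model parameters.

Supported families: uniform, normal, gamma (shape/rate), beta, and flat.
A ``flat`` prior is improper and contributes zero log-density everywhere on
the parameter's declared support.  Parameters with *no* prior attached are
flat on the sampler's unconstrained scale instead (e.g. flat on log sigma
for a positive parameter); see the methods note for the distinction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = ["Prior", "prior_log_density", "parse_prior"]

_FAMILIES = ("uniform", "normal", "gamma", "beta", "flat")


@dataclass(frozen=True)
class Prior:
    """A named distribution family with its (family-specific) parameter pair.

    uniform: (lo, hi) with lo < hi; normal: (mean, sd) with sd > 0;
    gamma: (shape, rate), both > 0; beta: (alpha, beta), both > 0;
    flat: no parameters.
    """

    family: str
    parameters: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValidationError(f"unknown prior family {self.family!r}; choose from {_FAMILIES}")
        p = tuple(float(v) for v in self.parameters)
        object.__setattr__(self, "parameters", p)
        if self.family == "flat":
            if p:
                raise ValidationError("flat prior takes no parameters")
            return
        if len(p) != 2 or not all(np.isfinite(p)):
            raise ValidationError(f"{self.family} prior needs two finite parameters, got {p}")
        a, b = p
        if self.family == "uniform" and not a < b:
            raise ValidationError("uniform prior needs lo < hi")
        if self.family == "normal" and not b > 0:
            raise ValidationError("normal prior needs sd > 0")
        if self.family in ("gamma", "beta") and not (a > 0 and b > 0):
            raise ValidationError(f"{self.family} prior needs both parameters > 0")

    def log_density(self, value) -> np.ndarray:
        """Log prior density at ``value``; -inf outside the support."""
        x = np.asarray(value, dtype=float)
        if self.family == "flat":
            return np.zeros_like(x)
        a, b = self.parameters
        if self.family == "uniform":
            out = np.where((x >= a) & (x <= b), -np.log(b - a), -np.inf)
        elif self.family == "normal":
            out = stats.norm.logpdf(x, loc=a, scale=b)
        elif self.family == "gamma":
            out = stats.gamma.logpdf(x, a, scale=1.0 / b)
        else:  # beta
            out = stats.beta.logpdf(x, a, b)
        return np.where(np.isnan(out), -np.inf, out)


def prior_log_density(prior: Prior, value: float) -> float:
    """Log density of ``prior`` at a scalar ``value`` (-inf outside support)."""
    if not isinstance(prior, Prior):
        raise ValidationError("prior must be a Prior instance")
    return float(prior.log_density(value))


_PRIOR_RE = re.compile(
    r"^\s*(?P<family>[a-zA-Z]+)\s*(?:\(\s*(?P<args>[^)]*)\)\s*)?$"
)


def parse_prior(text: str) -> Prior:
    """Parse ``"normal(0, 10)"`` / ``"flat"`` style strings (config and CLI)."""
    m = _PRIOR_RE.match(text)
    if not m:
        raise ValidationError(f"cannot parse prior specification {text!r}")
    family = m.group("family").lower()
    args = m.group("args")
    if args is None or not args.strip():
        params: tuple[float, ...] = ()
    else:
        try:
            params = tuple(float(tok) for tok in args.split(","))
        except ValueError as exc:
            raise ValidationError(f"non-numeric prior parameters in {text!r}") from exc
    return Prior(family, params)
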