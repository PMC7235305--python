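"""Posterior comparison: pairwise and multi-group probabilities, ROPE, HDI.

The inference surface of the package.  Comparisons are *draw-aligned*: the
i-th draw of one group is compared with the i-th draw of the other, so two
groups fitted with identical sampler settings yield P(a > b) =
#{a_i > b_i}/n.  With a ROPE (region of practical equivalence) the draws
whose difference falls inside [lower, upper] count as "equal"; the strict
inequalities are evaluated on the remaining draws.  Exact ties without a
ROPE are split evenly between the two sides.  Multi-group comparisons
additionally report, per group, the probability that its draw is the
largest (or smallest) across groups at each draw index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .draws import HDInterval, compute_hdi
from .errors import (
    AlignmentError,
    CompatibilityError,
    UnsupportedOperationError,
    ValidationError,
)
from .fits import BayesFit

__all__ = [
    "RopeInterval",
    "PairComparison",
    "ComparisonResult",
    "mean_draws_of",
    "compare_means_pair",
    "compare_means_multi",
    "compare_mean_to_point",
    "compare_means",
    "posterior_predictive_draws",
    "compare_distributions",
]

_N_SEGMENTS = 20  # segments used for the Monte Carlo SE of a probability


@dataclass(frozen=True)
class RopeInterval:
    """Region of practical equivalence around a null difference."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValidationError("ROPE needs lower < upper")

    @classmethod
    def parse(cls, text: str) -> "RopeInterval":
        """Parse a "lo,hi" string (CLI form)."""
        try:
            lo, hi = (float(tok) for tok in text.split(","))
        except ValueError as exc:
            raise ValidationError(f"cannot parse ROPE {text!r}; expected 'lo,hi'") from exc
        return cls(lo, hi)


@dataclass(frozen=True)
class PairComparison:
    """P(i < j), P(i > j), optional P(equal within ROPE), HDI of i - j."""

    p_smaller: float
    p_greater: float
    p_equal: float | None
    hdi: HDInterval
    se: float  # segment-based Monte Carlo SE of p_greater

    def __post_init__(self) -> None:
        total = self.p_smaller + self.p_greater + (self.p_equal or 0.0)
        if abs(total - 1.0) > 1e-12:
            raise ValidationError("comparison probabilities must sum to 1")


@dataclass
class ComparisonResult:
    """Comparison of 2..k groups of aligned mean draws.

    ``pairs`` maps ordered index pairs (i, j), i < j, to their
    :class:`PairComparison` (differences are draws_i - draws_j); for k > 2
    ``p_largest``/``p_smallest`` give the per-group probabilities of having
    the largest/smallest value, ties split evenly.
    """

    n_groups: int
    pairs: dict[tuple[int, int], PairComparison]
    p_largest: np.ndarray | None = None
    p_smallest: np.ndarray | None = None
    rope: RopeInterval | None = None
    group_names: list[str] = field(default_factory=list)

    def pair(self, i: int = 0, j: int = 1) -> PairComparison:
        if i == j:
            raise ValidationError("a pair needs two distinct groups")
        if (i, j) in self.pairs:
            return self.pairs[(i, j)]
        p = self.pairs[(j, i)]  # mirror
        return PairComparison(
            p_smaller=p.p_greater,
            p_greater=p.p_smaller,
            p_equal=p.p_equal,
            hdi=HDInterval(-p.hdi.upper, -p.hdi.lower, p.hdi.mass),
            se=p.se,
        )

    def _name(self, i: int) -> str:
        return self.group_names[i] if self.group_names else f"group{i + 1}"

    def to_frame(self) -> pd.DataFrame:
        """Serializable table: one row per ordered pair plus extreme rows."""
        rows = []
        for (i, j), p in sorted(self.pairs.items()):
            rows.append(
                {
                    "comparison": f"{self._name(i)} vs {self._name(j)}",
                    "p_smaller": p.p_smaller,
                    "p_greater": p.p_greater,
                    "p_equal": p.p_equal if p.p_equal is not None else np.nan,
                    "hdi_lower": p.hdi.lower,
                    "hdi_upper": p.hdi.upper,
                    "se": p.se,
                }
            )
        frame = pd.DataFrame(rows)
        if self.p_largest is not None:
            extremes = pd.DataFrame(
                {
                    "comparison": [self._name(i) for i in range(self.n_groups)],
                    "p_largest": self.p_largest,
                    "p_smallest": self.p_smallest,
                }
            )
            frame = pd.concat([frame, extremes], ignore_index=True)
        return frame

    def __str__(self) -> str:
        return self.to_frame().to_string(index=False)


def mean_draws_of(fit: BayesFit, which: str | None = None) -> np.ndarray:
    """The draws that represent a fit's *mean*, the comparison currency.

    t-test: mu; reaction time: mu_mu + 1/mu_lambda; success rate: group p;
    linear: selector among intercept/slope/sigma; color: selector among
    r, g, b, h, s, v (component means; hue in radians, circular);
    bootstrap: the statistic draws.
    """
    model = getattr(fit, "model", None)
    if model == "ttest":
        return fit.group_draws("mu")
    if model == "reaction_time":
        from .reaction_time import rt_group_mean_draws

        return rt_group_mean_draws(fit)
    if model == "success_rate":
        return fit.group_draws("p")
    if model == "linear":
        selector = {"intercept": "mu_alpha", "slope": "mu_beta", "sigma": "mu_sigma"}
        if which not in selector:
            raise ValidationError(
                "linear fits need which='intercept'|'slope'|'sigma' to pick the mean draws"
            )
        return fit.group_draws(selector[which])
    if model == "color":
        if which not in ("r", "g", "b", "h", "s", "v"):
            raise ValidationError("color fits need which= one of r, g, b, h, s, v")
        return fit.group_draws(f"{which}_mu")
    if model == "bootstrap":
        draws = fit.statistic_draws
        if draws.ndim != 1:
            raise ValidationError("vector-valued bootstrap statistics cannot be compared")
        return draws
    raise UnsupportedOperationError(f"no mean draws defined for model {model!r}")


def _wrap_angles(d: np.ndarray) -> np.ndarray:
    """Wrap differences to (-pi, pi]."""
    return np.pi - np.mod(np.pi - d, 2.0 * np.pi)


def _segment_se(indicator: np.ndarray) -> float:
    n = indicator.size
    m = min(_N_SEGMENTS, n)
    segments = np.array_split(indicator.astype(float), m)
    means = np.array([seg.mean() for seg in segments])
    if m < 2:
        return 0.0
    return float(means.std(ddof=1) / np.sqrt(m))


def _pair_from_diff(d: np.ndarray, rope: RopeInterval | None) -> PairComparison:
    n = d.size
    if rope is not None:
        eq = (d >= rope.lower) & (d <= rope.upper)
        p_eq = eq.mean()
        p_gt = float(np.mean(d > rope.upper))
        p_lt = float(np.mean(d < rope.lower))
        result = PairComparison(
            p_smaller=p_lt,
            p_greater=p_gt,
            p_equal=float(p_eq),
            hdi=compute_hdi(d, 0.95),
            se=_segment_se(d > rope.upper),
        )
        return result
    gt = d > 0
    lt = d < 0
    ties = n - gt.sum() - lt.sum()
    p_gt = float((gt.sum() + 0.5 * ties) / n)
    p_lt = float((lt.sum() + 0.5 * ties) / n)
    return PairComparison(
        p_smaller=p_lt,
        p_greater=p_gt,
        p_equal=None,
        hdi=compute_hdi(d, 0.95),
        se=_segment_se(gt + 0.5 * (~gt & ~lt)),
    )


def _aligned(vectors: list[np.ndarray]) -> list[np.ndarray]:
    arrs = [np.asarray(v, dtype=float).reshape(-1) for v in vectors]
    lengths = {a.size for a in arrs}
    if len(lengths) != 1:
        raise AlignmentError(
            f"draw vectors have different lengths {sorted(lengths)}; "
            "re-run the fits with identical chains/iter settings"
        )
    if arrs[0].size < 2:
        raise AlignmentError("comparison needs at least 2 aligned draws")
    return arrs


def compare_means_pair(
    a, b, rope: RopeInterval | None = None, circular: bool = False
) -> ComparisonResult:
    """Index-aligned comparison of two draw vectors.

    ``circular=True`` wraps differences to (-pi, pi] for angular draws
    (hue); the ROPE is then interpreted on the wrapped scale.
    """
    a, b = _aligned([a, b])
    d = a - b
    if circular:
        d = _wrap_angles(d)
    return ComparisonResult(n_groups=2, pairs={(0, 1): _pair_from_diff(d, rope)}, rope=rope)


def compare_mean_to_point(
    a, point: float, rope: RopeInterval | None = None, circular: bool = False
) -> ComparisonResult:
    """Compare draws against a fixed reference value (e.g. zero)."""
    a = np.asarray(a, dtype=float).reshape(-1)
    if a.size == 0:
        raise ValidationError("need at least one draw")
    if a.size == 1:
        a = np.repeat(a, 2)
    return compare_means_pair(a, np.full(a.size, float(point)), rope=rope, circular=circular)


def compare_means_multi(
    draw_sets: list, rope: RopeInterval | None = None, circular: bool = False
) -> ComparisonResult:
    """All ordered-pair comparisons plus P(largest)/P(smallest) per group."""
    if len(draw_sets) < 2:
        raise ValidationError("need at least two draw sets")
    arrs = _aligned(list(draw_sets))
    k = len(arrs)
    pairs = {}
    for i in range(k):
        for j in range(i + 1, k):
            d = arrs[i] - arrs[j]
            if circular:
                d = _wrap_angles(d)
            pairs[(i, j)] = _pair_from_diff(d, rope)
    stacked = np.stack(arrs)  # (k, n)
    maxima = stacked == stacked.max(axis=0, keepdims=True)
    minima = stacked == stacked.min(axis=0, keepdims=True)
    p_largest = (maxima / maxima.sum(axis=0, keepdims=True)).mean(axis=1)
    p_smallest = (minima / minima.sum(axis=0, keepdims=True)).mean(axis=1)
    return ComparisonResult(
        n_groups=k,
        pairs=pairs,
        p_largest=p_largest,
        p_smallest=p_smallest,
        rope=rope,
    )


def compare_means(
    fits: list[BayesFit],
    which: str | None = None,
    rope: RopeInterval | None = None,
) -> ComparisonResult:
    """Convenience wrapper: extract each fit's mean draws, then compare.

    For color fits with ``which='h'`` the comparison is circular and a ROPE
    given in degrees is converted to radians.
    """
    if len(fits) < 2:
        raise ValidationError("need at least two fits to compare")
    circular = all(getattr(f, "model", None) == "color" for f in fits) and which == "h"
    if circular and rope is not None:
        rope = RopeInterval(np.deg2rad(rope.lower), np.deg2rad(rope.upper))
    draws = [mean_draws_of(f, which) for f in fits]
    if len(fits) == 2:
        result = compare_means_pair(draws[0], draws[1], rope=rope, circular=circular)
    else:
        result = compare_means_multi(draws, rope=rope, circular=circular)
    return result


def posterior_predictive_draws(
    fit: BayesFit,
    n_per_draw: int = 1,
    seed: int = 1,
    x: float | None = None,
    which: str | None = None,
) -> np.ndarray:
    """Simulate new observations from the likelihood at each posterior draw.

    linear fits need the predictor value ``x``; color fits need the
    component selector ``which``.
    """
    if n_per_draw < 1:
        raise ValidationError("n_per_draw must be >= 1")
    rng = np.random.default_rng(seed)
    model = getattr(fit, "model", None)
    if model == "ttest":
        from .ttest import posterior_predictive

        return posterior_predictive(fit, n_per_draw, rng)
    if model == "reaction_time":
        mu = np.repeat(fit.group_draws("mu_mu"), n_per_draw)
        sigma = np.repeat(fit.group_draws("mu_sigma"), n_per_draw)
        lam = np.repeat(fit.group_draws("mu_lambda"), n_per_draw)
        return rng.normal(mu, sigma) + rng.exponential(1.0 / lam)
    if model == "success_rate":
        p = np.repeat(fit.group_draws("p"), n_per_draw)
        return (rng.random(p.size) < p).astype(float)
    if model == "linear":
        if x is None:
            raise ValidationError("linear predictive draws need the predictor value x=")
        alpha = np.repeat(fit.group_draws("mu_alpha"), n_per_draw)
        beta = np.repeat(fit.group_draws("mu_beta"), n_per_draw)
        sigma = np.repeat(fit.group_draws("mu_sigma"), n_per_draw)
        return rng.normal(alpha + beta * float(x), sigma)
    if model == "color":
        if which not in ("r", "g", "b", "h", "s", "v"):
            raise ValidationError("color predictive draws need which= one of r,g,b,h,s,v")
        if which == "h":
            mu = np.repeat(fit.group_draws("h_mu"), n_per_draw)
            kappa = np.repeat(fit.group_draws("h_kappa"), n_per_draw)
            return np.mod(rng.vonmises(mu - np.pi, kappa) + np.pi, 2 * np.pi)
        hi = 255.0 if which in ("r", "g", "b") else 1.0
        mu = np.repeat(fit.group_draws(f"{which}_mu"), n_per_draw)
        sd = np.repeat(fit.group_draws(f"{which}_sigma"), n_per_draw)
        out = rng.normal(mu, sd)
        bad = (out < 0) | (out > hi)
        while np.any(bad):  # redraw outside the truncation interval
            out[bad] = rng.normal(mu[bad], sd[bad])
            bad = (out < 0) | (out > hi)
        return out
    raise UnsupportedOperationError(f"no predictive distribution for model {model!r}")


def compare_distributions(
    fits: list[BayesFit],
    rope: RopeInterval | None = None,
    n_per_draw: int = 1,
    seed: int = 1,
    x: float | None = None,
    which: str | None = None,
) -> ComparisonResult:
    """Compare entire posterior predictive distributions across fits."""
    if len(fits) < 2:
        raise ValidationError("need at least two fits to compare")
    models = {getattr(f, "model", None) for f in fits}
    if len(models) != 1:
        raise CompatibilityError(f"cannot compare distributions across models {sorted(map(str, models))}")
    circular = models == {"color"} and which == "h"
    if circular and rope is not None:
        rope = RopeInterval(np.deg2rad(rope.lower), np.deg2rad(rope.upper))
    draws = [
        posterior_predictive_draws(f, n_per_draw=n_per_draw, seed=seed + i, x=x, which=which)
        for i, f in enumerate(fits)
    ]
    if len(fits) == 2:
        return compare_means_pair(draws[0], draws[1], rope=rope, circular=circular)
    return compare_means_multi(draws, rope=rope, circular=circular)
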