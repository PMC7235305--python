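"""Posterior draw containers and convergence/summary machinery.

The universal currency of the package is the :class:`DrawMatrix`: posterior
draws arranged as ``(chain, iteration, parameter)``.  On top of it live the
highest-density interval, split-R-hat, effective sample size, Monte Carlo
standard errors and the tabular summary that mirrors a sampler's
``print``/``show`` output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateChainError, UnknownParameterError, ValidationError

__all__ = [
    "DrawMatrix",
    "HDInterval",
    "ConvergenceReport",
    "compute_hdi",
    "circular_hdi",
    "split_rhat",
    "effective_sample_size",
    "summarize_fit",
    "summarize_draws",
    "extract_group_draws",
    "extract_subject_draws",
]


@dataclass
class DrawMatrix:
    """Posterior draws with shape ``(chains, iterations, parameters)``.

    Parameters are addressed by name; vector-valued model blocks use
    bracketed, 1-based labels such as ``"mu[3]"``.
    """

    values: np.ndarray
    parameter_names: list[str]
    warmup_discarded: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("DrawMatrix values must be (chains, iterations, parameters)")
        c, n, p = self.values.shape
        if n < 1 or c < 1:
            raise ValidationError("DrawMatrix needs at least one chain and one iteration")
        if len(self.parameter_names) != p:
            raise ValidationError("parameter_names length must match the parameter axis")
        if len(set(self.parameter_names)) != p:
            raise ValidationError("parameter_names must be unique")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_chains(self) -> int:
        return self.values.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.values.shape[1]

    @property
    def n_parameters(self) -> int:
        return self.values.shape[2]

    def _index(self, parameter: str) -> int:
        try:
            return self.parameter_names.index(parameter)
        except ValueError:
            raise UnknownParameterError(parameter, self.parameter_names) from None

    def chains_for(self, parameter: str) -> np.ndarray:
        """Draws for one parameter, shape ``(chains, iterations)``."""
        return self.values[:, :, self._index(parameter)]

    def flatten(self, parameter: str) -> np.ndarray:
        """Post-warmup draws flattened chain-major, length chains*iterations."""
        return self.chains_for(parameter).reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with chain and iteration columns (1-based)."""
        c, n, p = self.values.shape
        frame = pd.DataFrame(
            self.values.reshape(c * n, p), columns=self.parameter_names
        )
        frame.insert(0, "iteration", np.tile(np.arange(1, n + 1), c))
        frame.insert(0, "chain", np.repeat(np.arange(1, c + 1), n))
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DrawMatrix":
        """Inverse of :meth:`to_frame`."""
        names = [c for c in frame.columns if c not in ("chain", "iteration")]
        chains = np.sort(frame["chain"].unique())
        values = np.stack(
            [
                frame.loc[frame["chain"] == ch].sort_values("iteration")[names].to_numpy()
                for ch in chains
            ]
        )
        return cls(values, list(names))


@dataclass(frozen=True)
class HDInterval:
    """Highest density interval: shortest interval holding ``mass`` posterior mass."""

    lower: float
    upper: float
    mass: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 < self.mass < 1.0):
            raise ValidationError("HDI mass must lie in (0, 1)")
        if self.lower > self.upper:
            raise ValidationError("HDI lower bound exceeds upper bound")

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


def compute_hdi(draws: np.ndarray, mass: float = 0.95) -> HDInterval:
    """Shortest contiguous interval containing ``ceil(mass*n)`` sorted draws.

    Ties between equally short windows are broken towards the smallest
    lower bound (Kruschke's convention, made deterministic).
    """
    draws = np.asarray(draws, dtype=float).reshape(-1)
    if draws.size < 2:
        raise ValidationError("HDI needs at least 2 draws")
    if not (0.0 < mass < 1.0):
        raise ValidationError("HDI mass must lie in (0, 1)")
    if not np.all(np.isfinite(draws)):
        raise ValidationError("HDI draws must be finite")
    sorted_draws = np.sort(draws)
    n = sorted_draws.size
    k = int(np.ceil(mass * n))
    k = max(k, 2)
    widths = sorted_draws[k - 1 :] - sorted_draws[: n - k + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum: smallest lower bound
    return HDInterval(float(sorted_draws[i]), float(sorted_draws[i + k - 1]), mass)


def circular_hdi(angles: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest arc on the circle containing ``mass`` of the draws (radians).

    Returns ``(start, end)`` with both in ``[0, 2*pi)``; the arc runs
    counter-clockwise from start to end and may wrap through zero
    (in which case ``start > end``).
    """
    theta = np.mod(np.asarray(angles, dtype=float).reshape(-1), 2 * np.pi)
    if theta.size < 2:
        raise ValidationError("circular HDI needs at least 2 draws")
    theta = np.sort(theta)
    n = theta.size
    k = max(int(np.ceil(mass * n)), 2)
    doubled = np.concatenate([theta, theta + 2 * np.pi])
    widths = doubled[k - 1 : k - 1 + n] - theta
    i = int(np.argmin(widths))
    start = theta[i]
    end = doubled[i + k - 1] % (2 * np.pi)
    return float(start), float(end)


def _split_chains(x: np.ndarray) -> np.ndarray:
    """Split each chain in half; drops the middle draw of odd-length chains."""
    c, n = x.shape
    half = n // 2
    if half < 1:
        raise ValidationError("split diagnostics need at least 2 iterations per chain")
    first = x[:, :half]
    second = x[:, n - half :]
    return np.concatenate([first, second], axis=0)


def _rhat_from_chains(x: np.ndarray) -> float:
    m, n = x.shape
    within = x.var(axis=1, ddof=1)
    w = within.mean()
    if not np.isfinite(w) or w <= 0.0:
        raise DegenerateChainError("zero within-chain variance; R-hat undefined")
    if m < 2:
        return 1.0
    b = n * x.mean(axis=1).var(ddof=1)
    var_plus = ((n - 1) * w + b) / n
    return float(np.sqrt(var_plus / w))


def split_rhat(draws: DrawMatrix | np.ndarray, parameter: str | None = None) -> float:
    """Potential scale reduction factor on split chains; 1 at convergence.

    ``sqrt(var_plus / W)`` with ``var_plus = ((n-1)W + B)/n`` computed over
    the half-chains.
    """
    x = draws.chains_for(parameter) if isinstance(draws, DrawMatrix) else np.asarray(draws, float)
    if x.ndim == 1:
        x = x[None, :]
    return _rhat_from_chains(_split_chains(x))


def _autocovariance(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance of one chain via FFT, lags 0..n-1."""
    n = x.size
    xc = x - x.mean()
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, size)
    acov = np.fft.irfft(f * np.conjugate(f), size)[:n].real
    return acov / n


def effective_sample_size(
    draws: DrawMatrix | np.ndarray, parameter: str | None = None
) -> float:
    """Autocorrelation-based effective sample size across chains.

    Uses the multi-chain autocorrelation estimate based on ``var_plus`` with
    Geyer's initial-positive-sequence truncation; the estimate is capped at
    the total draw count (no super-efficiency reported).
    """
    x = draws.chains_for(parameter) if isinstance(draws, DrawMatrix) else np.asarray(draws, float)
    if x.ndim == 1:
        x = x[None, :]
    m, n = x.shape
    if n < 2:
        raise ValidationError("ESS needs at least 2 iterations per chain")
    within = x.var(axis=1, ddof=1)
    w = within.mean()
    if not np.isfinite(w) or w <= 0.0:
        raise DegenerateChainError("zero within-chain variance; ESS undefined")
    if m >= 2:
        b = n * x.mean(axis=1).var(ddof=1)
        var_plus = ((n - 1) * w + b) / n
    else:
        var_plus = (n - 1) * w / n
    acov = np.stack([_autocovariance(x[j]) for j in range(m)]).mean(axis=0)
    # multi-chain autocorrelation (Gelman et al. style): rho_t = 1 - (W - acov_t)/var_plus
    rho = 1.0 - (w - acov) / var_plus
    rho[0] = 1.0
    total = m * n
    # Geyer initial positive sequence over paired sums
    tau = -rho[0]
    t = 0
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0.0:
            break
        tau += 2.0 * pair
        t += 2
    if tau <= 0.0:
        return float(total)
    return float(min(total, total / tau))


@dataclass
class ConvergenceReport:
    """Per-parameter posterior summary with Monte Carlo diagnostics.

    Columns mirror the conventional sampler print-out: mean, se_mean, sd,
    central 2.5%/97.5% quantiles, n_eff and Rhat.
    """

    table: pd.DataFrame = field(repr=False)

    COLUMNS = ["parameter", "mean", "se_mean", "sd", "2.5%", "97.5%", "n_eff", "Rhat"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"summary table missing columns: {missing}")

    def row(self, parameter: str) -> pd.Series:
        match = self.table[self.table["parameter"] == parameter]
        if match.empty:
            raise UnknownParameterError(parameter, list(self.table["parameter"]))
        return match.iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __str__(self) -> str:
        return self.table.to_string(index=False, float_format=lambda v: f"{v:.4f}")


def summarize_draws(draws: DrawMatrix) -> ConvergenceReport:
    """Summary rows for every parameter of a draw matrix."""
    rows = []
    for name in draws.parameter_names:
        x = draws.chains_for(name)
        flat = x.reshape(-1)
        n_eff = effective_sample_size(draws, name)
        rhat = split_rhat(draws, name)
        sd = float(flat.std(ddof=1))
        rows.append(
            {
                "parameter": name,
                "mean": float(flat.mean()),
                "se_mean": sd / np.sqrt(n_eff),
                "sd": sd,
                "2.5%": float(np.quantile(flat, 0.025)),
                "97.5%": float(np.quantile(flat, 0.975)),
                "n_eff": n_eff,
                "Rhat": rhat,
            }
        )
    return ConvergenceReport(pd.DataFrame(rows, columns=ConvergenceReport.COLUMNS))


def summarize_fit(fit) -> ConvergenceReport:
    """Summary rows for every group-level and subject-level parameter of a fit."""
    tables = [summarize_draws(fit.group).table]
    subject = getattr(fit, "subject", None)
    if subject is not None:
        tables.append(summarize_draws(subject).table)
    table = pd.concat(tables, ignore_index=True)
    if table.empty:
        raise ValidationError("fit contains no parameters")
    return ConvergenceReport(table)


def extract_group_draws(fit, parameter: str) -> np.ndarray:
    """Flattened chain-major post-warmup draws of a group-level parameter."""
    return fit.group.flatten(parameter)


def extract_subject_draws(fit, parameter: str, subject: int) -> np.ndarray:
    """Draws of one subject's parameter from a hierarchical fit (1-based subject)."""
    from .errors import UnsupportedOperationError  # local to avoid cycle on partial init

    subject_draws = getattr(fit, "subject", None)
    n_subjects = getattr(fit, "n_subjects", None)
    if subject_draws is None or not n_subjects:
        raise UnsupportedOperationError(
            f"{getattr(fit, 'model', 'this')} fit has no subject-level parameters"
        )
    if not (1 <= subject <= n_subjects):
        raise IndexError(f"subject must be in 1..{n_subjects}, got {subject}")
    label = f"{parameter}[{subject}]"
    return subject_draws.flatten(label)
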