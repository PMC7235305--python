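"""Six-component Bayesian color model with RGB/HSV conversion.

Color responses are modelled component-wise: the red, green and blue
channels with normal distributions truncated to [0, 255]; saturation and
value with normals truncated to [0, 1]; and hue — an angle — with the von
Mises (circular normal) distribution.  Whichever color space the data
arrive in, the other is derived per row, and all six components are fitted
independently.  Hue is handled in radians internally and degrees at the
interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb as _mpl_hsv_to_rgb
from matplotlib.colors import rgb_to_hsv as _mpl_rgb_to_hsv
from scipy import special

from .draws import DrawMatrix
from .errors import UndefinedMeanError, ValidationError
from .fits import BayesFit
from .sampler import (
    CIRCULAR,
    POSITIVE,
    REAL,
    ModelSpec,
    ParameterBlock,
    SamplerSettings,
    sample_posterior,
)

__all__ = [
    "ColorData",
    "ColorFit",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "von_mises_log_density",
    "circular_mean",
    "fit_color",
]

RGB_COMPONENTS = ("r", "g", "b")
HSV_COMPONENTS = ("h", "s", "v")


def rgb_to_hsv(r, g, b):
    """(r, g, b) in 0..255 -> (hue degrees in [0, 360), s, v in [0, 1]).

    Standard hexcone conversion; achromatic input (s = 0) maps to hue 0.
    """
    rgb = np.stack(np.broadcast_arrays(np.asarray(r, float), np.asarray(g, float), np.asarray(b, float)), axis=-1)
    if np.any((rgb < 0) | (rgb > 255)):
        raise ValidationError("RGB components must lie in [0, 255]")
    hsv = _mpl_rgb_to_hsv(rgb / 255.0)
    h = np.mod(hsv[..., 0] * 360.0, 360.0)
    out = h, hsv[..., 1], hsv[..., 2]
    if np.isscalar(r) or np.asarray(r).ndim == 0:
        return tuple(float(v) for v in out)
    return out


def hsv_to_rgb(h, s, v):
    """(hue degrees, s, v) -> (r, g, b) in 0..255 (floats, not rounded)."""
    h = np.mod(np.asarray(h, float), 360.0) / 360.0
    s = np.asarray(s, float)
    v = np.asarray(v, float)
    if np.any((s < 0) | (s > 1)) or np.any((v < 0) | (v > 1)):
        raise ValidationError("saturation and value must lie in [0, 1]")
    rgb = _mpl_hsv_to_rgb(np.stack(np.broadcast_arrays(h, s, v), axis=-1)) * 255.0
    out = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    if np.asarray(h).ndim == 0:
        return tuple(float(x) for x in out)
    return out


def von_mises_log_density(theta, mu, kappa):
    """Log density kappa*cos(theta-mu) - log(2*pi*I0(kappa)); kappa=0 is uniform."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValidationError("von Mises concentration kappa must be >= 0")
    theta = np.asarray(theta, dtype=float)
    mu = np.asarray(mu, dtype=float)
    # log I0(k) = log i0e(k) + k keeps large kappa finite
    out = kappa * (np.cos(theta - mu) - 1.0) - np.log(2.0 * np.pi * special.i0e(kappa))
    return out if out.shape else float(out)


def circular_mean(angles) -> float:
    """Mean direction of angles in radians, wrapped to [0, 2*pi).

    Raises when the resultant vector length is numerically zero (e.g. an
    antipodal pair), in which case the mean direction is undefined.
    """
    theta = np.asarray(angles, dtype=float).reshape(-1)
    if theta.size == 0:
        raise ValidationError("circular_mean needs at least one angle")
    sin_bar = np.mean(np.sin(theta))
    cos_bar = np.mean(np.cos(theta))
    if np.hypot(sin_bar, cos_bar) < 1e-8:
        raise UndefinedMeanError("resultant length ~ 0: circular mean undefined")
    mean = float(np.mod(np.arctan2(sin_bar, cos_bar), 2.0 * np.pi))
    return 0.0 if 2.0 * np.pi - mean < 1e-12 else mean


@dataclass
class ColorData:
    """A table of color triplets, RGB in [0, 255] or HSV (hue in degrees)."""

    values: np.ndarray
    is_hsv: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValidationError("color data must be a three-column table")
        if v.shape[0] < 2:
            raise ValidationError("color model needs at least 2 rows")
        if self.is_hsv:
            ok = (
                np.all((v[:, 0] >= 0) & (v[:, 0] < 360))
                and np.all((v[:, 1] >= 0) & (v[:, 1] <= 1))
                and np.all((v[:, 2] >= 0) & (v[:, 2] <= 1))
            )
            if not ok:
                raise ValidationError("HSV rows need hue in [0,360), s and v in [0,1]")
        elif np.any((v < 0) | (v > 255)):
            raise ValidationError("RGB rows must lie in [0, 255]")
        self.values = v

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, is_hsv: bool = False) -> "ColorData":
        cols = ["h", "s", "v"] if is_hsv else ["r", "g", "b"]
        if all(c in frame.columns for c in cols):
            frame = frame[cols]
        return cls(frame.to_numpy(dtype=float), is_hsv=is_hsv)

    def both_spaces(self) -> dict[str, np.ndarray]:
        """Per-component observation vectors in both color spaces."""
        if self.is_hsv:
            h, s, v = self.values.T
            r, g, b = hsv_to_rgb(h, s, v)
        else:
            r, g, b = self.values.T
            h, s, v = rgb_to_hsv(r, g, b)
        return {"r": r, "g": g, "b": b, "h": np.deg2rad(h), "s": s, "v": v}


class ColorFit(BayesFit):
    """Component-wise color fit.

    Group parameters: ``{c}_mu`` / ``{c}_sigma`` for c in r, g, b, s, v
    (truncated-normal mean and sd) and ``h_mu`` (radians, [0, 2*pi)) /
    ``h_kappa`` for hue.
    """


def _fit_truncated_normal(x: np.ndarray, lo: float, hi: float, settings, seed: int):
    if np.ptp(x) <= 1e-9 * max(abs(float(x[0])), 1.0):
        raise ValidationError(
            "degenerate component: all values identical; add measurement jitter"
        )

    def log_likelihood(params):
        m = params["mu"]
        sd = params["sigma"]
        a = (lo - m) / sd
        b = (hi - m) / sd
        z = special.ndtr(b) - special.ndtr(a)
        ll = (
            -0.5 * ((x[None, :] - m) / sd) ** 2
        ).sum(axis=1) - x.size * (np.log(sd[:, 0]) + np.log(np.maximum(z[:, 0], 1e-300)))
        return ll

    from .priors import Prior

    model = ModelSpec(
        blocks=[ParameterBlock("mu", 1, REAL), ParameterBlock("sigma", 1, POSITIVE)],
        log_likelihood=log_likelihood,
        priors={"sigma": Prior("flat")},
        init=lambda rng: {
            "mu": np.array([float(np.mean(x))]),
            "sigma": np.array([max(float(np.std(x)), 1e-3 * (hi - lo))]),
        },
    )
    local = SamplerSettings(settings.chains, settings.warmup, settings.iter, seed)
    return sample_posterior(model, local)


def _fit_von_mises(theta: np.ndarray, settings, seed: int):
    if np.ptp(np.mod(theta, 2 * np.pi)) <= 1e-9:
        raise ValidationError(
            "degenerate hue component: all angles identical; add measurement jitter"
        )
    center = circular_mean(theta)

    def log_likelihood(params):
        mu = params["mu"]
        kappa = params["kappa"]
        c = np.cos(theta[None, :] - mu).sum(axis=1)
        return kappa[:, 0] * (c - theta.size) - theta.size * np.log(
            2.0 * np.pi * special.i0e(kappa[:, 0])
        )

    r_len = np.hypot(np.mean(np.sin(theta)), np.mean(np.cos(theta)))
    kappa0 = max(float(r_len * (2 - r_len**2) / max(1 - r_len**2, 1e-6)), 0.5)
    from .priors import Prior

    model = ModelSpec(
        blocks=[ParameterBlock("mu", 1, CIRCULAR), ParameterBlock("kappa", 1, POSITIVE)],
        log_likelihood=log_likelihood,
        priors={"kappa": Prior("flat")},
        init=lambda rng: {"mu": np.array([center]), "kappa": np.array([kappa0])},
    )
    local = SamplerSettings(settings.chains, settings.warmup, settings.iter, seed)
    return sample_posterior(model, local)


def fit_color(
    data: ColorData | pd.DataFrame | np.ndarray,
    settings: SamplerSettings | None = None,
    is_hsv: bool = False,
) -> ColorFit:
    """Fit all six color components independently.

    The missing color space is derived per row first; truncated-normal
    likelihoods include their truncation normalizing constants.
    """
    if isinstance(data, pd.DataFrame):
        data = ColorData.from_frame(data, is_hsv=is_hsv)
    elif not isinstance(data, ColorData):
        data = ColorData(np.asarray(data), is_hsv=is_hsv)
    settings = settings or SamplerSettings()
    comps = data.both_spaces()

    pieces: list[np.ndarray] = []
    names: list[str] = []
    for offset, c in enumerate(("r", "g", "b")):
        d = _fit_truncated_normal(comps[c], 0.0, 255.0, settings, settings.seed + offset)
        pieces.append(d.values)
        names += [f"{c}_mu", f"{c}_sigma"]
    d = _fit_von_mises(comps["h"], settings, settings.seed + 3)
    pieces.append(d.values)
    names += ["h_mu", "h_kappa"]
    for offset, c in enumerate(("s", "v"), start=4):
        d = _fit_truncated_normal(comps[c], 0.0, 1.0, settings, settings.seed + offset)
        pieces.append(d.values)
        names += [f"{c}_mu", f"{c}_sigma"]
    group = DrawMatrix(np.concatenate(pieces, axis=2), names)
    return ColorFit(model="color", group=group, data=data, settings=settings)
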