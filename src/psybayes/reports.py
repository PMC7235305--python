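"""Plot-ready numeric summaries and their rendering helpers.

Every figure the package can draw is backed by a :class:`PlotSummary` — a
pure numeric payload (histogram bins, HDI band endpoints, trace series,
hue bands) computed from draws alone, so visual output is unit-testable
without image comparison.  Rendering to matplotlib lives behind that
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .draws import DrawMatrix, circular_hdi, compute_hdi
from .errors import ValidationError
from .compare import RopeInterval, _aligned

__all__ = [
    "PlotSummary",
    "difference_summary",
    "trace_summary",
    "means_summary",
    "color_wheel_summary",
    "render",
]


@dataclass
class PlotSummary:
    """kind in {trace, fit, means, difference, color_wheel} + numeric payload."""

    kind: str
    payload: dict = field(default_factory=dict)


def difference_summary(
    a, b, rope: RopeInterval | None = None, bins: int = 30
) -> PlotSummary:
    """Histogram of aligned differences with mean line, HDI and ROPE bands."""
    if bins < 1:
        raise ValidationError("bins must be positive")
    a, b = _aligned([a, b])
    d = a - b
    if np.ptp(d) == 0.0:
        edges = np.linspace(d[0] - 0.5, d[0] + 0.5, bins + 1)
        counts, edges = np.histogram(d, bins=edges)
        hdi = (float(d[0]), float(d[0]))
    else:
        counts, edges = np.histogram(d, bins=bins)
        h = compute_hdi(d, 0.95)
        hdi = (h.lower, h.upper)
    payload = {
        "bin_edges": edges,
        "counts": counts,
        "mean": float(d.mean()),
        "hdi": hdi,
    }
    if rope is not None:
        payload["rope"] = (rope.lower, rope.upper)
    return PlotSummary("difference", payload)


def trace_summary(draws: DrawMatrix, parameter: str) -> PlotSummary:
    """Per-chain trace series for one parameter."""
    return PlotSummary(
        "trace",
        {
            "parameter": parameter,
            "series": draws.chains_for(parameter),
            "iterations": np.arange(1, draws.n_iterations + 1),
        },
    )


def means_summary(draw_sets: list, bins: int = 30) -> PlotSummary:
    """Histograms of each group's mean draws on a common grid."""
    arrs = [np.asarray(v, float).reshape(-1) for v in draw_sets]
    lo = min(a.min() for a in arrs)
    hi = max(a.max() for a in arrs)
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, bins + 1)
    counts = [np.histogram(a, bins=edges)[0] for a in arrs]
    hdis = [compute_hdi(a, 0.95) if a.size > 1 else None for a in arrs]
    return PlotSummary(
        "means",
        {
            "bin_edges": edges,
            "counts": counts,
            "means": [float(a.mean()) for a in arrs],
            "hdis": [(h.lower, h.upper) if h else None for h in hdis],
        },
    )


def color_wheel_summary(fit, mass: float = 0.95, annotations: dict | None = None) -> PlotSummary:
    """Hue mean angle and circular HDI band in degrees for a color fit.

    ``annotations`` (name -> hue degrees) pass through unchanged, as slots
    for external reference hues (e.g. theory-predicted responses).
    """
    h = fit.group_draws("h_mu")
    mean_deg = float(np.rad2deg(_circular_mean_safe(h)))
    if np.ptp(h) == 0.0:
        band = (mean_deg, mean_deg)
    else:
        lo, hi = circular_hdi(h, mass)
        band = (float(np.rad2deg(lo)), float(np.rad2deg(hi)))
    return PlotSummary(
        "color_wheel",
        {
            "mean_deg": mean_deg,
            "hdi_deg": band,
            "mass": mass,
            "annotations": dict(annotations or {}),
        },
    )


def _circular_mean_safe(h):
    from .color import circular_mean

    return circular_mean(h)


def render(summary: PlotSummary, path) -> None:
    """Draw a PlotSummary to an image file with matplotlib (Agg backend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    p = summary.payload
    if summary.kind == "difference":
        widths = np.diff(p["bin_edges"])
        ax.bar(p["bin_edges"][:-1], p["counts"], width=widths, align="edge", color="#4477aa")
        ax.axvline(p["mean"], color="blue")
        y0 = -0.03 * max(p["counts"].max(), 1)
        ax.plot(list(p["hdi"]), [y0, y0], color="black", lw=4)
        if "rope" in p:
            ax.plot(list(p["rope"]), [2 * y0, 2 * y0], color="gray", lw=4)
        ax.set_xlabel("difference")
    elif summary.kind == "trace":
        for i, series in enumerate(p["series"]):
            ax.plot(p["iterations"], series, lw=0.6, label=f"chain {i + 1}")
        ax.set_xlabel("iteration")
        ax.set_ylabel(p["parameter"])
        ax.legend(fontsize=7)
    elif summary.kind == "means":
        centers = 0.5 * (p["bin_edges"][:-1] + p["bin_edges"][1:])
        for i, counts in enumerate(p["counts"]):
            ax.step(centers, counts, where="mid", label=f"group {i + 1}")
        ax.legend(fontsize=7)
        ax.set_xlabel("mean")
    elif summary.kind == "color_wheel":
        ax.remove()
        ax = fig.add_subplot(projection="polar")
        mean = np.deg2rad(p["mean_deg"])
        lo, hi = np.deg2rad(p["hdi_deg"][0]), np.deg2rad(p["hdi_deg"][1])
        if hi < lo:
            hi += 2 * np.pi
        arc = np.linspace(lo, hi, 100)
        ax.plot(arc, np.ones_like(arc), lw=6, color="#cc6677")
        ax.plot([mean, mean], [0.0, 1.0], color="black")
        for name, deg in p["annotations"].items():
            th = np.deg2rad(deg)
            ax.plot([th, th], [0.0, 1.1], ls="--", lw=1)
            ax.text(th, 1.15, name, fontsize=7)
        ax.set_yticks([])
    else:
        raise ValidationError(f"cannot render summary kind {summary.kind!r}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
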