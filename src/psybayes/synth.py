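"""Seeded synthetic-experiment generators with recorded ground truth.

These emulate the structure of four classic psychology experiments — a
flanker task (reaction times + correctness, control vs. test group), an
adaptation-level weight-assessment task (per-subject linear trends), a
Stroop color-word test (paired completion times across four conditions) and
an afterimages color-matching task (circular hue responses) — so that every
analysis workflow in the package can run end-to-end without any external
data.  Each generator records the generating parameters for recovery tests;
regenerating with the same seed reproduces the table exactly.  The tables
are synthetic stand-ins; they are not the original experiments' data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .color import hsv_to_rgb, rgb_to_hsv
from .errors import ValidationError

__all__ = [
    "SyntheticDataset",
    "generate_flanker",
    "generate_adaptation",
    "generate_stroop",
    "generate_afterimages",
    "DEFAULT_STIMULI",
]


@dataclass
class SyntheticDataset:
    """A generated experiment table plus its generating parameters."""

    frame: pd.DataFrame
    ground_truth: dict
    seed: int

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _truncated_positive_normal(rng, mean, sd, size):
    """Draws from N(mean, sd) truncated to (0, inf), matching the model priors."""
    a = (0.0 - mean) / sd
    return stats.truncnorm(a, np.inf, loc=mean, scale=sd).rvs(size=size, random_state=rng)


def generate_flanker(
    n_per_group: int = 22,
    trials: int = 80,
    group_shift: float = 0.05,
    error_rate_gap: float = 0.01,
    seed: int = 1,
    raw_ids: bool = False,
    mu_mu: float = 0.40,
    sigma_mu: float = 0.04,
    mu_sigma: float = 0.06,
    sigma_sigma: float = 0.01,
    mu_lambda: float = 10.0,
    sigma_lambda: float = 1.5,
    p_correct: float = 0.95,
    tau: float = 60.0,
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Reaction-time and correctness tables for a control vs. test group.

    Per-subject exGaussian parameters are drawn from group-level normals;
    the test group's mu_mu is shifted by ``group_shift`` seconds and its
    per-trial correctness probability lowered by ``error_rate_gap``.
    ``raw_ids=True`` offsets subject ids (exercises the re-indexing
    validation of the models).  Returns (reaction_times, correctness).
    """
    if n_per_group < 1 or trials < 1:
        raise ValidationError("n_per_group and trials must be positive")
    if not 0 < p_correct < 1 or not 0 <= error_rate_gap < p_correct:
        raise ValidationError("correctness rates must stay inside (0, 1)")
    if mu_mu + group_shift <= 0:
        raise ValidationError("group_shift would push mean reaction times negative")
    rng = np.random.default_rng(seed)
    rt_rows = []
    correct_rows = []
    truth_subjects = {}
    for group, shift, p_ok in (
        ("control", 0.0, p_correct),
        ("test", group_shift, p_correct - error_rate_gap),
    ):
        mu_i = rng.normal(mu_mu + shift, sigma_mu, n_per_group)
        sigma_i = _truncated_positive_normal(rng, mu_sigma, sigma_sigma, n_per_group)
        lambda_i = _truncated_positive_normal(rng, mu_lambda, sigma_lambda, n_per_group)
        p_i = rng.beta(p_ok * tau, (1 - p_ok) * tau, n_per_group)
        truth_subjects[group] = {"mu": mu_i, "sigma": sigma_i, "lambda": lambda_i, "p": p_i}
        offset = 21 if raw_ids else 0
        for j in range(n_per_group):
            sid = j + 1 + offset
            t = rng.normal(mu_i[j], sigma_i[j], trials) + rng.exponential(
                1.0 / lambda_i[j], trials
            )
            t = np.maximum(t, 1e-3)
            ok = (rng.random(trials) < p_i[j]).astype(int)
            for k in range(trials):
                rt_rows.append((group, sid, ok[k], t[k]))
                correct_rows.append((group, sid, ok[k]))
    rt = pd.DataFrame(rt_rows, columns=["group", "subject", "correct", "rt"])
    cr = pd.DataFrame(correct_rows, columns=["group", "subject", "result"])
    truth = {
        "mu_mu": {"control": mu_mu, "test": mu_mu + group_shift},
        "group_mean": {
            "control": mu_mu + 1.0 / mu_lambda,
            "test": mu_mu + group_shift + 1.0 / mu_lambda,
        },
        "mu_sigma": mu_sigma,
        "mu_lambda": mu_lambda,
        "p": {"control": p_correct, "test": p_correct - error_rate_gap},
        "tau": tau,
        "subjects": truth_subjects,
    }
    return (
        SyntheticDataset(rt, truth, seed),
        SyntheticDataset(cr, truth, seed),
    )


def generate_adaptation(
    n_per_group: int = 10,
    n_trials: int = 10,
    intercepts: tuple[float, float] = (8.0, 5.8),
    slopes: tuple[float, float] = (-0.11, 0.12),
    noise_sd: float = 0.5,
    seed: int = 1,
    between_intercept_sd: float = 0.5,
    between_slope_sd: float = 0.02,
) -> SyntheticDataset:
    """Two groups of per-subject linear trends on a continuous response scale.

    Emulates the second phase of an adaptation-level experiment: the group
    that first handled light weights starts high and drifts down
    (intercept ~8, negative slope) while the heavy-first group starts low
    and drifts up, the two converging over the ``n_trials`` assessments.
    """
    if n_trials < 2:
        raise ValidationError("n_trials must be at least 2")
    if noise_sd <= 0:
        raise ValidationError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    truth_subjects = {}
    x = np.arange(1, n_trials + 1, dtype=float)
    for g, (a0, b0) in enumerate(zip(intercepts, slopes), start=1):
        a_i = rng.normal(a0, between_intercept_sd, n_per_group)
        b_i = rng.normal(b0, between_slope_sd, n_per_group)
        truth_subjects[g] = {"alpha": a_i, "beta": b_i}
        for j in range(n_per_group):
            y = a_i[j] + b_i[j] * x + rng.normal(0.0, noise_sd, n_trials)
            for k in range(n_trials):
                rows.append((g, j + 1, x[k], y[k]))
    frame = pd.DataFrame(rows, columns=["group", "subject", "sequence", "response"])
    truth = {
        "intercepts": tuple(intercepts),
        "slopes": tuple(slopes),
        "noise_sd": noise_sd,
        "between_intercept_sd": between_intercept_sd,
        "between_slope_sd": between_slope_sd,
        "subjects": truth_subjects,
    }
    return SyntheticDataset(frame, truth, seed)


STROOP_CONDITIONS = (
    "reading_neutral",
    "reading_incongruent",
    "naming_neutral",
    "naming_incongruent",
)


def generate_stroop(
    n_subjects: int = 40,
    condition_means: tuple[float, float, float, float] = (43.0, 46.0, 55.0, 69.0),
    within_subject_sd: float = 3.0,
    between_subject_sd: float = 5.0,
    seed: int = 1,
) -> SyntheticDataset:
    """Paired sheet-completion times (seconds) across four Stroop conditions.

    Each subject contributes one time per condition: a shared subject speed
    effect plus the condition mean plus trial noise, so within-subject
    differences are the informative contrasts.
    """
    if within_subject_sd <= 0 or between_subject_sd <= 0:
        raise ValidationError("standard deviations must be positive")
    if any(m <= 0 for m in condition_means):
        raise ValidationError("condition means are completion times; must be positive")
    rng = np.random.default_rng(seed)
    subject_effect = rng.normal(0.0, between_subject_sd, n_subjects)
    rows = []
    for j in range(n_subjects):
        for c, m in zip(STROOP_CONDITIONS, condition_means):
            rows.append((j + 1, c, m + subject_effect[j] + rng.normal(0.0, within_subject_sd)))
    frame = pd.DataFrame(rows, columns=["subject", "condition", "time"])
    truth = {
        "condition_means": tuple(condition_means),
        "within_subject_sd": within_subject_sd,
        "between_subject_sd": between_subject_sd,
        "subject_effect": subject_effect,
    }
    return SyntheticDataset(frame, truth, seed)


DEFAULT_STIMULI = {
    "red": (255, 0, 0),
    "green": (0, 255, 0),
    "blue": (0, 0, 255),
    "cyan": (0, 255, 255),
    "magenta": (255, 0, 255),
    "yellow": (255, 255, 0),
}


def generate_afterimages(
    n_responses_per_stimulus: int = 50,
    stimuli: dict[str, tuple[int, int, int]] | None = None,
    hue_kappa: float = 30.0,
    hue_offset: float = 0.0,
    seed: int = 1,
    sv_sd: float = 0.08,
) -> SyntheticDataset:
    """Color-matching responses clustered around each stimulus hue.

    Response hue ~ von Mises(stimulus hue + ``hue_offset``, ``hue_kappa``)
    (offset in radians; pi selects the complementary hue), saturation and
    value ~ normals around the stimulus values truncated to [0, 1].
    Responses are returned in RGB with the HSV ground truth recorded.
    """
    if hue_kappa <= 0:
        raise ValidationError("hue_kappa must be positive")
    stimuli = DEFAULT_STIMULI if stimuli is None else stimuli
    if not stimuli:
        raise ValidationError("need at least one stimulus")
    rng = np.random.default_rng(seed)
    rows = []
    truth: dict[str, dict] = {}
    for name, (r, g, b) in stimuli.items():
        h_deg, s0, v0 = rgb_to_hsv(r, g, b)
        target = np.deg2rad(h_deg) + hue_offset
        h = np.mod(rng.vonmises(target - np.pi, hue_kappa, n_responses_per_stimulus) + np.pi, 2 * np.pi)
        s = np.clip(rng.normal(max(s0, 0.9), sv_sd, n_responses_per_stimulus), 0.0, 1.0)
        v = np.clip(rng.normal(max(v0, 0.9), sv_sd, n_responses_per_stimulus), 0.0, 1.0)
        rr, gg, bb = hsv_to_rgb(np.rad2deg(h), s, v)
        truth[name] = {
            "stimulus_rgb": (r, g, b),
            "stimulus_hue_rad": float(np.deg2rad(h_deg)),
            "target_hue_rad": float(np.mod(target, 2 * np.pi)),
            "kappa": hue_kappa,
        }
        for k in range(n_responses_per_stimulus):
            rows.append((name, round(rr[k]), round(gg[k]), round(bb[k])))
    frame = pd.DataFrame(rows, columns=["stimulus", "r", "g", "b"])
    return SyntheticDataset(frame, {"stimuli": truth, "hue_offset": hue_offset}, seed)
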