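"""File formats: draws as delimited text, fit manifests, settings config.

Draws persist as plain CSV with ``chain`` and ``iteration`` columns plus
one column per parameter — diffable, no binary formats.  A YAML manifest
ties together the files of one fit (model tag, settings, draw files) so
downstream commands can reload it.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .draws import DrawMatrix
from .errors import ValidationError
from .fits import BayesFit
from .priors import Prior, parse_prior
from .sampler import SamplerSettings

__all__ = [
    "write_draws",
    "read_draws",
    "write_fit",
    "read_fit",
    "load_config",
    "priors_from_strings",
]


def write_draws(draws: DrawMatrix, path) -> None:
    draws.to_frame().to_csv(path, index=False)


def read_draws(path) -> DrawMatrix:
    frame = pd.read_csv(path)
    if "chain" not in frame.columns or "iteration" not in frame.columns:
        raise ValidationError(f"{path}: draw files need chain and iteration columns")
    return DrawMatrix.from_frame(frame)


def write_fit(fit: BayesFit, prefix: str | Path) -> Path:
    """Persist a fit as <prefix>_group.csv [+ _subject.csv] + <prefix>.yaml."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    group_path = prefix.with_name(prefix.name + "_group.csv")
    write_draws(fit.group, group_path)
    manifest = {
        "model": fit.model,
        "files": {"group": group_path.name},
        "n_subjects": fit.n_subjects,
    }
    if fit.subject is not None:
        subject_path = prefix.with_name(prefix.name + "_subject.csv")
        write_draws(fit.subject, subject_path)
        manifest["files"]["subject"] = subject_path.name
    if fit.settings is not None:
        manifest["settings"] = {
            "chains": fit.settings.chains,
            "warmup": fit.settings.warmup,
            "iter": fit.settings.iter,
            "seed": fit.settings.seed,
        }
    manifest_path = prefix.with_suffix(".yaml")
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def read_fit(manifest_path) -> BayesFit:
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    if not isinstance(manifest, dict) or "model" not in manifest:
        raise ValidationError(f"{manifest_path}: not a fit manifest")
    folder = manifest_path.parent
    group = read_draws(folder / manifest["files"]["group"])
    subject = None
    if "subject" in manifest.get("files", {}):
        subject = read_draws(folder / manifest["files"]["subject"])
    settings = None
    if "settings" in manifest:
        settings = SamplerSettings(**manifest["settings"])
    fit = BayesFit(
        model=manifest["model"],
        group=group,
        subject=subject,
        n_subjects=manifest.get("n_subjects"),
        settings=settings,
    )
    if manifest["model"] == "reaction_time":
        from .reaction_time import ReactionTimeFit

        fit.__class__ = ReactionTimeFit
    elif manifest["model"] == "bootstrap":
        from .bootstrap import BootstrapResult

        fit.__class__ = BootstrapResult
    return fit


def load_config(path) -> tuple[SamplerSettings, dict[str, Prior]]:
    """Read sampler settings and priors from a YAML key-value config file.

    Recognized keys: chains, warmup, iter, seed, and a ``priors`` mapping of
    parameter name to "family(a, b)" strings.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    settings = SamplerSettings(
        chains=int(raw.get("chains", 4)),
        warmup=int(raw.get("warmup", 1000)),
        iter=int(raw.get("iter", 1000)),
        seed=int(raw.get("seed", 1)),
    )
    priors = {name: parse_prior(spec) for name, spec in (raw.get("priors") or {}).items()}
    return settings, priors


def priors_from_strings(specs: tuple[str, ...]) -> dict[str, Prior]:
    """Parse repeated CLI ``--prior "param:family(a,b)"`` flags."""
    out = {}
    for spec in specs:
        if ":" not in spec:
            raise ValidationError(f"prior flag {spec!r} must look like 'param:family(a,b)'")
        name, dist = spec.split(":", 1)
        out[name.strip()] = parse_prior(dist)
    return out
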