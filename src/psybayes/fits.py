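"""Fit result containers shared by the model modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .draws import DrawMatrix
from .sampler import SamplerSettings

__all__ = ["BayesFit"]


@dataclass
class BayesFit:
    """A model-tagged bundle of group- and subject-level posterior draws.

    ``group`` holds the group-level draws; hierarchical models additionally
    carry ``subject`` draws labelled ``"name[i]"`` with 1-based subject
    index ``i``.  ``data`` echoes the validated model input.
    """

    model: str
    group: DrawMatrix
    subject: DrawMatrix | None = None
    n_subjects: int | None = None
    data: Any = None
    settings: SamplerSettings | None = None
    extra: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.group.n_chains * self.group.n_iterations

    def group_draws(self, parameter: str) -> np.ndarray:
        return self.group.flatten(parameter)
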