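"""Simulation configuration.

:class:`SimConfig` collects every knob of the simulation design: number of
Monte-Carlo iterations per cell, original sample sizes, the two truth
distributions (near-zero "spurious" effects and substantive "real" effects),
the publication-bias levels, and the analysis conventions shared by the
replication-success metrics (one-sided test level, Cauchy prior scale for the
Bayes factors, sidedness switches).

Configs round-trip through flat YAML files whose keys mirror the dataclass
fields; unknown keys are rejected by name so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["SimConfig", "load_config"]

SPURIOUS = "spurious"
REAL = "real"
TRUTH_LABELS = (SPURIOUS, REAL)


@dataclass(frozen=True)
class SimConfig:
    """All simulation and analysis parameters.

    Defaults reproduce the study design: 5000 iterations per (truth, n) cell,
    original sample sizes 25/50/75/100 (replications twice as large), spurious
    truths ~ N(0, 0.02), real truths ~ N(0.5, 0.15), unit data standard
    deviation, publication-bias levels 100/75/50/25/0 %, and a one-sided 0.05
    significance filter for publication.
    """

    iter_per_cell: int = 5000
    n_orig_set: tuple[int, ...] = (25, 50, 75, 100)
    spurious_mu: float = 0.0
    spurious_tau: float = 0.02
    real_mu: float = 0.5
    real_tau: float = 0.15
    data_sd: float = 1.0
    bias_levels: tuple[int, ...] = (100, 75, 50, 25, 0)
    pub_alpha: float = 0.05
    seed: int = 2021
    #: scale of the zero-centred Cauchy prior on the standardized effect used
    #: by all JZS-type Bayes factors (sqrt(2)/2 is the common "medium" default;
    #: 1.0 is the original JZS convention).
    cauchy_scale: float = math.sqrt(2.0) / 2.0
    #: if True (default), Bayes factors use the positive-half Cauchy prior,
    #: matching the directional design (one-sided tests, only positive effects
    #: of interest); set False for the symmetric two-sided JZS prior.
    bf_one_sided: bool = True
    #: the significance criterion requires a positive original effect in
    #: addition to a significant replication (the tabulated operationalization);
    #: set False for the replication-only variant.
    significance_requires_original_sign: bool = True
    #: alpha used both for the 33%-power benchmark effect and for the
    #: "significantly smaller" test of the Small Telescopes rule (fixed; this
    #: metric is a single decision point, not a threshold sweep).
    small_telescopes_alpha: float = 0.05
    #: one-sided level for the sceptical p-value's summary decision.
    sceptical_alpha: float = 0.025

    def __post_init__(self) -> None:
        if self.iter_per_cell < 0:
            raise ValueError("iter_per_cell must be non-negative")
        if not self.n_orig_set or any(int(n) < 2 for n in self.n_orig_set):
            raise ValueError("n_orig_set must contain sample sizes >= 2")
        for name in ("spurious_tau", "real_tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.data_sd <= 0:
            raise ValueError("data_sd must be > 0")
        if any(not 0 <= b <= 100 for b in self.bias_levels):
            raise ValueError("bias_levels must lie in [0, 100]")
        if not 0 < self.pub_alpha < 1:
            raise ValueError("pub_alpha must lie in (0, 1)")
        if self.cauchy_scale <= 0:
            raise ValueError("cauchy_scale must be > 0")
        if not 0 < self.small_telescopes_alpha < 1:
            raise ValueError("small_telescopes_alpha must lie in (0, 1)")
        if not 0 < self.sceptical_alpha < 1:
            raise ValueError("sceptical_alpha must lie in (0, 1)")
        # normalize sequence fields so configs hash/compare predictably
        object.__setattr__(self, "n_orig_set", tuple(int(n) for n in self.n_orig_set))
        object.__setattr__(self, "bias_levels", tuple(int(b) for b in self.bias_levels))

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["n_orig_set"] = list(self.n_orig_set)
        d["bias_levels"] = list(self.bias_levels)
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must be a flat key-value mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def replace(self, **changes: Any) -> "SimConfig":
        return dataclasses.replace(self, **changes)


def load_config(path: str | Path | None = None, **overrides: Any) -> SimConfig:
    """Load a config from YAML (or defaults) with keyword overrides."""
    cfg = SimConfig.from_yaml(path) if path is not None else SimConfig()
    return cfg.replace(**overrides) if overrides else cfg
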