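"""Generation of simulated original/replication study pairs.

The simulated world: a true standardized effect theta is drawn from either a
near-zero ("spurious") or a substantive ("real") normal distribution; an
original study of size n measures n iid Normal(theta, data_sd) observations
and is summarized by its one-sample one-sided t-test (H0: mu = 0 vs
Ha: mu > 0); a publication filter always keeps significant originals and keeps
non-significant ones with probability (100 - bias) %; every published original
is followed by one close replication with twice the sample size.

Studies are generated through their sufficient statistics — the sample mean is
Normal(theta, data_sd/sqrt(n)) and (n-1) sd^2 / data_sd^2 is chi-square with
n-1 degrees of freedom — which is distributionally identical to drawing raw
samples and much faster.

Randomness is fully reproducible: one master seed in :class:`SimConfig`, and
one named substream per (bias level, truth condition, sample size) cell, so
any scenario can be regenerated in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import REAL, SPURIOUS, TRUTH_LABELS, SimConfig

__all__ = [
    "TrueEffect",
    "StudySummary",
    "StudyPair",
    "draw_true_effects",
    "simulate_study",
    "publish",
    "run_scenario",
    "cell_rng",
    "iter_pairs",
    "pair_from_row",
    "PAIR_COLUMNS",
]

#: column schema of the pair-level table / CSV.
PAIR_COLUMNS = [
    "scenario",
    "bias",
    "truth_label",
    "theta",
    "n_orig",
    "mean_o",
    "sd_o",
    "d_o",
    "t_o",
    "p_o",
    "published",
    "n_rep",
    "mean_r",
    "sd_r",
    "d_r",
    "t_r",
    "p_r",
]


@dataclass(frozen=True)
class TrueEffect:
    """A true standardized population effect and its generating condition.

    ``label`` records which truth distribution produced ``theta`` — it is never
    inferred from the sign or size of theta (spurious draws may be negative).
    """

    theta: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in TRUTH_LABELS:
            raise ValueError(f"label must be one of {TRUTH_LABELS}")


@dataclass(frozen=True)
class StudySummary:
    """Sufficient statistics of one simulated one-sample study."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if int(self.n) < 2:
            raise ValueError("sample size must be >= 2")
        if not self.sd > 0:
            raise ValueError("sample standard deviation must be > 0")
        object.__setattr__(self, "n", int(self.n))

    @property
    def d(self) -> float:
        """Cohen's d: sample mean over sample standard deviation."""
        return self.mean / self.sd

    @property
    def t(self) -> float:
        """One-sample t statistic, equal to d * sqrt(n)."""
        return self.mean / (self.sd / math.sqrt(self.n))

    @property
    def p(self) -> float:
        """One-sided p-value for H0: mu = 0 vs Ha: mu > 0."""
        return float(stats.t.sf(self.t, self.n - 1))

    @classmethod
    def from_t(cls, t: float, n: int) -> "StudySummary":
        """Build a summary from a t statistic and sample size (unit sd)."""
        return cls(n=n, mean=t / math.sqrt(n), sd=1.0)


@dataclass(frozen=True)
class StudyPair:
    """An original study, its (optional) replication, and the ground truth."""

    truth: TrueEffect
    original: StudySummary
    replication: Optional[StudySummary]
    published: bool

    def __post_init__(self) -> None:
        if self.published and self.replication is None:
            raise ValueError("published pairs must carry a replication")
        if not self.published and self.replication is not None:
            raise ValueError("unpublished originals are never replicated")


# -- elementary generators -------------------------------------------------


def draw_true_effects(
    mu: float,
    tau: float,
    count: int,
    rng: np.random.Generator,
    label: str = SPURIOUS,
) -> list[TrueEffect]:
    """Draw ``count`` true effects from Normal(mu, tau) under one condition."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if count < 1:
        raise ValueError("count must be >= 1")
    thetas = rng.normal(mu, tau, size=count)
    return [TrueEffect(float(th), label) for th in thetas]


def _sample_summaries(
    thetas: np.ndarray, n: int, data_sd: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized sufficient-statistic sampling: (means, sds) for each theta."""
    means = rng.normal(thetas, data_sd / math.sqrt(n))
    sds = data_sd * np.sqrt(rng.chisquare(n - 1, size=np.shape(thetas)) / (n - 1))
    return means, sds


def simulate_study(
    theta: float, n: int, data_sd: float = 1.0, rng: np.random.Generator | None = None
) -> StudySummary:
    """Simulate one study of size ``n`` with true standardized effect ``theta``."""
    if n < 2:
        raise ValueError("sample size must be >= 2")
    if rng is None:
        rng = np.random.default_rng()
    means, sds = _sample_summaries(np.asarray(theta, dtype=float), int(n), data_sd, rng)
    return StudySummary(n=int(n), mean=float(means), sd=float(sds))


def publish(
    original: StudySummary,
    bias_percent: float,
    pub_alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> bool:
    """Publication filter: significant originals always pass; the rest pass
    with probability (100 - bias_percent) %."""
    if not 0 <= bias_percent <= 100:
        raise ValueError("bias_percent must lie in [0, 100]")
    if original.p < pub_alpha:
        return True
    if rng is None:
        rng = np.random.default_rng()
    return bool(rng.random() < (100.0 - bias_percent) / 100.0)


# -- scenario generation ----------------------------------------------------


def cell_rng(
    seed: int, bias_percent: int, truth_label: str, n_orig: int
) -> np.random.Generator:
    """Independent, reproducible random stream for one simulation cell."""
    truth_idx = TRUTH_LABELS.index(truth_label)
    ss = np.random.SeedSequence(
        entropy=int(seed), spawn_key=(int(bias_percent), truth_idx, int(n_orig))
    )
    return np.random.default_rng(ss)


def _truth_params(config: SimConfig, label: str) -> tuple[float, float]:
    if label == SPURIOUS:
        return config.spurious_mu, config.spurious_tau
    return config.real_mu, config.real_tau


def _cell_frame(
    config: SimConfig, bias_percent: int, label: str, n_orig: int
) -> pd.DataFrame:
    rng = cell_rng(config.seed, bias_percent, label, n_orig)
    m = config.iter_per_cell
    mu, tau = _truth_params(config, label)
    thetas = rng.normal(mu, tau, size=m)

    mean_o, sd_o = _sample_summaries(thetas, n_orig, config.data_sd, rng)
    t_o = mean_o / (sd_o / math.sqrt(n_orig))
    p_o = stats.t.sf(t_o, n_orig - 1)

    # one uniform per original, drawn even for significant ones, so the stream
    # layout does not depend on the data
    u = rng.random(size=m)
    published = (p_o < config.pub_alpha) | (u < (100.0 - bias_percent) / 100.0)

    n_rep = 2 * n_orig
    mean_r = np.full(m, np.nan)
    sd_r = np.full(m, np.nan)
    k = int(published.sum())
    if k:
        mr, sr = _sample_summaries(thetas[published], n_rep, config.data_sd, rng)
        mean_r[published] = mr
        sd_r[published] = sr
    t_r = mean_r / (sd_r / math.sqrt(n_rep))
    p_r = stats.t.sf(t_r, n_rep - 1)

    return pd.DataFrame(
        {
            "scenario": f"bias{bias_percent:03d}",
            "bias": bias_percent,
            "truth_label": label,
            "theta": thetas,
            "n_orig": n_orig,
            "mean_o": mean_o,
            "sd_o": sd_o,
            "d_o": mean_o / sd_o,
            "t_o": t_o,
            "p_o": p_o,
            "published": published,
            "n_rep": np.where(published, n_rep, -1),
            "mean_r": mean_r,
            "sd_r": sd_r,
            "d_r": mean_r / sd_r,
            "t_r": t_r,
            "p_r": p_r,
        }
    )


def run_scenario(
    config: SimConfig,
    bias_percent: int,
    truth_labels: Sequence[str] = TRUTH_LABELS,
) -> pd.DataFrame:
    """Generate the full pair table for one publication-bias level.

    Produces ``len(truth_labels) * len(n_orig_set) * iter_per_cell`` original
    studies; published originals get a replication of twice their size,
    unpublished ones are retained with ``published == False`` and NaN
    replication columns (so denominators can be audited; rates use published
    pairs only).
    """
    if not 0 <= bias_percent <= 100:
        raise ValueError("bias_percent must lie in [0, 100]")
    frames = [
        _cell_frame(config, int(bias_percent), label, n)
        for label in truth_labels
        for n in config.n_orig_set
    ]
    out = pd.concat(frames, ignore_index=True)
    out.index.name = "pair_id"
    return out


# -- object view of the pair table ------------------------------------------


def pair_from_row(row: pd.Series) -> StudyPair:
    """Materialize one table row as a :class:`StudyPair`."""
    truth = TrueEffect(float(row["theta"]), str(row["truth_label"]))
    original = StudySummary(int(row["n_orig"]), float(row["mean_o"]), float(row["sd_o"]))
    published = bool(row["published"])
    replication = (
        StudySummary(int(row["n_rep"]), float(row["mean_r"]), float(row["sd_r"]))
        if published
        else None
    )
    return StudyPair(truth=truth, original=original, replication=replication, published=published)


def iter_pairs(frame: pd.DataFrame) -> Iterator[StudyPair]:
    """Iterate a pair table as :class:`StudyPair` objects."""
    for _, row in frame.iterrows():
        yield pair_from_row(row)
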