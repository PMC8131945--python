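"""Aggregation of decisions into true/false-positive rates and sweeps.

The true positive rate of a metric at a threshold is the fraction of
successes among published (and applicable) pairs whose truth was drawn from
the real-effect distribution; the false positive rate is the same fraction
among pairs from the near-zero distribution. Threshold sweeps evaluate each
pair's evidence statistic once and derive every grid point by comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import REAL, SPURIOUS, SimConfig
from . import metrics as metrics_mod
from .metrics import (
    BF_KIND,
    FIXED_RULE,
    METRIC_IDS,
    NOT_APPLICABLE,
    P_KIND,
    STAT_COLUMN,
    SUCCESS,
    MetricDecision,
)

__all__ = [
    "ThresholdGrid",
    "alpha_grid",
    "bf_grid",
    "grid_for",
    "RatesCurve",
    "UndefinedRateError",
    "rates_at_threshold",
    "sweep",
    "table4_summary",
    "margin",
]


@dataclass(frozen=True)
class ThresholdGrid:
    """An ordered threshold grid, either alpha-valued or BF-valued."""

    kind: str  # "alpha" | "bf"
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("alpha", "bf"):
            raise ValueError("kind must be 'alpha' or 'bf'")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) < 1 or np.any(np.diff(v) <= 0):
            raise ValueError("values must be strictly increasing and 1-D")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


def alpha_grid() -> ThresholdGrid:
    """Significance thresholds 0.0001 to 0.5 in steps of 0.0001 (5000 values)."""
    return ThresholdGrid("alpha", (np.arange(5000) + 1) * 1e-4)


def bf_grid() -> ThresholdGrid:
    """Bayes-factor thresholds from 1/10 in steps of 1/25 (4998 values)."""
    return ThresholdGrid("bf", 0.1 + np.arange(4998) / 25.0)


def grid_for(metric_id: str) -> ThresholdGrid:
    """The sweep grid a metric uses (alpha for p-like, BF for Bayes factors)."""
    if metric_id in P_KIND:
        return alpha_grid()
    if metric_id in BF_KIND:
        return bf_grid()
    if metric_id in FIXED_RULE:
        return ThresholdGrid("alpha", np.array([0.05]))
    raise ValueError(f"unknown metric_id {metric_id!r}")


class UndefinedRateError(ValueError):
    """A rate with an empty denominator was requested."""


def margin(p: float, n_denominator: int) -> float:
    """95% Monte-Carlo half-width 1.96 * sqrt(p (1 - p) / n) for a proportion."""
    if n_denominator <= 0:
        raise UndefinedRateError("margin needs a positive denominator")
    p = float(p)
    return 1.96 * math.sqrt(p * (1.0 - p) / n_denominator)


def rates_at_threshold(
    decisions: Sequence[MetricDecision], labels: Sequence[str]
) -> tuple[float, float, dict[str, int]]:
    """(TPR, FPR, counts) for aligned per-pair decisions and truth labels.

    Not-applicable decisions are excluded from numerator and denominator.
    Raises :class:`UndefinedRateError` when either truth class has no
    applicable pairs.
    """
    if len(decisions) != len(labels):
        raise ValueError("decisions and labels must be aligned")
    counts = {
        "n_success_real": 0,
        "n_published_real": 0,
        "n_success_spurious": 0,
        "n_published_spurious": 0,
    }
    for dec, label in zip(decisions, labels):
        if dec.outcome == NOT_APPLICABLE:
            continue
        key = "real" if label == REAL else "spurious"
        counts[f"n_published_{key}"] += 1
        if dec.outcome == SUCCESS:
            counts[f"n_success_{key}"] += 1
    if counts["n_published_real"] == 0 or counts["n_published_spurious"] == 0:
        raise UndefinedRateError("empty denominator in at least one truth class")
    tpr = counts["n_success_real"] / counts["n_published_real"]
    fpr = counts["n_success_spurious"] / counts["n_published_spurious"]
    return tpr, fpr, counts


@dataclass(frozen=True)
class RatesCurve:
    """Per-threshold TPR/FPR with the underlying counts."""

    metric_id: str
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    n_success_real: np.ndarray
    n_published_real: int
    n_success_spurious: np.ndarray
    n_published_spurious: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": self.metric_id,
                "threshold": self.thresholds,
                "tpr": self.tpr,
                "fpr": self.fpr,
                "n_success_real": self.n_success_real,
                "n_published_real": self.n_published_real,
                "n_success_spurious": self.n_success_spurious,
                "n_published_spurious": self.n_published_spurious,
            }
        )


def _class_counts(
    ev: pd.DataFrame,
    metric_id: str,
    grid: ThresholdGrid,
    config: SimConfig,
    label: str,
) -> tuple[np.ndarray, int]:
    """Success counts along the grid and the applicable denominator for one class."""
    sub = ev.loc[ev["truth_label"] == label]
    applicable = np.ones(len(sub), dtype=bool)
    if metric_id == "replication_bf":
        applicable = sub["p_o"].to_numpy(float) < config.pub_alpha
    denom = int(applicable.sum())
    if metric_id in FIXED_RULE:
        ok, _ = metrics_mod.success_from_evidence(sub, metric_id, grid.values[0], config)
        return np.array([int(ok.sum())] * len(grid)), denom
    gate = metrics_mod._gate(sub, metric_id, config) & applicable
    stat = sub[STAT_COLUMN[metric_id]].to_numpy(float)[gate]
    stat = np.sort(stat[~np.isnan(stat)])
    if metric_id in P_KIND:
        counts = np.searchsorted(stat, grid.values, side="left")  # stat < alpha
    else:
        counts = len(stat) - np.searchsorted(stat, grid.values, side="right")  # stat > thr
    return counts.astype(int), denom


def sweep(
    ev: pd.DataFrame,
    metric_id: str,
    grid: ThresholdGrid | None = None,
    config: SimConfig | None = None,
) -> RatesCurve:
    """TPR/FPR of one metric across a threshold grid.

    ``ev`` is an evidence table (see :func:`repmetrics.metrics.evidence_table`)
    containing both truth classes. Evidence statistics are compared, never
    recomputed, so the full 5000-point grids are cheap.
    """
    cfg = config or SimConfig()
    g = grid or grid_for(metric_id)
    succ_real, n_real = _class_counts(ev, metric_id, g, cfg, REAL)
    succ_spur, n_spur = _class_counts(ev, metric_id, g, cfg, SPURIOUS)
    if n_real == 0 or n_spur == 0:
        raise UndefinedRateError(
            f"{metric_id}: empty applicable denominator (real={n_real}, spurious={n_spur})"
        )
    return RatesCurve(
        metric_id=metric_id,
        thresholds=g.values.copy(),
        tpr=succ_real / n_real,
        fpr=succ_spur / n_spur,
        n_success_real=succ_real,
        n_published_real=n_real,
        n_success_spurious=succ_spur,
        n_published_spurious=n_spur,
    )


def table4_summary(
    evidence_by_bias: Mapping[int, pd.DataFrame],
    config: SimConfig | None = None,
    per_n: bool = False,
) -> pd.DataFrame:
    """Percent TPR/FPR per metric and bias level at the liberal thresholds.

    Thresholds: alpha 0.05 for significance and classical meta-analysis, the
    fixed Small Telescopes rule, BF 1 for the three Bayes factors, 0.025 for
    the sceptical p-value. Rates pool the original sample sizes; pass
    ``per_n=True`` for a per-n breakdown. Replication-BF cells are missing
    (NaN) whenever some originals are non-significant (bias below 100%).
    """
    cfg = config or SimConfig()
    thresholds = metrics_mod.default_thresholds(cfg)
    rows = []
    for bias, ev in evidence_by_bias.items():
        n_groups = sorted(ev["n_orig"].unique()) if per_n else [None]
        for n_orig in n_groups:
            sub = ev if n_orig is None else ev.loc[ev["n_orig"] == n_orig]
            for metric_id in METRIC_IDS:
                if STAT_COLUMN[metric_id] not in sub.columns:
                    continue
                if metric_id == "replication_bf" and (sub["p_o"] >= cfg.pub_alpha).any():
                    # defined only when every published original is significant
                    row = dict(bias=bias, metric=metric_id, fpr=np.nan, tpr=np.nan,
                               n_spurious=0, n_real=0)
                    if per_n:
                        row["n_orig"] = n_orig
                    rows.append(row)
                    continue
                ok, applicable = metrics_mod.success_from_evidence(
                    sub, metric_id, thresholds[metric_id], cfg
                )
                spur = (sub["truth_label"] == SPURIOUS).to_numpy()
                real = (sub["truth_label"] == REAL).to_numpy()
                n_spur = int((spur & applicable).sum())
                n_real = int((real & applicable).sum())
                if n_spur == 0 or n_real == 0:
                    raise UndefinedRateError(
                        f"{metric_id} at bias {bias}: empty truth-class denominator"
                    )
                row = dict(
                    bias=bias,
                    metric=metric_id,
                    fpr=100.0 * (ok & spur).sum() / n_spur,
                    tpr=100.0 * (ok & real).sum() / n_real,
                    n_spurious=n_spur,
                    n_real=n_real,
                )
                if per_n:
                    row["n_orig"] = n_orig
                rows.append(row)
    return pd.DataFrame(rows)


def plot_curves(curves: Iterable[RatesCurve], path: str, title: str = "") -> None:
    """Convenience export of TPR-vs-FPR curves to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for curve in curves:
        order = np.argsort(curve.fpr)
        ax.plot(curve.fpr[order], curve.tpr[order], label=curve.metric_id)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
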