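"""The seven replication-success decision rules.

Each rule maps a published original/replication pair and a threshold to a
:class:`MetricDecision` with outcome ``success``, ``failure`` or — for the
replication Bayes factor applied to a non-significant original —
``not_applicable``. Sign gates use the sample effect strictly greater than
zero; an exact zero (measure-zero event) counts as failure.

Two call styles are provided:

* per-pair functions ``decide_*`` operating on :class:`StudyPair` objects;
* :func:`evidence_table`, which augments a pair table (see
  :mod:`repmetrics.studygen`) with one evidence-statistic column per metric so
  that threshold sweeps can be derived by comparison without recomputing any
  Bayes factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import inference
from .config import SimConfig
from .studygen import StudyPair

__all__ = [
    "SUCCESS",
    "FAILURE",
    "NOT_APPLICABLE",
    "METRIC_IDS",
    "P_KIND",
    "BF_KIND",
    "MetricDecision",
    "decide_significance",
    "decide_small_telescopes",
    "decide_meta_classical",
    "decide_jzs_bf",
    "decide_replication_bf",
    "decide_meta_bayes",
    "decide_sceptical",
    "decide",
    "evidence_table",
    "success_from_evidence",
    "default_thresholds",
]

SUCCESS = "success"
FAILURE = "failure"
NOT_APPLICABLE = "not_applicable"

METRIC_IDS = (
    "significance",
    "small_telescopes",
    "meta_classical",
    "jzs_bf",
    "replication_bf",
    "meta_bayes",
    "sceptical_p",
)

#: metrics whose evidence statistic is p-like (success when below threshold)
P_KIND = frozenset({"significance", "meta_classical", "sceptical_p"})
#: metrics whose evidence statistic is a Bayes factor (success when above)
BF_KIND = frozenset({"jzs_bf", "replication_bf", "meta_bayes"})
#: the Small Telescopes rule is a fixed single-point criterion (p > 0.05 with
#: alpha pinned at 0.05 for both steps); it is not swept over thresholds.
FIXED_RULE = frozenset({"small_telescopes"})


@dataclass(frozen=True)
class MetricDecision:
    metric_id: str
    threshold: float
    outcome: str

    def __post_init__(self) -> None:
        if self.metric_id not in METRIC_IDS:
            raise ValueError(f"unknown metric_id {self.metric_id!r}")
        if self.outcome not in (SUCCESS, FAILURE, NOT_APPLICABLE):
            raise ValueError(f"unknown outcome {self.outcome!r}")


def _require_published(pair: StudyPair) -> None:
    if not pair.published or pair.replication is None:
        raise ValueError("decisions are defined for published pairs only")


def _decision(metric_id: str, threshold: float, ok: bool) -> MetricDecision:
    return MetricDecision(metric_id, float(threshold), SUCCESS if ok else FAILURE)


def decide_significance(
    pair: StudyPair, alpha: float, require_original_sign: bool = True
) -> MetricDecision:
    """Success: positive original and replication effects and p_rep < alpha."""
    _require_published(pair)
    ok = pair.replication.d > 0 and pair.replication.p < alpha
    if require_original_sign:
        ok = ok and pair.original.d > 0
    return _decision("significance", alpha, ok)


def decide_small_telescopes(pair: StudyPair, alpha: float = 0.05) -> MetricDecision:
    """Success: positive original effect and the replication is not
    significantly smaller than the original design's 33%-power effect."""
    _require_published(pair)
    benchmark = inference.d33(pair.original.n, alpha)
    ok = (
        pair.original.d > 0
        and inference.small_telescope_p(pair.replication, benchmark) > alpha
    )
    return _decision("small_telescopes", alpha, ok)


def decide_meta_classical(pair: StudyPair, alpha: float) -> MetricDecision:
    """Success: positive original and combined effects and meta p < alpha."""
    _require_published(pair)
    meta = inference.fixed_effect_meta(pair.original, pair.replication)
    ok = pair.original.d > 0 and meta.d_combined > 0 and meta.p < alpha
    return _decision("meta_classical", alpha, ok)


def decide_jzs_bf(
    pair: StudyPair,
    bf_threshold: float,
    cauchy_scale: float = inference.DEFAULT_CAUCHY_SCALE,
    one_sided: bool = True,
) -> MetricDecision:
    """Success: positive effects in both studies and the replication's JZS
    Bayes factor above the threshold."""
    _require_published(pair)
    ok = (
        pair.original.d > 0
        and pair.replication.d > 0
        and inference.jzs_bf10(
            pair.replication.t, pair.replication.n, cauchy_scale, one_sided
        )
        > bf_threshold
    )
    return _decision("jzs_bf", bf_threshold, ok)


def decide_replication_bf(
    pair: StudyPair,
    bf_threshold: float,
    cauchy_scale: float = inference.DEFAULT_CAUCHY_SCALE,
    pub_alpha: float = 0.05,
    one_sided: bool = True,
) -> MetricDecision:
    """Success: replication BF above threshold, given a significant original;
    not applicable when the original is non-significant."""
    _require_published(pair)
    if pair.original.p >= pub_alpha:
        return MetricDecision("replication_bf", float(bf_threshold), NOT_APPLICABLE)
    bf = inference.replication_bf(pair.original, pair.replication, cauchy_scale, one_sided)
    return _decision("replication_bf", bf_threshold, bf > bf_threshold)


def decide_meta_bayes(
    pair: StudyPair,
    bf_threshold: float,
    cauchy_scale: float = inference.DEFAULT_CAUCHY_SCALE,
    one_sided: bool = True,
) -> MetricDecision:
    """Success: positive original and combined effects and the meta-analytic
    JZS Bayes factor above the threshold."""
    _require_published(pair)
    meta = inference.fixed_effect_meta(pair.original, pair.replication)
    ok = (
        pair.original.d > 0
        and meta.d_combined > 0
        and inference.meta_bf10(pair.original, pair.replication, cauchy_scale, one_sided)
        > bf_threshold
    )
    return _decision("meta_bayes", bf_threshold, ok)


def decide_sceptical(pair: StudyPair, alpha: float = 0.025) -> MetricDecision:
    """Success: positive original effect and sceptical p-value below alpha."""
    _require_published(pair)
    ok = (
        pair.original.d > 0
        and inference.sceptical_p(pair.original, pair.replication) < alpha
    )
    return _decision("sceptical_p", alpha, ok)


_DECIDERS = {
    "significance": decide_significance,
    "small_telescopes": decide_small_telescopes,
    "meta_classical": decide_meta_classical,
    "jzs_bf": decide_jzs_bf,
    "replication_bf": decide_replication_bf,
    "meta_bayes": decide_meta_bayes,
    "sceptical_p": decide_sceptical,
}


def decide(metric_id: str, pair: StudyPair, threshold: float, **kwargs) -> MetricDecision:
    """Dispatch to the decision rule named by ``metric_id``."""
    try:
        decider = _DECIDERS[metric_id]
    except KeyError:
        raise ValueError(f"unknown metric_id {metric_id!r}") from None
    return decider(pair, threshold, **kwargs)


def default_thresholds(config: SimConfig | None = None) -> dict[str, float]:
    """Liberal summary thresholds: alpha 0.05, BF 1, sceptical 0.025."""
    cfg = config or SimConfig()
    return {
        "significance": 0.05,
        "small_telescopes": cfg.small_telescopes_alpha,
        "meta_classical": 0.05,
        "jzs_bf": 1.0,
        "replication_bf": 1.0,
        "meta_bayes": 1.0,
        "sceptical_p": cfg.sceptical_alpha,
    }


# -- vectorized evidence computation ----------------------------------------

_CHUNK = 2000  # rows per Bayes-factor quadrature batch (bounds memory)


def _chunked(fn, *cols: np.ndarray) -> np.ndarray:
    n = cols[0].shape[0]
    out = np.empty(n)
    for start in range(0, n, _CHUNK):
        sl = slice(start, start + _CHUNK)
        out[sl] = fn(*(c[sl] for c in cols))
    return out


def evidence_table(
    frame: pd.DataFrame,
    config: SimConfig | None = None,
    metrics: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Evidence statistics for every published pair in ``frame``.

    Returns the published subset of the pair table with one added column per
    requested metric: ``p_rep``, ``st_p``, ``meta_d``/``meta_p``, ``jzs``,
    ``rep_bf`` (NaN where not applicable), ``meta_bf`` and ``scep_p``. Each
    statistic is computed once; thresholding is left to the caller.
    """
    cfg = config or SimConfig()
    wanted = tuple(metrics) if metrics is not None else METRIC_IDS
    unknown = sorted(set(wanted) - set(METRIC_IDS))
    if unknown:
        raise ValueError(f"unknown metric id(s): {', '.join(unknown)}")

    ev = frame.loc[frame["published"]].copy()
    t_o = ev["t_o"].to_numpy(float)
    n_o = ev["n_orig"].to_numpy(float)
    t_r = ev["t_r"].to_numpy(float)
    n_r = ev["n_rep"].to_numpy(float)

    if "significance" in wanted:
        ev["p_rep"] = ev["p_r"]
    if "small_telescopes" in wanted:
        bench_per_row = np.empty_like(n_o)
        for n in np.unique(n_o):
            bench_per_row[n_o == n] = inference.d33(int(n), cfg.small_telescopes_alpha)
        ev["st_p"] = inference.small_telescope_p((t_r, n_r), bench_per_row)
    if "meta_classical" in wanted or "meta_bayes" in wanted:
        meta = inference.fixed_effect_meta((t_o, n_o), (t_r, n_r))
        ev["meta_d"] = meta.d_combined
        ev["meta_p"] = meta.p
    if "jzs_bf" in wanted:
        ev["jzs"] = _chunked(
            lambda t, n: inference.jzs_bf10(t, n, cfg.cauchy_scale, cfg.bf_one_sided),
            t_r,
            n_r,
        )
    if "replication_bf" in wanted:
        applicable = ev["p_o"].to_numpy(float) < cfg.pub_alpha
        bf = np.full(len(ev), np.nan)
        if applicable.any():
            bf[applicable] = _chunked(
                lambda a, b, c, d: inference.replication_bf(
                    (a, b), (c, d), cfg.cauchy_scale, cfg.bf_one_sided
                ),
                t_o[applicable],
                n_o[applicable],
                t_r[applicable],
                n_r[applicable],
            )
        ev["rep_bf"] = bf
    if "meta_bayes" in wanted:
        ev["meta_bf"] = _chunked(
            lambda a, b, c, d: inference.meta_bf10(
                (a, b), (c, d), cfg.cauchy_scale, cfg.bf_one_sided
            ),
            t_o,
            n_o,
            t_r,
            n_r,
        )
    if "sceptical_p" in wanted:
        ev["scep_p"] = inference.sceptical_p((t_o, n_o), (t_r, n_r))
    return ev


#: evidence-table column holding each metric's statistic.
STAT_COLUMN = {
    "significance": "p_rep",
    "small_telescopes": "st_p",
    "meta_classical": "meta_p",
    "jzs_bf": "jzs",
    "replication_bf": "rep_bf",
    "meta_bayes": "meta_bf",
    "sceptical_p": "scep_p",
}


def _gate(ev: pd.DataFrame, metric_id: str, config: SimConfig) -> np.ndarray:
    """Sign gates: boolean mask of pairs eligible for success at any threshold."""
    d_o = ev["d_o"].to_numpy(float) > 0
    d_r = ev["d_r"].to_numpy(float) > 0
    if metric_id == "significance":
        return (d_o & d_r) if config.significance_requires_original_sign else d_r
    if metric_id in ("small_telescopes", "sceptical_p"):
        return d_o
    if metric_id in ("meta_classical", "meta_bayes"):
        return d_o & (ev["meta_d"].to_numpy(float) > 0)
    if metric_id == "jzs_bf":
        return d_o & d_r
    if metric_id == "replication_bf":  # applicability handled separately
        return np.ones(len(ev), dtype=bool)
    raise ValueError(f"unknown metric_id {metric_id!r}")


def success_from_evidence(
    ev: pd.DataFrame,
    metric_id: str,
    threshold: float,
    config: SimConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(success, applicable) boolean arrays at one threshold.

    ``applicable`` is all-true except for the replication BF, where pairs with
    a non-significant original are excluded.
    """
    cfg = config or SimConfig()
    stat = ev[STAT_COLUMN[metric_id]].to_numpy(float)
    gate = _gate(ev, metric_id, cfg)
    applicable = np.ones(len(ev), dtype=bool)
    if metric_id == "replication_bf":
        applicable = ev["p_o"].to_numpy(float) < cfg.pub_alpha
    if metric_id == "small_telescopes":
        ok = stat > cfg.small_telescopes_alpha  # fixed rule, threshold pinned
    elif metric_id in P_KIND:
        ok = stat < threshold
    else:
        ok = stat > threshold
    return gate & ok & applicable, applicable
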