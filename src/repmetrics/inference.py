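"""Statistical primitives behind the replication-success metrics.

All operations work on one-sample designs summarized by (t statistic, sample
size); sample-summary objects with ``.t`` / ``.n`` attributes (such as
:class:`repmetrics.studygen.StudySummary`) and plain ``(t, n)`` tuples of
scalars or aligned arrays are both accepted, so the whole module is
vectorized over batches of studies.

Bayes factors
-------------
The three evidence measures are JZS-type Bayes factors for the standardized
effect delta of a one-sample t-test:

* ``jzs_bf10`` — single study: Cauchy(0, r) prior on delta against the point
  null, integrating the noncentral-t likelihood of the observed t.
* ``replication_bf`` — the posterior of delta given the original study (JZS
  prior times original likelihood) is used as the prior for the replication;
  the BF contrasts that informed alternative with delta = 0.
* ``meta_bf10`` — one common delta behind both studies: the joint likelihood
  of the two t statistics under the Cauchy prior against the joint null.

All integrals are evaluated in log space on graded Simpson grids centred on
the likelihood peak(s); grids widen automatically until the integrand has
decayed by at least exp(-30) at the endpoints, and a failure to achieve that
raises :class:`QuadratureError`. Log Bayes factors are clipped to +-700
before exponentiation so extreme inputs saturate instead of overflowing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Any

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "DEFAULT_CAUCHY_SCALE",
    "MetaResult",
    "QuadratureError",
    "noncentral_power",
    "d33",
    "small_telescope_p",
    "fixed_effect_meta",
    "jzs_bf10",
    "replication_bf",
    "meta_bf10",
    "sceptical_p",
    "sceptical_p_from_z",
    "effect_se",
]

DEFAULT_CAUCHY_SCALE = math.sqrt(2.0) / 2.0

#: cap on |log BF| before exponentiation (saturates instead of overflowing).
_LOG_BF_CAP = 700.0


class QuadratureError(RuntimeError):
    """Raised when a Bayes-factor integral cannot be bracketed reliably."""


def _tn(study: Any) -> tuple[np.ndarray, np.ndarray]:
    """Coerce a study summary or (t, n) pair to float arrays."""
    if hasattr(study, "t") and hasattr(study, "n"):
        t, n = study.t, study.n
    else:
        t, n = study
    return np.asarray(t, dtype=float), np.asarray(n, dtype=float)


# -- frequentist primitives --------------------------------------------------


def noncentral_power(delta, n, alpha: float = 0.05):
    """Power of the one-sided one-sample t-test at standardized effect delta.

    P(T' > t_crit) with T' noncentral t (n-1 df, noncentrality delta*sqrt(n))
    and t_crit the upper-alpha quantile of the central t.
    """
    n = np.asarray(n, dtype=float)
    delta = np.asarray(delta, dtype=float)
    df = n - 1.0
    tcrit = stats.t.isf(alpha, df)
    out = stats.nct.sf(tcrit, df, delta * np.sqrt(n))
    return out if out.shape else float(out)


@lru_cache(maxsize=None)
def _d33_cached(n_orig: int, alpha: float, power_target: float) -> float:
    def gap(delta: float) -> float:
        return noncentral_power(delta, n_orig, alpha) - power_target

    lo, hi = 0.0, 10.0
    if not (gap(lo) < 0.0 < gap(hi)):
        raise QuadratureError(
            f"benchmark effect not bracketed in [0, 10] for n={n_orig}, alpha={alpha}"
        )
    return float(optimize.brentq(gap, lo, hi, xtol=1e-12, rtol=8.9e-16))


def d33(n_orig: int, alpha: float = 0.05, power_target: float = 1.0 / 3.0) -> float:
    """Effect size giving the original study ``power_target`` power (default 33%).

    This is the "small telescope" benchmark: the unique delta > 0 at which the
    original design's one-sided t-test has the target power.
    """
    if int(n_orig) < 2:
        raise ValueError("n_orig must be >= 2")
    return _d33_cached(int(n_orig), float(alpha), float(power_target))


def small_telescope_p(replication, benchmark):
    """One-sided p-value for H0: delta = benchmark vs Ha: delta < benchmark.

    Lower-tail probability of the replication t under the noncentral t with
    noncentrality benchmark * sqrt(n_rep). Small values mean the replication
    effect is significantly below the benchmark (a Small Telescopes failure).
    """
    t_r, n_r = _tn(replication)
    if np.any(np.asarray(benchmark) <= 0):
        raise ValueError("benchmark effect must be > 0")
    out = stats.nct.cdf(t_r, n_r - 1.0, np.asarray(benchmark) * np.sqrt(n_r))
    return out if out.shape else float(out)


def effect_se(d, n):
    """Large-sample standard error of Cohen's d: sqrt(1/n + d^2/(2n))."""
    d = np.asarray(d, dtype=float)
    n = np.asarray(n, dtype=float)
    return np.sqrt(1.0 / n + d * d / (2.0 * n))


@dataclass(frozen=True)
class MetaResult:
    """Fixed-effect meta-analytic combination of two standardized effects."""

    d_combined: Any
    se_combined: Any
    z: Any
    p: Any


def fixed_effect_meta(original, replication) -> MetaResult:
    """Inverse-variance fixed-effect meta-analysis of original + replication.

    Per-study Cohen's d with variance 1/n + d^2/(2n); the combined estimate is
    the inverse-variance weighted mean, tested one-sided against zero with a
    normal reference.
    """
    t_o, n_o = _tn(original)
    t_r, n_r = _tn(replication)
    d_o, d_r = t_o / np.sqrt(n_o), t_r / np.sqrt(n_r)
    w_o = 1.0 / effect_se(d_o, n_o) ** 2
    w_r = 1.0 / effect_se(d_r, n_r) ** 2
    d_c = (w_o * d_o + w_r * d_r) / (w_o + w_r)
    se_c = 1.0 / np.sqrt(w_o + w_r)
    z = d_c / se_c
    p = stats.norm.sf(z)
    if np.ndim(d_c) == 0:
        return MetaResult(float(d_c), float(se_c), float(z), float(p))
    return MetaResult(d_c, se_c, z, p)


# -- Bayes-factor quadrature -------------------------------------------------

# standard integration abscissae: a dense uniform core (Simpson-accurate
# across the likelihood peak) with geometrically graded tails out to +-3x the
# core half-width, mapped per study onto delta = centre + halfwidth * u / 15.
_U_CORE = np.linspace(-15.0, 15.0, 401)
_U_TAIL = 15.0 * np.geomspace(1.0, 3.0, 25)[1:]
_U_GRID = np.concatenate([-_U_TAIL[::-1], _U_CORE, _U_TAIL])


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(80)

#: above this df, scipy's noncentral-t implementation can overflow; switch to
#: direct integration over the chi scale factor.
_LARGE_DF = 2000.0


def _nct_logpdf_chi(x, df, nc) -> np.ndarray:
    """Noncentral-t log density by quadrature over u = sqrt(chi2_df / df).

    f(x) = int phi(x u - nc) u g_df(u) du with g_df the density of u, which
    for large df concentrates at 1 with spread ~ 1/sqrt(2 df); Gauss-Legendre
    over +-8 spreads is then essentially exact, and log-gamma keeps every
    factor finite at arbitrarily large df.
    """
    from scipy.special import gammaln, logsumexp

    x, df, nc = np.broadcast_arrays(
        np.asarray(x, float), np.asarray(df, float), np.asarray(nc, float)
    )
    su = 1.0 / np.sqrt(2.0 * df)
    u = 1.0 + 8.0 * su[..., None] * _GL_NODES
    logw = np.log(8.0 * su)[..., None] + np.log(_GL_WEIGHTS)
    half = df[..., None] / 2.0
    log_g = (
        math.log(2.0)
        + half * np.log(half)
        - gammaln(half)
        + (df[..., None] - 1.0) * np.log(u)
        - half * u * u
    )
    li = stats.norm.logpdf(x[..., None] * u - nc[..., None]) + np.log(u) + log_g
    return logsumexp(li + logw, axis=-1)


def _scipy_nct_rescued(x, df, nc) -> np.ndarray:
    """scipy nct.logpdf with raising elements recomputed via the chi path.

    boost can overflow for isolated deep-tail (x, df, nc) combinations, which
    aborts a whole vectorized call; bisect down to the offending elements and
    patch them. The flat arrays are assumed 1-D.
    """
    try:
        with np.errstate(invalid="ignore"):
            return np.asarray(stats.nct.logpdf(x, df, nc))
    except (FloatingPointError, OverflowError, ValueError):
        if x.size == 1:
            return _nct_logpdf_chi(x, df, nc)
        h = x.size // 2
        return np.concatenate(
            [
                _scipy_nct_rescued(x[:h], df[:h], nc[:h]),
                _scipy_nct_rescued(x[h:], df[h:], nc[h:]),
            ]
        )


def _nct_logpdf(x, df, nc) -> np.ndarray:
    """Noncentral-t log density, robust across extreme df and noncentrality.

    scipy's boost implementation is accurate near the density peak but can
    return NaN or overflow deep in the tails (true log density hundreds of
    units below any integrand peak; -inf is the safe substitute for NaN and
    the chi-scale quadrature rescues overflowing elements), and fails
    outright at very large df, where the chi path takes over entirely. The
    outer quadrature's decay check still errors out if a whole integrand
    vanishes.
    """
    x, df, nc = np.broadcast_arrays(
        np.asarray(x, float), np.asarray(df, float), np.asarray(nc, float)
    )
    shape = x.shape
    xf, dff, ncf = (np.ascontiguousarray(a, float).ravel() for a in (x, df, nc))
    # deep-tail screen: in the noncentrality direction the density falls off
    # essentially like a Gaussian with scale sqrt(1 + x^2/(2 df)); beyond 25
    # of those scales it is > 55 log-units below the peak (checked
    # empirically across df from 2 to 1000), so -inf is exact enough and the
    # boost code never sees the regions where it is slow or fails.
    sd = np.sqrt(1.0 + xf * xf / (2.0 * dff))
    zz = (xf - ncf * (1.0 + 3.0 / (4.0 * dff))) / sd
    live = np.abs(zz) < 25.0
    out = np.full(xf.shape, -np.inf)
    big = (dff > _LARGE_DF) & live
    small = ~(dff > _LARGE_DF) & live
    if small.any():
        out[small] = _scipy_nct_rescued(xf[small], dff[small], ncf[small])
    if big.any():
        out[big] = _nct_logpdf_chi(xf[big], dff[big], ncf[big])
    out = np.where(np.isnan(out), -np.inf, out)
    return out.reshape(shape)


def _d_and_scale(t: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Peak location and width of the t-likelihood viewed as a function of delta."""
    df = n - 1.0
    d = t / np.sqrt(n)
    s = np.sqrt((1.0 + t * t / (2.0 * df)) / n)
    return d, s


def _log_simpson_exp(logf: np.ndarray, x: np.ndarray) -> np.ndarray:
    """log of integral exp(logf) dx along the last axis, shift-protected."""
    m = np.max(logf, axis=-1, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    val = integrate.simpson(np.exp(logf - m), x=x, axis=-1)
    with np.errstate(divide="ignore"):
        return np.log(val) + m[..., 0]


def _log_integral(log_f, lo: np.ndarray, hi: np.ndarray, max_widen: int = 6) -> np.ndarray:
    """log of integral exp(log_f(delta)) ddelta with adaptive bracket widening.

    ``log_f`` maps a (batch, grid) array of delta values to log integrand
    values. The bracket [lo, hi] is the region the dense core must cover; the
    graded tails extend 3x beyond it. Rows whose integrand has not decayed by
    exp(-30) at the grid endpoints are recomputed on a doubled bracket.
    """
    lo = np.array(lo, dtype=float, ndmin=1, copy=True)
    hi = np.array(hi, dtype=float, ndmin=1, copy=True)
    out = np.full(lo.shape, np.nan)
    todo = np.ones(lo.shape, dtype=bool)
    for _ in range(max_widen):
        mid = 0.5 * (lo[todo] + hi[todo])
        half = 0.5 * (hi[todo] - lo[todo])
        delta = mid[:, None] + half[:, None] * (_U_GRID / 15.0)
        lf = log_f(delta, todo)
        out[todo] = _log_simpson_exp(lf, delta)
        peak = np.max(lf, axis=-1)
        decayed = (lf[:, 0] < peak - 30.0) & (lf[:, -1] < peak - 30.0)
        still = np.where(todo)[0][~decayed]
        if still.size == 0:
            return out
        todo = np.zeros(lo.shape, dtype=bool)
        todo[still] = True
        mid_s, half_s = 0.5 * (lo[still] + hi[still]), 0.5 * (hi[still] - lo[still])
        lo[still] = mid_s - 2.0 * half_s
        hi[still] = mid_s + 2.0 * half_s
    raise QuadratureError(
        f"integrand failed to decay at grid endpoints for {int(todo.sum())} input(s)"
    )


def _log_cauchy_prior(delta: np.ndarray, scale: float, one_sided: bool) -> np.ndarray:
    lp = stats.cauchy.logpdf(delta, scale=scale)
    if one_sided:
        lp = np.where(delta > 0, lp + math.log(2.0), -np.inf)
    return lp


def _clip_exp(log_bf: np.ndarray, scalar: bool):
    out = np.exp(np.clip(log_bf, -_LOG_BF_CAP, _LOG_BF_CAP))
    return float(out[0]) if scalar else out


def jzs_bf10(t, n, cauchy_scale: float = DEFAULT_CAUCHY_SCALE, one_sided: bool = False):
    """JZS Bayes factor BF10 for a single one-sample t-test.

    BF10 = integral of nct(t; n-1, delta*sqrt(n)) Cauchy(delta; 0, r) ddelta
    divided by the central t density of t. Values above 1 favour the presence
    of an effect. ``one_sided=True`` folds the prior onto delta > 0.
    """
    t_arr, n_arr = np.broadcast_arrays(*_tn((t, n)))
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr).astype(float)
    n_arr = np.atleast_1d(n_arr).astype(float)
    df = n_arr - 1.0
    d, s = _d_and_scale(t_arr, n_arr)
    lo, hi = d - 15.0 * s, d + 15.0 * s
    if one_sided:
        # the folded prior lives on delta > 0; make sure the core reaches it
        lo = np.minimum(lo, 0.0)
        hi = np.maximum(hi, np.maximum(15.0 * s, cauchy_scale))

    def log_f(delta: np.ndarray, mask: np.ndarray) -> np.ndarray:
        ll = _nct_logpdf(
            t_arr[mask, None], df[mask, None], delta * np.sqrt(n_arr[mask, None])
        )
        return ll + _log_cauchy_prior(delta, cauchy_scale, one_sided)

    log_num = _log_integral(log_f, lo, hi)
    log_den = stats.t.logpdf(t_arr, df)
    return _clip_exp(log_num - log_den, scalar)


def _pair_arrays(original, replication) -> tuple[np.ndarray, ...]:
    t_o, n_o = _tn(original)
    t_r, n_r = _tn(replication)
    t_o, n_o, t_r, n_r = np.broadcast_arrays(t_o, n_o, t_r, n_r)
    scalar = t_o.ndim == 0
    arrs = tuple(np.atleast_1d(a).astype(float) for a in (t_o, n_o, t_r, n_r))
    return (*arrs, scalar)


def _joint_bracket(
    t_o, n_o, t_r, n_r, one_sided: bool = False, cauchy_scale: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    d_o, s_o = _d_and_scale(t_o, n_o)
    d_r, s_r = _d_and_scale(t_r, n_r)
    lo = np.minimum(d_o - 15.0 * s_o, d_r - 15.0 * s_r)
    hi = np.maximum(d_o + 15.0 * s_o, d_r + 15.0 * s_r)
    if one_sided:
        # folded prior lives on delta > 0; keep that region inside the core
        lo = np.minimum(lo, 0.0)
        hi = np.maximum(hi, np.maximum(15.0 * np.maximum(s_o, s_r), cauchy_scale))
    return lo, hi


def replication_bf(
    original,
    replication,
    cauchy_scale: float = DEFAULT_CAUCHY_SCALE,
    one_sided: bool = False,
):
    """Replication Bayes factor: informed alternative vs delta = 0.

    The alternative's prior is the posterior of delta given the original study
    (noncentral-t likelihood times the JZS Cauchy prior, normalized
    numerically); the BF is the marginal likelihood of the replication t under
    that prior over its density under the null. Values above 1 mean the
    replication supports an effect like the original's. The measure is meant
    for significant originals; it is computed for any inputs.
    """
    t_o, n_o, t_r, n_r, scalar = _pair_arrays(original, replication)
    df_r = n_r - 1.0
    log_z_orig, log_z_joint = _posterior_and_joint(
        t_o, n_o, t_r, n_r, cauchy_scale, one_sided
    )
    log_bf = log_z_joint - log_z_orig - stats.t.logpdf(t_r, df_r)
    return _clip_exp(log_bf, scalar)


def _posterior_and_joint(
    t_o, n_o, t_r, n_r, cauchy_scale: float, one_sided: bool, max_widen: int = 6
) -> tuple[np.ndarray, np.ndarray]:
    """log of the prior-times-original and prior-times-both-likelihood
    integrals over delta, evaluated on one shared widening grid so each
    likelihood is computed once per pair."""
    df_o, df_r = n_o - 1.0, n_r - 1.0
    sqrt_no, sqrt_nr = np.sqrt(n_o), np.sqrt(n_r)
    lo, hi = _joint_bracket(t_o, n_o, t_r, n_r, one_sided, cauchy_scale)
    lo, hi = lo.copy(), hi.copy()
    z_orig = np.full(lo.shape, np.nan)
    z_joint = np.full(lo.shape, np.nan)
    todo = np.ones(lo.shape, dtype=bool)
    for _ in range(max_widen):
        mid = 0.5 * (lo[todo] + hi[todo])
        half = 0.5 * (hi[todo] - lo[todo])
        delta = mid[:, None] + half[:, None] * (_U_GRID / 15.0)
        ll_o = _nct_logpdf(t_o[todo, None], df_o[todo, None], delta * sqrt_no[todo, None])
        ll_r = _nct_logpdf(t_r[todo, None], df_r[todo, None], delta * sqrt_nr[todo, None])
        log_post = ll_o + _log_cauchy_prior(delta, cauchy_scale, one_sided)
        log_joint = log_post + ll_r
        z_orig[todo] = _log_simpson_exp(log_post, delta)
        z_joint[todo] = _log_simpson_exp(log_joint, delta)
        decayed = np.ones(delta.shape[0], dtype=bool)
        for lf in (log_post, log_joint):
            peak = np.max(lf, axis=-1)
            decayed &= (lf[:, 0] < peak - 30.0) & (lf[:, -1] < peak - 30.0)
        still = np.where(todo)[0][~decayed]
        if still.size == 0:
            return z_orig, z_joint
        todo = np.zeros(lo.shape, dtype=bool)
        todo[still] = True
        mid_s, half_s = 0.5 * (lo[still] + hi[still]), 0.5 * (hi[still] - lo[still])
        lo[still] = mid_s - 2.0 * half_s
        hi[still] = mid_s + 2.0 * half_s
    raise QuadratureError(
        f"posterior integrand failed to decay for {int(todo.sum())} pair(s)"
    )


def meta_bf10(
    original,
    replication,
    cauchy_scale: float = DEFAULT_CAUCHY_SCALE,
    one_sided: bool = False,
):
    """Fixed-effect meta-analytic JZS Bayes factor for two studies.

    One common delta generates both t statistics; BF10 integrates the joint
    noncentral-t likelihood against the Cauchy prior and divides by the joint
    central-t density (the point null for both studies).
    """
    t_o, n_o, t_r, n_r, scalar = _pair_arrays(original, replication)
    df_o, df_r = n_o - 1.0, n_r - 1.0
    sqrt_no, sqrt_nr = np.sqrt(n_o), np.sqrt(n_r)

    def log_joint(delta: np.ndarray, mask: np.ndarray) -> np.ndarray:
        ll = _nct_logpdf(t_o[mask, None], df_o[mask, None], delta * sqrt_no[mask, None])
        lr = _nct_logpdf(t_r[mask, None], df_r[mask, None], delta * sqrt_nr[mask, None])
        return ll + lr + _log_cauchy_prior(delta, cauchy_scale, one_sided)

    lo, hi = _joint_bracket(t_o, n_o, t_r, n_r, one_sided, cauchy_scale)
    log_num = _log_integral(log_joint, lo, hi)
    log_den = stats.t.logpdf(t_o, df_o) + stats.t.logpdf(t_r, df_r)
    return _clip_exp(log_num - log_den, scalar)


# -- sceptical p-value -------------------------------------------------------


def sceptical_p_from_z(z_o, z_r, c):
    """One-sided sceptical p-value from the pair's z statistics.

    ``z_o`` and ``z_r`` are the original and replication standardized-effect
    z values (d / se with se = sqrt(1/n + d^2/(2n))) and ``c`` the variance
    ratio se_o^2 / se_r^2. The sceptical p-value is the smallest one-sided
    level at which the sufficiently sceptical zero-mean normal prior — the one
    whose posterior, combined with the original data, has a credible interval
    just reaching zero — is itself contradicted by the replication estimate.

    Solving both conditions simultaneously gives z_s^2 as the positive root of
    (c - 1) x^2 + (z_o^2 + z_r^2) x - z_o^2 z_r^2 = 0 and p_s = Phi(-z_s).
    Pairs with a non-positive original or replication z cannot show one-sided
    replication success; they return 1 - p_s >= 0.5 instead.
    """
    z_o = np.asarray(z_o, dtype=float)
    z_r = np.asarray(z_r, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("variance ratio c must be > 0")
    zo2, zr2 = z_o * z_o, z_r * z_r
    s = zo2 + zr2
    disc = s * s + 4.0 * (c - 1.0) * zo2 * zr2
    denom = s + np.sqrt(disc)
    with np.errstate(invalid="ignore"):
        x = np.where(denom > 0, 2.0 * zo2 * zr2 / np.where(denom > 0, denom, 1.0), 0.0)
    z_s = np.sqrt(x)
    concordant = (z_o > 0) & (z_r > 0)
    out = np.where(concordant, stats.norm.sf(z_s), stats.norm.cdf(z_s))
    return out if out.shape else float(out)


def sceptical_p(original, replication):
    """One-sided sceptical p-value of an original/replication pair."""
    t_o, n_o = _tn(original)
    t_r, n_r = _tn(replication)
    d_o, d_r = t_o / np.sqrt(n_o), t_r / np.sqrt(n_r)
    se_o, se_r = effect_se(d_o, n_o), effect_se(d_r, n_r)
    return sceptical_p_from_z(d_o / se_o, d_r / se_r, (se_o / se_r) ** 2)
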