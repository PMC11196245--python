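"""Survival statistics used to judge synthetic-versus-actual similarity.

The evaluation battery rests on four estimators:

* the Kaplan-Meier product-limit curve with Greenwood variance,
* the median survival time (MST) with a Brookmeyer-Crowley style
  confidence interval obtained by inverting a transformed pointwise band,
* the two-group Cox proportional-hazards hazard ratio (Efron tie
  handling), from which the hazard-ratio distance ``HRD = 1 - |HR - 1|``
  is computed — HRD equals 1 exactly when the two hazards coincide and
  decreases (possibly below zero) as they diverge,
* the two-sample log-rank test.

All estimators are implemented from their defining formulas so that they
can be cross-checked against independent survival toolchains in the test
suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "MedianEstimate",
    "HRDResult",
    "km_curve",
    "median_survival",
    "cox_hr",
    "hrd",
    "logrank_test",
    "evaluate_pair",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Cox partial-likelihood optimization failed (e.g. complete separation)."""


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate on the grid of distinct event times."""

    event_times: np.ndarray  # strictly increasing, days
    n_at_risk: np.ndarray  # n_i just before each event time
    n_events: np.ndarray  # d_i at each event time
    survival: np.ndarray  # S(t_i) = prod_{j<=i} (1 - d_j/n_j)
    greenwood_var: np.ndarray  # Var(S(t_i)) by Greenwood's formula

    def survival_at(self, t: float) -> float:
        """Step-function value S(t), right-continuous."""
        i = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])


@dataclass(frozen=True)
class MedianEstimate:
    """Median survival time in days with its confidence interval.

    Any of the three values may be ``None``: the median is undefined when
    the curve never falls to 0.5, and either CI bound is undefined when
    the corresponding band never crosses 0.5 (open-ended interval).
    """

    mst: float | None
    ci_low: float | None
    ci_high: float | None
    conf_level: float


@dataclass(frozen=True)
class HRDResult:
    hr: float
    hrd: float
    reference_group: str = "actual"


def _check_surv_input(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape or t.ndim != 1 or len(t) == 0:
        raise ValueError("times and events must be equal-length non-empty 1-d arrays")
    if np.any(t <= 0):
        raise ValueError("survival times must be strictly positive")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event flags must be 0 or 1")
    return t, e


def km_curve(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    At tied times, events are processed before censorings (subjects
    censored at t remain in the risk set for events at t).  With an
    all-censored input the curve has no event times and is flat at 1.
    """
    t, e = _check_surv_input(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    ev_times = np.unique(t[e == 1])
    if len(ev_times) == 0:
        z = np.array([])
        return SurvivalCurve(z, z, z, z, z)
    # risk set at u: all subjects with observed time >= u
    n_at_risk = np.array([(t >= u).sum() for u in ev_times], dtype=float)
    n_events = np.array([((t == u) & (e == 1)).sum() for u in ev_times], dtype=float)
    frac = 1.0 - n_events / n_at_risk
    surv = np.cumprod(frac)
    # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d))); the term is
    # singular where d == n (S has reached 0, variance is 0 there).
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = n_events / (n_at_risk * (n_at_risk - n_events))
    terms[n_at_risk == n_events] = 0.0
    var = surv**2 * np.cumsum(terms)
    var[surv == 0.0] = 0.0
    return SurvivalCurve(ev_times, n_at_risk, n_events, surv, var)


def _pointwise_band(
    curve: SurvivalCurve, conf_level: float, transform: str
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise confidence band for S(t) on the event-time grid."""
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    s = curve.survival
    se = np.sqrt(curve.greenwood_var)
    lo = np.empty_like(s)
    hi = np.empty_like(s)
    interior = (s > 0.0) & (s < 1.0) & (se > 0.0)
    if transform == "plain":
        lo = np.clip(s - z * se, 0.0, 1.0)
        hi = np.clip(s + z * se, 0.0, 1.0)
    elif transform == "log":
        lo[:] = s
        hi[:] = s
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.exp(z * se / s)
        lo[interior] = (s / rel)[interior]
        hi[interior] = np.clip((s * rel)[interior], 0.0, 1.0)
    elif transform == "loglog":
        # band on log(-log S); keeps limits inside [0, 1]
        lo[:] = s
        hi[:] = s
        with np.errstate(divide="ignore", invalid="ignore"):
            theta = np.exp(z * se / (s * np.log(s)))
        lo[interior] = (s**theta)[interior]  # theta < 1 side
        hi[interior] = (s ** (1.0 / theta))[interior]
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return np.minimum(lo, hi), np.maximum(lo, hi)


def median_survival(
    curve: SurvivalCurve,
    conf_level: float = 0.95,
    transform: Literal["plain", "log", "loglog"] = "loglog",
) -> MedianEstimate:
    """Median survival time with a test-inversion confidence interval.

    The MST is the smallest event time with ``S(t) <= 0.5`` (undefined if
    the curve never reaches 0.5).  The CI inverts the transformed
    pointwise band (Brookmeyer-Crowley construction): the lower bound is
    the first event time at which the band's lower limit falls to 0.5,
    the upper bound the first at which its upper limit does.  A bound the
    band never yields is reported as ``None`` (open-ended).
    """
    if len(curve.event_times) == 0:
        return MedianEstimate(None, None, None, conf_level)
    lo_band, hi_band = _pointwise_band(curve, conf_level, transform)

    def first_leq(vals: np.ndarray) -> float | None:
        idx = np.flatnonzero(vals <= 0.5)
        return float(curve.event_times[idx[0]]) if len(idx) else None

    return MedianEstimate(
        mst=first_leq(curve.survival),
        ci_low=first_leq(lo_band),
        ci_high=first_leq(hi_band),
        conf_level=conf_level,
    )


def _two_group_tables(actual, synthetic):
    """Aggregate the pooled sample per distinct event time.

    Returns arrays over distinct event times: total and group-1 (synthetic)
    risk-set sizes and event counts.
    """
    ta, ea = _check_surv_input(*actual)
    ts, es = _check_surv_input(*synthetic)
    t = np.concatenate([ta, ts])
    e = np.concatenate([ea, es])
    g = np.concatenate([np.zeros(len(ta), int), np.ones(len(ts), int)])
    ev_times = np.unique(t[e == 1])
    if len(ev_times) == 0:
        raise ValueError("no events in either sample")
    n_tot = np.array([(t >= u).sum() for u in ev_times], dtype=float)
    n_1 = np.array([((t >= u) & (g == 1)).sum() for u in ev_times], dtype=float)
    d_tot = np.array([((t == u) & (e == 1)).sum() for u in ev_times], dtype=float)
    d_1 = np.array([((t == u) & (e == 1) & (g == 1)).sum() for u in ev_times], dtype=float)
    return n_tot, n_1, d_tot, d_1


def _efron_loglik_derivs(beta, n_tot, n_1, d_tot, d_1):
    """Log partial likelihood with Efron ties, its gradient and Hessian.

    With a single binary covariate the risk score is exp(beta * g), so the
    sums over the risk set and over tied deaths reduce to group counts.
    """
    eb = math.exp(beta)
    ll = float(np.sum(beta * d_1))
    grad = float(np.sum(d_1))
    hess = 0.0
    for k in range(len(d_tot)):
        d = int(d_tot[k])
        r0 = n_tot[k] - n_1[k]
        r1 = n_1[k]
        s0 = d_tot[k] - d_1[k]
        s1 = d_1[k]
        for l in range(d):
            f = l / d
            denom = (r0 - f * s0) + (r1 - f * s1) * eb
            num = (r1 - f * s1) * eb
            ll -= math.log(denom)
            p = num / denom
            grad -= p
            hess -= p * (1.0 - p)
    return ll, grad, hess


def cox_hr(actual, synthetic, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Hazard ratio of synthetic vs actual from a two-group Cox model.

    Fits ``h(t | g) = h0(t) exp(beta g)`` on the pooled sample with
    ``g = 1`` for synthetic records (actual is the reference), Efron
    handling of tied event times, by Newton iteration to gradient norm
    ``tol``.  Returns ``exp(beta_hat)``.
    """
    tables = _two_group_tables(actual, synthetic)
    n_tot, n_1, d_tot, d_1 = tables
    # complete separation: all events in one group at times when both at risk
    beta = 0.0
    for _ in range(max_iter):
        ll, grad, hess = _efron_loglik_derivs(beta, *tables)
        if abs(grad) <= tol:
            if abs(beta) > 15.0:
                # gradient decays exponentially along a monotone likelihood,
                # so a "converged" huge |beta| still means separation
                raise ConvergenceError(
                    "partial likelihood is monotone in beta (complete "
                    f"separation between groups); beta_hat = {beta:.2f}"
                )
            return math.exp(beta)
        if hess >= 0:  # flat or degenerate direction
            raise ConvergenceError(f"non-concave step at beta={beta:.3g}")
        step = -grad / hess
        # dampen overshoots; |beta| > 30 signals monotone likelihood
        step = max(min(step, 5.0), -5.0)
        beta += step
        if abs(beta) > 30.0:
            raise ConvergenceError(
                "partial likelihood is monotone in beta (complete separation "
                f"between groups); |beta| exceeded 30 (gradient {grad:.3g})"
            )
    raise ConvergenceError(f"Newton did not reach |grad| <= {tol} in {max_iter} iterations")


def hrd(hr: float) -> float:
    """Hazard-ratio distance ``1 - |HR - 1|``.

    Equals 1 iff HR = 1 and decreases as HR moves away from 1; values are
    negative for HR > 2.  Raises on non-positive HR.
    """
    if not hr > 0:
        raise ValueError(f"hazard ratio must be strictly positive, got {hr}")
    return 1.0 - abs(hr - 1.0)


def logrank_test(actual, synthetic) -> tuple[float, float]:
    """Two-sample log-rank chi-square statistic (1 df) and its p-value.

    Uses the hypergeometric variance at each distinct event time.  No
    multiplicity adjustment is applied.
    """
    n_tot, n_1, d_tot, d_1 = _two_group_tables(actual, synthetic)
    exp1 = d_tot * n_1 / n_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        var = d_tot * (n_1 / n_tot) * (1.0 - n_1 / n_tot) * (n_tot - d_tot) / (n_tot - 1.0)
    var[n_tot <= 1] = 0.0
    o_minus_e = float(np.sum(d_1 - exp1))
    v = float(np.nansum(var))
    if v == 0.0:
        return 0.0, 1.0  # groups never simultaneously at risk with events
    stat = o_minus_e**2 / v
    return stat, float(stats.chi2.sf(stat, df=1))


def evaluate_pair(
    actual_table,
    synthetic_table,
    endpoint: Literal["pfs", "os"],
    conf_level: float = 0.95,
    hr_direction: Literal["synthetic_vs_actual", "actual_vs_synthetic"] = "synthetic_vs_actual",
) -> dict:
    """All similarity metrics for one synthetic table against the actual one."""
    a = actual_table.endpoint(endpoint)
    s = synthetic_table.endpoint(endpoint)
    med = median_survival(km_curve(*s), conf_level)
    if hr_direction == "synthetic_vs_actual":
        hr = cox_hr(a, s)
    else:
        hr = cox_hr(s, a)
    stat, p = logrank_test(a, s)
    return {
        "endpoint": endpoint,
        "mst": med.mst,
        "ci_low": med.ci_low,
        "ci_high": med.ci_high,
        "hr": hr,
        "hrd": hrd(hr),
        "logrank_stat": stat,
        "logrank_p": p,
    }
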