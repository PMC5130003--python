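"""Survival-statistics primitives: Kaplan-Meier, Nelson-Aalen, log-rank,
hazard ratios, and a one-covariate Cox-Wald statistic.

All estimators take right-censored samples as parallel arrays of follow-up
times and event indicators (1 = event observed, 0 = censored).  Censored
observations at time t are considered at risk for events at t.

The log-rank code is organised around *prefix partitions*: when patients are
arranged along a fixed axis (sorted by a biomarker value, by AWR, or laid
out in group blocks), the observed/expected/variance quantities of every
contiguous split can be read off cumulative at-risk counts.  One pass builds
the cumulative tables; after that, any candidate cutpoint set is scored in
O(1).  This is what makes the exhaustive cutoff searches in
:mod:`psvmatch.ddg` affordable, and the public tests are thin wrappers over
the same table so a stored optimum is bit-for-bit reproducible by re-testing
the chosen split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import DimensionError, InputError, UndefinedStatisticError

__all__ = [
    "StepFunction",
    "TestResult",
    "km_estimate",
    "nelson_aalen",
    "logrank_test",
    "hazard_ratio",
    "cox_wald",
    "smoothed_hazard",
]


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous piecewise-constant function.

    ``values[i]`` holds on ``[times[i], times[i+1])``; ``initial`` holds
    before ``times[0]``.
    """

    times: np.ndarray
    values: np.ndarray
    initial: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise DimensionError("times and values must be 1-D and equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise InputError("step times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __call__(self, t):
        t_arr = np.asarray(t, dtype=float)
        padded = np.concatenate([[self.initial], self.values])
        out = padded[np.searchsorted(self.times, t_arr, side="right")]
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float


def _validate(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.size == 0:
        raise InputError("empty survival sample")
    if t.shape != e.shape or t.ndim != 1:
        raise DimensionError("times and events must be 1-D and equal length")
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise InputError("survival times must be finite and non-negative")
    if not np.all(np.isin(e, (0, 1))):
        raise InputError("event indicators must be 0 or 1")
    return t, e.astype(np.int64)


def _event_table(t, e):
    """Unique event times with event counts d and at-risk counts n."""
    uniq, d = np.unique(t[e == 1], return_counts=True)
    ts = np.sort(t)
    n_at = t.size - np.searchsorted(ts, uniq, side="left")
    return uniq, d, n_at


def km_estimate(times, events) -> StepFunction:
    """Kaplan-Meier product-limit estimate of the survival function."""
    t, e = _validate(times, events)
    uniq, d, n_at = _event_table(t, e)
    surv = np.cumprod(1.0 - d / n_at)
    return StepFunction(uniq, surv, initial=1.0)


def nelson_aalen(times, events) -> StepFunction:
    """Nelson-Aalen cumulative hazard: H(t) = sum_{event times <= t} d/n."""
    t, e = _validate(times, events)
    uniq, d, n_at = _event_table(t, e)
    return StepFunction(uniq, np.cumsum(d / n_at), initial=0.0)


class PrefixLogRank:
    """Log-rank O/E/V quantities for every contiguous prefix partition.

    Patients are taken in the order supplied (the "axis").  For a boundary
    m, the prefix group is patients ``0..m-1``.  After construction:

    - ``ocum[m]``  observed events in the prefix,
    - ``E[m]``     expected events sum_t d(t) * n1(t)/n(t),
    - ``L[m]``     sum_t c(t) * n1(t)/n(t),
    - ``Bdiag[m]`` sum_t c(t) * n1(t)^2/n(t)^2,

    with c(t) = d(n-d)/(n-1) (0 when n <= 1).  The 2-group statistic for a
    split at m is (O-E)^2 / (L - Bdiag); k-group statistics additionally
    need the bilinear table B[a, b] = sum_t c(t) n1(t,a) n1(t,b)/n(t)^2,
    built lazily via one matrix product.
    """

    def __init__(self, times, events):
        t, e = _validate(times, events)
        self.n_patients = t.size
        self.total_events = int(e.sum())
        uniq, d, n_at = _event_table(t, e)
        self.event_times, self.d, self.n_at = uniq, d, n_at
        with np.errstate(divide="ignore", invalid="ignore"):
            c = d * (n_at - d) / (n_at - 1.0)
        self.c = np.where(n_at > 1, c, 0.0)
        # (T, n) at-risk indicator, cumulated along the patient axis.
        ind = t[None, :] >= uniq[:, None]
        n1 = np.zeros((uniq.size, self.n_patients + 1))
        np.cumsum(ind, axis=1, out=n1[:, 1:])
        self.ocum = np.concatenate([[0], np.cumsum(e)]).astype(float)
        if uniq.size:
            self.E = (d / n_at) @ n1
            self.L = (self.c / n_at) @ n1
            self._cn2 = self.c / n_at**2
            self.Bdiag = self._cn2 @ (n1 * n1)
        else:  # no events at all
            self.E = np.zeros(self.n_patients + 1)
            self.L = np.zeros(self.n_patients + 1)
            self._cn2 = np.zeros(0)
            self.Bdiag = np.zeros(self.n_patients + 1)
        self._n1 = n1
        self._B = None

    @property
    def B(self):
        if self._B is None:
            self._B = self._n1.T @ (self._cn2[:, None] * self._n1)
        return self._B

    def two_group_statistic(self, m):
        """Log-rank chi-squared (1 df) for prefix sizes ``m`` (vectorized)."""
        m = np.asarray(m)
        u = self.ocum[m] - self.E[m]
        v = self.L[m] - self.Bdiag[m]
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(v > 0, u * u / v, 0.0)
        return stat

    def statistic_for_boundaries(self, bounds):
        """Log-rank chi-squared (k-1 df) for boundary matrix ``bounds``.

        ``bounds`` has shape (P, k+1) with each row
        ``0 = b0 < b1 < ... < bk = n`` defining k contiguous groups.
        """
        bounds = np.atleast_2d(np.asarray(bounds))
        k = bounds.shape[1] - 1
        if k == 2:
            return self.two_group_statistic(bounds[:, 1])
        B = self.B
        O = self.ocum[bounds[:, 1:]] - self.ocum[bounds[:, :-1]]
        E = self.E[bounds[:, 1:]] - self.E[bounds[:, :-1]]
        Lg = self.L[bounds[:, 1:]] - self.L[bounds[:, :-1]]
        r = k - 1
        u = (O - E)[:, :r]
        V = np.empty((bounds.shape[0], r, r))
        for g in range(r):
            for h in range(g, r):
                cross = (
                    B[bounds[:, g + 1], bounds[:, h + 1]]
                    - B[bounds[:, g + 1], bounds[:, h]]
                    - B[bounds[:, g], bounds[:, h + 1]]
                    + B[bounds[:, g], bounds[:, h]]
                )
                V[:, g, h] = V[:, h, g] = -cross
            V[:, g, g] += Lg[:, g]
        try:
            x = np.linalg.solve(V, u[..., None])[..., 0]
        except np.linalg.LinAlgError:
            x = np.einsum("pij,pj->pi", np.linalg.pinv(V), u)
        stat = np.einsum("pi,pi->p", u, x)
        return np.maximum(stat, 0.0)

    def observed_expected(self, bounds):
        """Per-group (O, E) arrays for one boundary row."""
        bounds = np.asarray(bounds)
        O = self.ocum[bounds[1:]] - self.ocum[bounds[:-1]]
        E = self.E[bounds[1:]] - self.E[bounds[:-1]]
        return O, E


def _concat_groups(groups):
    cleaned = []
    for g in groups:
        t, e = _validate(*g)
        cleaned.append((t, e))
    times = np.concatenate([t for t, _ in cleaned])
    events = np.concatenate([e for _, e in cleaned])
    bounds = np.concatenate([[0], np.cumsum([t.size for t, _ in cleaned])])
    return times, events, bounds


def logrank_test(groups) -> TestResult:
    """Multi-group log-rank test.

    Parameters
    ----------
    groups : sequence of (times, events) pairs, each non-empty.

    Returns the chi-squared statistic with ``len(groups) - 1`` degrees of
    freedom and its p-value.
    """
    if len(groups) < 2:
        raise InputError("log-rank test needs at least two groups")
    times, events, bounds = _concat_groups(groups)
    plr = PrefixLogRank(times, events)
    stat = float(plr.statistic_for_boundaries(bounds[None, :])[0])
    df = len(groups) - 1
    return TestResult(stat, df, float(sps.chi2.sf(stat, df)))


def hazard_ratio(group_a, group_b) -> float:
    """O/E-ratio hazard ratio of group a relative to group b.

    HR = (O_a/E_a) / (O_b/E_b) from the pooled log-rank table.  Requires at
    least one event in each group; satisfies HR(a, b) = 1/HR(b, a).
    """
    times, events, bounds = _concat_groups([group_a, group_b])
    (Oa, Ob), (Ea, Eb) = _oe_pair(times, events, bounds)
    if Oa == 0 or Ob == 0:
        raise UndefinedStatisticError("hazard ratio undefined: a group has zero events")
    return float((Oa / Ea) / (Ob / Eb))


def _oe_pair(times, events, bounds):
    plr = PrefixLogRank(times, events)
    O, E = plr.observed_expected(bounds)
    return O, E


def cox_wald(times, events, indicator) -> TestResult:
    """Wald chi-squared (1 df) from a one-covariate Cox model.

    ``indicator`` is the binary (0/1) group covariate.  Breslow handling of
    ties; Newton iterations from beta = 0 with a +/-20 cap on beta to guard
    against complete separation.
    """
    t, e = _validate(times, events)
    x = np.asarray(indicator, dtype=float)
    if x.shape != t.shape:
        raise DimensionError("indicator must match times in length")
    if e.sum() == 0:
        raise UndefinedStatisticError("no events: Cox model undefined")
    if np.all(x == x[0]):
        raise UndefinedStatisticError("constant covariate")
    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    uniq, d, _ = _event_table(t, e)
    # index of first patient still at risk at each event time
    start = np.searchsorted(t, uniq, side="left")
    sx_events = np.array([x[(t == u) & (e == 1)].sum() for u in uniq])
    beta = 0.0
    for _ in range(25):
        w = np.exp(beta * x)
        # suffix sums over the at-risk sets
        s0_all = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
        s1_all = np.concatenate([np.cumsum((w * x)[::-1])[::-1], [0.0]])
        s2_all = np.concatenate([np.cumsum((w * x * x)[::-1])[::-1], [0.0]])
        s0, s1, s2 = s0_all[start], s1_all[start], s2_all[start]
        mu = s1 / s0
        score = float(np.sum(sx_events - d * mu))
        info = float(np.sum(d * (s2 / s0 - mu * mu)))
        if info <= 0:
            break
        step = score / info
        beta = float(np.clip(beta + step, -20.0, 20.0))
        if abs(step) < 1e-10:
            break
    stat = beta * beta * info if info > 0 else 0.0
    return TestResult(float(stat), 1, float(sps.chi2.sf(stat, 1)))


def smoothed_hazard(times, events, bandwidth=None, grid=None):
    """Kernel-smoothed hazard from Nelson-Aalen increments.

    Epanechnikov kernel; default bandwidth is one tenth of the observed
    follow-up range.  Display aid only — no decision rule uses it.
    """
    t, e = _validate(times, events)
    uniq, d, n_at = _event_table(t, e)
    if uniq.size == 0:
        grid = np.linspace(0, t.max() if t.max() > 0 else 1.0, 100) if grid is None else np.asarray(grid)
        return grid, np.zeros_like(grid, dtype=float)
    if bandwidth is None:
        span = float(t.max() - t.min())
        bandwidth = span / 10.0 if span > 0 else 1.0
    if grid is None:
        grid = np.linspace(0, float(t.max()), 200)
    grid = np.asarray(grid, dtype=float)
    incr = d / n_at
    z = (grid[:, None] - uniq[None, :]) / bandwidth
    kern = np.where(np.abs(z) <= 1, 0.75 * (1 - z * z), 0.0) / bandwidth
    return grid, kern @ incr


def plot_survival_panels(groups, labels=None, path=None):
    """KM / cumulative-hazard / smoothed-hazard panel plot for 2+ groups.

    ``groups`` is a sequence of (times, events) pairs.  Returns the figure;
    saves to ``path`` (SVG/PNG by extension) when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = labels or [f"group {i + 1}" for i in range(len(groups))]
    fig, axes = plt.subplots(1, 3, figsize=(13, 3.8))
    for (t, e), lab in zip(groups, labels):
        t = np.asarray(t, dtype=float)
        km = km_estimate(t, e)
        na = nelson_aalen(t, e)
        gx = np.linspace(0, t.max(), 200)
        axes[0].step(np.r_[0, km.times], np.r_[1.0, km.values], where="post", label=lab)
        axes[1].step(np.r_[0, na.times], np.r_[0.0, na.values], where="post", label=lab)
        axes[2].plot(*smoothed_hazard(t, e, grid=gx), label=lab)
    for ax, title in zip(axes, ("Kaplan-Meier", "Cumulative hazard", "Hazard")):
        ax.set_title(title)
        ax.set_xlabel("time")
    axes[0].set_ylabel("S(t)")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path)
    return fig
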