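"""One-dimensional data-driven grouping (1D-DDg) and cohort stratification.

For each continuous prognostic variable (a gene's expression, or age), the
cohort is dichotomized at the cutoff that maximizes the separation of the
two Kaplan-Meier curves, scored by the 2-group log-rank statistic (or a
1-covariate Cox-Wald statistic, configurable).  The side of the cutoff with
the worse outcome (O/E hazard ratio > 1) is labelled high risk, so every
fitted variable has hazard_ratio >= 1 by construction.  The variable's
weight is -log10 of the minimized p-value; a signature orders its variables
by descending weight (the "variable axis").

Cohort-level stratification assigns each patient a risk-group label by an
exhaustive search over AWR cutpoints that maximizes the multi-group
log-rank statistic — an AWR-cutpoint simplification of statistically
weighted voting grouping, recorded in the model file as
``method = "awr-cutpoint"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

from . import signature as sig
from .exceptions import (
    ConfigError,
    FitError,
    InputError,
    NoCutoffError,
    StratificationError,
)
from .survival import PrefixLogRank, cox_wald, hazard_ratio, logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "VariableModel",
    "SignatureModel",
    "FitConfig",
    "StratifyResult",
    "ddg_fit",
    "ddg_apply",
    "fit_signature",
    "stratify_cohort",
    "quantile_group",
    "stratification_permutation_p",
]

# p-values are floored before taking -log10 so weights stay finite even for
# overwhelming separations.
_P_FLOOR = 1e-300


def group_label_names(n_groups: int) -> list[str]:
    if n_groups == 2:
        return ["low", "high"]
    if n_groups == 3:
        return ["low", "intermediate", "high"]
    return [f"group{i + 1}" for i in range(n_groups)]


@dataclass(frozen=True)
class VariableModel:
    """One variable's fitted binarization rule."""

    variable_id: str
    cutoff: float
    high_side: bool  # True: values > cutoff are high risk
    p_value: float
    weight: float
    hazard_ratio: float
    n_cutoffs_searched: int = 0

    def classify(self, value) -> int:
        """1 (low risk) or 2 (high risk).  Boundary values belong to the
        '<= cutoff' side."""
        if not np.isfinite(value):
            raise InputError(f"missing value for variable {self.variable_id!r}")
        above = value > self.cutoff
        return 2 if above == self.high_side else 1


def ddg_apply(model: VariableModel, value) -> int:
    """Binary risk value {1, 2} of ``value`` under a fitted variable rule."""
    return model.classify(value)


@dataclass
class FitConfig:
    """Knobs for signature fitting and stratification."""

    statistic: str = "logrank"  # or "wald"
    min_group_frac: float = 0.1
    top_n: int | None = None
    n_groups: int = 3

    def __post_init__(self):
        if self.statistic not in ("logrank", "wald"):
            raise ConfigError(f"unknown statistic {self.statistic!r}")
        if not 0 < self.min_group_frac <= 0.5:
            raise ConfigError("min_group_frac must be in (0, 0.5]")
        if not 2 <= self.n_groups <= 5:
            raise ConfigError("n_groups must be between 2 and 5")


def _candidate_boundaries(sorted_values, gmin):
    """Prefix sizes m where a cut between distinct values is admissible."""
    n = sorted_values.size
    ms = np.arange(gmin, n - gmin + 1)
    distinct = sorted_values[ms - 1] < sorted_values[ms] if ms.size else np.array([], bool)
    return ms[distinct]


def ddg_fit(values, times, events, min_group_frac=0.1, statistic="logrank") -> VariableModel:
    """Optimal survival-driven dichotomization of one variable.

    Cutoffs are midpoints of consecutive distinct sorted values such that
    both sides keep at least ``ceil(min_group_frac * N)`` patients; the
    cutoff minimizing the test p-value wins (first optimum on ties, i.e.
    the lowest cutoff).  The returned p-value and hazard ratio are
    recomputed on the chosen split through the public tests, so re-splitting
    the cohort at the stored cutoff reproduces them bit-for-bit.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if not (v.shape == t.shape == e.shape):
        raise InputError("values, times and events must be equal length")
    keep = np.isfinite(v)
    v, t, e = v[keep], t[keep], e[keep].astype(np.int64)
    n = v.size
    if n == 0:
        raise InputError("no patients with non-missing values")
    if e.sum() == 0:
        raise InputError("all observations censored: no cutoff can separate survival")
    gmin = math.ceil(min_group_frac * n)
    order = np.argsort(v, kind="stable")
    vs = v[order]
    ms = _candidate_boundaries(vs, gmin)
    if ms.size == 0:
        raise NoCutoffError(
            "no admissible cutoff (constant variable or min_group_frac too large)"
        )
    ts, es = t[order], e[order]
    if statistic == "logrank":
        plr = PrefixLogRank(ts, es)
        stats_arr = plr.two_group_statistic(ms)
    elif statistic == "wald":
        stats_arr = np.array(
            [cox_wald(ts, es, (np.arange(n) >= m).astype(float)).statistic for m in ms]
        )
    else:
        raise ConfigError(f"unknown statistic {statistic!r}")
    best = int(np.argmax(stats_arr))
    m = int(ms[best])
    cutoff = float((vs[m - 1] + vs[m]) / 2.0)

    # final statistics are recomputed through the public tests so that
    # re-splitting the cohort at the stored cutoff reproduces the stored
    # p-value and hazard ratio bit-for-bit
    below = v <= cutoff
    if statistic == "logrank":
        res = logrank_test([(t[below], e[below]), (t[~below], e[~below])])
    else:
        res = cox_wald(t, e, (~below).astype(float))
    O_below, O_above = int(e[below].sum()), int(e[~below].sum())
    if O_below == 0 and O_above == 0:
        high_side, hr = True, 1.0
    elif O_below == 0:
        high_side, hr = True, np.inf
    elif O_above == 0:
        high_side, hr = False, np.inf
    else:
        hr_above = hazard_ratio((t[~below], e[~below]), (t[below], e[below]))
        high_side = hr_above >= 1.0
        hr = (
            hr_above
            if high_side
            else hazard_ratio((t[below], e[below]), (t[~below], e[~below]))
        )
    p = max(float(res.p_value), _P_FLOOR)
    return VariableModel(
        variable_id="",
        cutoff=cutoff,
        high_side=bool(high_side),
        p_value=p,
        weight=-math.log10(p),
        hazard_ratio=float(hr),
        n_cutoffs_searched=int(ms.size),
    )


@dataclass(frozen=True)
class StratifyResult:
    labels: np.ndarray  # per-patient group label (strings)
    cutpoints: np.ndarray  # (n_groups - 1) AWR thresholds
    statistic: float
    p_value: float
    n_searched: int


def _boundary_combos(candidates, gmin, n, k, chunk=200_000):
    """Yield (P, k+1) boundary arrays for k groups, group sizes >= gmin."""
    cand = np.asarray(candidates)
    if k == 2:
        b = cand[(cand >= gmin) & (n - cand >= gmin)]
        if b.size:
            out = np.zeros((b.size, 3), dtype=np.int64)
            out[:, 1], out[:, 2] = b, n
            yield out
        return
    if k == 3:
        b1 = cand[:, None]
        b2 = cand[None, :]
        ok = (b2 - b1 >= gmin) & (b1 >= gmin) & (n - b2 >= gmin)
        i, j = np.nonzero(ok)
        for s in range(0, i.size, chunk):
            sl = slice(s, s + chunk)
            out = np.zeros((i[sl].size, 4), dtype=np.int64)
            out[:, 1], out[:, 2], out[:, 3] = cand[i[sl]], cand[j[sl]], n
            yield out
        return
    buf = []
    for combo in combinations(candidates, k - 1):
        b = (0, *combo, n)
        if all(b[g + 1] - b[g] >= gmin for g in range(k)):
            buf.append(b)
            if len(buf) >= chunk:
                yield np.asarray(buf, dtype=np.int64)
                buf = []
    if buf:
        yield np.asarray(buf, dtype=np.int64)


def _best_boundaries(awr_vals, times, events, n_groups, min_group_frac):
    """(best boundary row, best statistic, sorted awr, order, n searched)."""
    a = np.asarray(awr_vals, dtype=float)
    n = a.size
    gmin = math.ceil(min_group_frac * n)
    order = np.argsort(a, kind="stable")
    a_sorted = a[order]
    cand = _candidate_boundaries(a_sorted, gmin)
    plr = PrefixLogRank(np.asarray(times, float)[order], np.asarray(events)[order])
    best_stat, best_bounds, searched = -1.0, None, 0
    for bounds in _boundary_combos(cand, gmin, n, n_groups):
        stats_arr = plr.statistic_for_boundaries(bounds)
        searched += bounds.shape[0]
        i = int(np.argmax(stats_arr))
        if stats_arr[i] > best_stat:
            best_stat, best_bounds = float(stats_arr[i]), bounds[i]
    return best_bounds, best_stat, a_sorted, order, searched


def stratify_cohort(
    awr_vals, times, events, n_groups=3, min_group_frac=0.1
) -> StratifyResult:
    """Optimal AWR-cutpoint stratification into ``n_groups`` risk groups.

    Exhaustive search over all (n_groups - 1)-tuples of cutpoints lying
    between distinct sorted AWR values, each group at least
    ``ceil(min_group_frac * N)`` patients, maximizing the multi-group
    log-rank statistic.  Labels are ordered so mean AWR increases from
    "low" to "high"; membership depends only on a patient's AWR value, so
    the result is invariant to input order.
    """
    if not 2 <= n_groups <= 5:
        raise ConfigError("n_groups must be between 2 and 5")
    best_bounds, best_stat, a_sorted, _, searched = _best_boundaries(
        awr_vals, times, events, n_groups, min_group_frac
    )
    if best_bounds is None:
        raise StratificationError(
            f"no admissible {n_groups}-group cutpoint set under min_group_frac"
        )
    cutpoints = np.array(
        [(a_sorted[m - 1] + a_sorted[m]) / 2.0 for m in best_bounds[1:-1]]
    )
    a = np.asarray(awr_vals, dtype=float)
    idx = np.searchsorted(cutpoints, a, side="left")
    names = group_label_names(n_groups)
    labels = np.array([names[i] for i in idx])
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    res = logrank_test([(t[idx == g], e[idx == g]) for g in range(n_groups)])
    return StratifyResult(labels, cutpoints, res.statistic, res.p_value, searched)


def stratification_permutation_p(
    awr_vals, times, events, n_groups=2, min_group_frac=0.1, n_permutations=100, seed=0
) -> float:
    """Permutation-calibrated p-value for the *optimized* stratification.

    The observed maximal log-rank statistic from the AWR-cutpoint search is
    compared against the same maximal statistic recomputed after randomly
    permuting the AWR-to-survival pairing.  Returns
    (1 + #{perm >= observed}) / (1 + n_permutations), which calibrates away
    the optimism of cutpoint optimization.
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(awr_vals, dtype=float)
    _, obs, _, _, _ = _best_boundaries(a, times, events, n_groups, min_group_frac)
    if obs is None or obs < 0:
        raise StratificationError("no admissible stratification of the observed data")
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(a.size)
        _, stat, _, _, _ = _best_boundaries(a[perm], times, events, n_groups, min_group_frac)
        if stat >= obs:
            exceed += 1
    return (1 + exceed) / (1 + n_permutations)


def quantile_group(awr_vals, n_groups, patient_ids=None) -> np.ndarray:
    """Equal-sized AWR groups (1 = smallest AWR), remainder to the lowest
    groups; ties at a boundary resolved by patient id."""
    a = np.asarray(awr_vals, dtype=float)
    n = a.size
    if n_groups > n:
        raise InputError("more groups than patients")
    ids = np.asarray(patient_ids if patient_ids is not None else np.arange(n))
    order = np.lexsort((ids, a))
    base, rem = divmod(n, n_groups)
    sizes = [base + (1 if g < rem else 0) for g in range(n_groups)]
    labels = np.empty(n, dtype=np.int64)
    start = 0
    for g, s in enumerate(sizes, start=1):
        labels[order[start : start + s]] = g
        start += s
    return labels


@dataclass
class SignatureModel:
    """A fitted prognostic signature plus its reference cohort vectors."""

    variables: list[VariableModel]  # descending weight along the variable axis
    reference_ids: list[str]
    reference_G: np.ndarray  # (n_vars, n_refs) entries in {1, 2}
    reference_V: np.ndarray  # (n_vars, n_refs) PSVs
    reference_awr: np.ndarray  # (n_refs,)
    reference_group: np.ndarray  # (n_refs,) labels
    group_cutpoints: np.ndarray  # AWR thresholds between groups
    majority_risk: np.ndarray  # (n_vars,) training-majority risk per variable
    statistic_used: str = "logrank"
    stratification_method: str = "awr-cutpoint"
    n_groups: int = 3
    min_group_frac: float = 0.1
    reference_values: np.ndarray | None = None  # raw values, for raw-space matching

    @property
    def weights(self) -> np.ndarray:
        return np.array([v.weight for v in self.variables])

    @property
    def variable_ids(self) -> list[str]:
        return [v.variable_id for v in self.variables]

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def group_labels(self) -> list[str]:
        return group_label_names(self.n_groups)

    def reference_vectors(self, patient_id) -> sig.RiskVectors:
        j = self.reference_ids.index(patient_id)
        return sig.RiskVectors.from_g(self.weights, self.reference_G[:, j], patient_id)


def _order_variables(models: list[VariableModel]) -> list[VariableModel]:
    """Descending weight; ties by higher hazard ratio, then id."""
    return sorted(models, key=lambda m: (-m.weight, -m.hazard_ratio, m.variable_id))


def fit_signature(cohort, variable_ids=None, config: FitConfig | None = None) -> SignatureModel:
    """Fit the full prognostic signature on a training cohort.

    Runs :func:`ddg_fit` per variable (variables that cannot be dichotomized
    are dropped with a warning), orders the surviving variables by
    descending weight, optionally truncates to the ``top_n`` heaviest,
    builds the reference PBVV/PSV/AWR matrices, and stratifies the cohort
    into risk groups on the AWR axis.

    Patients with missing survival data are excluded from fitting; a patient
    missing one variable's value is excluded from that variable's
    binarization only, and their PBVV entry is imputed to the cohort
    majority risk for the variable.
    """
    config = config or FitConfig()
    if variable_ids is None:
        variable_ids = list(cohort.variable_ids)
    fitcoh = cohort.with_complete_survival()
    if fitcoh.n_patients < cohort.n_patients:
        logger.warning(
            "excluded %d patients with missing survival data from fitting",
            cohort.n_patients - fitcoh.n_patients,
        )
    times, events = fitcoh.times, fitcoh.events
    fitted = []
    for vid in variable_ids:
        vals = fitcoh.variable_values(vid)
        try:
            vm = ddg_fit(
                vals, times, events,
                min_group_frac=config.min_group_frac,
                statistic=config.statistic,
            )
        except (NoCutoffError, InputError) as exc:
            logger.warning("variable %r excluded from signature: %s", vid, exc)
            continue
        fitted.append(
            VariableModel(vid, vm.cutoff, vm.high_side, vm.p_value, vm.weight,
                          vm.hazard_ratio, vm.n_cutoffs_searched)
        )
    if len(fitted) < 2:
        raise FitError(f"only {len(fitted)} variables survived fitting; need at least 2")
    fitted = _order_variables(fitted)
    if config.top_n is not None:
        fitted = fitted[: config.top_n]

    n_vars, n_pat = len(fitted), fitcoh.n_patients
    G = np.empty((n_vars, n_pat), dtype=np.int64)
    raw = np.empty((n_vars, n_pat), dtype=float)
    majority = np.empty(n_vars, dtype=np.int64)
    for i, vm in enumerate(fitted):
        vals = np.asarray(fitcoh.variable_values(vm.variable_id), dtype=float)
        raw[i] = vals
        ok = np.isfinite(vals)
        calls = np.array([vm.classify(x) for x in vals[ok]])
        majority[i] = 2 if (calls == 2).sum() > (calls == 1).sum() else 1
        G[i, ok] = calls
        G[i, ~ok] = majority[i]

    W = np.array([v.weight for v in fitted])
    D = sig.center(G)
    V = np.cumsum(W[:, None] * D, axis=0)
    awr_vals = W @ G / W.sum()
    strat = stratify_cohort(
        awr_vals, times, events,
        n_groups=config.n_groups, min_group_frac=config.min_group_frac,
    )
    return SignatureModel(
        variables=fitted,
        reference_ids=list(fitcoh.patient_ids),
        reference_G=G,
        reference_V=V,
        reference_awr=awr_vals,
        reference_group=strat.labels,
        group_cutpoints=strat.cutpoints,
        majority_risk=majority,
        statistic_used=config.statistic,
        n_groups=config.n_groups,
        min_group_frac=config.min_group_frac,
        reference_values=raw,
    )
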