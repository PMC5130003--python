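"""Risk-vector algebra: PBVV centering, weighting, cumulative PSV, and AWR.

A patient's binary risk profile G (entries 1 = low risk, 2 = high risk,
one per signature variable, ordered by descending variable weight) is
transformed as

    D = 2 (G - 1.5)            centered profile, entries in {-1, +1}
    A = diag(W) D              weighted adjustment vector
    V_i = sum_{x <= i} A_x     prognostic signature vector (running sum)

and summarised by the average weighted risk

    AWR = sum_i w_i g_i / sum_i w_i   in [1, 2].

The terminal PSV value and the AWR are linked algebraically:
AWR = 1.5 + V_n / (2 sum_i w_i), which the tests use as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import CoverageError, DimensionError, InputError, UndefinedStatisticError

__all__ = ["RiskVectors", "center", "uncenter", "adjust", "psv", "awr", "build_pbvv"]


def center(G):
    """Map binary risk values {1, 2} to centered values {-1, +1}."""
    g = np.asarray(G)
    if not np.all(np.isin(g, (1, 2))):
        raise InputError("PBVV entries must be 1 (low risk) or 2 (high risk)")
    return 2.0 * (g - 1.5)


def uncenter(D):
    """Inverse of :func:`center`: {-1, +1} back to {1, 2}."""
    d = np.asarray(D)
    if not np.all(np.isin(d, (-1, 1))):
        raise InputError("centered entries must be -1 or +1")
    return (d / 2.0 + 1.5).astype(np.int64)


def adjust(W, D):
    """Adjustment vector A = diag(W) D (entrywise product)."""
    w = np.asarray(W, dtype=float)
    d = np.asarray(D, dtype=float)
    if w.shape != d.shape:
        raise DimensionError(f"weight and direction lengths differ: {w.shape} vs {d.shape}")
    return w * d


def psv(A):
    """Prognostic signature vector: running (prefix) sum of A."""
    a = np.asarray(A, dtype=float)
    if np.any(~np.isfinite(a)):
        raise InputError("adjustment vector must be finite")
    return np.cumsum(a)


def awr(W, G):
    """Average weighted risk: weighted mean of the binary risk values."""
    w = np.asarray(W, dtype=float)
    g = np.asarray(G, dtype=float)
    if w.shape != g.shape:
        raise DimensionError("weight and risk vectors must have equal length")
    total = w.sum()
    if total <= 0:
        raise UndefinedStatisticError("AWR undefined for all-zero weights")
    return float(np.dot(w, g) / total)


def build_pbvv(model, values, return_imputed=False):
    """Binary risk profile for one patient against a fitted signature.

    Parameters
    ----------
    model : SignatureModel
        Fitted signature (supplies per-variable cutoff rules, the variable
        axis order, and the training-cohort majority risk used to impute
        missing entries).
    values : mapping or sequence
        Variable values, either a mapping ``variable_id -> value`` or a
        sequence already in the model's variable-axis order.  ``NaN`` or an
        absent key marks a missing value.
    return_imputed : bool
        Also return the boolean mask of imputed (missing) positions.

    More than 20% missing variables raises :class:`CoverageError`.
    """
    n = len(model.variables)
    if isinstance(values, dict):
        vals = np.array(
            [float(values.get(v.variable_id, np.nan)) for v in model.variables], dtype=float
        )
    else:
        vals = np.asarray(values, dtype=float)
        if vals.shape != (n,):
            raise DimensionError(f"expected {n} values in variable-axis order, got {vals.shape}")
    missing = ~np.isfinite(vals)
    if missing.sum() > 0.2 * n:
        raise CoverageError(
            f"{int(missing.sum())}/{n} signature variables missing (>20%): refusing to impute"
        )
    G = np.empty(n, dtype=np.int64)
    for i, vm in enumerate(model.variables):
        G[i] = model.majority_risk[i] if missing[i] else vm.classify(vals[i])
    return (G, missing) if return_imputed else G


@dataclass(frozen=True)
class RiskVectors:
    """All derived vectors for one patient: G, D, A, V and the AWR scalar."""

    patient_id: str
    G: np.ndarray
    D: np.ndarray
    A: np.ndarray
    V: np.ndarray
    awr: float
    imputed: np.ndarray = field(default=None, repr=False)

    @classmethod
    def from_g(cls, W, G, patient_id="query", imputed=None):
        W = np.asarray(W, dtype=float)
        G = np.asarray(G)
        D = center(G)
        A = adjust(W, D)
        return cls(patient_id, G.astype(np.int64), D, A, psv(A), awr(W, G), imputed)

    @classmethod
    def from_values(cls, model, values, patient_id="query"):
        """Compute the full vector set for one patient's raw values."""
        G, imputed = build_pbvv(model, values, return_imputed=True)
        return cls.from_g(model.weights, G, patient_id, imputed)
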