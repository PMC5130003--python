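"""Similarity measures between patient vectors and reference ranking.

A query patient is compared to every reference patient of a fitted
signature in one of three vector spaces — the binary risk profile (PBVV),
the cumulative weighted signature vector (PSV, the recommended space), or
the raw variable values — under Euclidean distance, Kendall tau-b rank
correlation, or Mahalanobis distance.  The predicted risk group comes from
the nearest reference, a k-nearest-neighbour majority, or the closest
per-group median centroid.

Exact similarity ties are broken deterministically: the reference whose AWR
is closest to the query's AWR wins, then lexicographic reference id.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, DimensionError, InputError, UndefinedStatisticError
from .signature import RiskVectors

__all__ = [
    "MatchResult",
    "euclidean_distance",
    "kendall_tau",
    "kendall_tau_many",
    "mahalanobis_distance",
    "rank_references",
    "predict_risk",
]

MEASURES = ("euclidean", "kendall", "mahalanobis")
VECTOR_SPACES = ("pbvv", "psv", "raw")


@dataclass(frozen=True)
class MatchResult:
    query_id: str
    measure: str
    vector_space: str
    ranked_refs: list  # (reference_id, similarity) best first
    predicted_group: str
    mode: str = "nearest"
    ties: list = field(default_factory=list)  # groups of ids with equal similarity


def euclidean_distance(u, v) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise DimensionError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.sqrt(np.sum((u - v) ** 2)))


def _pair_signs(u):
    n = u.size
    i, j = np.triu_indices(n, k=1)
    return np.sign(u[i] - u[j])


def kendall_tau(u, v) -> float:
    """Kendall tau-b (tie-corrected) rank correlation."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise DimensionError("vectors must have equal length")
    if u.size < 2:
        raise InputError("kendall tau needs at least 2 entries")
    su, sv = _pair_signs(u), _pair_signs(v)
    n0 = su.size
    tu, tv = n0 - np.count_nonzero(su), n0 - np.count_nonzero(sv)
    if tu == n0 or tv == n0:
        raise UndefinedStatisticError("kendall tau undefined for a constant vector")
    return float((su * sv).sum() / np.sqrt((n0 - tu) * (n0 - tv)))


def kendall_tau_many(q, refs) -> np.ndarray:
    """tau-b of a query vector against every column of ``refs`` (n x M).

    Columns that are constant get NaN (undefined correlation).
    """
    q = np.asarray(q, dtype=float)
    refs = np.asarray(refs, dtype=float)
    if refs.shape[0] != q.size:
        raise DimensionError("reference matrix rows must match query length")
    i, j = np.triu_indices(q.size, k=1)
    sq = np.sign(q[i] - q[j])
    sr = np.sign(refs[i, :] - refs[j, :])  # (n0, M)
    n0 = sq.size
    tq = n0 - np.count_nonzero(sq)
    tr = n0 - np.count_nonzero(sr, axis=0)
    if tq == n0:
        # constant query: undefined against every reference
        return np.full(refs.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(float(n0 - tq) * (n0 - tr))
        tau = (sq @ sr) / denom
    tau[tr == n0] = np.nan
    return tau


def _regularized_cov(ensemble, ridge=None):
    ens = np.asarray(ensemble, dtype=float)
    if ens.ndim != 2:
        raise DimensionError("ensemble must be a (variables x patients) matrix")
    mu = ens.mean(axis=1)
    cov = np.atleast_2d(np.cov(ens))
    n = cov.shape[0]
    if ridge is None:
        ridge = 1e-6 * np.trace(cov) / n
    return mu, cov + ridge * np.eye(n)


def mahalanobis_distance(v, ensemble, ridge=None) -> float:
    """Mahalanobis distance of ``v`` to the ensemble mean under the
    (ridge-regularized) ensemble covariance."""
    mu, cov = _regularized_cov(ensemble, ridge)
    diff = np.asarray(v, dtype=float) - mu
    if diff.shape != mu.shape:
        raise DimensionError("vector length must match ensemble rows")
    try:
        sol = np.linalg.solve(cov, diff)
    except np.linalg.LinAlgError as exc:
        raise UndefinedStatisticError(f"singular covariance: {exc}") from exc
    return float(np.sqrt(max(diff @ sol, 0.0)))


def _mahalanobis_pairwise(q, refs, ridge=None):
    _, cov = _regularized_cov(refs, ridge)
    diff = refs - np.asarray(q, dtype=float)[:, None]
    sol = np.linalg.solve(cov, diff)
    return np.sqrt(np.maximum(np.einsum("ij,ij->j", diff, sol), 0.0))


def _query_and_ref_vectors(query, model, vector_space, query_raw=None):
    if vector_space == "pbvv":
        return query.G.astype(float), model.reference_G.astype(float)
    if vector_space == "psv":
        return query.V, model.reference_V
    if vector_space == "raw":
        if model.reference_values is None:
            raise ConfigError("model carries no raw reference values")
        if query_raw is None:
            raise ConfigError("raw-space matching needs the query's raw values")
        return np.asarray(query_raw, dtype=float), model.reference_values
    raise ConfigError(f"unknown vector space {vector_space!r}")


def _scores(qv, refs, measure):
    """(scores, higher_is_better).  NaN marks an undefined comparison and
    always ranks last."""
    if measure == "euclidean":
        return np.sqrt(np.sum((refs - qv[:, None]) ** 2, axis=0)), False
    if measure == "kendall":
        return kendall_tau_many(qv, refs), True
    if measure == "mahalanobis":
        return _mahalanobis_pairwise(qv, refs), False
    raise ConfigError(f"unknown measure {measure!r}")


def rank_references(
    query: RiskVectors, model, measure="euclidean", vector_space="psv", query_raw=None
) -> MatchResult:
    """Score and sort all reference patients against one query patient."""
    if model.n_variables == 0 or not model.reference_ids:
        raise InputError("empty model")
    qv, refs = _query_and_ref_vectors(query, model, vector_space, query_raw)
    scores, higher = _scores(qv, refs, measure)
    awr_gap = np.abs(model.reference_awr - query.awr)
    ids = np.asarray(model.reference_ids)
    sort_score = np.where(np.isnan(scores), -np.inf if higher else np.inf, scores)
    order = np.lexsort((ids, awr_gap, -sort_score if higher else sort_score))
    ranked = [(str(ids[i]), float(scores[i])) for i in order]
    # exact-score tie groups
    ties = []
    by_score = {}
    for i in order:
        by_score.setdefault(scores[i] if not np.isnan(scores[i]) else "nan", []).append(str(ids[i]))
    ties = [grp for grp in by_score.values() if len(grp) > 1]
    top_idx = order[0]
    return MatchResult(
        query_id=query.patient_id,
        measure=measure,
        vector_space=vector_space,
        ranked_refs=ranked,
        predicted_group=str(model.reference_group[top_idx]),
        mode="nearest",
        ties=ties,
    )


def _knn_label(result: MatchResult, model, k):
    labels_of = dict(zip(model.reference_ids, model.reference_group))
    top = [labels_of[rid] for rid, _ in result.ranked_refs[:k]]
    counts = Counter(top).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return top[0]  # tie: fall back to the single nearest
    return counts[0][0]


def _centroid_label(query, model, measure, vector_space, query_raw=None):
    qv, refs = _query_and_ref_vectors(query, model, vector_space, query_raw)
    best_label, best = None, None
    ranked = []
    for label in model.group_labels:
        members = np.asarray(model.reference_group) == label
        if not members.any():
            continue
        centroid = np.median(refs[:, members], axis=1)
        if measure == "euclidean":
            s, higher = euclidean_distance(qv, centroid), False
        elif measure == "kendall":
            s, higher = kendall_tau(qv, centroid), True
        elif measure == "mahalanobis":
            _, cov = _regularized_cov(refs)
            diff = qv - centroid
            s, higher = float(np.sqrt(max(diff @ np.linalg.solve(cov, diff), 0.0))), False
        else:
            raise ConfigError(f"unknown measure {measure!r}")
        ranked.append((f"centroid::{label}", float(s)))
        better = best is None or (s > best if higher else s < best)
        if better:
            best, best_label = s, label
    ranked.sort(key=lambda t: -t[1] if measure == "kendall" else t[1])
    return best_label, ranked


def predict_risk(
    query: RiskVectors,
    model,
    mode="nearest",
    k=5,
    measure="euclidean",
    vector_space="psv",
    query_raw=None,
):
    """Predict the query patient's risk group.

    Returns ``(label, MatchResult)``.  ``mode`` is one of:

    - ``nearest``: label of the single most similar reference;
    - ``knn``: majority label of the top ``k`` (odd) references, falling
      back to the nearest on a tied vote;
    - ``centroid``: label of the closest per-group median vector.
    """
    if mode not in ("nearest", "knn", "centroid"):
        raise ConfigError(f"unknown prediction mode {mode!r}")
    if mode == "centroid":
        label, ranked = _centroid_label(query, model, measure, vector_space, query_raw)
        return label, MatchResult(
            query.patient_id, measure, vector_space, ranked, label, mode="centroid"
        )
    result = rank_references(query, model, measure, vector_space, query_raw)
    if mode == "nearest":
        return result.predicted_group, result
    if k < 1 or k % 2 == 0:
        raise ConfigError("k must be a positive odd integer")
    label = _knn_label(result, model, k)
    return label, MatchResult(
        result.query_id, measure, vector_space, result.ranked_refs, label,
        mode="knn", ties=result.ties,
    )
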