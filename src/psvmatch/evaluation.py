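"""Assessment machinery: similarity-vs-AWR quadratic diagnostic, 10-fold
cross-validation of risk prediction, intra/inter-class distance summaries,
and clinical-association statistics (weighted kappa, chi-square).

The diagnostic rests on a simple expectation: if a similarity measure is
prognostically meaningful, then for a fixed query the scatter of similarity
against the reference patients' AWR should be roughly quadratic (most
similar near the query's own risk level, less similar toward both
extremes).  The goodness of that quadratic fit — the RMS residual after
min-max rescaling of the similarity axis to [0, 1] — compares measures and
vector spaces on a common footing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from . import ddg, matching
from .exceptions import (
    ConfigError,
    CrossValidationError,
    FitError,
    InputError,
    StratificationError,
    UndefinedStatisticError,
)
from .signature import RiskVectors
from .survival import TestResult

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "DiagnosticFit",
    "CVResult",
    "similarity_awr_fit",
    "cross_validate",
    "intra_inter_summary",
    "weighted_kappa",
    "weighted_kappa_permutation_p",
    "chi_square_independence",
]


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple
    col_labels: tuple
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (len(self.row_labels), len(self.col_labels)):
            raise InputError("counts shape must match label lengths")
        if np.any(c < 0) or c.sum() == 0:
            raise InputError("counts must be non-negative with positive total")
        object.__setattr__(self, "counts", c.astype(np.int64))
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))


@dataclass(frozen=True)
class DiagnosticFit:
    coefficients: tuple  # (c0, c1, c2) for c0 + c1*x + c2*x^2
    normalized_residual: float
    n_points: int


def similarity_awr_fit(similarities, awrs) -> DiagnosticFit:
    """Quadratic fit of (min-max rescaled) similarity on reference AWR.

    Returns the fit coefficients and the RMS residual on the rescaled
    [0, 1] similarity axis — a diagnostic of how well-structured the
    similarity-vs-risk relationship is.
    """
    s = np.asarray(similarities, dtype=float)
    a = np.asarray(awrs, dtype=float)
    if s.shape != a.shape or s.ndim != 1:
        raise InputError("similarities and awrs must be 1-D and equal length")
    ok = np.isfinite(s) & np.isfinite(a)
    s, a = s[ok], a[ok]
    if s.size < 4:
        raise InputError("need at least 4 points for a quadratic diagnostic")
    span = s.max() - s.min()
    if span == 0:
        raise UndefinedStatisticError("constant similarities: degenerate fit")
    y = (s - s.min()) / span
    c2, c1, c0 = np.polyfit(a, y, 2)
    resid = y - (c0 + c1 * a + c2 * a * a)
    return DiagnosticFit((float(c0), float(c1), float(c2)),
                         float(np.sqrt(np.mean(resid**2))), int(s.size))


@dataclass(frozen=True)
class CVResult:
    mean_accuracy: float
    sd_accuracy: float
    per_fold: tuple
    n_skipped: int = 0


def cross_validate(
    cohort,
    variable_ids=None,
    config: ddg.FitConfig | None = None,
    folds: int = 10,
    seed: int = 0,
    combos=(("euclidean", "psv"),),
    truth_labels=None,
) -> dict:
    """k-fold cross-validation of nearest-reference risk prediction.

    Ground truth is the group label each patient receives in a single
    full-cohort fit (or ``truth_labels``, a mapping patient_id -> label).
    Patients are partitioned at random (seeded); for each fold the
    signature and reference groups are refit on the other folds and the
    held-out patients are predicted by the most similar reference, for
    every (measure, vector_space) combination in ``combos``.

    Returns ``{(measure, space): CVResult}``.  A fold whose training side
    cannot be stratified is skipped with a warning; more than two skipped
    folds raise :class:`CrossValidationError`.
    """
    config = config or ddg.FitConfig()
    coh = cohort.with_complete_survival()
    if variable_ids is None:
        variable_ids = list(coh.variable_ids)
    if truth_labels is None:
        full = ddg.fit_signature(coh, variable_ids, config)
        truth_labels = dict(zip(full.reference_ids, full.reference_group))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(coh.n_patients)
    fold_of = np.empty(coh.n_patients, dtype=int)
    fold_of[perm] = np.arange(coh.n_patients) % folds
    per_fold = {c: [] for c in combos}
    skipped = 0
    for f in range(folds):
        test_idx = np.nonzero(fold_of == f)[0]
        train_idx = np.nonzero(fold_of != f)[0]
        if test_idx.size == 0:
            continue
        try:
            model = ddg.fit_signature(coh.subset(train_idx), variable_ids, config)
        except (StratificationError, FitError) as exc:
            logger.warning("fold %d skipped: %s", f, exc)
            skipped += 1
            if skipped > 2:
                raise CrossValidationError("more than two folds failed to stratify") from exc
            continue
        hits = {c: 0 for c in combos}
        for j in test_idx:
            pid = coh.patient_ids[j]
            values = coh.values_for_patient(pid, model.variable_ids)
            q = RiskVectors.from_values(model, values, patient_id=pid)
            for combo in combos:
                measure, space = combo
                label, _ = matching.predict_risk(
                    q, model, mode="nearest", measure=measure,
                    vector_space=space, query_raw=values if space == "raw" else None,
                )
                hits[combo] += int(label == truth_labels[pid])
        for combo in combos:
            per_fold[combo].append(hits[combo] / test_idx.size)
    return {
        combo: CVResult(
            float(np.mean(acc)), float(np.std(acc, ddof=0)), tuple(acc), skipped
        )
        for combo, acc in per_fold.items()
    }


def pipeline_permutation_p(
    cohort, variable_ids=None, config=None, n_permutations=100, seed=0
) -> float:
    """Permutation calibration of the whole fit-then-stratify pipeline.

    Because both the per-variable cutoffs and the AWR cutpoints are
    optimized on the same survival data, the in-sample stratification
    statistic is optimistic even for pure-noise variables.  A valid null
    therefore reruns the *entire* pipeline — DDg refit included — on each
    permutation of the survival-to-profile pairing.  Returns
    (1 + #{perm >= observed}) / (1 + n_permutations).
    """
    config = config or ddg.FitConfig()
    coh = cohort.with_complete_survival()
    if variable_ids is None:
        variable_ids = list(coh.variable_ids)
    rng = np.random.default_rng(seed)

    def _max_stat(c):
        model = ddg.fit_signature(c, variable_ids, config)
        best_bounds, stat, _, _, _ = ddg._best_boundaries(
            model.reference_awr, c.times, c.events, config.n_groups, config.min_group_frac
        )
        if best_bounds is None:
            raise StratificationError("no admissible stratification")
        return stat

    observed = _max_stat(coh)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(coh.n_patients)
        shuffled = [
            _replace_survival(p, coh.patients[j]) for p, j in zip(coh.patients, perm)
        ]
        from .cohort import Cohort

        permuted = Cohort(coh.matrix, coh.variable_ids, shuffled)
        if _max_stat(permuted) >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_permutations)


def _replace_survival(patient, donor):
    """Copy of ``patient`` carrying ``donor``'s survival time and event."""
    import dataclasses

    return dataclasses.replace(
        patient, survival_time=donor.survival_time, event=donor.event
    )


def intra_inter_summary(model, vector_space="psv", measure="euclidean") -> dict:
    """Mean and SD of pairwise similarity per group pair.

    Keys are (group_a, group_b) label pairs (symmetric, stored once with
    a <= b in label order); values are dicts with mean, sd and n_pairs.
    Intra-class entries for groups with fewer than 2 members are flagged
    undefined (NaN, n_pairs 0).
    """
    labels = np.asarray(model.reference_group)
    if vector_space == "pbvv":
        vecs = model.reference_G.astype(float)
    elif vector_space == "psv":
        vecs = model.reference_V
    elif vector_space == "raw":
        if model.reference_values is None:
            raise ConfigError("model carries no raw reference values")
        vecs = model.reference_values
    else:
        raise ConfigError(f"unknown vector space {vector_space!r}")
    group_names = [g for g in model.group_labels if (labels == g).any()]
    out = {}
    for gi, ga in enumerate(group_names):
        for gb in group_names[gi:]:
            ia = np.nonzero(labels == ga)[0]
            ib = np.nonzero(labels == gb)[0]
            if ga == gb:
                if ia.size < 2:
                    out[(ga, gb)] = {"mean": np.nan, "sd": np.nan, "n_pairs": 0}
                    continue
                pairs = [(i, j) for k, i in enumerate(ia) for j in ia[k + 1 :]]
            else:
                pairs = [(i, j) for i in ia for j in ib]
            vals = _pairwise_scores(vecs, pairs, measure)
            out[(ga, gb)] = {
                "mean": float(np.nanmean(vals)),
                "sd": float(np.nanstd(vals)),
                "n_pairs": len(pairs),
            }
    return out


def _pairwise_scores(vecs, pairs, measure):
    if measure == "euclidean":
        return np.array(
            [np.sqrt(np.sum((vecs[:, i] - vecs[:, j]) ** 2)) for i, j in pairs]
        )
    if measure == "kendall":
        vals = []
        for i, j in pairs:
            try:
                vals.append(matching.kendall_tau(vecs[:, i], vecs[:, j]))
            except UndefinedStatisticError:
                vals.append(np.nan)
        return np.array(vals)
    raise ConfigError(f"unsupported pairwise measure {measure!r}")


def _kappa_weights(k, scheme):
    i, j = np.indices((k, k))
    if scheme == "quadratic":
        return 1.0 - ((i - j) / (k - 1)) ** 2
    if scheme == "linear":
        return 1.0 - np.abs(i - j) / (k - 1)
    raise ConfigError(f"unknown kappa scheme {scheme!r}")


def weighted_kappa(table: ContingencyTable, scheme="quadratic") -> float:
    """Cohen's weighted kappa for a square ordinal contingency table.

    ``scheme = "quadratic"`` uses weights 1 - ((i-j)/(k-1))^2 (the default;
    the variant that reproduces the published association coefficients);
    ``"linear"`` uses 1 - |i-j|/(k-1).
    """
    c = np.asarray(table.counts, dtype=float)
    if c.shape[0] != c.shape[1]:
        raise InputError("weighted kappa needs a square table")
    k = c.shape[0]
    w = _kappa_weights(k, scheme)
    p = c / c.sum()
    po = float((w * p).sum())
    pe = float((w * np.outer(p.sum(axis=1), p.sum(axis=0))).sum())
    if pe == 1.0:
        raise UndefinedStatisticError("degenerate table: expected agreement is 1")
    return (po - pe) / (1.0 - pe)


def weighted_kappa_permutation_p(
    table: ContingencyTable, scheme="quadratic", n_draws=10_000, seed=0
) -> float:
    """Permutation p-value for weighted kappa under fixed margins."""
    observed = weighted_kappa(table, scheme)
    rng = np.random.default_rng(seed)
    dist = sps.random_table(table.counts.sum(axis=1), table.counts.sum(axis=0))
    draws = dist.rvs(n_draws, random_state=rng)
    k = table.counts.shape[0]
    w = _kappa_weights(k, scheme)
    total = table.counts.sum()
    p = draws / total
    po = (w * p).sum(axis=(1, 2))
    pe = float(
        (w * np.outer(table.counts.sum(axis=1), table.counts.sum(axis=0)) / total**2).sum()
    )
    kappas = (po - pe) / (1.0 - pe)
    return float((1 + np.sum(kappas >= observed)) / (1 + n_draws))


def chi_square_independence(table: ContingencyTable) -> TestResult:
    """Pearson chi-squared test of independence (no continuity correction)."""
    c = np.asarray(table.counts)
    if np.any(c.sum(axis=0) == 0) or np.any(c.sum(axis=1) == 0):
        raise InputError("zero marginal row or column")
    stat, p, dof, _ = sps.chi2_contingency(c, correction=False)
    return TestResult(float(stat), int(dof), float(p))
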