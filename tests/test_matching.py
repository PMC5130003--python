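"""Similarity measures and reference ranking / risk prediction."""

import numpy as np
import pytest
from scipy import stats as sps

import psvmatch as pm
from psvmatch.ddg import SignatureModel, VariableModel
from psvmatch.exceptions import ConfigError, DimensionError, UndefinedStatisticError
from psvmatch.matching import (
    kendall_tau_many,
    mahalanobis_distance,
    predict_risk,
    rank_references,
)
from psvmatch.signature import RiskVectors


class TestEuclidean:
    def test_identity(self):
        u = np.array([1.0, 2.0, 3.0])
        assert pm.euclidean_distance(u, u) == 0.0

    def test_3_4_5(self):
        assert pm.euclidean_distance([0.0, 0.0], [3.0, 4.0]) == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        u, v = rng.normal(size=37), rng.normal(size=37)
        acc = 0.0
        for a, b in zip(u, v):
            acc += (a - b) ** 2
        assert pm.euclidean_distance(u, v) == pytest.approx(np.sqrt(acc), abs=1e-12)

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            x, y, z = rng.normal(size=(3, 8))
            dxy = pm.euclidean_distance(x, y)
            assert dxy == pytest.approx(pm.euclidean_distance(y, x), abs=1e-12)
            assert pm.euclidean_distance(x, x) == 0.0
            assert dxy <= pm.euclidean_distance(x, z) + pm.euclidean_distance(z, y) + 1e-9

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            pm.euclidean_distance([1.0], [1.0, 2.0])


class TestKendall:
    def test_perfect_agreement(self):
        u = np.array([3.0, 1.0, 2.0, 5.0])
        assert pm.kendall_tau(u, u) == pytest.approx(1.0)

    def test_reversed(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        assert pm.kendall_tau(u, u[::-1]) == pytest.approx(-1.0)

    def test_hand_pair_enumeration(self):
        # pairs: concordant 2, discordant 1 -> 1/3
        assert pm.kendall_tau([1, 2, 3], [1, 3, 2]) == pytest.approx(1 / 3)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            pm.kendall_tau([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        u = rng.integers(1, 3, 30).astype(float)  # heavy ties, PBVV-like
        v = rng.integers(1, 4, 30).astype(float)
        ours = pm.kendall_tau(u, v)
        theirs = sps.kendalltau(u, v).statistic
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_bulk_matches_scalar(self):
        rng = np.random.default_rng(7)
        q = rng.normal(size=12)
        refs = rng.normal(size=(12, 9))
        bulk = kendall_tau_many(q, refs)
        for j in range(9):
            assert bulk[j] == pytest.approx(pm.kendall_tau(q, refs[:, j]), abs=1e-12)

    def test_bulk_constant_column_nan(self):
        q = np.array([1.0, 2.0, 3.0])
        refs = np.column_stack([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        bulk = kendall_tau_many(q, refs)
        assert np.isnan(bulk[0]) and bulk[1] == pytest.approx(1.0)


class TestMahalanobis:
    def test_zero_at_mean(self):
        rng = np.random.default_rng(0)
        ens = rng.normal(size=(3, 50))
        assert mahalanobis_distance(ens.mean(axis=1), ens) == pytest.approx(0.0, abs=1e-9)

    def test_whitened_reduces_to_euclidean(self):
        rng = np.random.default_rng(1)
        ens = rng.normal(size=(4, 4000))
        v = rng.normal(size=4)
        d = mahalanobis_distance(v, ens, ridge=0.0)
        mu = ens.mean(axis=1)
        # near-identity covariance at this sample size
        assert d == pytest.approx(pm.euclidean_distance(v, mu), rel=0.05)

    def test_one_dimensional_z_score(self):
        ens = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        sd = np.std(ens, ddof=1)
        assert mahalanobis_distance([3.0 + sd], ens, ridge=0.0) == pytest.approx(1.0)


def _tiny_model():
    """Hand-built 2-variable signature with 4 reference patients."""
    variables = [
        VariableModel("v1", 0.0, True, 1e-3, 3.0, 2.0),
        VariableModel("v2", 0.0, True, 1e-2, 2.0, 1.5),
    ]
    G = np.array([[1, 1, 2, 2], [1, 2, 1, 2]])
    W = np.array([3.0, 2.0])
    D = 2.0 * (G - 1.5)
    V = np.cumsum(W[:, None] * D, axis=0)
    awr = W @ G / W.sum()
    return SignatureModel(
        variables=variables,
        reference_ids=["r1", "r2", "r3", "r4"],
        reference_G=G,
        reference_V=V,
        reference_awr=awr,
        reference_group=np.array(["low", "low", "high", "high"]),
        group_cutpoints=np.array([1.5]),
        majority_risk=np.array([1, 1]),
        n_groups=2,
    )


class TestRankReferences:
    def test_identical_psv_ranks_first_with_zero_distance(self):
        model = _tiny_model()
        q = RiskVectors.from_g(model.weights, model.reference_G[:, 2], "q")
        res = rank_references(q, model)
        assert res.ranked_refs[0] == ("r3", 0.0)
        assert res.predicted_group == "high"

    def test_pbvv_space_produces_ties(self):
        """Binary profiles at equal Hamming distance are indistinguishable —
        the motivation for the cumulative-vector space."""
        model = _tiny_model()
        q = RiskVectors.from_g(model.weights, np.array([1, 1]), "q")
        res = rank_references(q, model, measure="euclidean", vector_space="pbvv")
        # r2 and r3 are both one flip away in PBVV space
        assert any({"r2", "r3"} <= set(grp) for grp in res.ties)
        # but in PSV space the weighted cumulative vectors differ
        res_psv = rank_references(q, model, measure="euclidean", vector_space="psv")
        assert not any({"r2", "r3"} <= set(grp) for grp in res_psv.ties)

    def test_reference_order_invariance(self, sep_model, sep_cohort):
        cohort, _ = sep_cohort
        pid = cohort.patient_ids[3]
        vals = cohort.values_for_patient(pid, sep_model.variable_ids)
        q = RiskVectors.from_values(sep_model, vals, pid)
        res1 = rank_references(q, sep_model)
        perm = np.random.default_rng(0).permutation(len(sep_model.reference_ids))
        import dataclasses

        shuffled = dataclasses.replace(
            sep_model,
            variables=sep_model.variables,
            reference_ids=[sep_model.reference_ids[i] for i in perm],
            reference_G=sep_model.reference_G[:, perm],
            reference_V=sep_model.reference_V[:, perm],
            reference_awr=sep_model.reference_awr[perm],
            reference_group=sep_model.reference_group[perm],
        ) if dataclasses.is_dataclass(sep_model) else None
        res2 = rank_references(q, shuffled)
        assert [r for r, _ in res1.ranked_refs] == [r for r, _ in res2.ranked_refs]
        # scores agree to floating-point summation order
        s1 = np.array([s for _, s in res1.ranked_refs])
        s2 = np.array([s for _, s in res2.ranked_refs])
        assert np.allclose(s1, s2, rtol=1e-12)

    def test_unknown_measure_rejected(self):
        model = _tiny_model()
        q = RiskVectors.from_g(model.weights, np.array([1, 1]), "q")
        with pytest.raises(ConfigError):
            rank_references(q, model, measure="cosine")
        with pytest.raises(ConfigError):
            rank_references(q, model, vector_space="latent")


class TestPredictRisk:
    def test_query_equal_to_low_reference(self):
        model = _tiny_model()
        q = RiskVectors.from_g(model.weights, model.reference_G[:, 0], "q")
        label, res = predict_risk(q, model, mode="nearest")
        assert label == "low" and res.mode == "nearest"

    def test_knn_majority(self, sep_model, sep_cohort):
        cohort, _ = sep_cohort
        pid = cohort.patient_ids[11]
        vals = cohort.values_for_patient(pid, sep_model.variable_ids)
        q = RiskVectors.from_values(sep_model, vals, pid)
        label, res = predict_risk(q, sep_model, mode="knn", k=5)
        labels_of = dict(zip(sep_model.reference_ids, sep_model.reference_group))
        top5 = [labels_of[r] for r, _ in res.ranked_refs[:5]]
        from collections import Counter

        counts = Counter(top5).most_common()
        if len(counts) == 1 or counts[0][1] > counts[1][1]:
            assert label == counts[0][0]
        else:
            assert label == top5[0]

    def test_knn_even_k_rejected(self):
        model = _tiny_model()
        q = RiskVectors.from_g(model.weights, np.array([1, 2]), "q")
        with pytest.raises(ConfigError):
            predict_risk(q, model, mode="knn", k=4)

    def test_centroid_agrees_with_nearest_on_separated_groups(self, sep_model):
        """>= 90% nearest/centroid agreement over 200 simulated queries."""
        qcfg = pm.SimConfig(
            n_patients=200, effect_size=3.0, group_hazard_ratios=(1.0, 4.0, 16.0), seed=55
        )
        qcoh, _ = pm.generate_cohort(qcfg)
        agree = 0
        for pid in qcoh.patient_ids:
            vals = qcoh.values_for_patient(pid, sep_model.variable_ids)
            q = RiskVectors.from_values(sep_model, vals, pid)
            l1, _ = predict_risk(q, sep_model, mode="nearest")
            l2, _ = predict_risk(q, sep_model, mode="centroid")
            agree += int(l1 == l2)
        assert agree >= 0.9 * qcoh.n_patients


def test_intra_distance_below_inter_in_psv_space(sep_model):
    """Patients within a risk group sit closer in the cumulative-vector
    space than patients of different groups."""
    from psvmatch.evaluation import intra_inter_summary

    summary = intra_inter_summary(sep_model, vector_space="psv")
    groups = ["low", "intermediate", "high"]
    for g in groups:
        intra = summary[(g, g)]["mean"]
        for h in groups:
            if h == g:
                continue
            key = (g, h) if (g, h) in summary else (h, g)
            assert intra < summary[key]["mean"]
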