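import numpy as np
import pytest

import psvmatch as pm
from psvmatch.ddg import FitConfig


@pytest.fixture(scope="session")
def sep_cohort():
    """A strongly separated 3-group cohort: large expression effect and
    wide hazard separation, so stratification is stable."""
    cfg = pm.SimConfig(
        n_patients=300,
        effect_size=3.0,
        group_hazard_ratios=(1.0, 4.0, 16.0),
        seed=1,
    )
    cohort, truth = pm.generate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def sep_model(sep_cohort):
    cohort, _ = sep_cohort
    ids = list(cohort.variable_ids) + ["age"]
    return pm.fit_signature(cohort, ids, FitConfig())


@pytest.fixture()
def toy_cohort_files(tmp_path):
    """3-variable x 4-patient toy expression/clinical file pair."""
    expr = tmp_path / "expr.tsv"
    clin = tmp_path / "clin.tsv"
    expr.write_text(
        "variable\tp1\tp2\tp3\tp4\n"
        "g1\t1.0\t2.0\t3.0\t4.0\n"
        "g2\t5.0\t6.0\t7.0\t8.0\n"
        "g3\t9.0\t10.0\t11.0\t12.0\n"
    )
    clin.write_text(
        "patient_id\tsurvival_time\tevent\tage\n"
        "p1\t10\t1\t55\n"
        "p2\t20\t0\t60\n"
        "p3\t30\t1\t65\n"
        "p4\t40\t0\t70\n"
    )
    return expr, clin


def exponential_cohort(rng, n, rate=0.1, censor_rate=None):
    """Right-censored exponential sample for survival-estimator tests."""
    t = rng.exponential(1.0 / rate, n)
    if censor_rate is None:
        return t, np.ones(n, dtype=int)
    c = rng.exponential(1.0 / censor_rate, n)
    return np.minimum(t, c), (t <= c).astype(int)
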