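"""Seeded synthetic cohorts with the structure the method assumes, plus the
published worked-example fixtures.

The generator plants k latent risk groups.  Informative variables are unit-SD
Gaussian with a mean shift of ``effect_size`` per group step, with a random
sign per variable (high expression may be adverse or protective, as in real
signatures); the remaining variables are pure noise.  Age is Gaussian around
60 with a per-group shift.  Event times are exponential (optionally Weibull)
with a hazard multiplied by the group's hazard ratio; independent exponential
censoring is calibrated so the expected censored fraction matches
``censoring_rate``.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

from .cohort import ClinicalRecord, Cohort
from .evaluation import ContingencyTable
from .exceptions import ConfigError, InputError

__all__ = ["SimConfig", "GroundTruth", "generate_cohort", "table_fixture"]


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a three-group cohort of 400 patients profiled on 37
    variables of which 20 carry a 2-SD-per-group-step signal, group hazard
    ratios 1/2/4 on an exponential baseline (rate 0.02 per time unit, median
    survival about 35 time units for the low-risk group), 30% censoring,
    and a 4-year mean age shift per group step.
    """

    n_patients: int = 400
    n_variables: int = 37
    n_informative: int = 20
    group_props: tuple = (1 / 3, 1 / 3, 1 / 3)
    effect_size: float = 2.0
    baseline_hazard: float = 0.02
    group_hazard_ratios: tuple = (1.0, 2.0, 4.0)
    censoring_rate: float = 0.3
    age_effect: float = 4.0
    weibull_shape: float = 1.0
    seed: int = 0
    structure_seed: int = 0

    def __post_init__(self):
        k = len(self.group_props)
        if abs(sum(self.group_props) - 1.0) > 1e-9:
            raise ConfigError("group proportions must sum to 1")
        if len(self.group_hazard_ratios) != k:
            raise ConfigError("need one hazard ratio per group")
        if any(np.diff(self.group_hazard_ratios) < 0):
            raise ConfigError("hazard ratios must be nondecreasing with group index")
        if not 1 <= self.n_informative <= self.n_variables:
            raise ConfigError("n_informative must be in [1, n_variables]")
        if not 0 <= self.censoring_rate < 1:
            raise ConfigError("censoring_rate must be in [0, 1)")
        if self.baseline_hazard <= 0 or self.weibull_shape <= 0:
            raise ConfigError("baseline_hazard and weibull_shape must be positive")

    @property
    def n_groups(self) -> int:
        return len(self.group_props)


@dataclass(frozen=True)
class GroundTruth:
    group: np.ndarray  # latent group index per patient (0 = lowest risk)
    informative: np.ndarray  # bool per variable
    shift_sign: np.ndarray  # +-1 per variable (0 for uninformative)


def _censoring_rate_for(mu, cfg):
    """Expected censored fraction for exponential censoring rate mu."""
    total = 0.0
    for prop, hr in zip(cfg.group_props, cfg.group_hazard_ratios):
        lam = cfg.baseline_hazard * hr
        if cfg.weibull_shape == 1.0:
            frac = mu / (mu + lam)
        else:
            # P(C < T) = 1 - E[exp(-mu T)], T ~ Weibull(shape a, rate lam)
            a = cfg.weibull_shape

            def integrand(t, lam=lam, a=a):
                return np.exp(-mu * t) * a * lam * (lam * t) ** (a - 1) * np.exp(-((lam * t) ** a))

            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", integrate.IntegrationWarning)
                frac = 1.0 - integrate.quad(integrand, 0, np.inf, limit=200)[0]
        total += prop * frac
    return total


def _solve_censoring_rate(cfg):
    if cfg.censoring_rate == 0:
        return None
    f = lambda mu: _censoring_rate_for(mu, cfg) - cfg.censoring_rate
    return optimize.brentq(f, 1e-12, 1e12)


def generate_cohort(config: SimConfig):
    """Generate one cohort and its ground truth.

    Returns ``(Cohort, GroundTruth)``.  Variable ids are VAR0001..; the age
    covariate lives in the clinical records (address it as variable "age").
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_patients, cfg.n_groups
    group = rng.choice(k, size=n, p=np.asarray(cfg.group_props))
    # Which variables carry signal, and in which direction, is part of the
    # study design, not of the sampling: cohorts that differ only in `seed`
    # (e.g. a train/test pair) share it.
    rng_structure = np.random.default_rng(cfg.structure_seed)
    informative = np.zeros(cfg.n_variables, dtype=bool)
    informative[
        rng_structure.choice(cfg.n_variables, size=cfg.n_informative, replace=False)
    ] = True
    sign = np.where(informative, rng_structure.choice((-1.0, 1.0), size=cfg.n_variables), 0.0)
    matrix = rng.standard_normal((cfg.n_variables, n))
    matrix += sign[:, None] * cfg.effect_size * group[None, :]
    age = np.maximum(30.0, 60.0 + cfg.age_effect * group + 10.0 * rng.standard_normal(n))

    lam = cfg.baseline_hazard * np.asarray(cfg.group_hazard_ratios)[group]
    raw = rng.exponential(1.0, size=n)
    t_event = (raw ** (1.0 / cfg.weibull_shape)) / lam if cfg.weibull_shape != 1.0 else raw / lam
    mu = _solve_censoring_rate(cfg)
    if mu is None:
        times, events = t_event, np.ones(n, dtype=int)
    else:
        t_cens = rng.exponential(1.0 / mu, size=n)
        events = (t_event <= t_cens).astype(int)
        times = np.minimum(t_event, t_cens)

    variable_ids = [f"VAR{i + 1:04d}" for i in range(cfg.n_variables)]
    patients = [
        ClinicalRecord(
            patient_id=f"P{j + 1:04d}",
            survival_time=float(times[j]),
            event=int(events[j]),
            age=float(age[j]),
        )
        for j in range(n)
    ]
    cohort = Cohort(matrix, variable_ids, patients)
    return cohort, GroundTruth(group=group, informative=informative, shift_sign=sign)


# ---------------------------------------------------------------------------
# Published worked-example fixtures
# ---------------------------------------------------------------------------
# The 37-variable worked example: per-rank (variable label, weight w,
# centered direction for the reference patient, centered direction for the
# query patient).  Weights are the printed 3-decimal values; the printed
# adjustment columns equal w * d exactly, while the printed cumulative
# columns carry up to 0.003 of accumulated rounding relative to these
# weights (the source rounded each cumulative cell independently).
_TABLE1_ROWS = [
    ("205382_s_at (CFD)", 3.429, -1, -1),
    ("202246_s_at (CDK4)", 3.124, -1, -1),
    ("204451_at (FZD1)", 3.071, -1, 1),
    ("201947_s_at (CCT2)", 3.024, -1, -1),
    ("205959_at (MMP13)", 2.928, -1, 1),
    ("201954_at (ARPC1B)", 2.805, -1, -1),
    ("age", 2.800, 1, -1),
    ("201615_x_at (CALD1)", 2.793, -1, 1),
    ("204464_s_at (EDNRA)", 2.713, -1, -1),
    ("208944_at (TGFBR2)", 2.673, -1, 1),
    ("203968_s_at (CDC6)", 2.660, -1, -1),
    ("209026_x_at (TUBB)", 2.640, -1, -1),
    ("201774_s_at (NCAPD2)", 2.559, -1, -1),
    ("212239_at (PIK3R1)", 2.545, -1, -1),
    ("203131_at (PDGFRA)", 2.468, -1, -1),
    ("212063_at (CD44)", 2.466, 1, 1),
    ("212782_x_at (POLR2J)", 2.464, -1, -1),
    ("214144_at (POLR2D)", 2.459, -1, 1),
    ("219588_s_at (NCAPG2)", 2.375, -1, -1),
    ("209960_at (HGF)", 2.364, -1, -1),
    ("212294_at (GNG12)", 2.360, -1, -1),
    ("207822_at (FGFR1)", 2.298, -1, 1),
    ("204441_s_at (POLA2)", 2.283, -1, -1),
    ("216598_s_at (CCL2)", 2.206, -1, 1),
    ("202107_s_at (MCM2)", 2.156, -1, -1),
    ("202202_s_at (LAMA4)", 2.116, -1, -1),
    ("215076_s_at (COL3A1)", 2.095, -1, 1),
    ("210845_s_at (PLAUR)", 2.081, -1, 1),
    ("201697_s_at (DNMT1)", 2.052, 1, 1),
    ("202877_s_at (CD93)", 2.044, -1, 1),
    ("203323_at (CAV2)", 1.985, -1, 1),
    ("221559_s_at (MIS12)", 1.961, -1, 1),
    ("208778_s_at (TCP1)", 1.955, -1, -1),
    ("201091_s_at (CBX3)", 1.921, -1, 1),
    ("205393_s_at (CHEK1)", 1.918, -1, -1),
    ("200931_s_at (VCL)", 1.902, -1, 1),
    ("212949_at (NCAPH)", 1.889, -1, -1),
]

# Printed cumulative signature columns (reference patient, query patient),
# kept for regression checks against the source table.
_TABLE1_V_REFERENCE = [
    -3.429, -6.553, -9.625, -12.648, -15.577, -18.382, -15.582, -18.374,
    -21.088, -23.760, -26.420, -29.060, -31.619, -34.165, -36.632, -34.166,
    -36.630, -39.089, -41.463, -43.827, -46.187, -48.486, -50.768, -52.974,
    -55.130, -57.246, -59.341, -61.422, -59.370, -61.413, -63.398, -65.359,
    -67.313, -69.234, -71.152, -73.055, -74.944,
]
_TABLE1_V_QUERY = [
    -3.429, -6.553, -3.482, -6.506, -3.577, -6.382, -9.182, -6.389, -9.102,
    -6.430, -9.090, -11.730, -14.289, -16.834, -19.302, -16.836, -19.299,
    -16.841, -19.215, -21.579, -23.939, -21.641, -23.924, -21.719, -23.875,
    -25.991, -23.896, -21.815, -19.763, -17.719, -15.735, -13.774, -15.729,
    -13.808, -15.727, -13.824, -15.714,
]

_TABLE2 = {
    # prognostic risk group x tumor residual disease (training cohort)
    "table2a": (
        ("low", "intermediate", "high"),
        ("no macroscopic disease", "1 to 20 mm", "> 20 mm"),
        [[25, 51, 14], [30, 104, 36], [3, 23, 10]],
    ),
    # prognostic risk group x primary therapy outcome (training cohort)
    "table2b": (
        ("low", "intermediate", "high"),
        ("complete response", "partial response", "progressive and stable disease"),
        [[82, 4, 11], [88, 33, 32], [13, 10, 3]],
    ),
    # predicted risk group x debulking (testing cohort)
    "table2c": (
        ("low", "intermediate", "high"),
        ("optimal", "suboptimal"),
        [[69, 36], [92, 92], [21, 21]],
    ),
}


def table_fixture(name):
    """Published worked-example fixtures.

    - ``"table1"``: dict with the 37 variable labels, weights ``W``, both
      centered-direction columns ``D`` and both printed cumulative columns
      ``V_printed``;
    - ``"table1_reference"`` / ``"table1_query"``: per-patient view with
      keys ``labels``, ``W``, ``D``, ``V_printed``;
    - ``"table2a"`` / ``"table2b"`` / ``"table2c"``: the three association
      count tables as :class:`ContingencyTable`.
    """
    if name == "table1":
        return {
            "labels": [r[0] for r in _TABLE1_ROWS],
            "W": np.array([r[1] for r in _TABLE1_ROWS]),
            "D_reference": np.array([r[2] for r in _TABLE1_ROWS], dtype=float),
            "D_query": np.array([r[3] for r in _TABLE1_ROWS], dtype=float),
            "V_printed_reference": np.array(_TABLE1_V_REFERENCE),
            "V_printed_query": np.array(_TABLE1_V_QUERY),
        }
    if name in ("table1_reference", "table1_query"):
        t = table_fixture("table1")
        which = name.split("_", 1)[1]
        return {
            "labels": t["labels"],
            "W": t["W"],
            "D": t[f"D_{which}"],
            "V_printed": t[f"V_printed_{which}"],
        }
    if name in _TABLE2:
        rows, cols, counts = _TABLE2[name]
        return ContingencyTable(rows, cols, np.array(counts))
    raise InputError(f"unknown fixture {name!r}")
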