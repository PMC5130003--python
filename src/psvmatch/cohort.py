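"""Cohort data model, delimited-text I/O, cross-cohort alignment and model
serialization.

A cohort is a variables x patients value matrix (gene expression and/or
clinical quantities) aligned column-by-column with per-patient clinical
records (survival time, event indicator, optional age and free categorical
covariates).  Expression files are TSV/CSV with variable ids in the first
column and patient ids in the header; clinical files are TSV/CSV with at
least ``patient_id``, ``survival_time`` and ``event`` columns.  The
delimiter is auto-detected from the header line (tab wins over comma).

The clinical variable ``age`` can be addressed like any matrix variable via
:meth:`Cohort.variable_values`, which is how a mixed expression + age
signature is fitted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ddg import SignatureModel, VariableModel
from .exceptions import (
    AlignmentError,
    FormatError,
    InputError,
    ModelIOError,
    ParseError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ClinicalRecord",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "align_to_reference",
    "save_model",
    "load_model",
]

_SCHEMA_TAG = "psvmatch-signature-model"
_SCHEMA_VERSION = 1

AGE_VARIABLE = "age"


@dataclass
class ClinicalRecord:
    patient_id: str
    survival_time: float | None
    event: int | None
    age: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.survival_time is not None:
            if not np.isfinite(self.survival_time) or self.survival_time < 0:
                raise InputError(
                    f"patient {self.patient_id!r}: survival_time must be >= 0"
                )
        if self.event is not None and self.event not in (0, 1):
            raise InputError(f"patient {self.patient_id!r}: event must be 0 or 1")

    @property
    def has_survival(self) -> bool:
        return self.survival_time is not None and self.event is not None


class Cohort:
    """Aligned container: variables x patients matrix + clinical records."""

    def __init__(self, matrix, variable_ids, patients):
        self.matrix = np.asarray(matrix, dtype=float)
        self.variable_ids = list(variable_ids)
        self.patients = list(patients)
        if self.matrix.ndim != 2:
            raise InputError("matrix must be 2-D (variables x patients)")
        if self.matrix.shape[0] != len(self.variable_ids):
            raise InputError("row count must equal number of variable ids")
        if self.matrix.shape[1] != len(self.patients):
            raise InputError("column count must equal number of patients")
        if len(set(self.variable_ids)) != len(self.variable_ids):
            raise InputError("duplicate variable ids")
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise InputError("duplicate patient ids")
        self._row = {v: i for i, v in enumerate(self.variable_ids)}

    # -- basic views ------------------------------------------------------
    @property
    def n_variables(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_patients(self) -> int:
        return self.matrix.shape[1]

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    @property
    def times(self) -> np.ndarray:
        return np.array(
            [np.nan if p.survival_time is None else p.survival_time for p in self.patients]
        )

    @property
    def events(self) -> np.ndarray:
        return np.array([-1 if p.event is None else p.event for p in self.patients])

    @property
    def ages(self) -> np.ndarray:
        return np.array([np.nan if p.age is None else p.age for p in self.patients])

    def variable_values(self, variable_id) -> np.ndarray:
        """Values of one variable across patients; ``"age"`` pulls from the
        clinical records unless a matrix row of that name exists."""
        if variable_id in self._row:
            return self.matrix[self._row[variable_id]]
        if variable_id == AGE_VARIABLE:
            return self.ages
        raise KeyError(f"unknown variable {variable_id!r}")

    def values_for_patient(self, patient_id, variable_ids) -> np.ndarray:
        j = self.patient_ids.index(patient_id)
        return np.array([self.variable_values(v)[j] for v in variable_ids])

    def subset(self, indices) -> "Cohort":
        indices = np.asarray(indices)
        return Cohort(
            self.matrix[:, indices],
            self.variable_ids,
            [self.patients[int(i)] for i in indices],
        )

    def with_complete_survival(self) -> "Cohort":
        keep = [i for i, p in enumerate(self.patients) if p.has_survival]
        return self if len(keep) == self.n_patients else self.subset(keep)


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_expression(path) -> pd.DataFrame:
    # no silent NA conversion: a non-numeric cell is a hard parse error,
    # only genuinely empty cells count as missing
    df = pd.read_csv(
        path, sep=_sniff_sep(path), index_col=0, dtype=str,
        keep_default_na=False, na_values=[],
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & (df[col].str.strip() != "")
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"non-numeric expression value {df.loc[row, col]!r} "
                f"at variable {row!r}, patient {col!r}"
            )
        out[col] = converted
    return out


def _read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sniff_sep(path))
    required = {"patient_id", "survival_time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"clinical table missing required columns: {sorted(missing)}")
    df["patient_id"] = df["patient_id"].astype(str)
    if df["patient_id"].duplicated().any():
        raise FormatError("duplicate patient_id in clinical table")
    return df


def _record_from_row(row) -> ClinicalRecord:
    def _num(x):
        v = pd.to_numeric(x, errors="coerce")
        return None if pd.isna(v) else float(v)

    st = _num(row["survival_time"])
    ev = _num(row["event"])
    age = _num(row["age"]) if "age" in row.index else None
    skip = {"patient_id", "survival_time", "event", "age"}
    extra = {
        k: row[k]
        for k in row.index
        if k not in skip and not (isinstance(row[k], float) and np.isnan(row[k]))
    }
    return ClinicalRecord(
        patient_id=str(row["patient_id"]),
        survival_time=st,
        event=None if ev is None else int(ev),
        age=age,
        extra=extra,
    )


def read_cohort(expression_path, clinical_path) -> Cohort:
    """Read a cohort from an expression matrix file and a clinical table.

    Columns are intersected on patient id and ordered by the clinical
    table's patient order; patients present in only one file are dropped
    with a logged warning.
    """
    expr = _read_expression(expression_path)
    clin = _read_clinical(clinical_path)
    expr_ids = set(expr.columns)
    clin_ids = clin["patient_id"].tolist()
    shared = [pid for pid in clin_ids if pid in expr_ids]
    if not shared:
        raise InputError("no overlapping patients between expression and clinical tables")
    dropped = (len(clin_ids) - len(shared)) + (len(expr_ids) - len(shared))
    if dropped:
        logger.warning("dropped %d patients absent from one of the two files", dropped)
    clin = clin.set_index("patient_id", drop=False).loc[shared]
    records = [_record_from_row(clin.loc[pid]) for pid in shared]
    return Cohort(expr[shared].to_numpy(), list(expr.index), records)


def write_cohort(cohort: Cohort, expression_path, clinical_path, sep="\t") -> None:
    pd.DataFrame(
        cohort.matrix, index=cohort.variable_ids, columns=cohort.patient_ids
    ).to_csv(expression_path, sep=sep)
    rows = []
    for p in cohort.patients:
        row = {
            "patient_id": p.patient_id,
            "survival_time": p.survival_time,
            "event": p.event,
            "age": p.age,
        }
        row.update(p.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(clinical_path, sep=sep, index=False)


def align_to_reference(query: Cohort, reference: Cohort) -> Cohort:
    """Shift each shared query variable by (reference mean - query mean).

    A per-variable mean alignment standing in for batch correction; it is
    idempotent and leaves the reference untouched.  Every reference matrix
    variable must be present in the query.
    """
    missing = [v for v in reference.variable_ids if v not in query.variable_ids]
    if missing:
        raise AlignmentError(f"query is missing shared variables: {missing}")
    matrix = query.matrix.copy()
    row_of = {v: i for i, v in enumerate(query.variable_ids)}
    for v in reference.variable_ids:
        ref_vals = reference.variable_values(v)
        q_row = row_of[v]
        q_vals = matrix[q_row]
        shift = np.nanmean(ref_vals) - np.nanmean(q_vals)
        matrix[q_row] = q_vals + shift
    return Cohort(matrix, query.variable_ids, [p for p in query.patients])


# -- model serialization --------------------------------------------------


def save_model(model: SignatureModel, path) -> None:
    """Serialize a fitted signature to a single JSON document."""
    doc = {
        "schema": _SCHEMA_TAG,
        "version": _SCHEMA_VERSION,
        "statistic_used": model.statistic_used,
        "stratification_method": model.stratification_method,
        "n_groups": model.n_groups,
        "min_group_frac": model.min_group_frac,
        "variables": [
            {
                "variable_id": v.variable_id,
                "cutoff": v.cutoff,
                "high_side": v.high_side,
                "p_value": v.p_value,
                "weight": v.weight,
                "hazard_ratio": v.hazard_ratio,
                "n_cutoffs_searched": v.n_cutoffs_searched,
            }
            for v in model.variables
        ],
        "reference_ids": model.reference_ids,
        "reference_G": model.reference_G.tolist(),
        "reference_V": model.reference_V.tolist(),
        "reference_awr": model.reference_awr.tolist(),
        "reference_group": model.reference_group.tolist(),
        "group_cutpoints": model.group_cutpoints.tolist(),
        "majority_risk": model.majority_risk.tolist(),
        "reference_values": (
            None if model.reference_values is None else model.reference_values.tolist()
        ),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> SignatureModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelIOError(f"not a valid model file: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("schema") != _SCHEMA_TAG:
        raise ModelIOError("file does not carry the expected model schema tag")
    if doc.get("version") != _SCHEMA_VERSION:
        raise ModelIOError(
            f"unsupported model schema version {doc.get('version')!r}"
        )
    variables = [
        VariableModel(
            variable_id=v["variable_id"],
            cutoff=v["cutoff"],
            high_side=v["high_side"],
            p_value=v["p_value"],
            weight=v["weight"],
            hazard_ratio=v["hazard_ratio"],
            n_cutoffs_searched=v.get("n_cutoffs_searched", 0),
        )
        for v in doc["variables"]
    ]
    rv = doc.get("reference_values")
    return SignatureModel(
        variables=variables,
        reference_ids=list(doc["reference_ids"]),
        reference_G=np.asarray(doc["reference_G"], dtype=np.int64),
        reference_V=np.asarray(doc["reference_V"], dtype=float),
        reference_awr=np.asarray(doc["reference_awr"], dtype=float),
        reference_group=np.asarray(doc["reference_group"]),
        group_cutpoints=np.asarray(doc["group_cutpoints"], dtype=float),
        majority_risk=np.asarray(doc["majority_risk"], dtype=np.int64),
        statistic_used=doc["statistic_used"],
        stratification_method=doc.get("stratification_method", "awr-cutpoint"),
        n_groups=doc["n_groups"],
        min_group_frac=doc["min_group_frac"],
        reference_values=None if rv is None else np.asarray(rv, dtype=float),
    )
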