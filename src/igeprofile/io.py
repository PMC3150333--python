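"""TSV/YAML file formats for phenotypes, matrices and configuration.

All stage artifacts are plain TSV (spreadsheet-compatible) or JSON so
each pipeline stage can be re-run independently:

* phenotype table — one subject per row, columns ``subject_id``,
  ``family_id``, ``role``, ``age``, ``sex``, one column per trait,
  ``asthma_severity``, ``asthma_persistency``, ``asthma_age_onset``;
* reactivity matrix — header row of allergen ids, first column
  ``subject_id``;
* calibration curve — two columns ``concentration_iu_ml``, ``signal``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import TRAITS, Role, Subject, TraitStatus
from .matrix import ReactivityMatrix, Unit
from .quantify import CalibrationCurve

log = logging.getLogger("igeprofile")

REQUIRED_PHENOTYPE_COLUMNS = (
    "subject_id", "family_id", "role", "age", "sex",
    "asthma", "rhinitis", "eczema", "conjunctivitis",
)


class FormatError(ValueError):
    """Input file violates the expected column/value conventions."""


def write_phenotypes(subjects: Sequence[Subject], path: str | Path) -> None:
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id, "family_id": s.family_id,
            "role": s.role.value, "age": s.age, "sex": s.sex,
            **{t: s.traits[t].value for t in TRAITS},
            "asthma_severity": s.asthma_severity,
            "asthma_persistency": s.asthma_persistency,
            "asthma_age_onset": "" if s.asthma_age_onset is None else s.asthma_age_onset,
        }
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> list[Subject]:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in REQUIRED_PHENOTYPE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"phenotype file missing required columns: {missing}")
    if frame["subject_id"].duplicated().any():
        dup = frame.loc[frame["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise FormatError(f"duplicate subject_id {dup!r}")
    subjects = []
    n_unknown = 0
    for _, row in frame.iterrows():
        if row["sex"] not in ("M", "F"):
            raise FormatError(f"unknown sex token {row['sex']!r} for {row['subject_id']}")
        if row["role"] not in (r.value for r in Role):
            raise FormatError(f"unknown role {row['role']!r} for {row['subject_id']}")
        traits = {}
        for t in TRAITS:
            token = row[t]
            try:
                traits[t] = TraitStatus(token)
            except ValueError:
                traits[t] = TraitStatus.UNDEFINED
                n_unknown += 1
        severity: int | str = row.get("asthma_severity", "undefined") or "undefined"
        if severity not in ("undefined",):
            try:
                severity = int(float(severity))
            except ValueError:
                severity = "undefined"
                n_unknown += 1
        onset_token = row.get("asthma_age_onset", "")
        onset = float(onset_token) if onset_token else None
        subjects.append(Subject(
            subject_id=row["subject_id"], family_id=row["family_id"],
            role=Role(row["role"]), age=float(row["age"]), sex=row["sex"],
            traits=traits, asthma_severity=severity,
            asthma_persistency=row.get("asthma_persistency", "undefined") or "undefined",
            asthma_age_onset=onset,
        ))
    if n_unknown:
        log.info("mapped %d unknown tokens to 'undefined'", n_unknown)
    return subjects


def write_matrix(matrix: ReactivityMatrix, path: str | Path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "subject_id"
    frame.to_csv(path, sep="\t")


def read_matrix(path: str | Path, expected_unit: Unit | str) -> ReactivityMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="subject_id")
    unit = Unit(expected_unit)
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = frame.map(lambda v: not isinstance(v, (int, float))).to_numpy()
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"non-numeric cell at ({frame.index[i]}, {frame.columns[j]}): "
            f"{frame.iloc[i, j]!r}"
        )
    try:
        return ReactivityMatrix.from_frame(frame, unit)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def read_calibration(path: str | Path) -> CalibrationCurve:
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise FormatError("calibration file needs 2 columns (concentration, signal)")
    conc, sig = frame.iloc[:, 0], frame.iloc[:, 1]
    return CalibrationCurve(tuple(float(c) for c in conc), tuple(float(s) for s in sig))


def write_calibration(curve: CalibrationCurve, path: str | Path) -> None:
    pd.DataFrame({"concentration_iu_ml": curve.concentrations,
                  "signal": curve.signals}).to_csv(path, sep="\t", index=False)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_panel(allergen_ids: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(allergen_ids) + "\n")


def read_panel(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
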