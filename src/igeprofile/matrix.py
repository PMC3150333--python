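"""Subjects × allergens reactivity matrix container.

The matrix carries one value per subject–allergen pair together with a
declared unit: raw fluorescence ``signal``, calibrated ``iu_per_ml``
(specific-IgE concentration), or the ordinal 0–5 ``class_score`` scale
used for profile clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd


class Unit(str, Enum):
    SIGNAL = "signal"
    IU_PER_ML = "iu_per_ml"
    CLASS_SCORE = "class_score"


VALID_CLASS_SCORES = frozenset(range(6))


@dataclass
class ReactivityMatrix:
    """Dense subjects × allergens reactivity values with a declared unit."""

    subject_ids: list[str]
    allergen_ids: list[str]
    values: np.ndarray
    unit: Unit

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.unit = Unit(self.unit)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if n != len(self.subject_ids) or p != len(self.allergen_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.allergen_ids)} allergens"
            )
        if np.isnan(self.values).any():
            raise ValueError("matrix contains missing cells")
        if self.unit is Unit.CLASS_SCORE:
            bad = ~np.isin(self.values, list(VALID_CLASS_SCORES))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"class-score cell ({self.subject_ids[i]}, {self.allergen_ids[j]}) "
                    f"= {self.values[i, j]} outside 0-5"
                )
        elif self.unit is Unit.IU_PER_ML and (self.values < 0).any():
            raise ValueError("IU/ml values must be non-negative")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_allergens(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.allergen_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, unit: Unit | str) -> "ReactivityMatrix":
        return cls(
            subject_ids=[str(s) for s in frame.index],
            allergen_ids=[str(a) for a in frame.columns],
            values=frame.to_numpy(dtype=float),
            unit=Unit(unit),
        )

    def select_subjects(self, subject_ids: Sequence[str]) -> "ReactivityMatrix":
        """Row subset (e.g. dropping undefined-diagnosis subjects), order preserved."""
        index = {s: i for i, s in enumerate(self.subject_ids)}
        rows = [index[s] for s in subject_ids]
        return ReactivityMatrix(list(subject_ids), list(self.allergen_ids),
                                self.values[rows], self.unit)

    def select_allergens(self, allergen_ids: Sequence[str]) -> "ReactivityMatrix":
        """Column subset (e.g. the filtered asthma-relevant panel), order preserved."""
        index = {a: j for j, a in enumerate(self.allergen_ids)}
        cols = [index[a] for a in allergen_ids]
        return ReactivityMatrix(list(self.subject_ids), list(allergen_ids),
                                self.values[:, cols], self.unit)
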