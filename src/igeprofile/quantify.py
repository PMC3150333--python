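"""Microarray fluorescence → IU/ml → 0–5 class score.

Raw spot fluorescence is background-subtracted, interpolated against an
on-slide calibration curve (anti-IgE spots incubated with WHO reference
standard concentrations 0.35, 1.0, 3.5, 10.0 and 50.0 IU/ml) to give a
specific-IgE concentration in IU/ml, and then binned into the standard
clinical 0–5 class-score scale:

    class 0  < 0.35 IU/ml          class 3  3.51–17.5 IU/ml
    class 1  0.35–0.7 IU/ml        class 4  17.51–50 IU/ml
    class 2  0.71–3.5 IU/ml        class 5  50.01–100 IU/ml

The printed bin labels are given at two-decimal precision and therefore
leave infinitesimal gaps (0.7 → 0.71, 3.5 → 3.51, …); the implemented
scale closes each gap at its midpoint (0.705, 3.505, 17.505, 50.005)
with half-open bins, so every concentration in [0, 100] maps to exactly
one class and the printed labels are honoured at printed precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .matrix import ReactivityMatrix, Unit

ASSAY_MAX_IU = 100.0
DETECTION_LIMIT_IU = 0.35

#: WHO reference standard concentrations printed on each slide (IU/ml).
REFERENCE_CONCENTRATIONS = (0.35, 1.0, 3.5, 10.0, 50.0)

#: Upper edges of classes 0..4 (class 5 runs to the assay ceiling).
DEFAULT_CLASS_EDGES = (0.35, 0.705, 3.505, 17.505, 50.005)


class CalibrationError(ValueError):
    """Calibration curve is unusable (too few points, non-monotone)."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone (concentration, signal) knots of the on-slide standard curve.

    Interpolation is piecewise linear in (log10 concentration, log10 signal)
    space: immunoassay response is locally power-law, so log–log linear
    segments track it closely between knots.
    """

    concentrations: tuple[float, ...]
    signals: tuple[float, ...]

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        sig = np.asarray(self.signals, dtype=float)
        if conc.size != sig.size:
            raise CalibrationError("concentration/signal length mismatch")
        if conc.size < 2:
            raise CalibrationError("calibration curve needs at least 2 points")
        if (conc <= 0).any() or (sig <= 0).any():
            raise CalibrationError("calibration knots must be strictly positive")
        if conc.min() < DETECTION_LIMIT_IU or conc.max() > ASSAY_MAX_IU:
            raise CalibrationError(
                f"calibration concentrations must lie within "
                f"[{DETECTION_LIMIT_IU}, {ASSAY_MAX_IU}] IU/ml"
            )
        if not (np.diff(conc) > 0).all() or not (np.diff(sig) > 0).all():
            raise CalibrationError(
                "calibration curve must be strictly increasing in both coordinates"
            )

    @classmethod
    def from_points(cls, points: Sequence[tuple[float, float]]) -> "CalibrationCurve":
        conc, sig = zip(*points)
        return cls(tuple(float(c) for c in conc), tuple(float(s) for s in sig))


@dataclass(frozen=True)
class ClassScale:
    """Contiguous half-open IU/ml bins mapping to class scores 0–5."""

    edges: tuple[float, ...] = DEFAULT_CLASS_EDGES

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        if edges.size != 5:
            raise ValueError("class scale needs exactly 5 inner edges (6 classes)")
        if not (np.diff(edges) > 0).all():
            raise ValueError("class-scale edges must be strictly increasing")
        if edges[0] <= 0 or edges[-1] > ASSAY_MAX_IU:
            raise ValueError(f"class-scale edges must lie in (0, {ASSAY_MAX_IU}]")


def subtract_background(signal: float, background: float) -> float:
    """Background-corrected fluorescence, floored at zero."""
    if signal < 0 or background < 0:
        raise ValueError("fluorescence values must be non-negative")
    return max(signal - background, 0.0)


def signal_to_iu(signal: float, curve: CalibrationCurve) -> float:
    """Interpolate a background-corrected signal on the calibration curve.

    Signals below the lowest calibration knot are below the 0.35 IU/ml
    detection limit and report as 0.0 (class 0); signals above the highest
    knot clamp to the 100 IU/ml assay ceiling.
    """
    if signal < 0:
        raise ValueError("signal must be non-negative")
    log_sig = np.log10(np.asarray(curve.signals, dtype=float))
    log_conc = np.log10(np.asarray(curve.concentrations, dtype=float))
    if signal <= 0 or np.log10(signal) < log_sig[0]:
        return 0.0
    log_iu = np.interp(np.log10(signal), log_sig, log_conc)
    # np.interp clamps to the last knot; extrapolate the top segment instead
    if np.log10(signal) > log_sig[-1]:
        slope = (log_conc[-1] - log_conc[-2]) / (log_sig[-1] - log_sig[-2])
        log_iu = log_conc[-1] + slope * (np.log10(signal) - log_sig[-1])
    return float(min(10.0 ** log_iu, ASSAY_MAX_IU))


def iu_to_class(iu: float, scale: ClassScale | None = None) -> int:
    """Bin an IU/ml concentration into its 0–5 class score."""
    if iu < 0:
        raise ValueError("IU/ml must be non-negative")
    scale = scale or ClassScale()
    if iu > ASSAY_MAX_IU:
        warnings.warn(
            f"IU/ml value {iu} above assay ceiling {ASSAY_MAX_IU}; clamped to class 5",
            stacklevel=2,
        )
        return 5
    return int(np.searchsorted(scale.edges, iu, side="right"))


def quantify_matrix(
    raw: ReactivityMatrix,
    curve: CalibrationCurve,
    background: float | np.ndarray = 0.0,
    scale: ClassScale | None = None,
) -> ReactivityMatrix:
    """Elementwise signal → IU/ml → class score over a whole matrix.

    ``background`` may be a scalar or an array broadcastable to the matrix
    (e.g. one local background per spot). Cell-level failures are re-raised
    with the offending (subject, allergen) coordinates.
    """
    if raw.unit is not Unit.SIGNAL:
        raise ValueError(f"expected a signal-unit matrix, got {raw.unit.value}")
    background = np.broadcast_to(np.asarray(background, dtype=float), raw.values.shape)
    scores = np.empty(raw.values.shape, dtype=float)
    for i in range(raw.n_subjects):
        for j in range(raw.n_allergens):
            try:
                corrected = subtract_background(raw.values[i, j], background[i, j])
                scores[i, j] = iu_to_class(signal_to_iu(corrected, curve), scale)
            except ValueError as exc:
                raise ValueError(
                    f"cell ({raw.subject_ids[i]}, {raw.allergen_ids[j]}): {exc}"
                ) from exc
    return ReactivityMatrix(list(raw.subject_ids), list(raw.allergen_ids),
                            scores, Unit.CLASS_SCORE)


def iu_matrix_to_class(matrix: ReactivityMatrix, scale: ClassScale | None = None) -> ReactivityMatrix:
    """Encode an IU/ml matrix into class scores (no calibration step)."""
    if matrix.unit is not Unit.IU_PER_ML:
        raise ValueError(f"expected an IU/ml matrix, got {matrix.unit.value}")
    scale = scale or ClassScale()
    clipped = np.minimum(matrix.values, ASSAY_MAX_IU)
    scores = np.searchsorted(scale.edges, clipped, side="right").astype(float)
    return ReactivityMatrix(list(matrix.subject_ids), list(matrix.allergen_ids),
                            scores, Unit.CLASS_SCORE)
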