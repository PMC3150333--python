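"""Synthetic family cohort with planted asthma-associated IgE signatures.

Emulates a family-based atopy study: ~283 nuclear families (one or two
parents plus 1–3 offspring, ~872 subjects in all), atopic-trait phenotypes
with role-specific prevalences (offspring almost all asthmatic, parents
mostly not — the ascertainment scheme of an affected-sib design), and a
subjects × allergens reactivity matrix on the IU/ml scale.

Reactivity is generated on the log10(IU/ml) scale as

    background(allergen) + family factor + signature shift + noise,

then exponentiated and clamped to the assay range [0, 100] IU/ml. The
shared family factor carries a fraction ``rho_fam`` of the profile
variance, inducing within-family correlation of log-reactivity; the
signature shift raises mean log-reactivity of asthma-affected subjects on
a chosen subset of allergens only. A configurable fraction of cells is
forced below the detection limit so that class-score distributions
concentrate at 0, as real specific-IgE panels do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ReactivityMatrix, Unit

TRAITS = ("asthma", "rhinitis", "eczema", "conjunctivitis")


class Role(str, Enum):
    PARENT = "parent"
    OFFSPRING = "offspring"


class TraitStatus(str, Enum):
    AFFECTED = "affected"
    NOT_AFFECTED = "not_affected"
    UNDEFINED = "undefined"


class SpecError(ValueError):
    """Invalid cohort specification (impossible prevalence, bad fraction)."""


class PanelError(ValueError):
    """Signature refers to an allergen index outside the panel."""


@dataclass
class Subject:
    """One individual: identifiers, family link, demographics, atopic traits."""

    subject_id: str
    family_id: str
    role: Role
    age: float
    sex: str  # "M" | "F"
    traits: dict[str, TraitStatus]
    asthma_severity: int | str = "undefined"  # 1..4 or "undefined"
    asthma_persistency: str = "undefined"  # "persistent" | "not_persistent" | "undefined"
    asthma_age_onset: float | None = None

    @property
    def asthma(self) -> TraitStatus:
        return self.traits["asthma"]


# Role-specific trait prevalences: (affected, not_affected) — remainder undefined.
DEFAULT_PREVALENCES: dict[str, dict[str, tuple[float, float]]] = {
    "offspring": {
        "asthma": (0.995, 0.0),
        "rhinitis": (0.754, 0.214),
        "eczema": (0.307, 0.654),
        "conjunctivitis": (0.444, 0.467),
    },
    "parent": {
        "asthma": (0.129, 0.774),
        "rhinitis": (0.235, 0.701),
        "eczema": (0.091, 0.826),
        "conjunctivitis": (0.167, 0.683),
    },
}

#: Odds-ratio coupling of secondary traits to asthma status.
DEFAULT_TRAIT_ASTHMA_OR: dict[str, float] = {
    "rhinitis": 3.0,
    "eczema": 1.5,
    "conjunctivitis": 3.0,
}


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Defaults emulate the study design: 283 families averaging ~1.56 parents
    and ~1.52 offspring each (~872 subjects, asthma prevalence ≈ 55.6%),
    103 allergens with heavy mass at class score 0, moderate familial
    correlation, and a 12-allergen planted signature of one-SD shifts.
    """

    n_families: int = 283
    offspring_per_family: tuple[float, float, float] = (0.55, 0.38, 0.07)
    two_parent_fraction: float = 0.562
    prevalences: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_PREVALENCES
    )
    trait_asthma_or: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_TRAIT_ASTHMA_OR
    )
    familial_correlation: float = 0.35
    panel_size: int = 103
    signature: Mapping[int, float] = field(
        default_factory=lambda: {j: 1.0 for j in range(0, 24, 2)}
    )
    background_mean: float = -1.5
    background_sd_across_allergens: float = 0.6
    noise_sd: float = 1.0
    negative_fraction: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_families < 1:
            raise SpecError("need at least one family")
        if not math.isclose(sum(self.offspring_per_family), 1.0, abs_tol=1e-9):
            raise SpecError("offspring_per_family must be a distribution over {1,2,3}")
        if not 0.0 <= self.familial_correlation < 1.0:
            raise SpecError("familial_correlation must lie in [0, 1)")
        if not 0.0 <= self.negative_fraction <= 1.0:
            raise SpecError("negative_fraction must lie in [0, 1]")
        if not 0.0 <= self.two_parent_fraction <= 1.0:
            raise SpecError("two_parent_fraction must lie in [0, 1]")
        for role, per_trait in self.prevalences.items():
            for trait, (p_aff, p_not) in per_trait.items():
                if min(p_aff, p_not) < 0 or p_aff + p_not > 1 + 1e-9:
                    raise SpecError(
                        f"impossible prevalences for {role}/{trait}: "
                        f"affected={p_aff}, not_affected={p_not}"
                    )
        for j, effect in self.signature.items():
            if not 0 <= j < self.panel_size:
                raise PanelError(f"signature allergen index {j} outside panel 0..{self.panel_size - 1}")
            if not math.isfinite(effect):
                raise PanelError(f"non-finite effect size for allergen {j}")


def _draw_status(rng: np.random.Generator, p_aff: float, p_not: float) -> TraitStatus:
    u = rng.random()
    if u < p_aff:
        return TraitStatus.AFFECTED
    if u < p_aff + p_not:
        return TraitStatus.NOT_AFFECTED
    return TraitStatus.UNDEFINED


def _coupled_probability(base: float, odds_ratio: float, shift_up: bool) -> float:
    """Tilt a base probability by ±log(OR)/2 on the logit scale."""
    if base <= 0.0 or base >= 1.0 or odds_ratio == 1.0:
        return base
    logit = math.log(base / (1 - base))
    logit += (0.5 if shift_up else -0.5) * math.log(odds_ratio)
    return 1.0 / (1.0 + math.exp(-logit))


def _make_subject(rng: np.random.Generator, spec: CohortSpec, subject_id: str,
                  family_id: str, role: Role) -> Subject:
    prev = spec.prevalences[role.value]
    sex = "M" if rng.random() < 0.51 else "F"
    age = float(np.clip(rng.normal(21.3, 12.0) if role is Role.OFFSPRING
                        else rng.normal(47.0, 10.5), 6.0, 89.0))
    asthma = _draw_status(rng, *prev["asthma"])
    traits = {"asthma": asthma}
    for trait in TRAITS[1:]:
        p_aff, p_not = prev[trait]
        odds_ratio = spec.trait_asthma_or.get(trait, 1.0)
        if asthma is not TraitStatus.UNDEFINED:
            scale = (_coupled_probability(p_aff, odds_ratio, asthma is TraitStatus.AFFECTED)
                     / p_aff if p_aff > 0 else 1.0)
            p_aff, p_not = min(p_aff * scale, 1.0 - p_not), p_not
        traits[trait] = _draw_status(rng, p_aff, p_not)

    severity: int | str = "undefined"
    persistency = "undefined"
    onset: float | None = None
    if asthma is not TraitStatus.NOT_AFFECTED:
        severity = int(rng.choice([1, 2, 3, 4], p=[0.29, 0.19, 0.19, 0.33]))
        persistency = "persistent" if rng.random() < 0.89 else "not_persistent"
        onset = float(np.clip(rng.gamma(shape=1.5, scale=7.0) + 1.0, 1.0, age))
    return Subject(subject_id, family_id, role, round(age, 1), sex, traits,
                   severity, persistency, None if onset is None else round(onset, 1))


def generate_cohort(spec: CohortSpec) -> tuple[list[Subject], ReactivityMatrix]:
    """Generate subjects and their IU/ml reactivity matrix.

    Deterministic for a fixed ``spec.seed``. Asthma-affected subjects have
    mean log10-reactivity shifted by ``effect × noise_sd`` on signature
    allergens; undefined-diagnosis subjects receive half the shift (their
    mix of true statuses is unknown).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    subjects: list[Subject] = []
    family_index: list[int] = []  # per subject, family number
    for f in range(spec.n_families):
        fam_id = f"FAM{f:04d}"
        n_parents = 2 if rng.random() < spec.two_parent_fraction else 1
        n_offspring = int(rng.choice([1, 2, 3], p=spec.offspring_per_family))
        for k in range(n_parents):
            subjects.append(_make_subject(
                rng, spec, f"S{len(subjects):04d}", fam_id, Role.PARENT))
            family_index.append(f)
        for k in range(n_offspring):
            subjects.append(_make_subject(
                rng, spec, f"S{len(subjects):04d}", fam_id, Role.OFFSPRING))
            family_index.append(f)

    n, p = len(subjects), spec.panel_size
    rho = spec.familial_correlation
    background = rng.normal(spec.background_mean, spec.background_sd_across_allergens, size=p)
    family_factor = rng.normal(0.0, spec.noise_sd * math.sqrt(rho),
                               size=(spec.n_families, p))
    noise = rng.normal(0.0, spec.noise_sd * math.sqrt(1.0 - rho), size=(n, p))

    shift = np.zeros((n, p))
    for j, effect in spec.signature.items():
        delta = effect * spec.noise_sd
        for i, subj in enumerate(subjects):
            if subj.asthma is TraitStatus.AFFECTED:
                shift[i, j] = delta
            elif subj.asthma is TraitStatus.UNDEFINED:
                shift[i, j] = 0.5 * delta

    log_iu = background[None, :] + family_factor[family_index, :] + shift + noise
    iu = np.clip(10.0 ** log_iu, 0.0, 100.0)
    below_detection = rng.random(size=(n, p)) < spec.negative_fraction
    iu[below_detection] = 0.0

    matrix = ReactivityMatrix(
        subject_ids=[s.subject_id for s in subjects],
        allergen_ids=[f"A{j:03d}" for j in range(p)],
        values=iu,
        unit=Unit.IU_PER_ML,
    )
    return subjects, matrix


def cohort_summary(subjects: Sequence[Subject]) -> pd.DataFrame:
    """Per-trait counts and percentages by role and combined.

    One row per (trait, status, group) with ``count``, ``group_size`` and
    ``percent`` = 100·count/group size rounded to 2 decimals.
    """
    if not subjects:
        raise ValueError("empty cohort")
    groups = {
        "offspring": [s for s in subjects if s.role is Role.OFFSPRING],
        "parent": [s for s in subjects if s.role is Role.PARENT],
        "combined": list(subjects),
    }
    rows = []
    for group, members in groups.items():
        size = len(members)
        if size == 0:
            continue
        for sex in ("M", "F"):
            count = sum(1 for s in members if s.sex == sex)
            rows.append(("sex", sex, group, count, size, round(100.0 * count / size, 2)))
        for trait in TRAITS:
            for status in TraitStatus:
                count = sum(1 for s in members if s.traits[trait] is status)
                rows.append((trait, status.value, group, count, size,
                             round(100.0 * count / size, 2)))
    return pd.DataFrame(
        rows, columns=["trait", "status", "group", "count", "group_size", "percent"]
    )
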