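"""Cluster–trait association tests and the matched case-control subset.

Tests whether atopic-trait frequencies differ across reactivity-profile
clusters (Pearson χ²), whether a single cluster deviates from the whole
study sample (goodness-of-fit χ²), whether numeric traits such as age of
asthma onset differ across clusters (Kruskal-Wallis), and whether members
of the same family co-segregate into clusters (permutation test).
Subjects with an undefined diagnosis for a trait are excluded from that
trait's table only, so totals may differ per trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Role, Subject, TraitStatus


@dataclass
class AssociationResult:
    test: str
    statistic: float
    df: int
    p: float
    note: str = ""


class TestError(ValueError):
    """Contingency structure makes the requested test undefined."""


def contingency_table(
    assignments: np.ndarray,
    subjects: Sequence[Subject],
    trait: str,
) -> pd.DataFrame:
    """Clusters × {not_affected, affected} counts, undefined rows dropped."""
    labels = np.asarray(assignments)
    rows = []
    for subj, lab in zip(subjects, labels):
        status = subj.traits[trait]
        if status is TraitStatus.UNDEFINED:
            continue
        rows.append((int(lab), status.value))
    if not rows:
        raise TestError(f"no defined-diagnosis subjects for trait {trait!r}")
    frame = pd.DataFrame(rows, columns=["cluster", "status"])
    table = pd.crosstab(frame["cluster"], frame["status"])
    return table.reindex(columns=["not_affected", "affected"], fill_value=0)


def chisq_test(table: pd.DataFrame | np.ndarray) -> AssociationResult:
    """Pearson χ² test of independence on an r × c count table."""
    counts = np.asarray(table, dtype=float)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise TestError("contingency table needs >= 2 rows and >= 2 columns")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise TestError("zero margin in contingency table")
    stat, p, df, expected = stats.chi2_contingency(counts, correction=False)
    note = ""
    if (expected < 5).mean() > 0.2:
        note = "more than 20% of expected counts below 5"
        warnings.warn(f"chi-square approximation suspect: {note}", stacklevel=2)
    return AssociationResult("pearson_chi2", float(stat), int(df), float(p), note)


def cluster_vs_population(
    cluster_counts: Sequence[float], population_counts: Sequence[float]
) -> AssociationResult:
    """Goodness-of-fit χ² of one cluster's trait counts vs whole-sample proportions."""
    obs = np.asarray(cluster_counts, dtype=float)
    pop = np.asarray(population_counts, dtype=float)
    if obs.shape != pop.shape:
        raise TestError("cluster and population count vectors differ in length")
    if obs.sum() > pop.sum():
        raise TestError("cluster larger than population")
    if (pop == 0).any():
        raise TestError("empty trait level in population")
    expected = pop / pop.sum() * obs.sum()
    stat, p = stats.chisquare(obs, expected)
    return AssociationResult("chi2_goodness_of_fit", float(stat), len(obs) - 1, float(p))


def kruskal_wallis(values: Sequence[float], groups: Sequence[int]) -> AssociationResult:
    """Tie-corrected Kruskal-Wallis H test of a numeric trait across clusters."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise TestError("Kruskal-Wallis needs >= 2 groups")
    samples = [values[groups == g] for g in uniq]
    if any(len(s) == 0 for s in samples):
        raise TestError("empty group")
    if np.all(values == values[0]):
        return AssociationResult("kruskal_wallis", 0.0, len(uniq) - 1, 1.0,
                                 "all values identical")
    stat, p = stats.kruskal(*samples)
    return AssociationResult("kruskal_wallis", float(stat), len(uniq) - 1, float(p))


def _family_indices(family_ids: Sequence[str]) -> list[np.ndarray]:
    """Index arrays of the families with at least two members."""
    frame = pd.Series(list(family_ids))
    groups = [np.asarray(idx) for _, idx in frame.groupby(frame).groups.items()]
    multi = [g for g in groups if len(g) >= 2]
    if not multi:
        raise TestError("no family with >= 2 members")
    return multi


def _coseg_from_indices(labels: np.ndarray, families: list[np.ndarray],
                        n_clusters: int) -> float:
    fractions = np.empty(len(families))
    for i, idx in enumerate(families):
        counts = np.bincount(labels[idx], minlength=n_clusters)
        m = len(idx)
        fractions[i] = (counts * (counts - 1)).sum() / (m * (m - 1))
    return float(fractions.mean())


def cosegregation_statistic(assignments: np.ndarray, family_ids: Sequence[str]) -> float:
    """Mean over multi-member families of the fraction of pairs sharing a cluster."""
    labels = np.asarray(assignments).astype(int)
    families = _family_indices(family_ids)
    return _coseg_from_indices(labels, families, labels.max() + 1)


def family_cosegregation(
    assignments: np.ndarray,
    subjects: Sequence[Subject],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> AssociationResult:
    """Permutation test for family members clustering together.

    The observed statistic is the mean within-family fraction of member
    pairs that share a cluster; the null distribution permutes the
    subject → cluster assignment, which preserves cluster sizes while
    breaking family structure. p = (1 + #{perm ≥ obs}) / (B + 1).
    """
    family_ids = [s.family_id for s in subjects]
    labels = np.asarray(assignments).astype(int)
    families = _family_indices(family_ids)
    n_clusters = labels.max() + 1
    observed = _coseg_from_indices(labels, families, n_clusters)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _coseg_from_indices(perm, families, n_clusters) >= observed - 1e-12:
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)
    return AssociationResult("family_cosegregation_permutation", observed,
                             0, float(p), f"B={n_permutations}")


class MatchingError(ValueError):
    """Not enough candidates to form the requested matched pairs."""


def matched_case_control(
    subjects: Sequence[Subject],
    n_pairs: int | None,
    max_age_gap: float | None = None,
) -> list[Subject]:
    """Greedy age-and-sex matched case-control subset among parents.

    Asthma-affected parents are cases; each is matched to the
    nearest-age not-affected parent of the same sex, without replacement.
    Returns exactly ``2·n_pairs`` subjects (cases then their controls,
    pair-aligned); with ``n_pairs=None`` every matchable case is paired.
    """
    parents = [s for s in subjects if s.role is Role.PARENT]
    cases = sorted((s for s in parents if s.asthma is TraitStatus.AFFECTED),
                   key=lambda s: (s.age, s.subject_id))
    controls = {
        sex: sorted((s for s in parents
                     if s.asthma is TraitStatus.NOT_AFFECTED and s.sex == sex),
                    key=lambda s: (s.age, s.subject_id))
        for sex in ("M", "F")
    }
    if n_pairs is not None and len(cases) < n_pairs:
        raise MatchingError(f"only {len(cases)} asthmatic parents for {n_pairs} pairs")
    matched_cases: list[Subject] = []
    matched_controls: list[Subject] = []
    for case in cases:
        if n_pairs is not None and len(matched_cases) == n_pairs:
            break
        pool = controls[case.sex]
        if not pool:
            continue
        best = min(range(len(pool)), key=lambda i: (abs(pool[i].age - case.age),
                                                    pool[i].subject_id))
        if max_age_gap is not None and abs(pool[best].age - case.age) > max_age_gap:
            continue
        matched_cases.append(case)
        matched_controls.append(pool.pop(best))
    if n_pairs is not None and len(matched_cases) < n_pairs:
        raise MatchingError(
            f"could only form {len(matched_cases)} of {n_pairs} matched pairs "
            f"(deficit {n_pairs - len(matched_cases)})"
        )
    if not matched_cases:
        raise MatchingError("no matchable case-control pair")
    return matched_cases + matched_controls


def trait_association_report(
    assignments: np.ndarray,
    subjects: Sequence[Subject],
    traits: Sequence[str] = ("asthma", "rhinitis", "eczema", "conjunctivitis"),
) -> pd.DataFrame:
    """Per-trait cluster χ² table with raw and Bonferroni-adjusted p-values."""
    rows = []
    for trait in traits:
        table = contingency_table(assignments, subjects, trait)
        res = chisq_test(table)
        rows.append((trait, res.statistic, res.df, res.p))
    report = pd.DataFrame(rows, columns=["trait", "chi2", "df", "p"])
    report["p_bonferroni"] = np.minimum(report["p"] * len(report), 1.0)
    return report
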