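#!/usr/bin/env python
"""Test cluster-trait associations on the all-allergen partition.

Pearson chi-square of each atopic trait across the three clusters, the
most asthma-enriched cluster against the whole study sample, a
Kruskal-Wallis test of asthma age-of-onset across clusters, the family
co-segregation permutation test, and a matched parent case-control
subset analysis.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from igeprofile import io
from igeprofile.association import (
    chisq_test,
    cluster_vs_population,
    contingency_table,
    family_cosegregation,
    kruskal_wallis,
    matched_case_control,
    trait_association_report,
)
from igeprofile.cohort import TraitStatus


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-pairs", type=int, default=None,
                        help="matched pairs to form (default: every matchable case)")
    parser.add_argument("--out-dir", type=Path, default=Path("results/analysis"))
    args = parser.parse_args()

    subjects = io.read_phenotypes(args.out_dir / "phenotypes.tsv")
    clusters = pd.read_csv(args.out_dir / "clusters_all.tsv", sep="\t")
    assignments = clusters.set_index("subject_id").loc[
        [s.subject_id for s in subjects], "cluster"].to_numpy()

    report = trait_association_report(assignments, subjects)
    report.to_csv(args.out_dir / "association_all.tsv", sep="\t", index=False)
    print("cluster-trait chi-square (all 103 allergens):")
    print(report.to_string(index=False))

    # most asthma-enriched cluster vs the whole study sample
    table = contingency_table(assignments, subjects, "asthma")
    enriched = int((table["affected"] / table.sum(axis=1)).idxmax())
    pop = table.sum(axis=0)
    res = cluster_vs_population(table.loc[enriched].tolist(), pop.tolist())
    print(f"\ncluster {enriched} ({table.loc[enriched].sum()} subjects, "
          f"{100 * table.loc[enriched, 'affected'] / table.loc[enriched].sum():.1f}% "
          f"asthmatic) vs whole sample: chi2 = {res.statistic:.3f}, p = {res.p:.3g}")

    onset = [(s.asthma_age_onset, a) for s, a in zip(subjects, assignments)
             if s.asthma is TraitStatus.AFFECTED and s.asthma_age_onset is not None]
    kw = kruskal_wallis([v for v, _ in onset], [g for _, g in onset])
    print(f"asthma age-of-onset across clusters: H = {kw.statistic:.3f}, "
          f"df = {kw.df}, p = {kw.p:.3g}")

    coseg = family_cosegregation(assignments, subjects, n_permutations=5000,
                                 seed=args.seed)
    print(f"family co-segregation: statistic = {coseg.statistic:.3f}, "
          f"permutation p = {coseg.p:.4f} ({coseg.note})")

    # age/sex matched parent case-control subset
    subset = matched_case_control(subjects, n_pairs=args.n_pairs)
    n_pairs = len(subset) // 2
    ids = {s.subject_id for s in subset}
    cc_subjects = [s for s in subjects if s.subject_id in ids]
    cc_assign = clusters.set_index("subject_id").loc[
        [s.subject_id for s in cc_subjects], "cluster"].to_numpy()
    cc_table = contingency_table(cc_assign, cc_subjects, "asthma")
    cc_res = chisq_test(cc_table)
    print(f"\nmatched case-control subset ({len(subset)} parents, "
          f"{n_pairs} pairs): cluster-asthma chi2 = {cc_res.statistic:.3f}, "
          f"p = {cc_res.p:.3g}")

    summary = {
        "enriched_cluster": enriched,
        "enriched_vs_population_chi2": res.statistic,
        "enriched_vs_population_p": res.p,
        "age_onset_H": kw.statistic, "age_onset_p": kw.p,
        "cosegregation_statistic": coseg.statistic, "cosegregation_p": coseg.p,
        "case_control_chi2": cc_res.statistic, "case_control_p": cc_res.p,
    }
    (args.out_dir / "association_extras.json").write_text(
        json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
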