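"""End-to-end pipeline: simulate → quantify → cluster → associate →
filter → re-cluster → classify → GEE.

Every stage writes plain TSV/JSON artifacts plus a ``manifest.json``
recording inputs, seeds and stage timings, so a fixed master seed
reproduces every file bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .allergen_filter import filter_allergens
from .association import family_cosegregation, trait_association_report
from .clustering import ClusteringConfig, kmeans, select_k
from .cohort import CohortSpec, TraitStatus, generate_cohort, cohort_summary
from .gee import GEEConfig, forward_select, univariate_screen, classification_from_gee
from .matrix import ReactivityMatrix, Unit
from .quantify import ClassScale, iu_matrix_to_class
from .rbf import TrainingProtocol, repeated_evaluation

log = logging.getLogger("igeprofile")


@dataclass
class PipelineConfig:
    output_dir: str = "results/pipeline"
    master_seed: int = 0
    simulate: bool = True
    cohort_spec: CohortSpec | None = None
    phenotypes_path: str | None = None
    matrix_path: str | None = None
    matrix_unit: str = "iu_per_ml"
    clustering: ClusteringConfig | None = None
    fixed_k: int = 3
    filter_alpha: float = 0.05
    rbf_protocol: TrainingProtocol | None = None
    gee: GEEConfig | None = None
    run_gee: bool = True
    run_select_k: bool = False
    cosegregation_permutations: int = 2000

    def validate(self) -> None:
        if not self.simulate and (self.phenotypes_path is None or self.matrix_path is None):
            raise ValueError(
                "config error: phenotypes_path and matrix_path required when simulate=False"
            )


def _covariate_frame(subjects) -> pd.DataFrame:
    age = np.array([s.age for s in subjects], dtype=float)
    male = np.array([1.0 if s.sex == "M" else 0.0 for s in subjects])
    return pd.DataFrame({"age": age, "male": male, "age_x_male": age * male})


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"master_seed": config.master_seed, "stages": {}, "artifacts": []}
    t_all = time.perf_counter()

    def stage(name):
        manifest["stages"][name] = {"start": time.perf_counter() - t_all}
        log.info("stage %s", name)

    def done(name, **info):
        entry = manifest["stages"][name]
        entry["seconds"] = round(time.perf_counter() - t_all - entry.pop("start"), 3)
        entry.update(info)

    def save(frame: pd.DataFrame, name: str, index: bool = False) -> None:
        frame.to_csv(out / name, sep="\t", index=index)
        manifest["artifacts"].append(name)

    try:
        # --- inputs -----------------------------------------------------
        stage("input")
        if config.simulate:
            spec = config.cohort_spec or CohortSpec(seed=config.master_seed)
            subjects, iu = generate_cohort(spec)
            io.write_phenotypes(subjects, out / "phenotypes.tsv")
            io.write_matrix(iu, out / "reactivity_iu.tsv")
            manifest["artifacts"] += ["phenotypes.tsv", "reactivity_iu.tsv"]
        else:
            subjects = io.read_phenotypes(config.phenotypes_path)
            iu = io.read_matrix(config.matrix_path, config.matrix_unit)
        save(cohort_summary(subjects), "cohort_summary.tsv")
        done("input", n_subjects=len(subjects), n_allergens=iu.n_allergens)

        # --- quantify ---------------------------------------------------
        stage("quantify")
        scores = iu if iu.unit is Unit.CLASS_SCORE else iu_matrix_to_class(iu, ClassScale())
        io.write_matrix(scores, out / "class_scores.tsv")
        manifest["artifacts"].append("class_scores.tsv")
        done("quantify")

        # defined-asthma analysis subset (485 affected + 342 not in the
        # emulated design; undefined-diagnosis subjects are excluded)
        defined = [i for i, s in enumerate(subjects)
                   if s.asthma is not TraitStatus.UNDEFINED]
        subj_def = [subjects[i] for i in defined]
        scores_def = scores.select_subjects([subjects[i].subject_id for i in defined])
        status = np.array([s.asthma is TraitStatus.AFFECTED for s in subj_def])
        families = [s.family_id for s in subj_def]

        cconf = config.clustering or ClusteringConfig(seed=config.master_seed)

        # --- cluster on the full panel ---------------------------------
        stage("cluster_all")
        if config.run_select_k:
            report = select_k(scores.values, cconf)
            save(report.table.rename_axis("k"), "validity_all.tsv", index=True)
            k_all = report.chosen_k
        else:
            k_all = config.fixed_k
        result_all = kmeans(scores.values, k_all, cconf)
        save(pd.DataFrame({"subject_id": scores.subject_ids,
                           "cluster": result_all.assignments}), "clusters_all.tsv")
        done("cluster_all", k=k_all, wcss=result_all.wcss)

        # --- associate (all allergens) ----------------------------------
        stage("associate_all")
        assoc_all = trait_association_report(result_all.assignments, subjects)
        save(assoc_all, "association_all.tsv")
        # same defined-diagnosis subset the filtered analysis uses, so the
        # before/after-filter asthma p-values are directly comparable
        assign_def = result_all.assignments[defined]
        assoc_all_def = trait_association_report(assign_def, subj_def)
        coseg = family_cosegregation(result_all.assignments, subjects,
                                     n_permutations=config.cosegregation_permutations,
                                     seed=config.master_seed)
        done("associate_all",
             asthma_p=float(assoc_all.set_index("trait").loc["asthma", "p"]),
             asthma_p_defined=float(assoc_all_def.set_index("trait").loc["asthma", "p"]),
             cosegregation_stat=coseg.statistic, cosegregation_p=coseg.p)

        # --- Mann-Whitney filter ---------------------------------------
        stage("filter")
        filt = filter_allergens(scores_def, status, alpha=config.filter_alpha)
        save(filt.table, "allergen_filter.tsv")
        io.write_panel(filt.retained_allergens, out / "retained_panel.txt")
        manifest["artifacts"].append("retained_panel.txt")
        done("filter", n_retained=filt.n_retained)

        # --- re-cluster on the filtered panel --------------------------
        stage("cluster_filtered")
        if filt.n_retained < 2:
            raise RuntimeError("fewer than 2 allergens retained; cannot re-cluster")
        scores_filt = scores_def.select_allergens(filt.retained_allergens)
        result_filt = kmeans(scores_filt.values, config.fixed_k, cconf)
        save(pd.DataFrame({"subject_id": scores_filt.subject_ids,
                           "cluster": result_filt.assignments}), "clusters_filtered.tsv")
        assoc_filt = trait_association_report(result_filt.assignments, subj_def)
        save(assoc_filt, "association_filtered.tsv")
        done("cluster_filtered",
             asthma_p=float(assoc_filt.set_index("trait").loc["asthma", "p"]))

        # --- RBF classifier --------------------------------------------
        stage("rbf")
        protocol = config.rbf_protocol or TrainingProtocol(seed=config.master_seed)
        report = repeated_evaluation(scores_filt.values, status.astype(int), protocol)
        rbf_rows = pd.DataFrame(report.repetition_rows)
        save(rbf_rows, "rbf_repetitions.tsv")
        done("rbf", sensitivity=report.sensitivity_mean,
             specificity=report.specificity_mean,
             accuracy=report.accuracy_mean, auc=report.auc_train_test)

        # --- GEE screen + forward selection -----------------------------
        if config.run_gee:
            stage("gee")
            gconf = config.gee or GEEConfig()
            covariates = _covariate_frame(subj_def)
            screen = univariate_screen(scores_filt, status.astype(int), families,
                                       covariates=None, config=gconf)
            save(screen, "gee_univariate.tsv")
            gee_set = set(screen.loc[screen["retained"], "allergen_id"])
            mw_set = set(filt.retained_allergens)
            overlap = {
                "gee_retained": len(gee_set), "mw_retained": len(mw_set),
                "common": len(gee_set & mw_set),
                "jaccard": (len(gee_set & mw_set) / len(gee_set | mw_set)
                            if gee_set | mw_set else 1.0),
            }
            fit, selected = forward_select(
                scores_filt, sorted(gee_set), status.astype(int), families,
                covariates, config=gconf)
            save(fit.table, "gee_final_model.tsv")
            design = pd.concat(
                [covariates.reset_index(drop=True)] + [
                    _factor(scores_filt, a) for a in selected], axis=1)
            classify = classification_from_gee(fit, design, status.astype(int),
                                               config=gconf)
            done("gee", selected=selected, overlap=overlap, **classify)
    except Exception as exc:
        manifest["failed_stage"] = next(
            (k for k, v in manifest["stages"].items() if "seconds" not in v), "?")
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    manifest["total_seconds"] = round(time.perf_counter() - t_all, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _factor(matrix: ReactivityMatrix, allergen: str) -> pd.DataFrame:
    from .gee import encode_class_factor
    j = matrix.allergen_ids.index(allergen)
    return encode_class_factor(matrix.values[:, j], prefix=f"{allergen}_s")
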