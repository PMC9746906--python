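"""End-to-end orchestration of the subtyping pipeline on a cohort.

Stage order mirrors the analysis design: cohort inclusion filter ->
per-platform clustering (mutation signatures, copy number, methylation) ->
cluster-of-clusters consensus integration -> subtype driver detection ->
immune checkpoint scoring -> focal-subtype expression classifier ->
two-panel drug screen -> survival summaries.  Every stage draws its
randomness from a seed derived deterministically from the master seed and
the stage name, so stages are decoupled and the whole run is reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import coca as coca_mod
from . import drivers as drivers_mod
from . import drugs as drugs_mod
from . import immune as immune_mod
from . import io as io_mod
from . import signatures as sig_mod
from . import survival as surv_mod
from .classifier import compare_methods, lasso_select_features, split_cohort
from .platform_clustering import (
    ClusterAssignment,
    choose_k,
    filter_driver_cpgs,
    hierarchical_cluster,
    select_top_variable_sites,
    trinarize_gistic,
)
from .synthetic import MultiomicsCohort, SyntheticConfig, generate_ccl_panel, generate_cohort

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) & 0x7FFFFFFF


def filter_cohort(
    frequencies: pd.Series,
    samples: pd.DataFrame,
    min_frequency: float = 0.10,
    min_complete: int = 50,
) -> tuple[list[str], list[str]]:
    """Cohort inclusion rule: keep cancer types whose TP53-mutant frequency
    strictly exceeds ``min_frequency`` and whose complete-profile mutant
    count strictly exceeds ``min_complete``; keep only complete-profile
    samples of those types.

    ``frequencies``: cancer type -> mutant fraction in [0, 1].
    ``samples``: columns (sample, cancer_type, complete).
    """
    if ((frequencies < 0) | (frequencies > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    if samples.empty:
        return [], []
    counts = samples[samples["complete"].astype(bool)].groupby("cancer_type").size()
    included = [
        t
        for t in frequencies.index
        if frequencies[t] > min_frequency and counts.get(t, 0) > min_complete
    ]
    kept = samples[samples["complete"] & samples["cancer_type"].isin(included)]
    if not included:
        logger.warning("filter_cohort: no cancer type passes the inclusion rule")
    return included, list(kept["sample"])


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults are the desk-scale study
    conditions for the default five-subtype synthetic cohort."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig.default)
    seed: int = 0
    output_dir: str | None = None
    # mutation stage
    rank_range: tuple[int, int] = (2, 7)
    nmf_restarts: int = 20
    mutation_k: int | str = "auto"
    platform_k_range: tuple[int, int] = (2, 8)
    # methylation stage
    n_top_sites: int = 1000
    # integration stage
    coca_k_range: tuple[int, int] = (2, 8)
    coca_item_fraction: float = 0.8
    coca_repetitions: int = 250
    coca_delta_threshold: float = 0.05
    # classifier stage
    train_fraction: float = 0.8
    lasso_alpha: float | str = 0.0015
    classifier_methods: tuple[str, ...] = (
        "neural_net",
        "svm",
        "logistic",
        "knn",
        "lda",
        "naive_bayes",
        "cart",
    )
    # drug stage
    n_cell_lines: int = 150
    n_drugs: int = 40
    drug_missing_rate: float = 0.1
    drug_max_missing: float = 0.2
    drug_knn: int = 5
    drug_alpha: float = 0.05
    planted_sensitive_effect: float = -1.0
    # stage switches
    run_drivers: bool = True
    run_immune: bool = True
    run_classifier: bool = True
    run_drugs: bool = True
    run_survival: bool = True


@dataclass
class PipelineReport:
    platform_labels: dict[str, pd.Series]
    coca_selected_k: int
    coca_labels: pd.Series
    ari_vs_truth: float | None = None
    platform_k: dict[str, int] = field(default_factory=dict)
    driver_events: pd.DataFrame | None = None
    driver_precision: float | None = None
    driver_recall: float | None = None
    focal_coca_label: int | None = None
    checkpoint_enrichment_p: float | None = None
    classifier_report: pd.DataFrame | None = None
    best_method: str | None = None
    best_validation_accuracy: float | None = None
    drug_candidates: list[str] | None = None
    logrank_p: float | None = None
    cox_table: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "coca_selected_k": self.coca_selected_k,
            "ari_vs_truth": self.ari_vs_truth,
            "platform_k": self.platform_k,
            "driver_precision": self.driver_precision,
            "driver_recall": self.driver_recall,
            "focal_coca_label": self.focal_coca_label,
            "checkpoint_enrichment_p": self.checkpoint_enrichment_p,
            "best_method": self.best_method,
            "best_validation_accuracy": self.best_validation_accuracy,
            "drug_candidates": self.drug_candidates,
            "logrank_p": self.logrank_p,
            "provenance": self.provenance,
        }


def cluster_platforms(
    cohort: MultiomicsCohort, cfg: PipelineConfig
) -> tuple[list[ClusterAssignment], dict]:
    """Run the three single-platform clusterings and return assignments plus
    stage metadata (selected k, retained-probe counts, signature rank)."""
    meta: dict = {}
    krange = range(cfg.platform_k_range[0], cfg.platform_k_range[1] + 1)

    motif = sig_mod.build_motif_matrix(cohort.mutation_records, cohort.sample_ids)
    model = sig_mod.extract_signatures(
        motif,
        range(cfg.rank_range[0], cfg.rank_range[1] + 1),
        n_restarts=cfg.nmf_restarts,
        seed=stage_seed(cfg.seed, "signatures"),
    )
    mut = sig_mod.cluster_exposures(model, k=cfg.mutation_k, k_range=krange)
    meta["signature_rank"] = model.selected_rank
    meta["cophenetic_by_rank"] = model.cophenetic_by_rank
    meta["signature_model"] = model

    trinary = trinarize_gistic(cohort.cnv)
    k_cnv, _ = choose_k(trinary, krange, linkage="ward")
    cnv = hierarchical_cluster(trinary, k_cnv, linkage="ward", platform="cnv")
    meta["trinary"] = trinary

    report = filter_driver_cpgs(
        cohort.methylation, cohort.methylation_normal, cohort.probe_annotation
    )
    n_sites = min(cfg.n_top_sites, len(report.retained))
    if n_sites < cfg.n_top_sites:
        logger.info("methylation: only %d retained probes; using all of them", n_sites)
    top_sites = select_top_variable_sites(cohort.methylation, report.retained, n_sites)
    beta_top = cohort.methylation.loc[top_sites]
    k_meth, _ = choose_k(beta_top, krange, linkage="ward")
    meth = hierarchical_cluster(beta_top, k_meth, linkage="ward", platform="methylation")
    meta["cpg_report"] = report
    meta["top_sites"] = top_sites
    return [mut, cnv, meth], meta


def run_pipeline(config: PipelineConfig, cohort: MultiomicsCohort | None = None) -> PipelineReport:
    cfg = config
    if cohort is None:
        cohort = generate_cohort(cfg.synthetic)
    truth = cohort.truth["subtype"] if cohort.truth else None

    assignments, meta = cluster_platforms(cohort, cfg)
    binary = coca_mod.encode_binary_membership(assignments)
    consensus = coca_mod.consensus_cluster(
        binary,
        range(cfg.coca_k_range[0], cfg.coca_k_range[1] + 1),
        item_fraction=cfg.coca_item_fraction,
        repetitions=cfg.coca_repetitions,
        seed=stage_seed(cfg.seed, "coca"),
        delta_threshold=cfg.coca_delta_threshold,
    )
    labels = ClusterAssignment(platform="coca", labels=consensus.labels)

    report = PipelineReport(
        platform_labels={a.platform: a.labels for a in assignments},
        coca_selected_k=consensus.selected_k,
        coca_labels=consensus.labels,
        platform_k={a.platform: a.k for a in assignments},
        provenance={
            "seed": cfg.seed,
            "n_samples": len(cohort.sample_ids),
            "signature_rank": meta["signature_rank"],
            "coca_repetitions": cfg.coca_repetitions,
            "coca_item_fraction": cfg.coca_item_fraction,
        },
    )
    if truth is not None:
        report.ari_vs_truth = float(
            adjusted_rand_score(truth.loc[consensus.labels.index], consensus.labels)
        )

    scfg = cfg.synthetic
    if cfg.run_drivers:
        smg = scfg.smg_list()
        status = cohort.mutation_status(smg)
        mut_events, _ = drivers_mod.mutation_driver_test(status, labels, smg)
        frag_to_genes = {
            f: [f"{'AMPG' if d == 'amp' else 'DELG'}{s}"]
            for f, s, d, _, _ in scfg.driver_fragments
        }
        scna_events = drivers_mod.scna_driver_test(
            meta["trinary"], labels, cohort.expression, frag_to_genes
        )
        probe_to_gene = {p: g for p, g, _, _, _ in scfg.driver_cpgs}
        meth_events = drivers_mod.methylation_driver_test(
            cohort.methylation, labels, cohort.expression, probe_to_gene, meta["top_sites"]
        )
        all_events = mut_events + scna_events + meth_events
        report.driver_events = drivers_mod._events_frame(all_events)
        if cohort.truth:
            # score against planted truth using the best alignment of COCA
            # labels to planted subtypes (majority vote per COCA cluster)
            aligned = _align_events(all_events, consensus.labels, truth)
            prec, rec = drivers_mod.driver_precision_recall(aligned, cohort.truth["drivers"])
            report.driver_precision, report.driver_recall = prec, rec

    focal_label = None
    if cfg.run_immune:
        sets = scfg.checkpoint_sets()
        cps = immune_mod.score_checkpoints(
            cohort.expression, sets["stimulatory"], sets["inhibitory"]
        )
        best_p, best_label = 1.1, None
        for s in sorted(consensus.labels.unique()):
            frac = (cps.categories[consensus.labels == s] == "inhibitory").mean()
            overall = (cps.categories == "inhibitory").mean()
            if frac <= overall:
                continue
            _, p = immune_mod.category_enrichment_test(cps.categories, labels, s)
            if p < best_p:
                best_p, best_label = p, int(s)
        report.focal_coca_label = best_label
        report.checkpoint_enrichment_p = best_p if best_label is not None else None
        focal_label = best_label

    if focal_label is None and truth is not None:
        # fallback: COCA label best matching the planted focal subtype
        focal_label = int(
            consensus.labels[truth.loc[consensus.labels.index] == scfg.focal_subtype]
            .mode()
            .iloc[0]
        )

    if cfg.run_classifier and focal_label is not None:
        binary_labels = (consensus.labels == focal_label).map(
            {True: "focal", False: "rest"}
        )
        seed_cls = stage_seed(cfg.seed, "classifier")
        train, val = split_cohort(
            cohort.sample_ids, binary_labels, cfg.train_fraction, seed=seed_cls
        )
        selected = lasso_select_features(
            cohort.expression[train], binary_labels.loc[train], penalty=cfg.lasso_alpha,
            seed=seed_cls,
        )
        if selected:
            cls_report, _ = compare_methods(
                cohort.expression,
                binary_labels,
                selected,
                train,
                val,
                methods=cfg.classifier_methods,
                seed=seed_cls,
            )
            report.classifier_report = cls_report
            report.best_method = cls_report.iloc[0]["method"]
            report.best_validation_accuracy = float(cls_report.iloc[0]["validation_accuracy"])

    if cfg.run_drugs and focal_label is not None:
        planted_subtype = scfg.focal_subtype
        pairs = [("DRUG001", planted_subtype, cfg.planted_sensitive_effect)]
        screens = {}
        for panel_name in ("panelA", "panelB"):
            panel = generate_ccl_panel(
                scfg,
                cfg.n_cell_lines,
                cfg.n_drugs,
                cfg.drug_missing_rate,
                pairs,
                seed=stage_seed(cfg.seed, f"drugs:{panel_name}"),
            )
            complete, _ = drugs_mod.prepare_drug_matrix(
                panel.auc, cfg.drug_max_missing, cfg.drug_knn
            )
            screens[panel_name] = drugs_mod.predict_patient_auc(
                panel.expression, complete, cohort.expression
            )
        result = drugs_mod.rank_candidate_drugs(
            screens, consensus.labels, focal_label, alpha=cfg.drug_alpha
        )
        report.drug_candidates = result.candidates

    if cfg.run_survival:
        clin = cohort.clinical.set_index("sample").loc[consensus.labels.index]
        out = surv_mod.km_logrank(
            clin["os_time"], clin["os_event"], consensus.labels.to_numpy()
        )
        report.logrank_p = out.logrank_p
        if focal_label is not None:
            cov = pd.DataFrame(
                {"focal": (consensus.labels == focal_label).astype(float)},
                index=consensus.labels.index,
            )
            cox = surv_mod.cox_fit(clin["os_time"], clin["os_event"], cov)
            report.cox_table = cox.hazard_table

    if cfg.output_dir:
        _write_artifacts(cfg, cohort, report)
    return report


def _align_events(events, coca_labels: pd.Series, truth: pd.Series):
    """Re-express detected events' COCA subtype labels as planted subtypes by
    majority vote so they can be compared with planted truth."""
    mapping = {}
    for c in coca_labels.unique():
        mapping[int(c)] = int(truth.loc[coca_labels[coca_labels == c].index].mode().iloc[0])
    out = []
    for e in events:
        e2 = dataclasses.replace(e, subtype=mapping.get(e.subtype, e.subtype))
        out.append(e2)
    return out


def _write_artifacts(cfg: PipelineConfig, cohort: MultiomicsCohort, report: PipelineReport) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"seed": cfg.seed, "n_samples": len(cohort.sample_ids)}
    for platform, lab in report.platform_labels.items():
        io_mod.write_assignment(
            lab, out / f"labels_{platform}.tsv", provenance={"stage": platform, **prov}
        )
    io_mod.write_assignment(
        report.coca_labels,
        out / "labels_coca.tsv",
        provenance={
            "stage": "coca",
            **prov,
            "repetitions": cfg.coca_repetitions,
            "item_fraction": cfg.coca_item_fraction,
        },
    )
    header = io_mod._provenance_line({"stage": "drivers", **prov})
    if report.driver_events is not None:
        (out / "driver_events.tsv").write_text(
            header + report.driver_events.to_csv(sep="\t", index=False)
        )
    if report.classifier_report is not None:
        (out / "classifier_report.tsv").write_text(
            io_mod._provenance_line({"stage": "classifier", **prov})
            + report.classifier_report.to_csv(sep="\t", index=False)
        )
    if report.cox_table is not None:
        (out / "cox_table.tsv").write_text(
            io_mod._provenance_line({"stage": "survival", **prov})
            + report.cox_table.to_csv(sep="\t", index=False)
        )
    io_mod.write_json(report.summary(), out / "report.json")
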