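"""Stage orchestration for the end-to-end synthetic demonstration run.

``run_all`` executes simulate -> normalize/filter -> differential expression
-> novel-miRNA catalog -> integrative anti-correlation -> survival
(discovery, validation, replication) -> NMF consensus clustering ->
enrichment aggregation, writing every stage's tables plus a summary report
comparing calls against the planted ground truth.  Every artifact set carries
a provenance sidecar (parameter echo + package version); reruns with the
same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import clustering, datagen, diffexp, enrichment, integrative, novelmir, survival
from .expression import (
    ExpressionMatrix,
    filter_expressed_mirna,
    filter_expressed_mrna,
    quantile_normalize,
    rpm_normalize,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "normalize", "de", "novel", "integrate", "survival", "cluster", "enrich",
)


@dataclass
class RunConfig:
    outdir: str = "results/demo"
    simulation: datagen.SimulationConfig = field(default_factory=datagen.SimulationConfig)
    min_rpm: float = 10.0
    min_fpkm: float = 1.0
    min_fraction: float = 0.10
    de_q_max: float = 0.05
    de_abs_m_min: float = 2.0
    merge_tol: int = 2
    n_permutations: int = 100
    n_bins: int = 40
    survival_min_fraction: float = 0.10
    survival_q_max: float = 0.05
    rank_k_min: int = 2
    rank_k_max: int = 8
    nmf_runs: int = 100
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-6
    enrich_n_terms: int = 20
    seed: int = 0

    def provenance(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = dataclasses.asdict(self.simulation)
        return {"version": __version__, "config": d}


class Pipeline:
    """Holds intermediate state across stages of one run."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.state: dict = {}

    def _write_provenance(self, stage: str) -> None:
        path = self.outdir / f"provenance_{stage}.json"
        with open(path, "w") as fh:
            json.dump({"stage": stage, **self.config.provenance()}, fh, indent=1, sort_keys=True)

    # ----- stages -------------------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.config.simulation
        mirna, mrna, ann, clinical, truth = datagen.simulate_cohort(cfg)
        novel = datagen.simulate_candidate_intervals(cfg, truth)
        self.outdir.mkdir(parents=True, exist_ok=True)
        datagen.write_cohort(self.outdir / "fixture", mirna, mrna, ann, clinical, truth, novel)
        self.state.update(
            mirna=mirna, mrna=mrna, annotation=ann, clinical=clinical, truth=truth, novel=novel
        )

    def stage_normalize(self) -> None:
        st = self.state
        cfg = self.config
        ann = st["annotation"]
        totals = ann.table["aligned_reads"]
        rpm = rpm_normalize(st["mirna"], totals)
        disc = ann.samples_in(cohort="discovery")
        valid = ann.samples_in(cohort="validation")
        rpm_disc = rpm.subset_samples(disc)
        expressed = filter_expressed_mirna(rpm_disc, cfg.min_rpm, cfg.min_fraction)
        mrna_kept = filter_expressed_mrna(st["mrna"], cfg.min_fpkm, cfg.min_fraction)
        qn = quantile_normalize(rpm_disc.subset_features(expressed))
        st.update(
            rpm=rpm,
            rpm_discovery=rpm_disc.subset_features(expressed),
            rpm_validation=rpm.subset_samples(valid).subset_features(expressed),
            expressed_mirna=expressed,
            expressed_mrna=mrna_kept,
            mrna_expressed=st["mrna"].subset_features(mrna_kept),
            qnorm=qn,
        )
        pd.Series(expressed, name="feature_id").to_csv(
            self.outdir / "expressed_mirna.tsv", sep="\t", index=False
        )
        pd.Series(mrna_kept, name="feature_id").to_csv(
            self.outdir / "expressed_mrna.tsv", sep="\t", index=False
        )
        self._write_provenance("normalize")

    def stage_de(self) -> None:
        st, cfg = self.state, self.config
        ann = st["annotation"]
        tumors = ann.samples_in(group="tumor", cohort="discovery")
        normals = ann.samples_in(group="normal", cohort="discovery")
        de = diffexp.differential_expression(
            st["qnorm"], tumors, normals, q_max=cfg.de_q_max, abs_m_min=cfg.de_abs_m_min
        )
        frame = diffexp.de_to_frame(de)
        frame.to_csv(self.outdir / "de_tumor_vs_normal.tsv", sep="\t", lineterminator="\n")
        st["de"] = frame
        self._write_provenance("de")

    def stage_novel(self) -> None:
        st, cfg = self.state, self.config
        novel = st["novel"]
        catalog = novelmir.merge_candidates(novel.per_sample, tol=cfg.merge_tol)
        catalog = novelmir.assign_names(catalog)
        catalog = novelmir.filter_rna_species(catalog, novel.blacklist)
        novelmir.write_catalog_bed(catalog, self.outdir / "novel_catalog.bed")
        st["novel_catalog"] = catalog
        self._write_provenance("novel")

    def stage_integrate(self) -> None:
        st, cfg = self.state, self.config
        truth = st["truth"]
        sites = integrative.sites_to_frame(truth.binding_sites)
        by_pred = {p: sites[sites["predictor"] == p] for p in ("A", "B")}
        pairs, null = integrative.integrate(
            st["rpm_discovery"],
            st["mrna_expressed"],
            by_pred,
            n_permutations=cfg.n_permutations,
            n_bins=cfg.n_bins,
            seed=cfg.seed,
        )
        hits = pairs[pairs["interaction"]]
        hits.to_csv(self.outdir / "interactions.tsv", sep="\t", index=False, lineterminator="\n")
        np.savetxt(
            self.outdir / "null_histogram.tsv",
            np.column_stack([null.bin_edges[:-1], null.bin_edges[1:], null.observed_counts, null.null_counts]),
            delimiter="\t", header="bin_lo\tbin_hi\tobserved\tnull_mean", comments="",
        )
        st["pairs"] = pairs
        st["null"] = null
        self._write_provenance("integrate")

    def stage_survival(self) -> None:
        st, cfg = self.state, self.config
        clinical = st["clinical"]
        disc_clin = survival.ClinicalTable(clinical.table[clinical.table["cohort"] == "discovery"])
        valid_clin = survival.ClinicalTable(clinical.table[clinical.table["cohort"] == "validation"])
        disc = survival.survival_screen(
            st["rpm_discovery"], disc_clin, mode="discovery",
            min_fraction=cfg.survival_min_fraction, q_max=cfg.survival_q_max,
        )
        valid = survival.survival_screen(
            st["rpm_validation"], valid_clin, mode="validation",
            min_fraction=cfg.survival_min_fraction,
        )
        replicated = survival.replicate(disc, valid)
        disc.to_csv(self.outdir / "survival_discovery.tsv", sep="\t", index=False, lineterminator="\n")
        valid.to_csv(self.outdir / "survival_validation.tsv", sep="\t", index=False, lineterminator="\n")
        pd.Series(replicated, name="feature_id").to_csv(
            self.outdir / "survival_replicated.tsv", sep="\t", index=False
        )
        st.update(survival_discovery=disc, survival_validation=valid, survival_replicated=replicated)
        self._write_provenance("survival")

    def stage_cluster(self) -> None:
        st, cfg = self.state, self.config
        ann = st["annotation"]
        tumors = ann.samples_in(group="tumor", cohort="discovery")
        qn = st["qnorm"].subset_samples(tumors)
        V = qn.values.to_numpy(dtype=float)
        results, report = clustering.rank_survey(
            V,
            k_range=range(cfg.rank_k_min, cfg.rank_k_max + 1),
            n_runs=cfg.nmf_runs,
            seed=cfg.seed,
            max_iter=cfg.nmf_max_iter,
            tol=cfg.nmf_tol,
            sample_ids=tumors,
        )
        report.to_csv(self.outdir / "rank_survey.tsv", sep="\t", index=False, lineterminator="\n")
        k2 = next(r for r in results if r.k == 2)
        k2.assignments.rename("cluster").to_csv(
            self.outdir / "clusters_k2.tsv", sep="\t", lineterminator="\n"
        )
        markers = clustering.characterize_clusters(k2.assignments, qn)
        diffexp.de_to_frame(markers).to_csv(
            self.outdir / "cluster_markers.tsv", sep="\t", lineterminator="\n"
        )
        st["cluster_k2"] = k2
        st["rank_survey"] = report
        self._write_provenance("cluster")

    def stage_enrich(self) -> None:
        st, cfg = self.state, self.config
        pairs = st["pairs"]
        hits = pairs[pairs["interaction"]]
        universe = set(st["mrna"].feature_ids)
        rng = np.random.default_rng(cfg.seed + 1)
        genes = sorted(universe)
        term_sets = {
            f"TERM{i + 1:04d}": set(rng.choice(genes, size=30, replace=False))
            for i in range(cfg.enrich_n_terms)
        }
        # one term concentrating the planted targets, so the aggregation has signal
        planted_targets = {t for _m, t, _s in st["truth"].regulatory_pairs}
        term_sets["TERM_REG"] = planted_targets | set(rng.choice(genes, size=10, replace=False))
        targets_by_mirna = {m: set(g["mrna_id"]) for m, g in hits.groupby("mirna_id")}
        # every tested miRNA gets a flag row; no interactions means no targets,
        # hence no enriched terms
        flags = {}
        for mid in pairs["mirna_id"].unique():
            targets = targets_by_mirna.get(mid, set())
            res = enrichment.term_enrich(targets & universe, term_sets, universe, mirna_id=mid)
            flags[mid] = {r.term_id: r.enriched for r in res}
        if flags:
            enr = pd.DataFrame(flags).T.fillna(False)
            reg_mirnas = {m for m, _t, _s in st["truth"].regulatory_pairs}
            category = pd.Series(
                [m in reg_mirnas for m in enr.index], index=enr.index, name="planted_regulator"
            )
            if category.any() and not category.all():
                group = enrichment.group_term_tests(enr, category, category="planted_regulator")
            else:
                group = pd.DataFrame()
        else:
            group = pd.DataFrame()
        group.to_csv(self.outdir / "enrichment_group.tsv", sep="\t", index=False, lineterminator="\n")
        st["enrichment"] = group
        self._write_provenance("enrich")

    # ----- report -------------------------------------------------------
    def report(self) -> dict:
        st = self.state
        truth = st["truth"]
        rep: dict = {}
        if "de" in st:
            called = set(st["de"].index[st["de"]["call"] != "none"])
            planted = set(truth.de_mirna)
            rep["de"] = _prf(planted, called)
        if "novel_catalog" in st:
            retained = [c for c in st["novel_catalog"] if c.retained]
            rep["novel"] = {
                "true_loci": len(truth.novel_loci),
                "merged_retained": len(retained),
                "merged_total": len(st["novel_catalog"]),
            }
        if "pairs" in st:
            called = {
                (r.mirna_id, r.mrna_id) for r in st["pairs"][st["pairs"]["interaction"]].itertuples()
            }
            planted = {(m, t) for m, t, _s in truth.regulatory_pairs}
            rep["integrative"] = _prf(planted, called)
        if "survival_replicated" in st:
            planted = {
                f for f, rec in truth.survival_mirna.items() if not rec["confounded"]
            }
            rep["survival"] = _prf(planted, set(st["survival_replicated"]))
        if "cluster_k2" in st:
            from sklearn.metrics import adjusted_rand_score

            labels = st["cluster_k2"].assignments
            true_labels = [truth.cluster_labels[s] for s in labels.index]
            rep["clustering"] = {
                "ari": float(adjusted_rand_score(true_labels, labels.to_numpy())),
                "cophenetic_k2": float(st["cluster_k2"].cophenetic),
            }
        if "enrichment" in st and len(st["enrichment"]):
            sig = st["enrichment"][st["enrichment"]["significant"]]
            rep["enrichment"] = {
                "significant_terms": sorted(sig["term_id"]),
            }
        return rep

    def run_stage(self, name: str) -> None:
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}; valid stages: {', '.join(STAGES)}")
        getattr(self, f"stage_{name}")()

    def run_all(self) -> dict:
        for name in STAGES:
            logger.info("stage %s", name)
            self.run_stage(name)
        rep = self.report()
        with open(self.outdir / "report.json", "w") as fh:
            json.dump(rep, fh, indent=1, sort_keys=True)
        return rep


def _prf(planted: set, called: set) -> dict:
    tp = len(planted & called)
    recall = tp / len(planted) if planted else None
    precision = tp / len(called) if called else None
    return {
        "planted": len(planted),
        "called": len(called),
        "true_positive": tp,
        "recall": recall,
        "precision": precision,
    }


def run_all(config: RunConfig) -> dict:
    """Execute the full synthetic demonstration and return the truth-vs-called
    summary report."""
    return Pipeline(config).run_all()


def run_stage(name: str, config: RunConfig, pipeline: Pipeline | None = None) -> Pipeline:
    """Run a single named stage (earlier stages it depends on must have run on
    the same ``Pipeline``)."""
    pl = pipeline or Pipeline(config)
    pl.run_stage(name)
    return pl
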