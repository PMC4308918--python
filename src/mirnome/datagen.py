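"""Synthetic miRNome cohorts with planted ground truth.

Emulates the statistical structure the downstream analyses assume: a
discovery cohort of 92 tumors and 15 normal (centroblast) libraries plus an
independent 112-sample validation cohort, with

* negative-binomial miRNA counts over per-sample library sizes, with a set of
  planted differentially abundant miRNAs (group mean ratio 2^de_log2fc);
* an mRNA isoform FPKM matrix where planted regulatory pairs follow
  mRNA = baseline + slope * standardized miRNA RPM + Gaussian noise, with
  matching binding sites recorded for two pseudo-predictors (plus seed-match
  sequences);
* survival-associated miRNAs with a step hazard at a planted expression
  cutpoint under an exponential outcome model with independent censoring,
  optionally confounded with cell of origin;
* a two-cluster tumor expression structure carried by marker miRNAs;
* per-library candidate novel-miRNA intervals with +/-2 bp coordinate jitter
  and decoys overlapping an RNA-species blacklist track.

All distributions are stand-ins chosen for testability; the generator makes
no fidelity claim about real miRNA-seq data.  Identical configs (same seed)
produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, SampleAnnotation
from .integrative import BindingSite, sites_to_frame
from .novelmir import CandidateInterval
from .survival import ClinicalTable

NT = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    n_tumor: int = 92
    n_normal: int = 15
    n_validation: int = 112
    n_mirna: int = 300
    n_mrna: int = 600
    n_de_mirna: int = 30
    de_log2fc: float = 3.0
    n_regulatory_pairs: int = 30
    targets_per_regulator: int = 3  # planted pairs shared per regulator miRNA
    regulatory_strength: float = -1.0  # slope of mRNA on standardized miRNA RPM
    regulatory_noise_sd: float = 0.4
    n_survival_mirna: int = 4
    survival_log_hazard: float = 1.2
    confounded_fraction: float = 0.0  # fraction of survival miRNAs explained by COO
    censoring_rate: float = 0.3
    n_clusters: int = 2
    n_cluster_markers: int = 40
    cluster_log2fc: float = 3.0
    dispersion: float = 10.0  # negative-binomial size r: var = mu + mu^2 / r
    library_size_range: tuple[int, int] = (1_000_000, 5_000_000)
    validation_distortion_sd: float = 0.0  # per-feature lognormal scale (FFPET-like)
    coo_log_hazard: float = 0.5  # ABC vs GCB
    ipi_log_hazard: float = 0.15  # per IPI point
    decoy_site_rate: float = 0.01  # dual-predictor decoy binding-site rate
    n_novel_loci: int = 10
    novel_jitter: int = 2
    novel_support_fraction: float = 1.0
    novel_decoy_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_tumor": self.n_tumor, "n_normal": self.n_normal,
            "n_validation": self.n_validation, "n_mirna": self.n_mirna,
            "n_mrna": self.n_mrna, "n_clusters": self.n_clusters,
        }
        counts["targets_per_regulator"] = self.targets_per_regulator
        for name, v in counts.items():
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        nonneg = {
            "n_de_mirna": self.n_de_mirna, "n_regulatory_pairs": self.n_regulatory_pairs,
            "n_survival_mirna": self.n_survival_mirna, "n_cluster_markers": self.n_cluster_markers,
            "n_novel_loci": self.n_novel_loci, "novel_jitter": self.novel_jitter,
        }
        for name, v in nonneg.items():
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        for name, v in (
            ("censoring_rate", self.censoring_rate),
            ("confounded_fraction", self.confounded_fraction),
            ("novel_support_fraction", self.novel_support_fraction),
            ("novel_decoy_fraction", self.novel_decoy_fraction),
            ("decoy_site_rate", self.decoy_site_rate),
        ):
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v!r}")
        for name, v in (
            ("de_log2fc", self.de_log2fc), ("regulatory_strength", self.regulatory_strength),
            ("survival_log_hazard", self.survival_log_hazard),
            ("regulatory_noise_sd", self.regulatory_noise_sd),
            ("cluster_log2fc", self.cluster_log2fc),
            ("validation_distortion_sd", self.validation_distortion_sd),
        ):
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.dispersion <= 0 or not np.isfinite(self.dispersion):
            raise ValueError(f"dispersion must be > 0, got {self.dispersion!r}")
        if self.n_de_mirna > self.n_mirna:
            raise ValueError("n_de_mirna exceeds n_mirna")
        if self.n_regulatory_pairs > self.n_mirna * self.n_mrna:
            raise ValueError("n_regulatory_pairs exceeds n_mirna * n_mrna")
        if self.n_regulatory_pairs > self.n_mrna:
            raise ValueError("n_regulatory_pairs exceeds n_mrna (one target isoform per pair)")
        planted = self.n_de_mirna + self.n_survival_mirna + self.n_cluster_markers
        if planted + min(self.n_regulatory_pairs, self.n_mirna - planted or 1) > self.n_mirna:
            if planted >= self.n_mirna:
                raise ValueError("planted feature sets exceed n_mirna")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError(f"library_size_range must be increasing and positive, got {self.library_size_range!r}")


@dataclass
class GroundTruth:
    """Planted-effect record for every downstream stage."""

    de_mirna: dict = field(default_factory=dict)  # id -> signed log2 fold change
    regulatory_pairs: list = field(default_factory=list)  # (mirna_id, mrna_id, slope)
    survival_mirna: dict = field(default_factory=dict)  # id -> {log_hazard, cutpoint, confounded}
    cluster_labels: dict = field(default_factory=dict)  # sample_id -> int
    binding_sites: list = field(default_factory=list)  # BindingSite, predictors A and B
    mirna_seqs: dict = field(default_factory=dict)
    transcript_seqs: dict = field(default_factory=dict)  # id -> (seq, [(region, s, e)])
    novel_loci: list = field(default_factory=list)  # (chrom, start, end, strand, arm)

    def to_json(self, path) -> None:
        payload = {
            "de_mirna": self.de_mirna,
            "regulatory_pairs": [list(p) for p in self.regulatory_pairs],
            "survival_mirna": self.survival_mirna,
            "cluster_labels": self.cluster_labels,
            "binding_sites": [
                [s.mirna_id, s.transcript_id, s.region, s.start, s.end, s.predictor]
                for s in self.binding_sites
            ],
            "mirna_seqs": self.mirna_seqs,
            "transcript_seqs": {
                k: [seq, [list(r) for r in regions]] for k, (seq, regions) in self.transcript_seqs.items()
            },
            "novel_loci": [list(l) for l in self.novel_loci],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            de_mirna=d["de_mirna"],
            regulatory_pairs=[tuple(p) for p in d["regulatory_pairs"]],
            survival_mirna=d["survival_mirna"],
            cluster_labels=d["cluster_labels"],
            binding_sites=[BindingSite(*row) for row in d["binding_sites"]],
            mirna_seqs=d["mirna_seqs"],
            transcript_seqs={
                k: (seq, [tuple(r) for r in regions]) for k, (seq, regions) in d["transcript_seqs"].items()
            },
            novel_loci=[tuple(l) for l in d["novel_loci"]],
        )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(NT[rng.integers(0, 4, size=length)])


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def simulate_cohort(config: SimulationConfig):
    """Generate (miRNA counts, mRNA FPKM, annotation, clinical, truth).

    The miRNA matrix covers discovery tumors, normals and the validation
    cohort; the mRNA matrix covers the discovery samples only (matching the
    data actually available for the integrative analysis).  Per-sample
    aligned read totals are recorded in the annotation column
    ``aligned_reads``.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    (s_base, s_counts, s_mrna, s_clin, s_seq, s_valid, s_sites) = [
        np.random.default_rng(ss) for ss in root.spawn(7)
    ]

    mirna_ids = [f"mir-{i + 1:04d}" for i in range(config.n_mirna)]
    mrna_ids = [f"tx-{i + 1:04d}" for i in range(config.n_mrna)]
    tumors = [f"T{i + 1:03d}" for i in range(config.n_tumor)]
    normals = [f"N{i + 1:03d}" for i in range(config.n_normal)]
    valids = [f"V{i + 1:03d}" for i in range(config.n_validation)]

    # --- planted feature sets (disjoint miRNA pools) --------------------
    order = s_base.permutation(config.n_mirna)
    cursor = 0

    def take(n):
        nonlocal cursor
        ids = [mirna_ids[i] for i in order[cursor : cursor + n]]
        cursor += n
        return ids

    de_ids = take(config.n_de_mirna)
    surv_ids = take(config.n_survival_mirna)
    marker_ids = take(config.n_cluster_markers)
    n_regulators = -(-config.n_regulatory_pairs // max(config.targets_per_regulator, 1))
    reg_pool = take(min(n_regulators, config.n_mirna - cursor))
    if config.n_regulatory_pairs and not reg_pool:
        raise ValueError("no miRNAs left for regulatory pairs; reduce planted sets")

    # --- baseline concentrations (RPM scale) ----------------------------
    conc = s_base.lognormal(mean=np.log(50.0), sigma=1.5, size=config.n_mirna)
    conc_df = pd.Series(conc, index=mirna_ids)

    de_sign = {fid: (1 if i % 2 == 0 else -1) for i, fid in enumerate(de_ids)}
    truth = GroundTruth(de_mirna={fid: de_sign[fid] * config.de_log2fc for fid in de_ids})

    # cluster labels for tumor + validation samples
    cluster_of = {}
    for s in tumors + valids:
        cluster_of[s] = int(s_base.integers(1, config.n_clusters + 1))
    truth.cluster_labels = dict(cluster_of)
    marker_cluster = {fid: (i % config.n_clusters) + 1 for i, fid in enumerate(marker_ids)}

    # survival miRNAs: bimodal across patients; planted cutpoint between modes
    n_conf = int(round(config.confounded_fraction * config.n_survival_mirna))
    conf_ids = set(surv_ids[:n_conf])
    surv_high = {}  # per survival feature: latent per-sample high indicator
    coo_choices = np.array(["ABC", "GCB", "unclassified"])
    coo_probs = np.array([30, 41, 21]) / 92.0
    coo_of = {s: str(s_clin.choice(coo_choices, p=coo_probs)) for s in tumors + valids}
    for fid in surv_ids:
        if fid in conf_ids:
            surv_high[fid] = {s: float(coo_of[s] == "ABC") for s in tumors + valids}
        else:
            surv_high[fid] = {s: float(s_clin.random() < 0.5) for s in tumors + valids}

    def concentration(sample: str, group: str, distort: np.ndarray | None) -> np.ndarray:
        c = conc_df.copy()
        if group == "tumor":
            for fid in de_ids:
                c[fid] *= 2.0 ** (de_sign[fid] * config.de_log2fc)
            cl = cluster_of[sample]
            for fid in marker_ids:
                if marker_cluster[fid] == cl:
                    c[fid] *= 2.0 ** config.cluster_log2fc
            for fid in surv_ids:
                if surv_high[fid][sample]:
                    c[fid] *= 16.0  # wide separation keeps the cutpoint identifiable
        if distort is not None:
            c *= distort
        return c.to_numpy()

    # --- counts ---------------------------------------------------------
    lo, hi = config.library_size_range
    all_samples = tumors + normals + valids
    lib_sizes = pd.Series(
        s_counts.integers(lo, hi + 1, size=len(all_samples)), index=all_samples
    )
    distort = None
    if config.validation_distortion_sd > 0:
        distort = s_valid.lognormal(0.0, config.validation_distortion_sd, size=config.n_mirna)
    r = config.dispersion
    counts = np.empty((config.n_mirna, len(all_samples)), dtype=np.int64)
    for j, s in enumerate(all_samples):
        group = "normal" if s.startswith("N") else "tumor"
        dis = distort if s.startswith("V") else None
        mu = concentration(s, group, dis) * lib_sizes[s] / 1e6
        rng_c = s_counts if not s.startswith("V") else s_valid
        counts[:, j] = rng_c.negative_binomial(r, r / (r + mu))
    mirna = ExpressionMatrix(
        values=pd.DataFrame(counts, index=mirna_ids, columns=all_samples), unit="counts"
    )
    rpm = mirna.values / lib_sizes * 1e6

    # planted survival cutpoints on the RPM scale (between the two modes)
    for fid in surv_ids:
        truth.survival_mirna[fid] = {
            "log_hazard": 0.0 if fid in conf_ids else config.survival_log_hazard,
            "cutpoint": float(conc_df[fid] * 4.0),  # geometric midpoint of the modes
            "confounded": fid in conf_ids,
        }

    # --- mRNA FPKM over discovery samples -------------------------------
    disc = tumors + normals
    base_t = s_mrna.lognormal(np.log(10.0), 1.0, size=config.n_mrna)
    fpkm = base_t[:, None] * s_mrna.lognormal(0.0, 0.5, size=(config.n_mrna, len(disc)))
    target_idx = s_mrna.permutation(config.n_mrna)[: config.n_regulatory_pairs]
    for p_i, t_i in enumerate(target_idx):
        mi = reg_pool[(p_i // max(config.targets_per_regulator, 1)) % len(reg_pool)]
        tx = mrna_ids[t_i]
        x = rpm.loc[mi, disc].to_numpy(dtype=float)
        z = (x - x.mean()) / (x.std() or 1.0)
        vals = 8.0 + config.regulatory_strength * z + s_mrna.normal(0.0, config.regulatory_noise_sd, size=len(disc))
        fpkm[t_i, :] = np.maximum(vals, 0.0)
        truth.regulatory_pairs.append((mi, tx, config.regulatory_strength))
    mrna = ExpressionMatrix(
        values=pd.DataFrame(fpkm, index=mrna_ids, columns=disc), unit="FPKM"
    )

    # --- sequences and binding sites ------------------------------------
    truth.mirna_seqs = {fid: _random_seq(s_seq, 22).replace("T", "U") for fid in mirna_ids}
    regions = [("5UTR", 0, 200), ("CDS", 200, 800), ("3UTR", 800, 1100)]
    truth.transcript_seqs = {tid: (_random_seq(s_seq, 1100), list(regions)) for tid in mrna_ids}
    for mi, tx, _slope in truth.regulatory_pairs:
        seed7 = truth.mirna_seqs[mi].replace("U", "T")[1:8]
        probe = seed7.translate(_COMPLEMENT)[::-1]
        region = regions[int(s_seq.integers(0, 3))]
        pos = int(s_seq.integers(region[1], region[2] - 7))
        seq, regs = truth.transcript_seqs[tx]
        truth.transcript_seqs[tx] = (seq[:pos] + probe + seq[pos + 7 :], regs)
        for pred in ("A", "B"):
            truth.binding_sites.append(BindingSite(mi, tx, region[0], pos, pos + 7, pred))
    # decoy sites: dual-predictor at decoy_site_rate, single-predictor at twice that
    planted = {(m, t) for m, t, _ in truth.regulatory_pairs}
    n_decoy = int(config.decoy_site_rate * config.n_mirna * config.n_mrna)
    for kind in ("both", "single"):
        for _ in range(n_decoy):
            mi = mirna_ids[int(s_sites.integers(0, config.n_mirna))]
            tx = mrna_ids[int(s_sites.integers(0, config.n_mrna))]
            if (mi, tx) in planted:
                continue
            region = regions[int(s_sites.integers(0, 3))]
            pos = int(s_sites.integers(region[1], region[2] - 7))
            preds = ("A", "B") if kind == "both" else (("A",) if s_sites.random() < 0.5 else ("B",))
            for pred in preds:
                truth.binding_sites.append(BindingSite(mi, tx, region[0], pos, pos + 7, pred))

    # --- annotation ------------------------------------------------------
    ann = pd.DataFrame(
        {
            "group": ["tumor"] * len(tumors) + ["normal"] * len(normals) + ["tumor"] * len(valids),
            "subtype": [coo_of.get(s, "none") for s in tumors]
            + ["none"] * len(normals)
            + [coo_of.get(s, "none") for s in valids],
            "cohort": ["discovery"] * len(disc) + ["validation"] * len(valids),
            "cancer_type": ["DLBCL"] * len(tumors) + ["centroblast"] * len(normals) + ["DLBCL"] * len(valids),
            "aligned_reads": lib_sizes.loc[all_samples].to_numpy(),
        },
        index=all_samples,
    )
    annotation = SampleAnnotation(table=ann)

    # --- clinical outcomes ----------------------------------------------
    clinical = _simulate_clinical(
        config, s_clin, tumors + valids, coo_of, surv_ids, conf_ids, rpm, truth
    )
    return mirna, mrna, annotation, clinical, truth


def _simulate_clinical(config, rng, patients, coo_of, surv_ids, conf_ids, rpm, truth):
    rate0 = {"os": np.log(2) / 1500.0, "pfs": np.log(2) / 1000.0}
    ipi = {s: int(rng.integers(0, 6)) for s in patients}
    lp_of = {}
    for s in patients:
        lp = config.coo_log_hazard * (coo_of[s] == "ABC") + config.ipi_log_hazard * ipi[s]
        for fid in surv_ids:
            if fid in conf_ids:
                continue
            if rpm.loc[fid, s] > truth.survival_mirna[fid]["cutpoint"]:
                lp += config.survival_log_hazard
        lp_of[s] = lp
    # censoring hazard anchored to the cohort-mean event hazard, shared by all
    # patients (non-informative), so the realized censored fraction tracks
    # censoring_rate
    c = config.censoring_rate
    mean_mult = float(np.mean([np.exp(lp) for lp in lp_of.values()]))
    rows = {}
    for s in patients:
        row = {}
        for ep in ("os", "pfs"):
            lam = rate0[ep] * np.exp(lp_of[s])
            t_event = rng.exponential(1.0 / lam)
            if c > 0:
                lam_c = rate0[ep] * mean_mult * c / (1.0 - c) if c < 1 else np.inf
                t_cens = rng.exponential(1.0 / lam_c) if np.isfinite(lam_c) else 0.0
            else:
                t_cens = np.inf
            row[f"{ep}_time"] = float(min(t_event, t_cens))
            row[f"{ep}_event"] = int(t_event <= t_cens)
        row["ipi"] = ipi[s]
        row["coo"] = coo_of[s]
        row["cohort"] = "discovery" if s.startswith("T") else "validation"
        rows[s] = row
    return ClinicalTable(table=pd.DataFrame.from_dict(rows, orient="index"))


@dataclass
class NovelSimulation:
    per_sample: dict  # sample -> list[CandidateInterval]
    blacklist: dict  # label -> [(chrom, start, end, strand)]
    true_loci: list  # (chrom, start, end, strand, arm)


def simulate_candidate_intervals(
    config: SimulationConfig,
    truth: GroundTruth | None = None,
    n_samples: int | None = None,
    jitter: int | None = None,
) -> NovelSimulation:
    """Per-library candidate novel-miRNA intervals with coordinate jitter.

    Each true locus appears in a random subset of libraries (probability
    ``novel_support_fraction``) with independent uniform start/end jitter on
    {-jitter..+jitter}; decoy intervals are placed inside the emitted
    RNA-species blacklist track at rate ``novel_decoy_fraction`` per library.
    """
    config.validate()
    if n_samples is None:
        n_samples = config.n_tumor
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    jit = config.novel_jitter if jitter is None else jitter
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[-1])
    samples = [f"T{i + 1:03d}" for i in range(n_samples)]

    chroms = [f"chr{i}" for i in range(1, 23)]
    loci = []
    used: set[tuple[str, int]] = set()
    while len(loci) < config.n_novel_loci:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(10_000, 5_000_000)) * 10  # loci >= 10 bp apart
        strand = "+" if rng.random() < 0.5 else "-"
        arm = "mature" if rng.random() < 0.7 else "star"
        if (chrom, start) in used:
            continue
        used.add((chrom, start))
        loci.append((chrom, start, start + 22, strand, arm))
    blacklist = {"snoRNA": [], "tRNA": []}
    for label in blacklist:
        for _ in range(max(5, config.n_novel_loci)):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(6_000_000, 9_000_000)) * 10
            blacklist[label].append((chrom, start, start + 80, "+"))
    per_sample: dict[str, list[CandidateInterval]] = {s: [] for s in samples}
    for chrom, start, end, strand, arm in loci:
        for s in samples:
            if rng.random() >= config.novel_support_fraction:
                continue
            ds = int(rng.integers(-jit, jit + 1)) if jit else 0
            de_ = int(rng.integers(-jit, jit + 1)) if jit else 0
            per_sample[s].append(CandidateInterval(chrom, start + ds, end + de_, strand, arm, s))
    all_black = [iv for ivs in blacklist.values() for iv in ivs]
    for s in samples:
        n_decoy = int(round(config.novel_decoy_fraction * config.n_novel_loci))
        for _ in range(n_decoy):
            chrom, bstart, bend, strand = all_black[int(rng.integers(0, len(all_black)))]
            pos = int(rng.integers(bstart, bend - 22))
            per_sample[s].append(CandidateInterval(chrom, pos, pos + 22, strand, "mature", s))
    if truth is not None:
        truth.novel_loci = list(loci)
    return NovelSimulation(per_sample=per_sample, blacklist=blacklist, true_loci=loci)


def write_cohort(
    outdir,
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    annotation: SampleAnnotation,
    clinical: ClinicalTable,
    truth: GroundTruth,
    novel: NovelSimulation | None = None,
) -> None:
    """Write the full fixture set as plain-text artifacts (TSV/BED6/FASTA/JSON)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mirna.to_tsv(outdir / "mirna_counts.tsv")
    mrna.to_tsv(outdir / "mrna_fpkm.tsv")
    annotation.to_tsv(outdir / "samples.tsv")
    clinical.to_tsv(outdir / "clinical.tsv")
    truth.to_json(outdir / "truth.json")
    sites_to_frame(truth.binding_sites).to_csv(outdir / "binding_sites.tsv", sep="\t", index=False)
    with open(outdir / "mirna.fa", "w") as fh:
        for fid, seq in truth.mirna_seqs.items():
            fh.write(f">{fid}\n{seq}\n")
    with open(outdir / "transcripts.fa", "w") as fh:
        for tid, (seq, regions) in truth.transcript_seqs.items():
            reg = ",".join(f"{r}:{s}-{e}" for r, s, e in regions)
            fh.write(f">{tid} regions={reg}\n{seq}\n")
    if novel is not None:
        cand_dir = outdir / "candidates"
        cand_dir.mkdir(exist_ok=True)
        for sample, ivs in novel.per_sample.items():
            with open(cand_dir / f"{sample}.bed", "w") as fh:
                for iv in ivs:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.arm}\t0\t{iv.strand}\n")
        with open(outdir / "blacklist.bed", "w") as fh:
            for label, ivs in novel.blacklist.items():
                for chrom, start, end, strand in ivs:
                    fh.write(f"{chrom}\t{start}\t{end}\t{label}\t0\t{strand}\n")


def read_fasta_with_regions(path) -> dict[str, tuple[str, list[tuple[str, int, int]]]]:
    """Read transcript FASTA whose headers carry ``regions=5UTR:0-200,...``."""
    out: dict[str, tuple[str, list[tuple[str, int, int]]]] = {}
    name, desc, chunks = None, "", []
    def flush():
        if name is None:
            return
        regions = []
        for token in desc.split():
            if token.startswith("regions="):
                for part in token[len("regions="):].split(","):
                    rname, span = part.split(":")
                    s, e = span.split("-")
                    regions.append((rname, int(s), int(e)))
        out[name] = ("".join(chunks), regions)
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                header = line[1:].split(None, 1)
                name = header[0]
                desc = header[1] if len(header) > 1 else ""
                chunks = []
            else:
                chunks.append(line)
        flush()
    return out


def read_fasta(path) -> dict[str, str]:
    return {k: v for k, (v, _r) in read_fasta_with_regions(path).items()}


def config_to_json(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True)
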