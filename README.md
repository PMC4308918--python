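# mirnome

An analysis pipeline for miRNA-seq profiling of diffuse large B-cell lymphoma
(DLBCL) cohorts, rebuilt as a tested, reusable Python package and exercised
end-to-end on synthetic cohorts with planted ground truth.

Tumor miRNA profiles carry three kinds of signal this pipeline extracts:
miRNAs differentially abundant between DLBCL tumors and normal centroblasts,
miRNAs that repress specific mRNA isoforms (visible as expression
anti-correlation backed by predicted binding sites), and miRNAs whose
expression stratifies patient survival independently of the established
prognostic factors — cell of origin (COO: ABC/GCB/unclassified) and the
International Prognostic Index (IPI). Because the original patient data are
controlled-access, the package ships a cohort simulator that emulates the
study design (92 tumor + 15 centroblast discovery libraries, a 112-sample
validation cohort) and plants every effect type with a recorded ground truth,
so each stage's recall and precision are measurable.

## Methods at the core

- **Presence filtering and normalization.** miRNAs kept at > 10 RPM in > 10%
  of samples, mRNA isoforms at ≥ 1 FPKM in ≥ 10%; quantile normalization
  (mean-quantile reference, mean-rank ties) before differential testing.
- **Differential abundance.** Per-feature two-sided Wilcoxon rank-sum,
  Benjamini–Hochberg (BH) step-up q-values, calls at q < 0.05 and
  |M| > 2 where M = log₂(mean_A/mean_B); a one-vs-each pan-cancer variant
  requires the call in every comparison at |M| > 3.
- **Novel-miRNA catalog.** Per-library candidate loci are merged when chrom,
  strand and arm match and both start and end differ by ≤ 2 bp (transitive
  closure), filtered against snoRNA/tRNA annotation tracks, and named
  `NOVEL[M/S]XXXXX`.
- **Integrative miRNA:mRNA screen.** Spearman ρ for every pair, BH within
  each miRNA's family, anti-correlation filter (ρ < 0, q < 0.05), then an
  empirical-noise filter: the ρ distribution is binned (40 bins over
  [−1, 1]) and compared with a null built from 100 permutations of the miRNA
  sample labels; within each bin only the `round(observed − mean null)`
  smallest-q pairs survive. An interaction additionally needs a binding site
  from *both* target predictors (a 7-mer seed-match predictor is built in;
  external predictions can be supplied as tables).
- **Survival screening.** Per miRNA and endpoint (OS, PFS), patients are
  dichotomized at the expression cutpoint maximizing the log-rank χ²
  (exhaustive search, both groups ≥ 10% of patients). Discovery-cohort
  p-values are BH-corrected (q < 0.05); validation uses raw p < 0.05.
  Candidates are then fit with Cox proportional hazards alongside COO and
  IPI (Efron ties); a miRNA is *independent* when its group term has
  p < 0.05 for both endpoints, and *replicated* when that holds in both
  cohorts with concordant effect direction.
- **NMF consensus clustering.** Brunet multiplicative updates minimizing the
  KL divergence D(V‖WH), 100-run consensus matrices for k = 2..8, cophenetic
  correlation profile, and Wilcoxon/BH characterization of the k = 2
  clusters.
- **Enrichment aggregation.** Hypergeometric per-miRNA term enrichment of
  interaction-derived target sets (a pluggable stand-in accepting external
  per-miRNA flags), then a two-sided Fisher exact test per term comparing
  in-category vs out-of-category miRNAs, BH across terms (q < 0.05).

## Worked example

```
mirnome all --outdir results/demo --seed 0
```

runs simulate → filter/normalize → DE → novel catalog → integrative screen →
survival (discovery, validation, replication) → clustering → enrichment and
prints the truth-vs-called report. With the default configuration and seed 0
it prints (abridged):

```
"de":          {"planted": 30, "called": 33, "true_positive": 22, "recall": 0.73, ...}
"integrative": {"planted": 30, "called": 24, "true_positive": 24, "recall": 0.80, "precision": 1.0}
"novel":       {"true_loci": 10, "merged_retained": 10, "merged_total": 135}
"clustering":  {"ari": 1.0, "cophenetic_k2": 1.0}
```

meaning: 22 of 30 planted differentially abundant miRNAs are recalled (the
extra calls are cluster-marker and survival miRNAs, which genuinely shift
tumor means); 24 of 30 planted repression pairs are recovered with no false
pairs among ~1.6 × 10⁵ candidates; all 10 planted novel loci survive merging
and blacklist filtering; and the k = 2 consensus solution reproduces the
planted tumor clusters exactly (adjusted Rand index 1.0).

The same stages are available as numbered narrative scripts under
`analysis/` (`01_simulate_cohort.py` … `08_enrichment.py`), each writing its
tables under `results/analysis/`.

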