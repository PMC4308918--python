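# Methods

This note documents the statistical procedures the package implements, the
assumptions behind the synthetic-cohort generator, the numerical choices
made where a published description was ambiguous, and the problem sizes the
test suite and acceptance script use.

## Expression units and filtering

miRNA abundance is measured in reads per million aligned small-RNA reads
(RPM; totals are all aligned small-RNA reads, not miRNA-assigned reads only,
configurable). mRNA isoform abundance is FPKM. Presence thresholds:

- miRNA: value **> 10 RPM in strictly more than 10%** of samples. The
  inequalities are strict by design; an inclusive variant is available via
  parameters.
- mRNA isoform: value **≥ 1 FPKM in at least 10%** of samples (inclusive).

Quantile normalization maps every sample onto the mean-quantile reference
(row means of the column-sorted matrix). Ties within a column receive the
mean of the reference values at their tied ranks — the conventional
mean-rank dialect. Consequence: exact cross-column value-multiset equality
holds on tie-free input; integer-derived RPM matrices have ties and agree
only up to tie averaging.

## Differential abundance

Two-sided Wilcoxon rank-sum per feature: exact null distribution for
tie-free pooled samples of total size ≤ 20, otherwise the normal
approximation with tie-corrected variance and continuity correction.
BH step-up is implemented directly (q(i) = min over j ≥ i of p(j)·n/j,
clipped at 1) and cross-checked against statsmodels and a brute-force
oracle. Fold changes are computed on group means of un-logged normalized
values with a pseudocount (default 1.0 on the RPM scale; the zero-safe
convention). Calls use strict thresholds: q < 0.05 and |M| > 2
(tumor-vs-normal) or |M| > 3 in every comparison of the one-vs-each
pan-cancer screen. Subtype comparisons (ABC vs GCB) use q < 0.05 with no
fold-change floor.

## Novel-miRNA catalog processing

Coordinates are 0-based half-open throughout (BED convention). Two candidate
loci are duplicates when chromosome, strand and arm match and |Δstart| ≤ 2
and |Δend| ≤ 2 **separately** (a coordinate comparison, not an overlap
criterion); merging is the transitive closure of this relation, computed by
union-find and verified against a brute-force oracle. The representative
interval is the modal coordinate pair, ties broken by smallest start then
end. Blacklist filtering drops any candidate overlapping (≥ 1 bp,
strand-agnostic by default) an annotation track of another RNA species,
except allowlisted names, which stay retained with the label recorded.
Names follow `NOVEL[M/S]XXXXX` with a trailing arm letter by default (the
dialect observed in published identifiers), switchable to the bare form.

## Integrative miRNA:mRNA screen

Spearman ρ is the Pearson correlation of mid-ranks, computed for all pairs
by matrix multiplication of standardized rank matrices; p-values use the
t approximation with n − 2 df. Constant vectors give ρ = NaN and are
excluded downstream. BH is applied within each miRNA's pair family.

The permutation null randomizes the **miRNA** matrix's sample labels (the
mRNA matrix stays fixed; the opposite target is available and statistically
indistinguishable), recomputing all pair correlations per permutation —
100 permutations by default. Histograms use 40 equal-width right-closed bins
over [−1, 1], ρ = −1 assigned to bin 0. The per-bin survivor count is
`max(0, round(observed − mean null count))`, rounding half-up; within a bin
pairs are ranked by q, ties by p then pair id, making the filter invariant
to input order. The per-bin rule is the most literal count-excess reading of
a threshold "set by counts from the null distribution"; it is pluggable so
alternatives (e.g. a null-quantile count) can be swapped. The null filter is
computed on all pairs and combined with the anti-correlation filter by
conjunction; the published ordering of the two filters is not stated, and
the conjunction is order-independent.

Binding sites: the built-in stand-in predictor reports an exact 7-mer match
of the reverse complement of the miRNA seed (nucleotides 2–8) inside a
single annotated transcript region (5'UTR, CDS or 3'UTR; sites spanning a
region boundary are not reported). Real predictor outputs can be supplied
as TSV tables; an interaction requires a site from **every** required
predictor (two by default).

## Survival screening

The cutpoint search re-creates X-tile-style cohort separation as a
transparent exhaustive maximal log-rank search: every midpoint between
consecutive distinct expression values is admissible when both groups keep
≥ 10% of patients; ties break toward the more balanced split, then the
smaller cutpoint. Expression is on the RPM scale by default. The log-rank
statistic uses the standard O − E form with hypergeometric variance.

Selection inflation is real and documented: the maximal log-rank p is the
minimum over many correlated tests and is anti-conservative; the pipeline
applies BH to it exactly as the published procedure does (a ranking device,
not a calibrated error rate). A related consequence is **argmax jitter**:
flipping one patient across a candidate cutpoint perturbs χ² by O(1),
comparable to the noise among neighboring splits, so the recovered cutpoint
scatters within a few patients of a planted hazard step even when the step
itself is strong.

Cox models use lifelines with Efron tie handling; COO enters as two
indicators (ABC, unclassified; GCB reference) and IPI as a single ordinal
covariate (a dichotomized IPI column is accepted too — the published
encoding is unstated). Constant covariates are dropped. Independence for a
miRNA means its group term has Wald p < 0.05 for **both** OS and PFS; the
single-endpoint gate is measurably leakier because the maximally selected
grouping carries selection bias into the Cox fit. Replication re-derives
cutpoints in the validation cohort (transfer from discovery is available via
flag) and requires both-endpoint independence in both cohorts with
concordant coefficient signs.

## NMF consensus clustering

Brunet multiplicative updates minimize the generalized KL divergence
D(V‖WH); the objective is non-increasing by construction and asserted in
tests. Initialization is uniform random scaled by √(mean(V)/k); per-run
iteration cap 2,000 with relative-change tolerance 10⁻⁶ checked every 10
iterations. "Iterations" for the consensus machinery means **runs**: 100
randomly initialized runs per rank, samples assigned to the argmax metagene,
consensus[i,j] = co-assignment frequency, final labels from average-linkage
clustering of 1 − consensus cut at k. The cophenetic score is the Pearson
correlation between the off-diagonal consensus distances and the cophenetic
distances of their dendrogram; a constant distance matrix returns NaN. The
rank survey covers k = 2..8 and only reports the cophenetic profile —
selecting the preferred k is a judgment call left to the analyst. Input is
presence-filtered, quantile-normalized expression (non-negative by
construction here; a per-feature min-shift is applied if an input is not).

## Enrichment aggregation

Per-miRNA term enrichment is a one-sided hypergeometric upper tail on the
interaction-derived target set against the expressed-transcript universe —
a deliberately simple stand-in behind the same interface as model-based
enrichment tools, whose externally computed per-miRNA flags can be supplied
instead (their effect-size thresholds have no hypergeometric analogue, so
numerical agreement with such tools is not expected). The group-level test
is the package's own computation: a two-sided Fisher exact test per term on
(miRNA in category) × (miRNA enriches term), BH across terms, significant at
q < 0.05. Every tested miRNA contributes a flag row; miRNAs without called
interactions have empty target sets and enrich nothing.

## Synthetic-cohort generator

The generator emulates the cohort design (92 tumor / 15 normal discovery,
112-sample validation) and the statistical structure the analyses assume;
all distributions are stand-ins chosen for testability, not fidelity claims
about real miRNA-seq data.

- **Counts.** Negative binomial with shared size parameter r (default 10;
  var = μ + μ²/r) over per-sample library sizes uniform on [10⁶, 5×10⁶];
  baseline concentrations log-normal (median 50 RPM, σ = 1.5 on the log
  scale). RPM is computed downstream from recorded aligned totals.
- **Differential abundance.** Planted DE miRNAs scale tumor concentration by
  2^±3 (half up, half down).
- **Regulatory pairs.** Each planted regulator miRNA represses 3 target
  isoforms (multiple targets make per-miRNA enrichment meaningful):
  target FPKM = 8 + slope · z(miRNA RPM) + N(0, 0.4), slope −1, clipped at
  0; matching binding sites are recorded for both pseudo-predictors and the
  seed match is planted in the transcript sequence. Decoy sites are sprinkled
  at rate 0.01 (dual-predictor) and 0.02 (single-predictor).
- **Survival.** Exponential outcomes (baseline median 1500 days OS,
  1000 days PFS) with a step hazard exp(1.2 · I[RPM > cutpoint]). Survival
  miRNA expression is bimodal with 16-fold mode separation and the planted
  cutpoint at the geometric midpoint; a narrower separation leaves the
  log-rank surface flat near the step and the cutpoint unidentifiable. COO
  (ABC) and IPI add log-hazards 0.5 and 0.15/point. Censoring is exponential
  and independent of covariates, with its rate anchored to the cohort-mean
  event hazard so the realized censored fraction tracks `censoring_rate`
  (default 0.3). A configurable fraction of survival miRNAs is *confounded*:
  expression tracks COO (no direct hazard), exercising the Cox independence
  gate.
- **Clusters.** Tumor samples split into 2 clusters; 40 marker miRNAs (half
  per cluster) scale by 2³ in their cluster.
- **Validation cohort.** Same truth, independent draws, optional per-feature
  log-normal scale distortion emulating fixation artefacts (off by default).
- **Candidate loci.** True novel loci ≥ 10 bp apart with per-library
  start/end jitter uniform on {−2..+2}; decoys are placed inside the emitted
  snoRNA/tRNA blacklist tracks.

What the generator does **not** emulate: read-level artefacts, isomiR
structure, batch effects, library-preparation biases, dependence between
miRNAs, or realistic GO term structure. Passing tests therefore demonstrate
correctness of the statistical machinery under its stated model, not
performance on real cohorts.

## Determinism and problem sizes

Every stochastic component consumes a `numpy` SeedSequence derived from a
single seed; two runs with one configuration are byte-identical (provenance
sidecars echo the configuration and package version and deliberately carry
no timestamps). The default demonstration uses the full study-sized cohort
(300 miRNAs × 219 samples, 600 isoforms × 107 samples, ~1.6×10⁵ tested
pairs, 100 permutations, k = 2..8 × 100 NMF runs) and completes in a few
minutes on one CPU. The test suite uses reduced cohorts (tens of features
and samples) everywhere except the recovery checks, which keep the
study-scale conditions they verify (e.g. 2,000-replicate type-I simulations,
20 null replicates of the 200×500-pair screen, 50 confounding replicates).

## Known limitations

- The maximally selected log-rank p is anti-conservative by construction;
  downstream BH reproduces the published procedure rather than repairing it.
- The per-bin count-excess rule is one defensible reading of the null
  filter; the published threshold rule is not given as a formula.
- The hypergeometric enrichment stand-in will not numerically match
  model-based enrichment tools; only the Fisher aggregation layer is
  expected to transfer.
- Cox fits on groupings nearly collinear with COO can fail to converge;
  the screen skips such features with a log message, and the independence
  gate treats non-identifiable fits as failures.
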