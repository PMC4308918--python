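"""Generate the synthetic discovery and validation cohorts with planted truth.

Writes the full fixture set (count/FPKM matrices, annotations, clinical
tables, candidate-interval BEDs, sequences, truth JSON) under
results/analysis/fixture/.
"""

from common import pipeline_through

pl = pipeline_through("simulate")
truth = pl.state["truth"]
print(f"miRNA matrix: {pl.state['mirna'].shape}, mRNA matrix: {pl.state['mrna'].shape}")
print(
    f"planted: {len(truth.de_mirna)} DE miRNAs, {len(truth.regulatory_pairs)} regulatory pairs, "
    f"{len(truth.survival_mirna)} survival miRNAs, {len(set(truth.cluster_labels.values()))} clusters"
)
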