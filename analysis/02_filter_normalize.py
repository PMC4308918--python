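"""Presence-filter and normalize expression.

miRNAs are kept at >10 RPM in >10% of discovery samples (strict), mRNA
isoforms at >=1 FPKM in >=10% of samples (inclusive); retained miRNAs are
quantile normalized for the downstream differential and clustering analyses.
"""

from common import pipeline_through

pl = pipeline_through("normalize")
print(f"expressed miRNAs: {len(pl.state['expressed_mirna'])} of {pl.state['mirna'].shape[0]}")
print(f"expressed mRNA isoforms: {len(pl.state['expressed_mrna'])} of {pl.state['mrna'].shape[0]}")
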