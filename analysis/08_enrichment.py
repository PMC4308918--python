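"""Group-level term-enrichment aggregation.

Per-miRNA hypergeometric enrichment of interaction-derived target sets, then
a two-sided Fisher exact test per term asking whether planted regulator
miRNAs collectively enrich it (BH across terms, significant at q < 0.05).
"""

from common import pipeline_through

pl = pipeline_through("enrich")
g = pl.state["enrichment"]
sig = g[g["significant"]] if len(g) else g
print(f"terms tested: {len(g)}; significant: {list(sig['term_id']) if len(sig) else []}")
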