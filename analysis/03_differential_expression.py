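"""Tumor-vs-normal differential abundance.

Wilcoxon rank-sum per miRNA on quantile-normalized values, BH correction,
calls at q < 0.05 and |log2 fold change| > 2; compares calls with the
planted ground truth.
"""

from common import pipeline_through

pl = pipeline_through("de")
rep = pl.report()["de"]
de = pl.state["de"]
print(f"called: {rep['called']} ({(de['call'] == 'up').sum()} up, {(de['call'] == 'down').sum()} down)")
print(f"planted: {rep['planted']}, recall {rep['recall']:.2f}, precision {rep['precision']:.2f}")
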