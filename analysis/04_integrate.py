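#!/usr/bin/env python
"""Integrate the two assays: anticorrelation, median-split classes,
high-confidence overlap, 2-fold induction subset, gene-set enrichment."""

from pathlib import Path

from capmeth import integration as itg, io, ip

OUT = Path(__file__).resolve().parent.parent / "results"

meth = io.read_table(OUT / "methylation.tsv")
tag = io.read_table(OUT / "captag.tsv")
counts = io.read_count_matrix(OUT / "counts.tsv")
terms = io.read_gmt(OUT / "gene_sets.gmt")

r, n = itg.correlate(meth["pct_methylation"], tag["pct_input_corrected"], "pearson")
print(f"Pearson r between % methylation and % input: {r:.3f} over {n} mRNAs")

filtered, _ = ip.filter_min_reads(counts.select(assay="ip"), 10)
norm = ip.spike_normalize(filtered)
inputs = {
    cond: norm.select(assay="ip", condition=cond, fraction="input").counts.mean(axis=1)
    for cond in ("rich", "min")
}
labels = itg.classify(meth, tag, inputs["min"], inputs["rich"], fold=2.0)
io.write_table(labels, OUT / "class_labels.tsv", "integration", {"fold": 2.0})
hc_high = labels.index[labels["high_confidence_high"]]
hc_low = labels.index[labels["high_confidence_low"]]
print(f"high-confidence highly methylated: {len(hc_high)}; lowly methylated: {len(hc_low)}")
print(f"2-fold induced among high-confidence-high: {int(labels.loc[hc_high, 'induced'].sum())}")

universe = labels.index
for name, query in (
    ("high", hc_high),
    ("low", hc_low),
    ("high_induced", hc_high[labels.loc[hc_high, "induced"]]),
):
    res = itg.enrich(query, terms, universe)
    io.write_table(res, OUT / f"enrichment_{name}.tsv", "integration", {"query": name})
    top = res.iloc[0]
    print(f"enrichment[{name}]: top term {res.index[0]} "
          f"(k/K = {int(top['k'])}/{int(top['K'])}, q = {top['q_value']:.2e})")
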