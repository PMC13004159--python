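#!/usr/bin/env python
"""Auxiliary metrics on the same simulated transcriptome: Abd1 occupancy,
differential H3K36me3, translation efficiency, intron/exon ratios, and
bulk cap-species percentages."""

from pathlib import Path

import pandas as pd

from capmeth import aux, integration as itg, io, synthetic as sd

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1

truth = io.read_table(OUT / "ground_truth.tsv")
meth = io.read_table(OUT / "methylation.tsv")

# Abd1 occupancy relative to Pol II vs cap methylation
occ = sd.simulate_occupancy(truth, seed=SEED)
occ["relative_occupancy"] = aux.relative_occupancy(
    occ["abd1_peak_signal"], occ["polii_genebody_signal"]
)
io.write_table(occ, OUT / "occupancy.tsv", "aux_metrics", {"seed": SEED})
r, n = itg.correlate(occ["relative_occupancy"], meth["pct_methylation"])
print(f"relative Abd1 occupancy vs % methylation: Pearson r = {r:.3f} (n = {n})")

# differential H3K36me3 (K36/H3 log-ratio t-test, BH)
cm, planted = sd.simulate_histone_counts(n_genes=1000, seed=SEED)
hist = aux.histone_diff(cm)
io.write_table(hist, OUT / "histone_diff.tsv", "aux_metrics", {"seed": SEED})
up = hist.index[hist["upregulated"]]
print(f"H3K36me3 upregulated genes (log2FC > 0, q < 0.05): {len(up)} "
      f"of which {len(up.intersection(planted))} are the planted gains")

# translation efficiency
ribo = sd.simulate_ribo(truth, seed=SEED)
te = aux.translation_table(ribo)
io.write_table(te, OUT / "translation.tsv", "aux_metrics", {"seed": SEED})
r_te, n_te = itg.correlate(te["te_min"], meth["pct_methylation"])
print(f"TE (min) vs % methylation: Pearson r = {r_te:.3f} (n = {n_te})")

# intron/exon read ratios per library class
reads = sd.simulate_intron_reads(truth, seed=SEED)
ratios = aux.summarize_intron_ratios(reads).to_frame("intron_exon_ratio")
io.write_table(ratios, OUT / "intron_ratios.tsv", "aux_metrics", {"seed": SEED})
print("intron/exon ratios:",
      ", ".join(f"{k} = {v:.4f}" for k, v in ratios["intron_exon_ratio"].items()))

# bulk cap-species percentages
amounts = io.read_table(OUT / "bulk_cap_amounts.tsv")["amount"]
pct = aux.bulk_cap_percent(amounts).to_frame("percent")
io.write_table(pct, OUT / "bulk_cap_percent.tsv", "aux_metrics", {})
print("bulk cap percentages:",
      ", ".join(f"{k} = {v:.1f}%" for k, v in pct["percent"].items()))
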