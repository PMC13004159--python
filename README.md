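# capmeth

Per-transcript quantification of mRNA 5' cap methylation from
sequencing assays, for yeast methionine/SAM-starvation experiments and
simulations thereof.

Not every mRNA cap is methylated. Transcripts start with an
unmethylated GpppN cap that the cap methyltransferase converts to
m⁷GpppN using SAM; when methionine (and hence SAM) is scarce, cells
accumulate cap-unmethylated mRNAs, and they do so gene-specifically.
This package computes, per gene:

* **% methylation** from anti-m⁷G immunoprecipitation (m⁷G-IP):
  ERCC-spike-normalized IP/input count ratios, with the rich-medium
  condition calibrated to 100% per transcript
  (`X_g = 100 / (IP_g^rich/input_g^rich)`,
  `%meth_g^min = (IP_g^min/input_g^min) · X_g`, capped at 100);
* **% input** from the Cap-Tag assay (chemical labeling + pulldown of
  *unmethylated* caps): `(pulldown / input / 22.5) × 100`, with the
  methyltransferase-omitted control's background rescaled via a fully
  methylated eGFP spike and subtracted per gene;
* their integration: correlation, median-split high/low classes,
  high-confidence overlaps, ≥2-fold-induction subsetting, and gene-set
  overrepresentation (one-sided Fisher exact + Benjamini–Hochberg);
* auxiliary metrics: relative Abd1 occupancy (Abd1 peak signal /
  Pol II gene-body signal), differential H3-normalized H3K36me3,
  translation efficiency (footprint/mRNA), intron/exon read ratios per
  library class, and bulk cap-species percentages.

A generative simulator (`capmeth.synthetic`) models the capture
chemistry of both assays — specific capture of the targeted cap state
plus nonspecific background, spike-in structure, negative-binomial
sequencing noise — and supplies the ground truth against which the
estimators are validated. See `docs/methods.md` for the model and its
assumptions.

## Worked example

Simulate a starved transcriptome and quantify both assays:

```python
from capmeth import synthetic as sd, ip, captag, integration as itg

truth = sd.generate_ground_truth(2000, "starvation", seed=1)
libs = sd.simulate_libraries(truth, sd.AssayConfig(seed=1))

meth, _ = ip.quantify_ip(libs)          # % methylation table
tag, _ = captag.quantify_captag(libs)   # corrected % input table
r, n = itg.correlate(meth["pct_methylation"], tag["pct_input_corrected"])
print(f"r = {r:.3f} over {n} genes")
```

The numbered drivers under `analysis/` run the full study on this
simulated dataset (`python analysis/01_simulate.py`, then 02–05),
writing their tables under `results/`. A run at the default settings
prints, among other lines:

```
bulk unmethylated caps: 43.4%
1975 genes quantified (25 excluded by the <10-read filter)
112 transcripts exceeded 100% and were capped
Spearman rho vs true methylated fraction: 0.968
Pearson r between % methylation and % input: -0.962 over 1906 mRNAs
high-confidence highly methylated: 876; lowly methylated: 876
enrichment[high]: top term PLANTED (k/K = 93/93, q = 3.21e-32)
```

Read: after one hour of simulated starvation, ~43% of bulk caps are
unmethylated, but the per-transcript estimates (rank correlation 0.97
with truth) show this is far from uniform; the two orthogonal assays
anticorrelate strongly (r = −0.96), their median-split overlap defines
high-confidence gene classes, and the gene set planted in the
high-methylation mode is recovered as the top enrichment hit.

The same stages are available as a CLI
(`capmeth simulate | quantify-ip | quantify-captag | integrate |
metrics | run`), e.g.:

```
capmeth simulate --n-genes 2000 --seed 1 --out counts.tsv
capmeth quantify-ip --counts counts.tsv --threshold 10 --calibration per_transcript
capmeth quantify-captag --counts counts.tsv --dilution 22.5
capmeth integrate --meth methylation.tsv --captag captag.tsv --gmt sets.gmt --fold 2
```

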