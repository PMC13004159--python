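# Methods

## The measurement problem

Every RNA-polymerase-II transcript begins life with an unmethylated
GpppN cap; the cap methyltransferase (Abd1 in *S. cerevisiae*) converts
it to the canonical m⁷GpppN (cap 0) using S-adenosylmethionine (SAM) as
the methyl donor. Under methionine/SAM limitation a substantial pool of
mRNAs retains unmethylated caps, and the fraction is gene-specific. Two
sequencing assays read out complementary sides of this cap state:

* **m⁷G-IP** — anti-m⁷G immunoprecipitation of poly(A)+ RNA; the
  IP/input count ratio of a gene grows with its cap-methylated fraction.
* **Cap-Tag** — in-vitro transfer of a propargyl group from the SAM
  analog ProSeAM onto *unmethylated* caps by a capping enzyme, followed
  by click biotinylation and streptavidin pulldown; pulldown/input
  grows with the cap-*unmethylated* fraction. A methyltransferase-
  omitted (ΔMTase) reaction measures nonspecific pulldown.

capmeth implements the estimators for both assays, their integration
into high-confidence methylation classes with gene-set enrichment, a
set of auxiliary per-gene metrics, and a generative simulator used to
validate that the estimators invert the assays' capture chemistry.

## Capture model (simulator)

For gene *g* with abundance `A_g` and true methylated fraction `m_g`,
expected captured molecules are linear in the two cap states:

```
input          ~ A_g
IP             ~ A_g [ m_g·η_ip + (1 − m_g)·β_ip ]
Cap-Tag pull   ~ A_g [ (1 − m_g)·λ_tag + β_tag ]
ΔMTase pull    ~ A_g · β_tag
```

with specific capture efficiencies η_ip (default 0.6) and λ_tag (0.35)
and nonspecific backgrounds β_ip (0.02) and β_tag (0.01). Methylated
plus unmethylated molecules always sum to `A_g` (the yeast model has no
third cap state, and internal m⁷G is absent). This is the simplest
generative model under which the ratio estimators below are consistent,
which is precisely what makes it useful for recovery testing; it is not
a claim about the assays' detailed kinetics.

Spike-ins: ERCC rows are appended to every library at fixed known
amounts (a geometric ladder summing to 2% of the transcriptome by
default) *after* enrichment, so they report only library scaling. The
eGFP spike (CleanCap, fully methylated) is added before the Cap-Tag
reaction; it is present in the input at its full amount but appears in
pulldown and ΔMTase libraries only at the background rate β_tag, which
is what makes it a background sensor.

**Noise.** Each library is scaled so its expected total equals the
configured depth, then counts are drawn negative-binomially with a
single global dispersion φ (default 0.1; Var = μ + φμ²). The
overdispersion is realised as a gamma factor per (gene, assay arm,
condition, replicate) shared across the fractions of one RNA prep —
IP and input of a replicate are aliquots of the same poly(A)+ RNA, as
are the Cap-Tag input/pulldown/ΔMTase — with Poisson counting noise on
top. Marginally each count is exactly NB(μ, φ) and φ = 0 degenerates to
Poisson; the sharing reflects the real experiment, in which biological
variation cancels in within-prep ratios. Spike rows receive Poisson
noise only (they are defined amounts, not biology).

**Study conditions.** Rich-medium methylation is drawn uniform on
[0.96, 1] (near-complete). The starvation scenario draws the
minimal-medium fraction from the mixture
0.8·Beta(mean 0.45, conc 10) + 0.2·Beta(mean 0.9, conc 20): a broad
partially-unmethylated bulk (population unmethylated mean 0.46,
consistent with the ~40–50% bulk unmethylated caps the simulator's
LC-MS-style readout produces) plus a high-methylation subpopulation.
Abundances are log-normal (σ = 1.2) with log-normal induction
fold-changes (σ = 0.5); 5% of genes carry an intron occupying 5–35% of
the gene. These mixture parameters are configuration, not biological
claims.

## m⁷G-IP estimator

1. **Filter**: genes with fewer than 10 raw reads in any sample of the
   arm are excluded (threshold configurable; spike rows exempt).
2. **Spike normalization**: each sample's gene counts are divided by
   that sample's summed ERCC counts (total-count division, as quoted in
   the protocol; spike rows are then dropped). This makes the estimator
   exactly invariant to rescaling any single library.
3. **Calibration**: IP/input ratios are computed per replicate and
   arithmetic-averaged per condition. In per-transcript mode (default)
   the rich-medium ratio of each gene is mapped to 100%
   (X_g = 100/ratio_g^rich) and the minimal-medium percent is
   ratio_g^min / ratio_g^rich × 100; this is the only reading under
   which "rich = 100%" holds for every gene and under which transcripts
   can exceed 100%, as observed. A global mode using one scalar
   X = 100/median(rich ratios) is provided for sensitivity analysis.
4. **Capping**: values above 100 are reported as exactly 100 with
   `capped=True`; the uncapped value is retained. Capping follows
   replicate averaging. The raw percent is computed as a single
   quotient so that a minimal ratio exactly equal to the rich ratio
   yields exactly 100.0 and never trips the flag through floating-point
   round-off.

Genes whose rich ratio is zero or non-finite are flagged
`passed_filter=False` rather than raising; no pseudocounts are used —
the ≥10-read filter precedes all ratios.

## Cap-Tag estimator

`% input = (pulldown / input / dilution) × 100` with dilution 22.5 (the
published bookkeeping constant for the 1-of-17 µL input save; it is a
configurable parameter, and percents are exactly inverse-linear in it).
Per-replicate percents are averaged, then the ΔMTase background is
subtracted per gene on the %-input scale after rescaling by
`(eGFP %input in sample) / (eGFP %input in ΔMTase)`, and floored at 0
to keep percents interpretable. The eGFP spike percent is computed
before filtering so the filter cannot remove the normalizer. On
noiseless expected counts the corrected percent is exactly proportional
to (1 − m_g)·λ_tag — the library-scaling factors cancel through the
eGFP rescaling — and a fully methylated transcriptome corrects to 0.
Quantification defaults to the minimal-medium condition, the assay's
biological target.

## Integration

Correlation (Pearson/Spearman) is computed on the intersection of
finite-valued genes of the two tables. Median splits label a gene
`high` iff its value is strictly above the median; ties at the median
go to `low` (so the classes always partition the universe — the tie
rule is our choice, the source convention being silent). High-
confidence highly methylated genes are methylation-high AND
%-input-low; the low-confidence class is the converse. Induction is
minimal/rich spike-normalized input ≥ 2-fold (boundary inclusive).

Enrichment: one-sided Fisher exact test (overrepresentation), computed
as the upper hypergeometric tail P(X ≥ k | N, K, n), with
Benjamini–Hochberg q-values across all tested terms. The universe is
the set of genes passing both assays' filters. Tests verify the p-value
against exact integer enumeration for every table with N ≤ 60 and the
BH q-values against a literal step-up implementation.

## Auxiliary metrics

* **Relative Abd1 occupancy** = Abd1 signal over its called peaks /
  Pol II gene-body signal; consumed as precomputed per-gene normalized
  signals (peak calling and normalization are upstream of this
  package), degree-0 homogeneous by construction.
* **Differential H3K36me3**: per-gene K36/H3 log2 ratios per replicate;
  log2FC = mean(min) − mean(rich); two-sample t-test on the replicate
  log ratios with BH correction; `upregulated` = log2FC > 0 at
  q < 0.05. This is a deliberately simple log-ratio t-test standing in
  for consensus-peak differential-binding machinery: the downstream
  logic only needs the flag, and shrinkage estimation is out of scope.
* **Translation efficiency** = footprint reads / mRNA reads per
  condition (plain ratio definition; no model-based moderation), with
  log2FC(min/rich).
* **Intron/exon ratio** per library class, summarised as total intronic
  over total exonic reads.
* **Bulk cap percentages**: % of each dinucleotide species within its
  +1-base family (m⁷GpppA vs GpppA; m⁷GpppG vs GpppG), summing to 100
  within a family whenever the family total is positive.

## Numerical and design choices

* Replicate aggregation is the arithmetic mean of per-replicate ratios
  (the aggregation was unstated at the source; two biological
  replicates is the default).
* All tabular IO is TSV (UTF-8, '.' decimals) so outputs diff
  bit-exactly; result tables carry a comment header naming the
  producing module and a hash of the computational parameters (paths
  and output locations are excluded from the hash so fixed-seed reruns
  are byte-identical).
* Zero denominators never crash gene-level computations; the gene is
  flagged not-evaluable (NaN + flag) instead. Structural problems
  (missing fractions, absent spikes, zero spike totals) raise typed
  errors naming the offender.
* Every stochastic routine takes an explicit integer seed and is
  deterministic given it.

## Problem sizes and what the tests show

Recovery suites run at 2,000 genes, 2×10⁶ reads/library, dispersion
0.1, two replicates — comfortably desk-scale while deep enough that
filter effects and capping are exercised (the analysis run caps ~110
transcripts and excludes a few dozen low-count genes). The planted
gene-set suite uses 100 seeded runs of 500 genes; the histone suite 20
seeded runs of 1,000 genes with a 4× planted gain in 10% of genes.

The simulator emulates capture chemistry, spike-in structure and
NB sequencing noise. It does **not** emulate read-level artifacts
(mappability, positional bias, strand errors), antibody sequence
preferences, partial poly(A) selection, transcript-length effects on
counting, or cell-to-cell heterogeneity. Passing recovery tests
therefore shows the estimators correctly invert the stated capture
model under realistic counting noise — not that real libraries are free
of biases outside that model. Real-data correlations between the
auxiliary metrics and methylation are emphatically not asserted; the
simulator only plants directional couplings so the sign conventions of
the code can be tested.
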