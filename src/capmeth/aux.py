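"""Auxiliary per-gene metrics.

Relative cap-methyltransferase (Abd1) occupancy, a simplified
differential H3K36me3 computation, translation efficiency from ribosome
profiling, intron/exon read ratios per library class, and bulk
cap-species percentages from calibrated amounts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CountMatrix, ConfigurationError

__all__ = [
    "relative_occupancy",
    "histone_diff",
    "translation_efficiency",
    "translation_table",
    "intron_exon_ratio",
    "summarize_intron_ratios",
    "bulk_cap_percent",
    "bulk_percent_unmethylated",
]


def relative_occupancy(abd1, polii):
    """Abd1 peak signal divided by Pol II gene-body signal.

    A transcription-independent binding metric: both signals scale with
    transcription, so their ratio does not. Zero/negative Pol II signal
    yields NaN (not evaluable).
    """
    abd1 = np.asarray(abd1, dtype=float)
    polii = np.asarray(polii, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(polii > 0, abd1 / polii, np.nan)
    return out if out.ndim else float(out)


def _rep_log2_ratios(cm: CountMatrix, condition: str) -> pd.DataFrame:
    reps = cm.replicates("chip", condition)
    if len(reps) < 2:
        raise ConfigurationError(
            f"histone_diff needs >= 2 replicates per condition, have {len(reps)} for {condition!r}"
        )
    cols = {}
    for rep in reps:
        k36 = cm.counts[cm.sample_id(assay="chip", condition=condition, fraction="k36", replicate=rep)]
        h3 = cm.counts[cm.sample_id(assay="chip", condition=condition, fraction="h3", replicate=rep)]
        with np.errstate(divide="ignore", invalid="ignore"):
            cols[rep] = np.log2(k36 / h3)
    return pd.DataFrame(cols)


def histone_diff(cm: CountMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Differential H3-normalized H3K36me3 between minimal and rich medium.

    Per gene the signal is the K36/H3 ratio; ``log2fc`` is the log2 of
    the mean minimal over mean rich ratio, the p-value comes from a
    two-sample t-test on per-replicate log2 ratios, and q-values are
    Benjamini-Hochberg across evaluable genes. ``upregulated`` flags
    log2fc > 0 at q < ``alpha``. Genes with zero H3 or K36 signal in
    any replicate are flagged not evaluable.
    """
    lr_rich = _rep_log2_ratios(cm, "rich")
    lr_min = _rep_log2_ratios(cm, "min")
    evaluable = np.isfinite(lr_rich).all(axis=1) & np.isfinite(lr_min).all(axis=1)
    log2fc = lr_min.mean(axis=1) - lr_rich.mean(axis=1)
    t = stats.ttest_ind(lr_min, lr_rich, axis=1)
    p = pd.Series(t.pvalue, index=lr_rich.index).where(evaluable)
    out = pd.DataFrame(
        {"log2fc": log2fc.where(evaluable), "p_value": p, "evaluable": evaluable}
    )
    out["q_value"] = np.nan
    mask = evaluable & np.isfinite(p)
    if mask.any():
        out.loc[mask, "q_value"] = multipletests(p[mask].to_numpy(), method="fdr_bh")[1]
    out["upregulated"] = (out["log2fc"] > 0) & (out["q_value"] < alpha)
    return out


def translation_efficiency(footprint, mrna):
    """TE = ribosome-footprint reads / mRNA reads; NaN where mRNA is zero."""
    footprint = np.asarray(footprint, dtype=float)
    mrna = np.asarray(mrna, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mrna > 0, footprint / mrna, np.nan)
    return out if out.ndim else float(out)


def translation_table(cm: CountMatrix) -> pd.DataFrame:
    """Per-gene TE in both conditions and its log2 fold change (min/rich).

    Replicate counts are summed per condition and fraction before the
    ratio.
    """
    te = {}
    for cond in ("rich", "min"):
        fp = cm.select(assay="ribo", condition=cond, fraction="footprint").counts.sum(axis=1)
        mr = cm.select(assay="ribo", condition=cond, fraction="mrna").counts.sum(axis=1)
        te[f"te_{cond}"] = pd.Series(translation_efficiency(fp, mr), index=cm.gene_ids)
    out = pd.DataFrame(te)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log2fc_te"] = np.log2(out["te_min"] / out["te_rich"])
    return out


def intron_exon_ratio(intronic, exonic):
    """Intronic / exonic read ratio; NaN where exonic is zero."""
    intronic = np.asarray(intronic, dtype=float)
    exonic = np.asarray(exonic, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(exonic > 0, intronic / exonic, np.nan)
    return out if out.ndim else float(out)


def summarize_intron_ratios(reads: pd.DataFrame) -> pd.Series:
    """Aggregate intron/exon ratio per library class.

    ``reads`` is long-form with columns ``library_class``, ``intronic``,
    ``exonic``; the summary ratio per class is total intronic over total
    exonic reads.
    """
    g = reads.groupby("library_class")[["intronic", "exonic"]].sum()
    return pd.Series(intron_exon_ratio(g["intronic"], g["exonic"]), index=g.index)


#: +1-base families of cap dinucleotide species.
CAP_FAMILIES = {"A": ("m7GpppA", "GpppA"), "G": ("m7GpppG", "GpppG")}


def bulk_cap_percent(amounts: pd.Series) -> pd.Series:
    """Percent of each cap species within its +1-base family.

    Within a family, %m7GpppN + %GpppN = 100 whenever the family total
    is positive; a zero family total leaves both species NaN.
    """
    out = {}
    for _, (meth, unmeth) in CAP_FAMILIES.items():
        if meth not in amounts.index or unmeth not in amounts.index:
            continue
        total = amounts[meth] + amounts[unmeth]
        if total > 0:
            out[meth] = amounts[meth] / total * 100.0
            out[unmeth] = amounts[unmeth] / total * 100.0
        else:
            out[meth] = out[unmeth] = np.nan
    return pd.Series(out)


def bulk_percent_unmethylated(amounts: pd.Series) -> float:
    """Unmethylated (GpppN) share of all caps, in percent."""
    unmeth = sum(amounts.get(f"Gppp{b}", 0.0) for b in ("A", "G"))
    total = float(amounts.sum())
    if total <= 0:
        return float("nan")
    return unmeth / total * 100.0
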