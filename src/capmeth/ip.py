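"""Per-transcript % cap methylation from m7G-IP and input libraries.

The estimator mirrors the published convention: read counts are
normalized to the total counts of the ERCC spike-ins in each library,
genes with fewer than ``threshold`` reads in any sample are excluded,
rich-medium methylation is arbitrarily set to 100% to calibrate a
scaling factor X, minimal-medium methylation is (IP/input) * X, and
values exceeding 100% are capped at 100 with a flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import CountMatrix, NormalizationError

__all__ = ["spike_normalize", "filter_min_reads", "percent_methylation", "quantify_ip"]


def spike_normalize(m: CountMatrix) -> CountMatrix:
    """Divide each sample's gene counts by that sample's summed spike counts.

    Spike rows are dropped from the output. Raises
    :class:`NormalizationError` naming the sample if any sample has a
    zero spike total.
    """
    spike_totals = m.counts.loc[m.spike_flag].sum(axis=0)
    zero = spike_totals.index[spike_totals <= 0].tolist()
    if zero:
        raise NormalizationError(f"zero spike-in total in sample(s): {zero}")
    norm = m.counts.loc[~m.spike_flag].div(spike_totals, axis=1)
    return CountMatrix(norm, m.sample_meta, m.spike_flag.loc[~m.spike_flag])


def filter_min_reads(
    m: CountMatrix, threshold: int = 10
) -> tuple[CountMatrix, list[str]]:
    """Drop genes with fewer than ``threshold`` raw reads in any sample.

    Spike rows are exempt (they are normalization controls, not genes).
    Returns the filtered matrix and the excluded gene ids for logging.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    gene_rows = ~m.spike_flag
    ok = (m.counts.loc[gene_rows] >= threshold).all(axis=1)
    excluded = ok.index[~ok].tolist()
    keep = m.spike_flag | m.spike_flag.index.isin(ok.index[ok])
    return (
        CountMatrix(m.counts.loc[keep], m.sample_meta, m.spike_flag.loc[keep]),
        excluded,
    )


def _replicate_mean_ratio(norm: CountMatrix, condition: str) -> pd.Series:
    """Per-gene IP/input ratio, computed per replicate then averaged."""
    reps = norm.replicates("ip", condition)
    if not reps:
        raise NormalizationError(f"no IP-arm samples for condition {condition!r}")
    ratios = []
    for rep in reps:
        ip = norm.counts[norm.sample_id(assay="ip", condition=condition, fraction="ip", replicate=rep)]
        inp = norm.counts[norm.sample_id(assay="ip", condition=condition, fraction="input", replicate=rep)]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios.append(ip / inp)
    return pd.concat(ratios, axis=1).mean(axis=1)


def percent_methylation(
    norm: CountMatrix, calibration: str = "per_transcript"
) -> pd.DataFrame:
    """Compute the % methylation table from a spike-normalized matrix.

    Per-transcript calibration (default): X_g = 100 / (IP_g^rich /
    input_g^rich), so the rich condition maps to exactly 100% for every
    gene, and pct_uncapped_raw = (IP_g^min / input_g^min) * X_g.
    Global calibration uses one scalar X = 100 / median_g of the rich
    ratios. Ratios are computed per replicate and arithmetic-averaged
    before calibration; capping at 100 follows averaging.

    Returns a DataFrame indexed by gene id with columns
    ``pct_methylation``, ``pct_uncapped_raw``, ``capped``,
    ``passed_filter`` and ``scaling_factor``. Genes whose rich ratio is
    zero or non-finite are flagged ``passed_filter=False`` rather than
    raising.
    """
    if calibration not in ("per_transcript", "global"):
        raise ValueError(f"unknown calibration mode {calibration!r}")
    ratio_rich = _replicate_mean_ratio(norm, "rich")
    ratio_min = _replicate_mean_ratio(norm, "min")

    ok = np.isfinite(ratio_rich) & (ratio_rich > 0) & np.isfinite(ratio_min)
    with np.errstate(divide="ignore", invalid="ignore"):
        if calibration == "per_transcript":
            scaling = 100.0 / ratio_rich
            # single quotient, so a min ratio equal to the rich ratio maps to
            # exactly 100.0 and never trips the capped flag spuriously
            raw = ratio_min / ratio_rich * 100.0
        else:
            med = float(ratio_rich[ok].median()) if ok.any() else np.nan
            scaling = pd.Series(100.0 / med, index=ratio_rich.index)
            raw = ratio_min / med * 100.0
    raw = raw.where(ok)
    capped = raw > 100.0
    pct = raw.clip(upper=100.0)
    return pd.DataFrame(
        {
            "pct_methylation": pct,
            "pct_uncapped_raw": raw,
            "capped": capped.fillna(False),
            "passed_filter": ok,
            "scaling_factor": scaling,
        }
    )


def quantify_ip(
    counts: CountMatrix, threshold: int = 10, calibration: str = "per_transcript"
) -> tuple[pd.DataFrame, list[str]]:
    """Full IP-arm pipeline: read filter -> spike normalization -> % methylation.

    Operates on the IP-arm samples of ``counts``; returns the
    methylation table and the list of filtered-out genes.
    """
    arm = counts.select(assay="ip")
    filtered, excluded = filter_min_reads(arm, threshold)
    if len(filtered.drop_spikes().gene_ids) == 0:
        empty = pd.DataFrame(
            columns=[
                "pct_methylation",
                "pct_uncapped_raw",
                "capped",
                "passed_filter",
                "scaling_factor",
            ]
        )
        empty.index.name = "gene_id"
        return empty, excluded
    norm = spike_normalize(filtered)
    return percent_methylation(norm, calibration), excluded
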