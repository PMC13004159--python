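"""Cap-Tag % input: enrichment of cap-unmethylated transcripts.

% input = (count_pulldown / count_input / dilution) x 100, with the
dilution constant defaulting to 22.5 (the published bookkeeping for the
1-of-17 uL input save). The methyltransferase-omitted (dMTase) control
estimates nonspecific pulldown; its % input is rescaled by the ratio of
the fully methylated eGFP spike's % input between sample and control
and subtracted per gene, floored at zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    CountMatrix,
    ConfigurationError,
    EGFP_SPIKE_ID,
    NormalizationError,
)
from .ip import filter_min_reads

__all__ = ["percent_input", "background_subtract", "quantify_captag"]

DEFAULT_DILUTION = 22.5


def percent_input(pulldown, input_, dilution: float = DEFAULT_DILUTION):
    """(pulldown / input / dilution) x 100, element-wise.

    Accepts scalars or aligned array-likes. Raises on non-positive
    scalar input counts; vector inputs with zeros yield NaN (the gene
    should have been removed by the read filter upstream).
    """
    if dilution <= 0:
        raise ValueError(f"dilution must be > 0, got {dilution}")
    if np.isscalar(input_):
        if input_ <= 0:
            raise ZeroDivisionError("undefined ratio: input count is zero")
        return pulldown / input_ / dilution * 100.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = pulldown / input_ / dilution * 100.0
    return out.where(input_ > 0) if isinstance(out, pd.Series) else out


def background_subtract(
    raw: pd.Series, dmtase_raw: pd.Series, spike_scale: float
) -> pd.DataFrame:
    """Subtract the spike-scaled dMTase background per gene, floored at 0.

    ``spike_scale`` is (eGFP % input in the sample) / (eGFP % input in
    the dMTase control); it must be finite and positive.
    """
    if not np.isfinite(spike_scale) or spike_scale <= 0:
        raise NormalizationError(f"invalid eGFP spike scale: {spike_scale}")
    dm = dmtase_raw.reindex(raw.index)
    bg = dm * spike_scale
    corrected = (raw - bg).clip(lower=0.0)
    return pd.DataFrame(
        {
            "pct_input_raw": raw,
            "pct_input_bg": bg,
            "pct_input_corrected": corrected,
        }
    )


def _replicate_mean_pct(
    arm: CountMatrix, condition: str, fraction: str, dilution: float
) -> pd.Series:
    reps = arm.replicates("captag", condition)
    cols = []
    for rep in reps:
        pull = arm.counts[
            arm.sample_id(assay="captag", condition=condition, fraction=fraction, replicate=rep)
        ]
        inp = arm.counts[
            arm.sample_id(assay="captag", condition=condition, fraction="input", replicate=rep)
        ]
        cols.append(percent_input(pull, inp, dilution))
    return pd.concat(cols, axis=1).mean(axis=1)


def quantify_captag(
    counts: CountMatrix,
    threshold: int = 10,
    dilution: float = DEFAULT_DILUTION,
    condition: str = "min",
    spike_gene: str = EGFP_SPIKE_ID,
) -> tuple[pd.DataFrame, list[str]]:
    """Full Cap-Tag pipeline for one condition.

    Read filter -> per-replicate % input for pulldown and dMTase
    fractions -> replicate mean -> eGFP-scaled background subtraction.
    Returns a DataFrame indexed by gene id with columns
    ``pct_input_raw``, ``pct_input_bg``, ``pct_input_corrected``,
    ``passed_filter``, plus the excluded gene list.
    """
    arm = counts.select(assay="captag", condition=condition)
    fracs = set(arm.sample_meta["fraction"])
    if "dmtase" not in fracs:
        raise ConfigurationError("Cap-Tag matrix lacks the dMTase control fraction")
    if "pulldown" not in fracs or "input" not in fracs:
        raise ConfigurationError("Cap-Tag matrix lacks pulldown and/or input fractions")
    if spike_gene not in arm.gene_ids:
        raise NormalizationError(f"eGFP spike row {spike_gene!r} absent from matrix")

    # spike % input from the unfiltered matrix (the spike must survive filtering)
    egfp_sample = float(_replicate_mean_pct(arm, condition, "pulldown", dilution)[spike_gene])
    egfp_dmtase = float(_replicate_mean_pct(arm, condition, "dmtase", dilution)[spike_gene])
    if not np.isfinite(egfp_dmtase) or egfp_dmtase <= 0:
        raise NormalizationError("eGFP spike has no signal in the dMTase control")
    spike_scale = egfp_sample / egfp_dmtase

    filtered, excluded = filter_min_reads(arm, threshold)
    genes = filtered.drop_spikes()
    if len(genes.gene_ids) == 0:
        empty = pd.DataFrame(
            columns=["pct_input_raw", "pct_input_bg", "pct_input_corrected", "passed_filter"]
        )
        empty.index.name = "gene_id"
        return empty, excluded
    raw = _replicate_mean_pct(filtered, condition, "pulldown", dilution).loc[genes.gene_ids]
    dm = _replicate_mean_pct(filtered, condition, "dmtase", dilution).loc[genes.gene_ids]
    table = background_subtract(raw, dm, spike_scale)
    table["passed_filter"] = np.isfinite(table["pct_input_raw"])
    return table, excluded
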