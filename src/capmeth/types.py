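"""Core containers shared by every pipeline stage.

The central object is :class:`CountMatrix`: a gene x sample table of
sequencing read counts together with per-sample metadata (assay arm,
growth condition, library fraction, replicate index) and a per-gene flag
marking synthetic spike-in rows (ERCC standards, the eGFP Cap-Tag spike).

Downstream result tables (% methylation, Cap-Tag % input, class labels,
enrichment results) are plain :class:`pandas.DataFrame` objects with
documented column schemas; see the producing functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Recognised assay arms.
ASSAYS = ("ip", "captag", "chip", "ribo")
#: Recognised growth conditions (rich = YPL-style rich medium, min = minimal).
CONDITIONS = ("rich", "min")
#: Recognised library fractions across all assay arms.
FRACTIONS = ("input", "ip", "pulldown", "dmtase", "footprint", "mrna", "k36", "h3")

#: Prefix that auto-flags ERCC spike-in rows on file read.
ERCC_PREFIX = "ERCC-"
#: Gene id of the CleanCap eGFP mRNA spiked prior to Cap-Tag.
EGFP_SPIKE_ID = "spike_eGFP"


class CapmethError(Exception):
    """Base class for all capmeth errors."""


class FormatError(CapmethError):
    """Malformed input table."""


class NormalizationError(CapmethError):
    """Spike-in normalization cannot be performed."""


class InsufficientDataError(CapmethError):
    """Too few genes/values to compute the requested statistic."""


class ConfigurationError(CapmethError):
    """A required library fraction or parameter is missing."""


@dataclass
class CountMatrix:
    """Gene x sample count matrix with sample metadata and spike flags.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id, one column per sample id. Raw
        matrices hold non-negative integers; spike-normalized matrices
        hold non-negative reals.
    sample_meta
        DataFrame indexed by sample id with columns ``assay``,
        ``condition``, ``fraction``, ``replicate``. The (condition,
        fraction, replicate) triple must be unique within an assay.
    spike_flag
        Boolean Series indexed like ``counts`` marking spike-in rows.
        Defaults to all-False if omitted.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    spike_flag: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.spike_flag is None:
            self.spike_flag = pd.Series(False, index=self.counts.index)
        self.spike_flag = self.spike_flag.reindex(self.counts.index, fill_value=False)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups}")
        if (c.to_numpy() < 0).any():
            raise FormatError("negative counts present")
        missing = [s for s in c.columns if s not in self.sample_meta.index]
        if missing:
            raise FormatError(f"samples missing from metadata: {missing}")
        extra = [s for s in self.sample_meta.index if s not in c.columns]
        if extra:
            raise FormatError(f"metadata samples missing from count header: {extra}")
        meta = self.sample_meta
        for col in ("assay", "condition", "fraction", "replicate"):
            if col not in meta.columns:
                raise FormatError(f"sample metadata lacks required column '{col}'")
        bad_assay = set(meta["assay"]) - set(ASSAYS)
        if bad_assay:
            raise FormatError(f"unknown assay values: {sorted(bad_assay)}")
        bad_frac = set(meta["fraction"]) - set(FRACTIONS)
        if bad_frac:
            raise FormatError(f"unknown fraction values: {sorted(bad_frac)}")
        key = meta[["assay", "condition", "fraction", "replicate"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].to_dict()
            raise FormatError(f"duplicate sample key within assay: {dup}")

    # -- convenience accessors ---------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def select(self, **where: object) -> "CountMatrix":
        """Subset samples by metadata equality, e.g. ``select(assay="ip")``."""
        mask = pd.Series(True, index=self.sample_meta.index)
        for col, val in where.items():
            mask &= self.sample_meta[col] == val
        ids = self.sample_meta.index[mask]
        return CountMatrix(self.counts[ids], self.sample_meta.loc[ids], self.spike_flag)

    def sample_id(self, **where: object) -> str:
        """Return the unique sample id matching the metadata query."""
        sub = self.select(**where)
        if len(sub.sample_ids) != 1:
            raise ConfigurationError(
                f"expected exactly one sample for {where}, found {len(sub.sample_ids)}"
            )
        return str(sub.sample_ids[0])

    def drop_spikes(self) -> "CountMatrix":
        keep = ~self.spike_flag
        return CountMatrix(
            self.counts.loc[keep], self.sample_meta, self.spike_flag.loc[keep]
        )

    def replicates(self, assay: str, condition: str) -> list[int]:
        meta = self.sample_meta
        m = (meta["assay"] == assay) & (meta["condition"] == condition)
        return sorted(meta.loc[m, "replicate"].unique().tolist())

    def __eq__(self, other: object) -> bool:  # value equality, for round-trip tests
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.sample_meta.equals(other.sample_meta)
            and self.spike_flag.equals(other.spike_flag)
        )


def flag_spikes(gene_ids: pd.Index, extra_spike_ids: tuple[str, ...] = (EGFP_SPIKE_ID,)) -> pd.Series:
    """Auto-flag spike rows by the ERCC prefix or configured spike ids."""
    arr = np.array(
        [g.startswith(ERCC_PREFIX) or g in extra_spike_ids for g in gene_ids],
        dtype=bool,
    )
    return pd.Series(arr, index=gene_ids)
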