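"""Tabular file formats and pipeline configuration.

One tabular dialect throughout: tab-separated UTF-8 with '.' decimals,
chosen so outputs diff bit-exactly in tests. Count matrices travel as a
TSV (first column gene_id, header row of sample ids) plus a sidecar
metadata TSV (sample_id, assay, condition, fraction, replicate). Every
result table written by :func:`write_table` carries comment header
lines naming the producing module and a parameter hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .types import CountMatrix, FormatError, flag_spikes

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_table",
    "write_table",
    "read_gmt",
    "write_gmt",
    "PipelineConfig",
]


def meta_path_for(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(".meta.tsv")


def write_count_matrix(m: CountMatrix, path: str | Path) -> None:
    """Write counts TSV plus the ``.meta.tsv`` sidecar next to it."""
    path = Path(path)
    m.counts.to_csv(path, sep="\t")
    m.sample_meta.to_csv(meta_path_for(path), sep="\t")


def read_count_matrix(
    path: str | Path, meta_path: str | Path | None = None
) -> CountMatrix:
    """Read a counts TSV and its sample-metadata sidecar.

    Spike rows are auto-flagged by the ``ERCC-`` prefix or the eGFP
    spike id. Malformed input (duplicate gene ids, negative counts,
    metadata/header mismatches) raises :class:`FormatError` naming the
    offender.
    """
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else meta_path_for(path)
    if not path.exists():
        raise FormatError(f"count matrix not found: {path}")
    if not meta_path.exists():
        raise FormatError(f"sample metadata not found: {meta_path}")
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.index.name = "gene_id"
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    meta.index.name = "sample_id"
    return CountMatrix(counts, meta, flag_spikes(counts.index))


def _params_hash(params: dict) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(
    df: pd.DataFrame, path: str | Path, module: str, params: dict | None = None
) -> None:
    """Write a result table with provenance comment headers."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    params = params or {}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# capmeth module={module} params_hash={_params_hash(params)}\n")
        if params:
            fh.write(f"# params={json.dumps(params, sort_keys=True, default=str)}\n")
        df.to_csv(fh, sep="\t")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a result table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from GMT (term <tab> description <tab> genes...)."""
    terms: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            term = parts[0]
            if term in terms:
                raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
            terms[term] = {g for g in parts[2:] if g}
    return terms


def write_gmt(terms: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, genes in terms.items():
            fh.write("\t".join([term, description, *sorted(genes)]) + "\n")


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters; defaults are the published constants.

    threshold=10 (minimum reads per sample), dilution=22.5 (Cap-Tag
    % input divisor), fold=2 (induction cutoff).
    """

    counts: str | None = None
    meta: str | None = None
    gmt: str | None = None
    threshold: int = 10
    dilution: float = 22.5
    fold: float = 2.0
    calibration: str = "per_transcript"
    seed: int = 0
    outdir: str = "results"
    simulate: bool = False
    n_genes: int = 2000
    depth: float = 2e6
    dispersion: float = 0.1
    n_replicates: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
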