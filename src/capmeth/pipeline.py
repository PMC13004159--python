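"""End-to-end pipeline driver.

simulate (optional) -> quantify-ip -> quantify-captag -> integrate ->
metrics; writes every table plus a machine-readable run log (JSON) with
parameters, seed, per-stage gene counts and the capped-transcript
count. Idempotent for a fixed seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import aux, captag, integration, ip, synthetic
from .io import PipelineConfig, read_count_matrix, write_count_matrix, write_table
from .types import CapmethError, CountMatrix

__all__ = ["run_pipeline", "StageError"]


class StageError(CapmethError):
    """An error raised by a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _input_means(norm: CountMatrix, condition: str) -> pd.Series:
    cols = norm.select(assay="ip", condition=condition, fraction="input")
    return cols.counts.mean(axis=1)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a dict with the result tables and the log."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"parameters": config.to_dict(), "stages": {}}
    # hash only computational parameters so fixed-seed reruns into different
    # directories stay byte-identical
    params = {
        k: v for k, v in config.to_dict().items()
        if k not in ("outdir", "counts", "meta", "gmt")
    }

    stage = "simulate"
    try:
        if config.simulate:
            truth = synthetic.generate_ground_truth(
                config.n_genes, "starvation", seed=config.seed
            )
            cfg = synthetic.AssayConfig(
                depth=config.depth,
                dispersion=config.dispersion,
                n_replicates=config.n_replicates,
                seed=config.seed,
            )
            counts = synthetic.simulate_libraries(truth, cfg)
            write_table(truth, outdir / "ground_truth.tsv", "synthetic_data", params)
            write_count_matrix(counts, outdir / "counts.tsv")
            log["stages"][stage] = {"n_genes": int(config.n_genes)}
        else:
            if config.counts is None:
                raise CapmethError("no counts file given and simulate=False")
            counts = read_count_matrix(config.counts, config.meta)
            log["stages"]["read"] = {"n_genes": int((~counts.spike_flag).sum())}
    except Exception as e:  # noqa: BLE001 - stage name propagation
        raise StageError(stage, e) from e

    stage = "quantify-ip"
    try:
        meth, ip_excluded = ip.quantify_ip(counts, config.threshold, config.calibration)
        write_table(meth, outdir / "methylation.tsv", "capquant_ip", params)
        norm_inputs = None
        if len(meth):
            arm = counts.select(assay="ip")
            filtered, _ = ip.filter_min_reads(arm, config.threshold)
            norm_inputs = ip.spike_normalize(filtered)
        log["stages"][stage] = {
            "genes_in": int((~counts.select(assay="ip").spike_flag).sum()),
            "genes_out": int(len(meth)),
            "excluded": len(ip_excluded),
            "capped": int(meth["capped"].sum()) if len(meth) else 0,
        }
    except Exception as e:
        raise StageError(stage, e) from e

    stage = "quantify-captag"
    try:
        tag, tag_excluded = captag.quantify_captag(
            counts, config.threshold, config.dilution
        )
        write_table(tag, outdir / "captag.tsv", "capquant_captag", params)
        log["stages"][stage] = {
            "genes_out": int(len(tag)),
            "excluded": len(tag_excluded),
        }
    except Exception as e:
        raise StageError(stage, e) from e

    stage = "integrate"
    try:
        labels = pd.DataFrame()
        enrichment = {}
        if len(meth) and len(tag):
            kw = {}
            if norm_inputs is not None:
                kw = dict(
                    input_min=_input_means(norm_inputs, "min"),
                    input_rich=_input_means(norm_inputs, "rich"),
                    fold=config.fold,
                )
            labels = integration.classify(meth, tag, **kw)
            write_table(labels, outdir / "class_labels.tsv", "integration", params)
            if config.gmt:
                from .io import read_gmt

                terms = read_gmt(config.gmt)
                universe = labels.index
                for name, mask in (
                    ("high", labels["high_confidence_high"]),
                    ("low", labels["high_confidence_low"]),
                ):
                    res = integration.enrich(universe[mask], terms, universe)
                    enrichment[name] = res
                    write_table(
                        res, outdir / f"enrichment_{name}.tsv", "integration", params
                    )
        log["stages"][stage] = {
            "n_classified": int(len(labels)),
            "high_confidence_high": int(labels["high_confidence_high"].sum()) if len(labels) else 0,
            "high_confidence_low": int(labels["high_confidence_low"].sum()) if len(labels) else 0,
        }
    except Exception as e:
        raise StageError(stage, e) from e

    stage = "metrics"
    try:
        metrics: dict = {}
        if config.simulate:
            # auxiliary assays are only available with simulated ground truth
            occ = synthetic.simulate_occupancy(truth, seed=config.seed)
            occ["relative_occupancy"] = aux.relative_occupancy(
                occ["abd1_peak_signal"], occ["polii_genebody_signal"]
            )
            te = aux.translation_table(synthetic.simulate_ribo(truth, seed=config.seed))
            reads = synthetic.simulate_intron_reads(truth, seed=config.seed)
            ratios = aux.summarize_intron_ratios(reads).to_frame("intron_exon_ratio")
            bulk = synthetic.simulate_bulk_cap(truth, seed=config.seed)
            pct = aux.bulk_cap_percent(bulk).to_frame("percent")
            metrics = {"occupancy": occ, "translation": te, "intron_ratios": ratios,
                       "bulk_cap_percent": pct}
            for name, df in metrics.items():
                write_table(df, outdir / f"{name}.tsv", "aux_metrics", params)
        log["stages"][stage] = {"tables": sorted(metrics)}
    except Exception as e:
        raise StageError(stage, e) from e

    log_path = outdir / "run_log.json"
    with open(log_path, "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return {
        "methylation": meth,
        "captag": tag,
        "labels": labels,
        "enrichment": enrichment,
        "metrics": metrics,
        "log": log,
        "outdir": outdir,
    }
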