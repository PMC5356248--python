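"""End-to-end orchestration: QC -> annotation -> burden -> association.

``run_pipeline`` reads the three (optionally four) input files, runs every
stage in order, and writes a result bundle into the output directory:

* ``qc_excluded_samples.tsv`` + ``qc_summary.txt``
* ``per_sample_burden.tsv`` and ``burden_table.tsv``
* ``association.tsv`` (Table-style layout, full precision)
* ``genelist_report.tsv`` when a gene list is supplied
* ``manifest.json`` — tool version, config hash, and a flow table with the
  counts entering and leaving each stage

Outputs contain no timestamps, so re-running on identical inputs is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

import cnvburden
from cnvburden.annotate import (
    assign_cnv_regions,
    collapse_transcripts,
    flag_rare_regions,
    screen_gene_list,
)
from cnvburden.association import run_association
from cnvburden.burden import burden_table, per_sample_burden
from cnvburden.errors import ValidationError
from cnvburden.io import (
    read_gene_list,
    read_penncnv_calls,
    read_sample_sheet,
    read_transcript_table,
    write_results_table,
)
from cnvburden.qc import QcThresholds, apply_qc


@dataclass(frozen=True)
class RunConfig:
    """Inputs and knobs for one pipeline run."""

    calls: str
    samples: str
    transcripts: str
    genelist: str | None = None
    outdir: str = "cnvburden_out"
    thresholds: QcThresholds = QcThresholds()
    rare_fraction: float = 0.01
    rarity_unit: str = "events"
    mode: str = "each_state"
    alpha: float = 0.05
    min_events: int = 1

    def validate_paths(self) -> None:
        for label, p in (
            ("calls", self.calls),
            ("samples", self.samples),
            ("transcripts", self.transcripts),
            ("genelist", self.genelist),
        ):
            if p is not None and not Path(p).is_file():
                raise ValidationError(f"[config] {label} path not found: {p}")


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the result bundle; returns it in memory."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    calls = read_penncnv_calls(config.calls)
    samples = read_sample_sheet(config.samples)
    transcripts = read_transcript_table(config.transcripts)

    kept_calls, qc_report = apply_qc(calls, samples, config.thresholds)
    kept_samples = samples[
        samples["sample_id"].isin(qc_report.kept_samples)
    ].reset_index(drop=True)
    if len(kept_samples) == 0:
        raise ValidationError("[qc] no samples survived quality control")

    genes = collapse_transcripts(transcripts)
    events = assign_cnv_regions(kept_calls, genes)
    region_flags = flag_rare_regions(
        events,
        n_samples=len(kept_samples),
        rare_fraction=config.rare_fraction,
        unit=config.rarity_unit,
    )

    per_sample = per_sample_burden(kept_calls, events, region_flags, kept_samples)
    burden = burden_table(per_sample, kept_samples)

    association = run_association(
        events,
        kept_samples,
        mode=config.mode,
        alpha=config.alpha,
        min_events=config.min_events,
    ) if len(events) else pd.DataFrame()

    genelist_report = None
    if config.genelist is not None:
        genelist_report = screen_gene_list(
            events, region_flags, read_gene_list(config.genelist), kept_samples
        )

    qc_report.sample_frame().to_csv(
        outdir / "qc_excluded_samples.tsv", sep="\t", index=False
    )
    (outdir / "qc_summary.txt").write_text(qc_report.summary() + "\n")
    write_results_table(per_sample, outdir / "per_sample_burden.tsv")
    write_results_table(burden, outdir / "burden_table.tsv")
    write_results_table(association, outdir / "association.tsv", float_precision=8)
    if genelist_report is not None:
        write_results_table(genelist_report, outdir / "genelist_report.tsv")

    manifest = {
        "tool": "cnvburden",
        "version": cnvburden.__version__,
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "config_hash": _config_hash(config),
        "flow": {
            "samples_in": len(samples),
            "samples_kept": len(kept_samples),
            "samples_excluded": len(qc_report.excluded_samples),
            "calls_in": len(calls),
            "calls_kept": len(kept_calls),
            "calls_excluded": {
                k: int(v) for k, v in qc_report.excluded_calls.items()
            },
            "regions_with_events": int(events["gene_symbol"].nunique())
            if len(events)
            else 0,
            "tests_run": len(association),
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return {
        "qc_report": qc_report,
        "per_sample_burden": per_sample,
        "burden_table": burden,
        "association": association,
        "genelist_report": genelist_report,
        "manifest": manifest,
    }
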