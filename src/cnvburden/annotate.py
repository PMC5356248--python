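"""Gene-centric CNV region annotation.

Transcripts of a gene symbol are collapsed into one genomic interval per
(symbol, chromosome) spanning all isoforms; those gene boundaries define the
CNV regions.  A call belongs to a region when the two intervals share at
least one base; a call overlapping k genes contributes one event to each of
the k regions (regions are per-gene, never merged into super-regions).  A
region is *rare* when its cohort-wide event count stays below 1% of the
cohort size (count cut = ceiling(fraction x N), so with N = 493 and the
default 1% fraction, regions with >= 5 events are common).

All intervals are 0-based half-open.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from cnvburden.errors import ValidationError
from cnvburden.io import classify_state

GENE_COLUMNS = ["gene_symbol", "chrom", "start", "end"]
EVENT_COLUMNS = [
    "gene_symbol",
    "sample_id",
    "state_class",
    "chrom",
    "start",
    "end",
    "copy_number",
    "call_index",
]


def collapse_transcripts(transcripts: pd.DataFrame) -> pd.DataFrame:
    """Collapse transcript records to one interval per (gene_symbol, chrom).

    The interval runs from the minimum ``tx_start`` to the maximum ``tx_end``
    over all transcripts of the symbol on that chromosome.  Output is sorted
    by chromosome then start.  A symbol appearing on two chromosomes yields
    two intervals and a warning.
    """
    if len(transcripts) == 0:
        return pd.DataFrame(
            {
                "gene_symbol": pd.Series(dtype=str),
                "chrom": pd.Series(dtype=str),
                "start": pd.Series(dtype=np.int64),
                "end": pd.Series(dtype=np.int64),
            }
        )
    grouped = (
        transcripts.groupby(["gene_symbol", "chrom"], sort=False)
        .agg(start=("tx_start", "min"), end=("tx_end", "max"))
        .reset_index()
    )
    multi = grouped["gene_symbol"].value_counts()
    multi = multi[multi > 1]
    if len(multi):
        warnings.warn(
            f"gene symbol(s) on multiple chromosomes: {list(multi.index)}",
            stacklevel=2,
        )
    return grouped.sort_values(["chrom", "start"], kind="mergesort").reset_index(
        drop=True
    )[GENE_COLUMNS]


def overlaps(
    call_chrom: str,
    call_start: int,
    call_end: int,
    gene_chrom: str,
    gene_start: int,
    gene_end: int,
) -> bool:
    """True iff the two half-open intervals share >= 1 base on the same chromosome."""
    return (
        call_chrom == gene_chrom
        and call_start < gene_end
        and gene_start < call_end
    )


def assign_cnv_regions(calls: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Intersect QC-passed calls with gene intervals (>= 1 bp overlap).

    Returns the event table: one row per overlapping (call, gene) pair with
    the gene symbol, sample, state class (loss for copy number 0/1, gain for
    3/4) and the originating call's coordinates and positional index.
    Regions with zero events simply do not appear.
    """
    pieces = []
    calls = calls.reset_index(drop=True)
    for chrom, gsub in genes.groupby("chrom", sort=False):
        csub = calls[calls["chrom"] == chrom]
        if csub.empty:
            continue
        cs = csub["start"].to_numpy()[:, None]
        ce = csub["end"].to_numpy()[:, None]
        gs = gsub["start"].to_numpy()[None, :]
        ge = gsub["end"].to_numpy()[None, :]
        ci, gi = np.nonzero((cs < ge) & (gs < ce))
        if len(ci) == 0:
            continue
        hit_calls = csub.iloc[ci]
        pieces.append(
            pd.DataFrame(
                {
                    "gene_symbol": gsub["gene_symbol"].to_numpy()[gi],
                    "sample_id": hit_calls["sample_id"].to_numpy(),
                    "state_class": classify_state(
                        hit_calls["copy_number"].to_numpy()
                    ),
                    "chrom": chrom,
                    "start": hit_calls["start"].to_numpy(),
                    "end": hit_calls["end"].to_numpy(),
                    "copy_number": hit_calls["copy_number"].to_numpy(),
                    "call_index": csub.index.to_numpy()[ci],
                }
            )
        )
    if not pieces:
        return pd.DataFrame(
            {c: pd.Series(dtype=object) for c in EVENT_COLUMNS}
        ).astype({"start": np.int64, "end": np.int64, "copy_number": np.int64,
                  "call_index": np.int64}, errors="ignore")
    return pd.concat(pieces, ignore_index=True)[EVENT_COLUMNS]


def flag_rare_regions(
    events: pd.DataFrame,
    n_samples: int,
    rare_fraction: float = 0.01,
    unit: str = "events",
) -> pd.DataFrame:
    """Summarise regions and flag the rare ones.

    A region is rare when its cohort-wide count is below
    ``ceiling(rare_fraction * n_samples)``.  ``unit`` selects what is
    counted: ``"events"`` (default; every overlapping call counts) or
    ``"carriers"`` (distinct samples with >= 1 event in the region).

    Returns one row per region with ``gene_symbol, n_events, n_carriers,
    is_rare``.
    """
    if n_samples <= 0:
        raise ValidationError("n_samples must be positive")
    if unit not in ("events", "carriers"):
        raise ValidationError(f"unknown rarity unit {unit!r}")
    cut = math.ceil(rare_fraction * n_samples)
    summary = (
        events.groupby("gene_symbol", sort=False)
        .agg(n_events=("sample_id", "size"), n_carriers=("sample_id", "nunique"))
        .reset_index()
    )
    counted = summary["n_events"] if unit == "events" else summary["n_carriers"]
    summary["is_rare"] = counted < cut
    return summary


def screen_gene_list(
    events: pd.DataFrame,
    region_flags: pd.DataFrame,
    gene_list: list[str],
    groups: pd.DataFrame,
) -> pd.DataFrame:
    """Report rare CNV events overlapping a user-supplied gene list.

    One row per (rare event, listed gene) match — e.g. a single spiked BRCA1
    deletion in a case yields exactly one row — sorted by gene then sample.
    Symbols match case-sensitively; harmonise vocabularies upstream.
    """
    if not gene_list:
        raise ValidationError("gene list is empty")
    rare_genes = set(region_flags.loc[region_flags["is_rare"], "gene_symbol"])
    wanted = rare_genes & set(gene_list)
    hits = events[events["gene_symbol"].isin(wanted)].copy()
    group_of = dict(zip(groups["sample_id"], groups["group"]))
    hits["group"] = hits["sample_id"].map(group_of)
    cols = ["gene_symbol", "sample_id", "group", "state_class", "chrom", "start", "end"]
    return (
        hits[cols]
        .sort_values(["gene_symbol", "sample_id"], kind="mergesort")
        .reset_index(drop=True)
    )
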