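import numpy as np
import pandas as pd
import pytest

from cnvburden.simulate import SimConfig, generate_cohort


def make_calls(rows):
    """Build a call table from (sample, chrom, start, end, cn, n_probes) tuples.

    Coordinates are internal 0-based half-open.
    """
    df = pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start", "end", "copy_number", "n_probes"]
    )
    df["length_bp"] = df["end"] - df["start"]
    df["confidence"] = np.nan
    return df


def make_samples(rows):
    """Build a sample sheet from (sample_id, group) pairs with clean metrics."""
    df = pd.DataFrame(rows, columns=["sample_id", "group"])
    df["lrr_sd"] = 0.15
    df["baf_drift"] = 0.002
    df["waviness"] = 0.01
    return df


def make_transcripts(rows):
    """(transcript_id, gene_symbol, chrom, tx_start, tx_end) tuples to a frame."""
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "gene_symbol", "chrom", "tx_start", "tx_end"],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic synthetic cohort, small enough for fast tests."""
    cfg = SimConfig(
        seed=42,
        n_cases=40,
        n_controls=60,
        n_genes=60,
        genome=(("chr1", 12_000_000), ("chr2", 12_000_000)),
        mean_deletions_control=6.0,
        mean_gains_control=4.0,
        spiked_loci=((5, "loss", 0.5, 0.05),),
    )
    calls, samples, transcripts, truth = generate_cohort(cfg)
    return cfg, calls, samples, transcripts, truth
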