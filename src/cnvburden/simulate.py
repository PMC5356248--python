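"""Synthetic case-control CNV cohorts with known ground truth.

The generator emits everything the pipeline consumes — a transcript table,
a sample sheet with array-QC metrics, and a PennCNV-style call set — from a
single seed, so every stage can be tested end-to-end without array data.

The stated world
----------------
Defaults are calibrated to a young-onset breast cancer cohort of 200 cases
and 293 controls: control samples carry Poisson(12.4) deletions and
Poisson(8.5) duplications, cases have their deletion mean multiplied by 1.5
(and gains by 0.9); call sizes are log-normal (median ~33 kb, matching a
0.6-998 kb observed range); 34% of calls are placed to overlap a gene.
Copy numbers are hemizygous-biased: deletions are cn=1 with probability 0.9
(else 0), gains cn=3 with probability 0.9 (else 4).  Probe counts follow a
fixed density of one probe per 4 kb (minimum 3), so the "<5 probes" QC
filter removes small calls naturally.

Spiked association loci add one gene-spanning carrier call per carrier with
configured per-group carrier probabilities; spiked genes are excluded from
background genic placement so the realised carrier sets match the
configured probabilities.  A configurable fraction of samples receives QC
metrics violating one randomly chosen threshold.

Randomness is a single root seed feeding one spawned generator per sample,
so per-sample streams are reproducible independent of generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from cnvburden.errors import ValidationError
from cnvburden.io import write_penncnv_calls

DEFAULT_GENOME: tuple[tuple[str, int], ...] = tuple(
    (f"chr{i}", 30_000_000) for i in range(1, 9)
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated cohort (defaults = the stated world above)."""

    seed: int = 0
    n_cases: int = 200
    n_controls: int = 293
    n_genes: int = 500
    genome: tuple[tuple[str, int], ...] = DEFAULT_GENOME
    mean_deletions_control: float = 12.4
    mean_gains_control: float = 8.5
    deletion_enrichment: float = 1.5
    gain_enrichment: float = 0.9
    size_log_mean: float = 10.4  # natural log of bp; median ~33 kb
    size_log_sd: float = 1.1
    fraction_genic: float = 0.34
    spiked_loci: tuple[tuple[int, str, float, float], ...] = ()
    qc_fail_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("need at least one case and one control")
        if self.n_genes < 1 or not self.genome:
            raise ValidationError("need n_genes >= 1 and a non-empty genome")
        for rate in (
            self.mean_deletions_control,
            self.mean_gains_control,
        ):
            if rate <= 0:
                raise ValidationError("Poisson means must be positive")
        if self.deletion_enrichment < 0 or self.gain_enrichment < 0:
            raise ValidationError("enrichment multipliers must be >= 0")
        if not (0.0 <= self.fraction_genic <= 1.0):
            raise ValidationError("fraction_genic must lie in [0, 1]")
        if not (0.0 <= self.qc_fail_fraction <= 1.0):
            raise ValidationError("qc_fail_fraction must lie in [0, 1]")
        for gi, cls, p_case, p_ctrl in self.spiked_loci:
            if not (0 <= gi < self.n_genes):
                raise ValidationError(f"spiked gene index {gi} out of range")
            if cls not in ("loss", "gain"):
                raise ValidationError(f"spiked state class {cls!r} invalid")
            if not (0 <= p_case <= 1 and 0 <= p_ctrl <= 1):
                raise ValidationError("carrier probabilities must lie in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth recorded while generating a cohort.

    ``per_sample`` has the *emitted* deletion/gain counts per sample
    (background + spiked + any QC-failure padding), so recounting the
    rawcnv file reproduces it exactly.  ``spiked_carriers`` maps
    ``(gene_symbol, state_class)`` to the sample ids that received a spiked
    call.  ``qc_fail_samples`` lists samples given failing metrics.
    """

    per_sample: pd.DataFrame
    spiked_carriers: dict = field(default_factory=dict)
    deletion_enrichment: float = 1.0
    gain_enrichment: float = 1.0
    qc_fail_samples: list[str] = field(default_factory=list)


def _rngs(config: SimConfig):
    """Root-derived generators: (annotation, cohort-level, per-sample list)."""
    n = config.n_cases + config.n_controls
    children = np.random.SeedSequence(config.seed).spawn(n + 2)
    return (
        np.random.default_rng(children[0]),
        np.random.default_rng(children[1]),
        [np.random.default_rng(c) for c in children[2:]],
    )


def generate_annotation(config: SimConfig) -> pd.DataFrame:
    """Generate a refGene-style transcript table.

    Genes are laid out without overlap, spread over the genome proportional
    to chromosome length; each gene has 1-3 transcripts (the first spans the
    full gene, further ones are nested within it), so collapsing transcripts
    recovers exactly ``n_genes`` intervals.
    """
    rng, _, _ = _rngs(config)
    chroms = [c for c, _ in config.genome]
    lengths = np.array([l for _, l in config.genome], dtype=float)
    # proportional allocation, remainders to the largest chromosomes
    quota = config.n_genes * lengths / lengths.sum()
    per_chrom = np.floor(quota).astype(int)
    for i in np.argsort(quota - per_chrom)[::-1][: config.n_genes - per_chrom.sum()]:
        per_chrom[i] += 1
    rows = []
    gene_no = 0
    for chrom, chrom_len, n_here in zip(chroms, lengths.astype(int), per_chrom):
        if n_here == 0:
            continue
        slot = chrom_len // n_here
        if slot < 2_000:
            raise ValidationError(
                f"genome too small to place {config.n_genes} genes"
            )
        for j in range(n_here):
            max_len = int(0.6 * slot)
            glen = int(
                np.clip(rng.lognormal(np.log(30_000), 0.8), 1_000, max_len)
            )
            gstart = j * slot + int(rng.integers(0, slot - glen))
            gend = gstart + glen
            symbol = f"GENE{gene_no:04d}"
            n_tx = int(rng.integers(1, 4))
            rows.append((f"NM_{gene_no:05d}.1", symbol, chrom, gstart, gend))
            for t in range(1, n_tx):
                off1 = int(rng.integers(0, glen // 3 + 1))
                off2 = int(rng.integers(0, glen // 3 + 1))
                rows.append(
                    (
                        f"NM_{gene_no:05d}.{t + 1}",
                        symbol,
                        chrom,
                        gstart + off1,
                        gend - off2,
                    )
                )
            gene_no += 1
    return pd.DataFrame(
        rows, columns=["transcript_id", "gene_symbol", "chrom", "tx_start", "tx_end"]
    )


def _genes_from_annotation(transcripts: pd.DataFrame) -> pd.DataFrame:
    from cnvburden.annotate import collapse_transcripts

    genes = collapse_transcripts(transcripts)
    # restore generation order (GENE0000, GENE0001, ...) for index-based spiking
    return genes.sort_values("gene_symbol", kind="mergesort").reset_index(drop=True)


def _draw_call(rng, chroms, chrom_lens, genes, genic_ok, fraction_genic,
               size_log_mean, size_log_sd):
    """One background call: (chrom, start, end) with log-normal size."""
    size = max(600, int(rng.lognormal(size_log_mean, size_log_sd)))
    if len(genic_ok) and rng.random() < fraction_genic:
        g = genes.iloc[genic_ok[rng.integers(0, len(genic_ok))]]
        chrom = g["chrom"]
        chrom_len = chrom_lens[chrom]
        lo = max(0, g["start"] - size + 1)
        hi = min(g["end"] - 1, chrom_len - size)
        start = int(rng.integers(lo, max(lo, hi) + 1))
    else:
        ci = rng.integers(0, len(chroms))
        chrom = chroms[ci]
        chrom_len = chrom_lens[chrom]
        size = min(size, chrom_len - 1)
        start = int(rng.integers(0, chrom_len - size))
    return chrom, start, start + size


def _probe_count(size: int) -> int:
    # fixed probe density: 1 per 4 kb, minimum 3
    return max(3, int(round(size / 4_000)))


def generate_cohort(
    config: SimConfig, outdir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate one cohort: (calls, samples, transcripts, truth).

    ``calls`` uses the internal 0-based half-open convention and parses
    losslessly through the rawcnv writer/reader.  When ``outdir`` is given,
    ``calls.rawcnv``, ``samples.csv``, ``transcripts.tsv`` and
    ``truth.json`` are written there.
    """
    _, cohort_rng, sample_rngs = _rngs(config)
    transcripts = generate_annotation(config)
    genes = _genes_from_annotation(transcripts)
    chroms = [c for c, _ in config.genome]
    chrom_lens = dict(config.genome)
    spiked_idx = {gi for gi, *_ in config.spiked_loci}
    genic_ok = np.array(
        [i for i in range(len(genes)) if i not in spiked_idx], dtype=int
    )

    n_total = config.n_cases + config.n_controls
    sample_ids = [f"S{i:04d}" for i in range(n_total)]
    groups = ["case"] * config.n_cases + ["control"] * config.n_controls
    n_fail = int(round(config.qc_fail_fraction * n_total))
    fail_idx = set(
        cohort_rng.choice(n_total, size=n_fail, replace=False).tolist()
    ) if n_fail else set()

    call_rows = []
    truth_rows = []
    spiked_carriers: dict[tuple[str, str], list[str]] = {
        (genes.at[gi, "gene_symbol"], cls): []
        for gi, cls, _, _ in config.spiked_loci
    }
    metric_rows = []

    for i, (sid, group) in enumerate(zip(sample_ids, groups)):
        rng = sample_rngs[i]
        is_case = group == "case"
        mean_del = config.mean_deletions_control * (
            config.deletion_enrichment if is_case else 1.0
        )
        mean_gain = config.mean_gains_control * (
            config.gain_enrichment if is_case else 1.0
        )
        n_del = int(rng.poisson(mean_del))
        n_gain = int(rng.poisson(mean_gain))
        my_calls = []
        for kind, n in (("loss", n_del), ("gain", n_gain)):
            for _ in range(n):
                chrom, start, end = _draw_call(
                    rng, chroms, chrom_lens, genes, genic_ok,
                    config.fraction_genic, config.size_log_mean,
                    config.size_log_sd,
                )
                if kind == "loss":
                    cn = 1 if rng.random() < 0.9 else 0
                else:
                    cn = 3 if rng.random() < 0.9 else 4
                my_calls.append((sid, chrom, start, end, cn))
        # spiked locus carrier calls span the whole gene (recurrent CNV locus)
        for gi, cls, p_case, p_ctrl in config.spiked_loci:
            if rng.random() < (p_case if is_case else p_ctrl):
                g = genes.iloc[gi]
                pad = int(rng.integers(1_000, 10_000))
                start = max(0, int(g["start"]) - pad)
                end = min(chrom_lens[g["chrom"]], int(g["end"]) + pad)
                if end - start < 20_000:  # keep spiked calls QC-proof
                    end = min(chrom_lens[g["chrom"]], start + 20_000)
                cn = 1 if cls == "loss" else 3
                my_calls.append((sid, g["chrom"], start, end, cn))
                spiked_carriers[(g["gene_symbol"], cls)].append(sid)

        fail_reason = None
        if i in fail_idx:
            fail_reason = ("lrr_sd", "baf_drift", "waviness", "call_count")[
                rng.integers(0, 4)
            ]
        lrr = float(rng.uniform(0.12, 0.26))
        baf = float(rng.uniform(0.0005, 0.008))
        wav = float(rng.uniform(-0.035, 0.035))
        if fail_reason == "lrr_sd":
            lrr = float(rng.uniform(0.29, 0.40))
        elif fail_reason == "baf_drift":
            baf = float(rng.uniform(0.011, 0.02))
        elif fail_reason == "waviness":
            wav = float(rng.choice([-1, 1]) * rng.uniform(0.041, 0.08))
        elif fail_reason == "call_count":
            while len(my_calls) <= 70:  # pad with extra calls past the cut
                chrom, start, end = _draw_call(
                    rng, chroms, chrom_lens, genes, genic_ok,
                    config.fraction_genic, config.size_log_mean,
                    config.size_log_sd,
                )
                my_calls.append((sid, chrom, start, end, 1))

        call_rows.extend(my_calls)
        n_del_emitted = sum(1 for r in my_calls if r[4] <= 1)
        n_gain_emitted = len(my_calls) - n_del_emitted
        truth_rows.append((sid, group, n_del_emitted, n_gain_emitted))
        metric_rows.append((sid, group, lrr, baf, wav, len(my_calls)))

    calls = pd.DataFrame(
        call_rows, columns=["sample_id", "chrom", "start", "end", "copy_number"]
    )
    calls["n_probes"] = (calls["end"] - calls["start"]).map(_probe_count)
    calls["length_bp"] = calls["end"] - calls["start"]
    calls["confidence"] = np.nan

    samples = pd.DataFrame(
        metric_rows,
        columns=["sample_id", "group", "lrr_sd", "baf_drift", "waviness", "n_calls"],
    )
    truth = SimTruth(
        per_sample=pd.DataFrame(
            truth_rows, columns=["sample_id", "group", "n_deletions", "n_gains"]
        ),
        spiked_carriers=spiked_carriers,
        deletion_enrichment=config.deletion_enrichment,
        gain_enrichment=config.gain_enrichment,
        qc_fail_samples=[sample_ids[i] for i in sorted(fail_idx)],
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_penncnv_calls(calls, outdir / "calls.rawcnv")
        samples.to_csv(outdir / "samples.csv", index=False)
        tx = transcripts.rename(
            columns={
                "transcript_id": "name",
                "gene_symbol": "name2",
                "chrom": "chrom",
                "tx_start": "txStart",
                "tx_end": "txEnd",
            }
        )[["name", "chrom", "txStart", "txEnd", "name2"]]
        tx.to_csv(outdir / "transcripts.tsv", sep="\t", index=False)
        payload = {
            "config": {**asdict(config),
                       "genome": [list(g) for g in config.genome],
                       "spiked_loci": [list(s) for s in config.spiked_loci]},
            "per_sample": truth.per_sample.to_dict(orient="list"),
            "spiked_carriers": {
                f"{g}|{cls}": sids
                for (g, cls), sids in truth.spiked_carriers.items()
            },
            "qc_fail_samples": truth.qc_fail_samples,
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    return calls, samples, transcripts, truth


def analyze_cohort(
    calls: pd.DataFrame,
    samples: pd.DataFrame,
    transcripts: pd.DataFrame,
    spiked_genes: list[tuple[str, str]] | None = None,
    compute_or: bool = False,
):
    """Run the core pipeline stages in memory on one (synthetic) cohort.

    Returns a dict with the QC report, burden deletion ratio, the full
    association table, and — when ``spiked_genes`` (gene symbol, state
    class) pairs are given — the estimated OR and exact CI at each.
    ``compute_or=False`` (the default, for simulation sweeps) skips the
    conditional-MLE OR for non-spiked regions; their p-values are unaffected.
    """
    from cnvburden.annotate import assign_cnv_regions, collapse_transcripts
    from cnvburden.association import odds_ratio_cmle, run_association
    from cnvburden.qc import apply_qc

    kept_calls, report = apply_qc(calls, samples)
    kept_samples = samples[samples["sample_id"].isin(report.kept_samples)]
    genes = collapse_transcripts(transcripts)
    events = assign_cnv_regions(kept_calls, genes)

    del_counts = (
        kept_calls[kept_calls["copy_number"] <= 1]
        .groupby("sample_id")
        .size()
        .reindex(kept_samples["sample_id"], fill_value=0)
    )
    grp = kept_samples.set_index("sample_id")["group"]
    mean_case = del_counts[grp == "case"].mean()
    mean_ctrl = del_counts[grp == "control"].mean()

    assoc = run_association(events, kept_samples, compute_or=compute_or)
    out = {
        "qc_report": report,
        "deletion_ratio": float(mean_case / mean_ctrl) if mean_ctrl else np.nan,
        "association": assoc,
        "spiked": {},
    }
    if spiked_genes:
        n_case = int((kept_samples["group"] == "case").sum())
        n_ctrl = int((kept_samples["group"] == "control").sum())
        for gene, cls in spiked_genes:
            row = assoc[
                (assoc["gene_symbol"] == gene) & (assoc["state_class"] == cls)
            ]
            if len(row):
                rec = row.iloc[0].to_dict()
                if not compute_or:
                    a, c = int(rec["case_carriers"]), int(rec["control_carriers"])
                    rec["odds_ratio"], rec["ci_low"], rec["ci_high"] = (
                        odds_ratio_cmle(a, n_case - a, c, n_ctrl - c)
                    )
                out["spiked"][(gene, cls)] = rec
    return out
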