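"""Sample- and call-level quality control for CNV call sets.

Samples are excluded when any array-quality metric exceeds its threshold
(strict inequalities: a sample at exactly the threshold is kept):

* LRR standard deviation > 0.28
* BAF drift > 0.01
* |waviness factor| > 0.04
* raw CNV call count > 70

Calls are excluded when supported by fewer than 5 probes or spanning
>= 1 Mb (the probe criterion is strict-below, the size criterion
inclusive-at, matching the mixed "<5" / ">=1000 kb" convention).

Sample filtering runs first on raw call counts; call-level filters then
apply to calls of surviving samples, and the report records both stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from cnvburden.errors import ValidationError


@dataclass(frozen=True)
class QcThresholds:
    """Exclusion thresholds for sample- and call-level QC."""

    max_lrr_sd: float = 0.28
    max_baf_drift: float = 0.01
    max_abs_waviness: float = 0.04
    max_calls_per_sample: int = 70
    min_probes_per_call: int = 5
    max_call_length_bp: int = 1_000_000

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValidationError(f"QC threshold {name} must be strictly positive")


@dataclass
class QcReport:
    """Auditable record of what QC removed and why.

    ``excluded_samples`` maps each removed sample to *all* criteria it
    failed; ``excluded_calls`` tallies call-level exclusions per reason (a
    call failing both criteria counts once under each).
    """

    kept_samples: list[str] = field(default_factory=list)
    excluded_samples: dict[str, list[str]] = field(default_factory=dict)
    kept_calls: int = 0
    excluded_calls: dict[str, int] = field(default_factory=dict)

    def sample_frame(self) -> pd.DataFrame:
        """Excluded samples as a TSV-ready table (semicolon-joined reasons)."""
        return pd.DataFrame(
            {
                "sample_id": list(self.excluded_samples),
                "failed_criteria": [
                    ";".join(v) for v in self.excluded_samples.values()
                ],
            }
        )

    def summary(self) -> str:
        lines = [
            f"samples kept: {len(self.kept_samples)}",
            f"samples excluded: {len(self.excluded_samples)}",
            f"calls kept: {self.kept_calls}",
        ]
        for reason, n in sorted(self.excluded_calls.items()):
            lines.append(f"calls excluded ({reason}): {n}")
        return "\n".join(lines)


SAMPLE_CRITERIA = ("lrr_sd", "baf_drift", "waviness", "call_count")


def filter_samples(
    samples: pd.DataFrame,
    call_counts: pd.Series | dict[str, int],
    thresholds: QcThresholds = QcThresholds(),
) -> QcReport:
    """Partition samples into kept and excluded by the array-quality criteria.

    Parameters
    ----------
    samples
        Sample sheet frame with ``sample_id, lrr_sd, baf_drift, waviness``.
    call_counts
        Raw per-sample CNV call counts (zero allowed).  Every sample in
        ``samples`` must be present; extra keys are an error, since a sample
        with calls but no metrics cannot be assessed.
    """
    counts = pd.Series(call_counts, dtype=float)
    extra = set(counts.index) - set(samples["sample_id"])
    if extra:
        raise ValidationError(
            f"samples present in calls but absent from metrics: {sorted(extra)}"
        )
    report = QcReport()
    for row in samples.itertuples(index=False):
        failed = []
        if row.lrr_sd > thresholds.max_lrr_sd:
            failed.append("lrr_sd")
        if row.baf_drift > thresholds.max_baf_drift:
            failed.append("baf_drift")
        if abs(row.waviness) > thresholds.max_abs_waviness:
            failed.append("waviness")
        if counts.get(row.sample_id, 0) > thresholds.max_calls_per_sample:
            failed.append("call_count")
        if failed:
            report.excluded_samples[row.sample_id] = failed
        else:
            report.kept_samples.append(row.sample_id)
    return report


def filter_calls(
    calls: pd.DataFrame, thresholds: QcThresholds = QcThresholds()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop calls with too few probes or an excessive span.

    Returns the kept calls (original order) and a tally of exclusions per
    reason.
    """
    few_probes = calls["n_probes"] < thresholds.min_probes_per_call
    too_long = calls["length_bp"] >= thresholds.max_call_length_bp
    tally = {
        "few_probes": int(few_probes.sum()),
        "too_long": int(too_long.sum()),
    }
    kept = calls.loc[~(few_probes | too_long)].reset_index(drop=True)
    return kept, tally


def drop_calls_of_excluded_samples(
    calls: pd.DataFrame, report: QcReport
) -> pd.DataFrame:
    """Keep only calls whose sample survived sample-level QC."""
    return calls.loc[calls["sample_id"].isin(report.kept_samples)].reset_index(
        drop=True
    )


def apply_qc(
    calls: pd.DataFrame,
    samples: pd.DataFrame,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[pd.DataFrame, QcReport]:
    """Run the full QC stage: sample filters first, then call filters.

    The per-sample call count used by the ``>70 calls`` criterion is the raw
    count before any call-level filtering: the ``n_calls`` column of the
    sample sheet if present, else a recount of ``calls``.
    """
    if "n_calls" in samples.columns:
        counts = pd.Series(
            samples["n_calls"].values, index=samples["sample_id"].values
        )
    else:
        counts = calls["sample_id"].value_counts()
        counts = counts.reindex(samples["sample_id"], fill_value=0)
    unknown = set(calls["sample_id"]) - set(samples["sample_id"])
    if unknown:
        raise ValidationError(
            f"samples present in calls but absent from metrics: {sorted(unknown)}"
        )
    report = filter_samples(samples, counts, thresholds)
    surviving = drop_calls_of_excluded_samples(calls, report)
    kept, tally = filter_calls(surviving, thresholds)
    report.kept_calls = len(kept)
    report.excluded_calls = tally
    report.excluded_calls["excluded_sample"] = len(calls) - len(surviving)
    return kept, report
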