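"""Per-sample CNV burden metrics and case-vs-control comparisons.

For every sample the burden counts are: numbers of calls (all / deletions /
gains), numbers of calls overlapping at least one gene, numbers of distinct
genes overlapped, the mean call size, and rare-restricted versions of the
gene-overlap counts (events confined to rare regions).  Each metric is then
compared between cases and controls with a Welch unequal-variance t-test on
the per-sample values — each sample contributes one observation — yielding
group means, difference with 95% CI, case/control ratio, and the two-sided
p-value.

Sizes enter as each sample's mean call length, so the size comparison uses
the same per-sample unit as the count comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cnvburden.errors import ValidationError


@dataclass(frozen=True)
class WelchResult:
    """Welch two-sample t-test outcome for mean(x) - mean(y)."""

    t_stat: float
    df: float
    p_value: float
    diff: float
    ci_low: float
    ci_high: float


def welch_t_test(
    values_case: np.ndarray, values_control: np.ndarray, confidence: float = 0.95
) -> WelchResult:
    """Two-sided Welch t-test with Welch-Satterthwaite degrees of freedom.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2), with
    df = (s1^2/n1 + s2^2/n2)^2 / [ (s1^2/n1)^2/(n1-1) + (s2^2/n2)^2/(n2-1) ].
    The CI of the difference uses the t quantile at that df.  Two groups that
    are constant and equal give t = 0, p = 1 by convention.
    """
    x = np.asarray(values_case, dtype=float)
    y = np.asarray(values_control, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValidationError("Welch t-test needs >= 2 values per group")
    m1, m2 = x.mean(), y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    diff = m1 - m2
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        if diff == 0.0:
            return WelchResult(0.0, float(n1 + n2 - 2), 1.0, 0.0, 0.0, 0.0)
        t = np.inf if diff > 0 else -np.inf
        return WelchResult(t, float(n1 + n2 - 2), 0.0, diff, diff, diff)
    se = np.sqrt(se2)
    t = diff / se
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df)
    return WelchResult(t, df, min(p, 1.0), diff, diff - tcrit * se, diff + tcrit * se)


#: burden metric columns produced by :func:`per_sample_burden`
BURDEN_METRICS = [
    "n_cnvs_all", "n_cnvs_del", "n_cnvs_gain",
    "n_genic_all", "n_genic_del", "n_genic_gain",
    "n_genes_all", "n_genes_del", "n_genes_gain",
    "mean_size_all", "mean_size_del", "mean_size_gain",
    "n_rare_genic_all", "n_rare_genic_del", "n_rare_genic_gain",
    "n_rare_genes_all", "n_rare_genes_del", "n_rare_genes_gain",
]


def _class_mask(df: pd.DataFrame, cls: str, col: str = "copy_number") -> pd.Series:
    if cls == "all":
        return pd.Series(True, index=df.index)
    if cls == "del":
        return df[col] <= 1
    return df[col] >= 3


def per_sample_burden(
    calls: pd.DataFrame,
    events: pd.DataFrame,
    region_flags: pd.DataFrame,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Tabulate burden metrics for every sample in the sheet.

    Parameters
    ----------
    calls
        QC-passed call table.
    events
        Region event table from :func:`cnvburden.annotate.assign_cnv_regions`
        computed on the same calls.
    region_flags
        Per-region summary with ``is_rare`` from ``flag_rare_regions``.
    samples
        Sample sheet; samples with zero calls get all-zero counts (their mean
        sizes are NaN and drop out of size comparisons).
    """
    rare_genes = set(region_flags.loc[region_flags["is_rare"], "gene_symbol"])
    rare_events = events[events["gene_symbol"].isin(rare_genes)]
    rows = []
    calls_by = dict(iter(calls.groupby("sample_id", sort=False)))
    ev_by = dict(iter(events.groupby("sample_id", sort=False)))
    rev_by = dict(iter(rare_events.groupby("sample_id", sort=False)))
    empty_c = calls.iloc[0:0]
    empty_e = events.iloc[0:0]
    for sid in samples["sample_id"]:
        c = calls_by.get(sid, empty_c)
        e = ev_by.get(sid, empty_e)
        re_ = rev_by.get(sid, empty_e)
        row = {"sample_id": sid}
        for cls in ("all", "del", "gain"):
            cm = _class_mask(c, cls)
            em = _class_mask(e, cls)
            rm = _class_mask(re_, cls)
            cc = c[cm]
            ee = e[em]
            rr = re_[rm]
            row[f"n_cnvs_{cls}"] = len(cc)
            row[f"n_genic_{cls}"] = ee["call_index"].nunique()
            row[f"n_genes_{cls}"] = ee["gene_symbol"].nunique()
            row[f"mean_size_{cls}"] = (
                float(cc["length_bp"].mean()) if len(cc) else np.nan
            )
            row[f"n_rare_genic_{cls}"] = rr["call_index"].nunique()
            row[f"n_rare_genes_{cls}"] = rr["gene_symbol"].nunique()
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id"] + BURDEN_METRICS)


def burden_table(
    per_sample: pd.DataFrame,
    samples: pd.DataFrame,
    metrics: list[str] | None = None,
) -> pd.DataFrame:
    """Case-vs-control Welch comparison of every burden metric.

    Returns one row per metric with group means, total counts, difference in
    means with 95% CI, case/control ratio (NaN when the control mean is 0),
    Welch t, df, and two-sided p.
    """
    merged = per_sample.merge(
        samples[["sample_id", "group"]], on="sample_id", validate="one_to_one"
    )
    if merged["group"].isna().any() or len(merged) != len(per_sample):
        raise ValidationError("every sample needs a case/control group")
    cases = merged[merged["group"] == "case"]
    controls = merged[merged["group"] == "control"]
    if len(cases) < 2 or len(controls) < 2:
        raise ValidationError("each group needs >= 2 samples")
    rows = []
    for metric in metrics or BURDEN_METRICS:
        x = cases[metric].dropna().to_numpy(dtype=float)
        y = controls[metric].dropna().to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            continue
        w = welch_t_test(x, y)
        m1, m2 = x.mean(), y.mean()
        rows.append(
            {
                "metric": metric,
                "total_case": x.sum(),
                "total_control": y.sum(),
                "mean_case": m1,
                "mean_control": m2,
                "diff": w.diff,
                "diff_ci_low": w.ci_low,
                "diff_ci_high": w.ci_high,
                "ratio": m1 / m2 if m2 != 0 else np.nan,
                "t_stat": w.t_stat,
                "df": w.df,
                "p_value": w.p_value,
            }
        )
    return pd.DataFrame(rows)


def size_summary(
    calls: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Case-vs-control comparison of per-sample mean call sizes per class.

    Convenience wrapper: computes only the ``mean_size_*`` rows of
    :func:`burden_table` directly from a call table.
    """
    rows = []
    for sid, c in calls.groupby("sample_id", sort=False):
        row = {"sample_id": sid}
        for cls in ("all", "del", "gain"):
            sub = c[_class_mask(c, cls)]
            row[f"mean_size_{cls}"] = (
                float(sub["length_bp"].mean()) if len(sub) else np.nan
            )
        rows.append(row)
    per_sample = pd.DataFrame(
        rows, columns=["sample_id", "mean_size_all", "mean_size_del", "mean_size_gain"]
    )
    per_sample = per_sample.merge(
        samples[["sample_id"]], on="sample_id", how="right"
    )
    return burden_table(
        per_sample, samples, metrics=["mean_size_all", "mean_size_del", "mean_size_gain"]
    )
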