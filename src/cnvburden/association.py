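"""Gene-region carrier association with exact statistics.

For each gene-boundary CNV region and state class (loss / gain) the cohort
is reduced to a 2x2 carrier table

    =========  ========  ============
    .          carrier   non-carrier
    =========  ========  ============
    cases      a         b
    controls   c         d
    =========  ========  ============

where a carrier is a sample with at least one event of the class in the
region.  The table is tested with the two-sided Fisher exact test; the
effect size is the conditional maximum-likelihood odds ratio (the value of
the noncentral hypergeometric parameter that makes the expected first cell
equal the observed one, conditioning on both margins — the convention of
R's ``fisher.test``), with an exact confidence interval obtained by
inverting the one-sided exact tests.  P-values across all emitted tables
are adjusted with the Benjamini-Yekutieli step-up procedure, which controls
the false discovery rate under arbitrary dependence.

All tail computations run in log space via ``gammaln``/``logsumexp``, so
tables of any size are overflow-safe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

from cnvburden.errors import ValidationError

#: relative tolerance when comparing table probabilities in the two-sided tail
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """Carrier 2x2 table for one gene region and one state class."""

    gene_symbol: str
    state_class: str
    a: int  # case carriers
    b: int  # case non-carriers
    c: int  # control carriers
    d: int  # control non-carriers

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency cells must be non-negative")


def _support_logw(a: int, b: int, c: int, d: int):
    """Support of the first cell given fixed margins, with log hypergeometric weights."""
    m1, m2, k = a + b, c + d, a + c
    if m1 == 0 or m2 == 0 or k == 0 or b + d == 0:
        raise ValidationError("all margins of the 2x2 table must be positive")
    lo, hi = max(0, k - m2), min(k, m1)
    x = np.arange(lo, hi + 1)
    logw = (
        gammaln(m1 + 1) - gammaln(x + 1) - gammaln(m1 - x + 1)
        + gammaln(m2 + 1) - gammaln(k - x + 1) - gammaln(m2 - k + x + 1)
    )
    return x, logw


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums the central hypergeometric probabilities of every table with the
    same margins whose probability does not exceed the observed table's
    (ties compared with relative tolerance 1e-7).
    """
    x, logw = _support_logw(a, b, c, d)
    logp = logw - logsumexp(logw)
    log_obs = logp[a - x[0]]
    in_tail = logp <= log_obs + np.log1p(_TIE_RTOL)
    return float(min(1.0, np.exp(logsumexp(logp[in_tail]))))


def _log_expected_minus_a(theta: float, x, logw, a: int) -> float:
    """E_psi[X] - a at log-odds-ratio theta, computed stably."""
    lp = logw + theta * x
    lp -= lp.max()
    w = np.exp(lp)
    return float((w * x).sum() / w.sum() - a)


def _log_tail(theta: float, x, logw, a: int, upper: bool) -> float:
    """P(X >= a | psi) if upper else P(X <= a | psi), psi = exp(theta)."""
    lp = logw + theta * x
    lp -= logsumexp(lp)
    mask = x >= a if upper else x <= a
    return float(np.exp(logsumexp(lp[mask])))


def _solve(f, lo: float = -1.0, hi: float = 1.0) -> float:
    """Root of a monotone function of theta, expanding the bracket as needed."""
    flo, fhi = f(lo), f(hi)
    for _ in range(200):
        if flo == 0.0:
            return lo
        if fhi == 0.0:
            return hi
        if flo * fhi < 0:
            return brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
        if abs(flo) < abs(fhi):
            lo, hi = 2 * lo - hi, lo
            flo, fhi = f(lo), flo
        else:
            lo, hi = hi, 2 * hi - lo
            flo, fhi = fhi, f(hi)
    raise RuntimeError("could not bracket the odds-ratio root")


def odds_ratio_cmle(
    a: int, b: int, c: int, d: int, confidence: float = 0.95
) -> tuple[float, float, float]:
    """Conditional-MLE odds ratio with exact confidence interval.

    Returns ``(estimate, ci_low, ci_high)``.  The estimate is the noncentral
    hypergeometric parameter under which the conditional expectation of the
    first cell equals the observed ``a``; the CI limits invert the one-sided
    exact tests at (1 - confidence)/2 per side.  When ``a`` sits at the
    lower end of its support the estimate is 0 (lower limit 0); at the upper
    end it is ``inf`` (upper limit ``inf``).
    """
    x, logw = _support_logw(a, b, c, d)
    lo_sup, hi_sup = int(x[0]), int(x[-1])
    alpha = (1.0 - confidence) / 2.0

    if a == lo_sup:
        est = 0.0
    elif a == hi_sup:
        est = np.inf
    else:
        est = float(np.exp(_solve(lambda t: _log_expected_minus_a(t, x, logw, a))))

    if a == lo_sup:
        ci_low = 0.0
    else:
        # largest psi still rejected by the lower one-sided test
        ci_low = float(
            np.exp(_solve(lambda t: _log_tail(t, x, logw, a, upper=True) - alpha))
        )
    if a == hi_sup:
        ci_high = np.inf
    else:
        ci_high = float(
            np.exp(_solve(lambda t: _log_tail(t, x, logw, a, upper=False) - alpha))
        )
    return est, ci_low, ci_high


def by_fdr(p_values) -> np.ndarray:
    """Benjamini-Yekutieli adjusted p-values, in the input order.

    With m tests and c(m) = sum_{i=1..m} 1/i, the sorted p-values become
    adj_(i) = min(1, min_{j >= i} m * c(m) * p_(j) / j).  Output is monotone
    in the input p-values and always >= the Benjamini-Hochberg adjustment.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    m = len(p)
    cm = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m * cm / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


def build_contingency(
    region_events: pd.DataFrame,
    groups: pd.DataFrame,
    mode: str = "each_state",
) -> list[ContingencyTable]:
    """Reduce one region's events to carrier 2x2 table(s).

    ``mode="each_state"`` emits one table per state class present in the
    region (so a region with both deletions and gains is tested twice);
    ``mode="dominant_state"`` emits only the class with more events, with
    ties resolved to loss.  Carriers are counted at sample level: a sample
    with several events of a class in the region contributes once.
    """
    if mode not in ("each_state", "dominant_state"):
        raise ValidationError(f"unknown contingency mode {mode!r}")
    if region_events.empty:
        raise ValidationError("region has no events")
    group_of = dict(zip(groups["sample_id"], groups["group"]))
    missing = set(region_events["sample_id"]) - set(group_of)
    if missing:
        raise ValidationError(f"samples without a group: {sorted(missing)}")
    n_cases = int((groups["group"] == "case").sum())
    n_controls = int((groups["group"] == "control").sum())
    gene = region_events["gene_symbol"].iloc[0]

    counts = region_events.groupby("state_class")["sample_id"].size()
    if mode == "dominant_state":
        classes = [
            "loss"
            if counts.get("loss", 0) >= counts.get("gain", 0)
            else "gain"
        ]
    else:
        classes = [c for c in ("loss", "gain") if counts.get(c, 0) > 0]

    tables = []
    for cls in classes:
        carriers = set(
            region_events.loc[region_events["state_class"] == cls, "sample_id"]
        )
        a = sum(1 for s in carriers if group_of[s] == "case")
        c = len(carriers) - a
        tables.append(
            ContingencyTable(gene, cls, a, n_cases - a, c, n_controls - c)
        )
    return tables


def run_association(
    events: pd.DataFrame,
    groups: pd.DataFrame,
    mode: str = "each_state",
    alpha: float = 0.05,
    min_events: int = 1,
    confidence: float = 0.95,
    compute_or: bool = True,
) -> pd.DataFrame:
    """Test every gene region for case-control carrier-frequency differences.

    Emits one row per (region, state class) table with carrier counts, the
    conditional-MLE odds ratio and exact CI, the two-sided Fisher p, and the
    BY-adjusted p computed jointly over all emitted tables.  Results are
    sorted by p-value; ``significant`` flags adjusted p < alpha.  Regions
    with fewer than ``min_events`` events are not tested.  ``compute_or``
    can be switched off in large simulation sweeps that only need p-values.
    """
    if events.empty:
        raise ValidationError("no region events to test")
    rows = []
    for gene, region_events in events.groupby("gene_symbol", sort=False):
        if len(region_events) < min_events:
            continue
        for tab in build_contingency(region_events, groups, mode=mode):
            p = fisher_exact_two_sided(tab.a, tab.b, tab.c, tab.d)
            if compute_or:
                or_est, ci_lo, ci_hi = odds_ratio_cmle(
                    tab.a, tab.b, tab.c, tab.d, confidence=confidence
                )
            else:
                or_est = ci_lo = ci_hi = np.nan
            rows.append(
                {
                    "gene_symbol": gene,
                    "state_class": tab.state_class,
                    "case_carriers": tab.a,
                    "control_carriers": tab.c,
                    "odds_ratio": or_est,
                    "ci_low": ci_lo,
                    "ci_high": ci_hi,
                    "p_value": p,
                }
            )
    results = pd.DataFrame(rows)
    if results.empty:
        return results
    results["p_adjusted"] = by_fdr(results["p_value"].to_numpy())
    results["significant"] = results["p_adjusted"] < alpha
    return results.sort_values(
        "p_value", kind="mergesort", ignore_index=True
    )
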