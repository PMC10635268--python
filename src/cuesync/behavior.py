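"""Inter-subject correlation and its relation to behavior.

Leave-one-out ISC: each subject's projected series is correlated with
the mean series of the rest of their group; per-ROI values are
aggregated over an ROI set (e.g. all OFC parcels) by Fisher
z-transforming, averaging, and inverse-transforming.  The aggregated
score (and its between-session change) is then correlated with craving
measures under BH-FDR.  Utilities for sample-description statistics
(pooled two-sample t from summary statistics, paired Wilcoxon
signed-rank) live here as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bias import fdr_bh


@dataclass
class IscScore:
    """Per-subject leave-one-out ISC, per ROI and aggregated."""

    subject_id: str
    session: str
    per_roi_r: dict = field(default_factory=dict)
    aggregate_r: float = float("nan")


@dataclass
class WilcoxonResult:
    """Wilcoxon signed-rank test summary (zero differences dropped)."""

    statistic: float  # min(w_plus, w_minus)
    p_value: float
    w_plus: float
    w_minus: float
    n_used: int
    method: str


def loo_isc(series) -> np.ndarray:
    """Leave-one-out ISC per subject.

    For each subject, the Pearson correlation between their series and
    the mean of all other subjects' series.  Constant series yield NaN
    with a warning.
    """
    values = np.atleast_2d(np.asarray(getattr(series, "values", series), dtype=float))
    n_subj, n_trs = values.shape
    if n_subj < 3:
        raise ValueError("leave-one-out ISC requires at least 3 subjects")
    total = values.sum(axis=0)
    out = np.empty(n_subj)
    for i in range(n_subj):
        rest = (total - values[i]) / (n_subj - 1)
        if np.std(values[i]) == 0 or np.std(rest) == 0:
            warnings.warn(f"constant series for subject {i}; ISC undefined", RuntimeWarning)
            out[i] = np.nan
            continue
        out[i] = np.corrcoef(values[i], rest)[0, 1]
    return out


def fisher_aggregate(r_values) -> float:
    """Aggregate correlations via Fisher z: tanh(mean(atanh(r)))."""
    r = np.asarray(list(np.atleast_1d(r_values)), dtype=float)
    if r.size == 0:
        raise ValueError("no correlations to aggregate")
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher transform; clip upstream")
    return float(np.tanh(np.mean(np.arctanh(r))))


def isc_behavior_correlations(
    isc: pd.DataFrame,
    behavior: pd.DataFrame,
    measures: list[str],
    sessions: tuple[str, str] = ("baseline", "followup"),
    q: float = 0.05,
) -> pd.DataFrame:
    """Correlate aggregated ISC with craving measures, with BH-FDR.

    ``isc`` has columns (subject_id, session, isc).  For each measure,
    the baseline Pearson correlation and the correlation of
    between-session deltas (second minus first session, for both
    variables) are computed; BH-FDR is applied over the whole family.
    Requires at least 4 paired observations per correlation.
    """
    s1, s2 = sessions
    merged = behavior.merge(isc, on=["subject_id", "session"], how="inner")
    rows = []
    for measure in measures:
        if measure not in merged.columns:
            raise KeyError(f"measure {measure!r} not in behavior table")
        base = merged[merged["session"] == s1].dropna(subset=[measure, "isc"])
        for kind, x, y in _correlation_pairs(merged, measure, s1, s2, base):
            if len(x) < 4:
                raise ValueError(
                    f"fewer than 4 paired observations for {measure} ({kind})"
                )
            r, p = stats.pearsonr(x, y)
            # parametric p underflows to 0 for perfect correlations
            p = max(float(p), 5e-324)
            rows.append(
                {"measure": measure, "session_or_delta": kind, "n": len(x), "r": r, "p": p}
            )
    table = pd.DataFrame(rows)
    q_values, reject = fdr_bh(table["p"].to_numpy(), q=q)
    table["q"] = q_values
    table["significant"] = reject
    return table


def _correlation_pairs(merged, measure, s1, s2, base):
    yield "baseline", base["isc"].to_numpy(), base[measure].to_numpy()
    wide = merged.pivot_table(
        index="subject_id", columns="session", values=["isc", measure], aggfunc="first"
    )
    try:
        isc_delta = wide[("isc", s2)] - wide[("isc", s1)]
        meas_delta = wide[(measure, s2)] - wide[(measure, s1)]
    except KeyError:
        return
    ok = isc_delta.notna() & meas_delta.notna()
    yield "delta", isc_delta[ok].to_numpy(), meas_delta[ok].to_numpy()


def pooled_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int]:
    """Classic pooled two-sample t statistic from summary statistics.

    t = (mean1 - mean2) / sqrt(s2p (1/n1 + 1/n2)), with the pooled
    variance s2p = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2) and
    df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("SDs must be positive")
    df = n1 + n2 - 2
    s2p = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (mean1 - mean2) / np.sqrt(s2p * (1.0 / n1 + 1.0 / n2))
    return float(t), int(df)


def _signed_rank_exact_p(ranks2: np.ndarray, w2_plus: float, alternative: str) -> float:
    """Exact signed-rank p by dynamic programming over doubled ranks.

    ``ranks2`` are mid-ranks doubled to integers, so ties are handled
    exactly.  Enumerates the distribution of 2*W+ over all equally
    likely sign assignments.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    counts /= counts.sum()
    w = int(round(w2_plus))
    p_le = counts[: w + 1].sum()
    p_ge = counts[w:].sum()
    if alternative == "greater":
        return float(p_ge)
    if alternative == "less":
        return float(p_le)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def paired_nonparametric(delta_values, alternative: str = "two-sided") -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; ties get mid-ranks.  The p-value is
    exact (enumeration of all sign assignments, ties handled) when at
    most 25 nonzero deltas remain, else the normal approximation with
    tie correction.  ``alternative='greater'`` tests for positive
    deltas.
    """
    d = np.asarray(list(delta_values), dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("deltas contain non-finite values")
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all deltas are zero; test undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    if n <= 25:
        ranks2 = np.round(2 * ranks).astype(int)
        p = _signed_rank_exact_p(ranks2, 2 * w_plus, alternative)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        z = (w_plus - mu) / np.sqrt(var)
        if alternative == "greater":
            p = float(stats.norm.sf(z))
        elif alternative == "less":
            p = float(stats.norm.cdf(z))
        else:
            p = float(2 * stats.norm.sf(abs(z)))
        method = "normal-approximation"
    return WilcoxonResult(
        statistic=min(w_plus, w_minus),
        p_value=min(1.0, p),
        w_plus=w_plus,
        w_minus=w_minus,
        n_used=n,
        method=method,
    )
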