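"""Replicate-free differential abundance testing against a Laplace null.

Without biological replicates, the technical-noise distribution of protein
log-ratios is estimated from three 1 g control samples processed
identically, under the assumption that measurement error is identically
distributed across proteins and conditions. The pooled control log-ratios
are fitted by a Laplace distribution (maximum likelihood: location = median,
scale = mean absolute deviation from the median), which matches the
heavy-tailed Q-Q behaviour of such ratios better than a Normal. Two-sided
p-values follow in closed form,

    p(x) = exp(-|x - mu| / b),

since P(|X - mu| >= t) = exp(-t/b) for X ~ Laplace(mu, b). Benjamini-
Hochberg correction is applied within each comparison family, and a protein
is called over- (under-) represented in microgravity only when both of its
microgravity-versus-1 g ratios are significant in the same direction while
the 1 g space / 1 g ground ratio is not significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import CONTROL_SAMPLES, ONEG_GROUND, ONEG_SPACE, UG_SPACE

COMPARISONS = (
    ("ug_vs_1gspace", UG_SPACE, ONEG_SPACE),
    ("ug_vs_1gground", UG_SPACE, ONEG_GROUND),
    ("1gspace_vs_1gground", ONEG_SPACE, ONEG_GROUND),
)


class NullEstimationError(ValueError):
    pass


@dataclass
class LaplaceNull:
    """Fitted technical-noise distribution of control log-ratios."""

    location: float
    scale: float
    n_ratios: int
    qq_correlation_laplace: float = np.nan
    qq_correlation_normal: float = np.nan


@dataclass
class QQDiagnostic:
    positions: np.ndarray
    empirical: np.ndarray
    laplace_theoretical: np.ndarray
    normal_theoretical: np.ndarray
    correlation_laplace: float
    correlation_normal: float
    closer_law: str


def condition_means(matrix) -> pd.DataFrame:
    """Mean natural-log abundance per protein per condition.

    The mean runs over every fraction run (and, for the 1 g space
    condition, every control sample) where the protein was quantified.
    Log first, then average. Returns a frame with one row per (protein,
    condition) profile carrying ``mean_log_abundance`` and
    ``n_fractions_used``; proteins absent from a condition have no row.
    """
    ab = matrix.abundance if hasattr(matrix, "abundance") else matrix
    if (ab.values[~np.isnan(ab.values)] <= 0).any():
        raise ValueError("abundances must be strictly positive where present")
    log_ab = np.log(ab)
    cond = log_ab.T.groupby(level="condition")
    means = cond.mean().T
    counts = cond.count().T
    rows = []
    for condition in means.columns:
        present = counts[condition] > 0
        rows.append(pd.DataFrame({
            "protein_accession": means.index[present],
            "condition": condition,
            "mean_log_abundance": means.loc[present, condition].values,
            "n_fractions_used": counts.loc[present, condition].values,
        }))
    return pd.concat(rows, ignore_index=True)


def sample_mean_logs(matrix, samples=CONTROL_SAMPLES) -> pd.DataFrame:
    """Per-protein mean log abundance within each listed sample."""
    ab = matrix.abundance if hasattr(matrix, "abundance") else matrix
    sub = ab.loc[:, ab.columns.get_level_values("sample").isin(samples)]
    log_ab = np.log(sub)
    return log_ab.T.groupby(level="sample").mean().T


def control_log_ratios(matrix, samples=CONTROL_SAMPLES) -> np.ndarray:
    """Pooled log-ratios between the control samples.

    For every protein quantified in at least two control samples, the
    log-ratio of each unordered sample pair (earlier sample minus later
    sample, fixed ordering) is emitted, pooled across proteins.
    """
    per_sample = sample_mean_logs(matrix, samples)
    samples = [s for s in sorted(samples) if s in per_sample.columns]
    if len(samples) < 2:
        raise NullEstimationError(
            "need at least two control samples with quantified proteins")
    pairs = [(samples[i], samples[j])
             for i in range(len(samples)) for j in range(i + 1, len(samples))]
    # order as (1,2),(2,3),(1,3) for three samples
    if len(samples) == 3:
        pairs = [(samples[0], samples[1]), (samples[1], samples[2]),
                 (samples[0], samples[2])]
    out = []
    for a, b in pairs:
        d = (per_sample[a] - per_sample[b]).dropna().values
        out.append(d)
    ratios = np.concatenate(out) if out else np.array([])
    if ratios.size == 0:
        raise NullEstimationError("no protein shared between control samples")
    return ratios


def fit_laplace(ratios: np.ndarray) -> LaplaceNull:
    """Maximum-likelihood Laplace fit with Q-Q diagnostics.

    location = sample median; scale = mean |x - median|. A Normal fitted by
    moments provides the competing law for the quantile-correlation
    diagnostic.
    """
    ratios = np.asarray(ratios, dtype=float)
    if len(ratios) < 10:
        raise NullEstimationError("need at least 10 control log-ratios")
    if np.allclose(ratios, ratios[0]):
        raise NullEstimationError("degenerate null: all ratios identical")
    mu = float(np.median(ratios))
    b = float(np.mean(np.abs(ratios - mu)))
    null = LaplaceNull(location=mu, scale=b, n_ratios=len(ratios))
    qq = qq_diagnostic(ratios, null)
    null.qq_correlation_laplace = qq.correlation_laplace
    null.qq_correlation_normal = qq.correlation_normal
    return null


def laplace_pvalue(x, null: LaplaceNull):
    """Two-sided tail probability of a log-ratio under the fitted null."""
    if null.scale <= 0:
        raise ValueError("null scale must be > 0")
    return np.exp(-np.abs(np.asarray(x, dtype=float) - null.location)
                  / null.scale)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def qq_diagnostic(ratios: np.ndarray, null: LaplaceNull | None = None
                  ) -> QQDiagnostic:
    """Quantile-quantile comparison of the ratios against Laplace and
    Normal candidates, at plotting positions (i - 0.5)/n.

    Both laws are located/scaled from the data (Laplace: median and mean
    absolute deviation; Normal: mean and standard deviation), so the
    correlations are invariant under constant shifts of the sample.
    """
    ratios = np.sort(np.asarray(ratios, dtype=float))
    n = len(ratios)
    if n < 10:
        raise ValueError("need at least 10 ratios for a Q-Q diagnostic")
    pos = (np.arange(1, n + 1) - 0.5) / n
    if null is None:
        mu = np.median(ratios)
        b = np.mean(np.abs(ratios - mu))
    else:
        mu, b = null.location, null.scale
    lap_q = stats.laplace.ppf(pos, loc=mu, scale=b)
    norm_q = stats.norm.ppf(pos, loc=np.mean(ratios), scale=np.std(ratios, ddof=1))
    c_lap = float(np.corrcoef(lap_q, ratios)[0, 1])
    c_norm = float(np.corrcoef(norm_q, ratios)[0, 1])
    return QQDiagnostic(
        positions=pos, empirical=ratios, laplace_theoretical=lap_q,
        normal_theoretical=norm_q, correlation_laplace=c_lap,
        correlation_normal=c_norm,
        closer_law="laplace" if c_lap >= c_norm else "normal")


def differential_table(matrix, null: LaplaceNull | None = None,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Per-protein log-ratios, raw and BH-adjusted p-values, and calls.

    The testable set is the proteins quantified in all three conditions;
    BH correction is applied separately within each of the three comparison
    families over that set. If ``null`` is omitted it is fitted from the
    control samples of the matrix itself.
    """
    if null is None:
        null = fit_laplace(control_log_ratios(matrix))
    prof = condition_means(matrix)
    wide = prof.pivot(index="protein_accession", columns="condition",
                      values="mean_log_abundance")
    records = pd.DataFrame(index=wide.index)
    testable = wide.notna().all(axis=1)
    for name, num, den in COMPARISONS:
        r = wide[num] - wide[den]
        records[f"ratio_{name}"] = np.exp(r)
        records[f"log_ratio_{name}"] = r
        p = pd.Series(np.nan, index=wide.index)
        p.loc[testable] = laplace_pvalue(r[testable].values, null)
        records[f"p_raw_{name}"] = p
        padj = pd.Series(np.nan, index=wide.index)
        if testable.any():
            padj.loc[testable] = bh_adjust(p[testable].values)
        records[f"p_adj_{name}"] = padj
    records["call"] = call_proteins(records, alpha=alpha)
    return records.reset_index().rename(
        columns={records.index.name or "index": "protein_accession"})


def call_proteins(records: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Dual-condition selection rule.

    over: both microgravity-vs-1 g comparisons significant (BH < alpha)
    with positive log-ratios AND the 1 g/1 g comparison not significant
    (BH > alpha); under: symmetric with negative log-ratios; anything
    discordant is unchanged; proteins missing any comparison are
    untestable.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    cols_p = [f"p_adj_{name}" for name, _, _ in COMPARISONS]
    cols_r = [f"log_ratio_{name}" for name, _, _ in COMPARISONS]
    p1, p2, p3 = (records[c] for c in cols_p)
    r1, r2, _ = (records[c] for c in cols_r)
    complete = pd.concat([records[c].notna() for c in cols_p + cols_r],
                         axis=1).all(axis=1)
    sig_both = (p1 < alpha) & (p2 < alpha) & (p3 > alpha)
    over = complete & sig_both & (r1 > 0) & (r2 > 0)
    under = complete & sig_both & (r1 < 0) & (r2 < 0)
    call = pd.Series("unchanged", index=records.index, dtype=object)
    call[over] = "over"
    call[under] = "under"
    call[~complete] = "untestable"
    return call
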