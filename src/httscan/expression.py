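"""Count normalization and the max-fold-change differential-expression screen.

The screen statistic is deliberately simple: for each transcript, counts
are summarized per experimental group (mean of normalized counts over the
group's samples) and

    max fold change (MFC) = maximum group count / minimum group count,

with a pseudocount of one replacing a zero minimum.  MFC >= 1 always, so a
threshold sweep starting at 1 includes every transcript and the retained
proportion is non-increasing in the threshold.

Normalization is TMM (trimmed mean of M-values), re-implemented here: each
sample's log2 expression ratios (M) against a reference sample are trimmed
at the extremes of both M (default 30 % each tail) and average abundance A
(default 5 % each tail) before averaging, which makes the scaling factor
robust to a minority of genuinely differential genes.  Factors are rescaled
to geometric mean one, and normalized counts are raw counts divided by
(factor x relative library size).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CountMatrix


@dataclass
class ExpressionStats:
    """Per-transcript MFC summary plus the sample normalization factors."""

    table: pd.DataFrame          # columns: max_count, min_count, max_fold_change
    factors: pd.Series           # per-sample TMM factor
    group_values: pd.DataFrame   # transcripts x groups summary counts

    @property
    def mfc(self) -> pd.Series:
        return self.table["max_fold_change"]


def tmm_normalize(matrix: CountMatrix, trim_m: float = 0.30,
                  trim_a: float = 0.05
                  ) -> tuple[pd.Series, pd.DataFrame]:
    """TMM factors (geometric mean 1) and the normalized count matrix.

    The reference sample is the one whose upper-quartile of library-scaled
    counts is closest to the mean upper-quartile.  A sample with no reads
    at all is an error.
    """
    counts = matrix.counts.astype(float)
    libsize = counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"samples with all-zero counts: {list(zero.index)}")
    scaled = counts.div(libsize, axis=1)
    uq = scaled.quantile(0.75)
    ref = (uq - uq.mean()).abs().idxmin()

    log_factors = {}
    for sample in counts.columns:
        if sample == ref:
            log_factors[sample] = 0.0
            continue
        y, yr = counts[sample], counts[ref]
        mask = (y > 0) & (yr > 0)
        if not mask.any():
            log_factors[sample] = 0.0
            continue
        ys = y[mask] / libsize[sample]
        yrs = yr[mask] / libsize[ref]
        m = np.log2(ys / yrs)
        a = 0.5 * np.log2(ys * yrs)
        lo_m, hi_m = m.quantile(trim_m), m.quantile(1 - trim_m)
        lo_a, hi_a = a.quantile(trim_a), a.quantile(1 - trim_a)
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        log_factors[sample] = float(m[keep].mean()) if keep.any() else 0.0

    logf = pd.Series(log_factors).loc[counts.columns]
    logf = logf - logf.mean()                 # geometric mean 1 (log2 scale)
    factors = np.exp2(logf)
    rel_lib = libsize / np.exp(np.log(libsize).mean())
    normalized = counts.div(factors * rel_lib, axis=1)
    return factors, normalized


def max_fold_change(group_counts: Sequence[float]) -> float:
    """MFC over per-group counts; a zero minimum takes a pseudocount of one
    (and an all-zero transcript therefore scores exactly 1)."""
    vals = list(group_counts)
    if len(vals) < 2:
        raise ValueError("max_fold_change needs counts from >= 2 groups")
    if any(v < 0 for v in vals):
        raise ValueError("counts must be non-negative")
    hi, lo = max(vals), min(vals)
    if hi == 0:           # all-zero transcript: pseudocounts top and bottom
        return 1.0
    return hi / (lo if lo > 0 else 1.0)


def group_summary(matrix: CountMatrix, normalized: bool = True
                  ) -> tuple[pd.DataFrame, pd.Series]:
    """(transcripts x groups mean-count table, TMM factors).  With
    ``normalized=False`` raw counts are averaged and factors are all 1."""
    if normalized:
        factors, table = tmm_normalize(matrix)
    else:
        factors = pd.Series(1.0, index=matrix.counts.columns)
        table = matrix.counts.astype(float)
    cols = {g: table[matrix.samples_in_group(g)].mean(axis=1)
            for g in matrix.group_order}
    return pd.DataFrame(cols, columns=matrix.group_order), factors


def expression_stats(matrix: CountMatrix, normalized: bool = True
                     ) -> ExpressionStats:
    """Per-transcript group summaries and MFC for a whole count matrix."""
    if len(matrix.group_order) < 2:
        raise ValueError("expression_stats needs >= 2 groups")
    group_values, factors = group_summary(matrix, normalized=normalized)
    hi = group_values.max(axis=1)
    lo = group_values.min(axis=1)
    lo_pc = lo.where(lo > 0, 1.0)
    mfc = hi.where(hi > 0, 1.0) / lo_pc
    table = pd.DataFrame({
        "max_count": hi, "min_count": lo_pc, "max_fold_change": mfc})
    return ExpressionStats(table=table, factors=factors,
                           group_values=group_values)


_NESTING = [("HTT", "TE"), ("TE", "overall")]


def threshold_sweep(stats: ExpressionStats,
                    sets: Mapping[str, Iterable[str]],
                    thresholds: Sequence[float] = tuple(range(1, 41)),
                    ) -> pd.DataFrame:
    """Proportion of each named transcript set at or above each MFC
    threshold (rows: thresholds, columns: set names).

    Sets must be non-empty subsets of the stats index; when the
    conventional overall/TE/HTT names are present their nesting
    (HTT within TE within overall) is enforced.
    """
    mfc = stats.mfc
    resolved: dict[str, set[str]] = {}
    for name, ids in sets.items():
        ids = set(ids)
        if not ids:
            raise ValueError(f"set {name!r} is empty")
        unknown = ids - set(mfc.index)
        if unknown:
            raise ValueError(
                f"set {name!r} has ids absent from stats: "
                f"{sorted(unknown)[:5]}")
        resolved[name] = ids
    for inner, outer in _NESTING:
        if inner in resolved and outer in resolved and \
                not resolved[inner] <= resolved[outer]:
            raise ValueError(f"set {inner!r} must be a subset of {outer!r}")
    out = {}
    for name, ids in resolved.items():
        vals = mfc.loc[sorted(ids)]
        out[name] = [float((vals >= t).mean()) for t in thresholds]
    return pd.DataFrame(out, index=list(thresholds))


def _significance_mark(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class AnovaResult:
    group_means: pd.Series
    group_ses: pd.Series
    f_stat: float
    p_value: float
    pairwise: pd.DataFrame       # group_a, group_b, p_value, mark
    n_transcripts: int
    threshold: float

    @property
    def mark(self) -> str:
        return _significance_mark(self.p_value)


def _one_way_f(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects F from between/within sums of squares."""
    k = len(groups)
    ns = [len(g) for g in groups]
    n = sum(ns)
    grand = float(np.concatenate(groups).mean())
    ss_between = sum(m * (float(g.mean()) - grand) ** 2
                     for m, g in zip(ns, groups))
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    df_b, df_w = k - 1, n - k
    if df_w <= 0 or ss_within == 0:
        f = 0.0 if ss_between == 0 else np.inf
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return float(f), p


def group_mean_anova(matrix: CountMatrix, subset: Iterable[str],
                     threshold: float = 1.0, normalized: bool = True,
                     stats: ExpressionStats | None = None) -> AnovaResult:
    """Per-group mean +- SE of transcript counts above an MFC threshold,
    with a one-way ANOVA across groups and pairwise significance marks.

    Observations are transcripts (each transcript contributes its mean
    count within a group), matching the 'average read counts of
    transcripts' reading of grouped expression summaries.
    """
    if len(matrix.group_order) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    for g in matrix.group_order:
        if len(matrix.samples_in_group(g)) < 1:
            raise ValueError(f"group {g!r} has no samples")
    if stats is None:
        stats = expression_stats(matrix, normalized=normalized)
    subset = set(subset)
    kept = [t for t in stats.group_values.index
            if t in subset and stats.mfc.loc[t] >= threshold]
    if len(kept) < 2:
        raise ValueError(
            f"fewer than 2 transcripts at MFC >= {threshold} in subset")
    values = stats.group_values.loc[kept]
    arrays = {g: values[g].to_numpy(dtype=float)
              for g in matrix.group_order}
    f, p = _one_way_f(list(arrays.values()))
    means = values.mean()
    ses = values.std(ddof=1) / np.sqrt(len(kept))
    rows = []
    order = matrix.group_order
    for i, ga in enumerate(order):
        for gb in order[i + 1:]:
            _, pp = _one_way_f([arrays[ga], arrays[gb]])
            rows.append({"group_a": ga, "group_b": gb, "p_value": pp,
                         "mark": _significance_mark(pp)})
    return AnovaResult(group_means=means, group_ses=ses, f_stat=f,
                       p_value=p,
                       pairwise=pd.DataFrame(
                           rows, columns=["group_a", "group_b", "p_value",
                                          "mark"]),
                       n_transcripts=len(kept), threshold=threshold)
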