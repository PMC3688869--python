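"""Two-class unpaired SAM-style permutation test.

The statistic per feature is a regularised t-like score

    d_i = (mean2_i - mean1_i) / (s_i + s0)

with s_i the pooled standard error and s0 a fudge factor chosen by the
standard percentile-minimisation rule (the value, among percentiles of the
s_i, that minimises the coefficient of variation of the d-statistic's
spread across the s-range).  The null distribution is built from label
permutations — all distinct two-class assignments when there are fewer
than the requested number, otherwise that many sampled without
replacement — and each feature's q-value is the median number of null
exceedances of |d| divided by the observed number of exceedances,
monotonised so q never increases with |d|.

Exposed statsmodels-style: ``SAMTwoClass(data, labels).fit()`` returns a
:class:`SAMResults` with the per-feature table and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd


def _group_stats(X: np.ndarray, mask2: np.ndarray):
    """Mean difference and pooled SE per row for one label assignment."""
    n2 = int(mask2.sum())
    n1 = X.shape[1] - n2
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    X1, X2 = X[:, ~mask2], X[:, mask2]
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    ss = ((X1 - m1[:, None]) ** 2).sum(axis=1) \
        + ((X2 - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return m2 - m1, s


def _safe_d(diff: np.ndarray, s: np.ndarray, s0: float) -> np.ndarray:
    """d with a zero result where both spread and difference vanish
    (constant features, e.g. rows zeroed by the expression filter)."""
    denom = s + s0
    return np.divide(diff, denom, out=np.zeros_like(diff),
                     where=denom > 0)


def d_statistic(values, labels, s0: float = 0.0) -> float:
    """SAM d for one feature: (mean2 - mean1) / (pooled SE + s0).

    `labels` may be any two-level vector; groups are taken in sorted
    label order (group1 = smaller label).
    """
    values = np.asarray(values, dtype=float)
    mask2 = _binary_mask(np.asarray(labels))
    diff, s = _group_stats(values[None, :], mask2)
    return float(diff[0] / (s[0] + s0))


def _binary_mask(labels: np.ndarray) -> np.ndarray:
    levels = sorted(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 classes, got {levels}")
    return labels == levels[1]


def choose_s0(diff: np.ndarray, s: np.ndarray) -> float:
    """Fudge factor by the percentile-minimisation rule.

    Candidates are the 0,5,...,100 percentiles of s; for each candidate
    the features are binned into quantiles of s and the coefficient of
    variation of the median absolute d across bins is minimised.
    """
    if len(s) < 10:  # too few features to estimate the spread profile
        return float(np.median(s))
    candidates = np.percentile(s, np.arange(0, 101, 5))
    edges = np.percentile(s, np.arange(0, 101, 1))
    bins = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, 99)
    best, best_cv = candidates[0], np.inf
    for alpha in candidates:
        denom = s + alpha
        d = np.divide(diff, denom, out=np.zeros_like(diff),
                      where=denom > 0)
        mads = []
        for b in range(100):
            sel = bins == b
            if sel.sum() >= 2:
                db = d[sel]
                mads.append(np.median(np.abs(db - np.median(db))))
        mads = np.asarray(mads)
        if len(mads) < 2 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv:
            best_cv, best = cv, alpha
    return float(best)


def fold_change(matrix: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Signed fold change of group means on the un-logged scale.

    r = mean(group2)/mean(group1), reported as r when r >= 1 and -1/r
    otherwise, so magnitudes are symmetric around +/-1 and a negative
    value means higher expression in group1.  Zero denominators fall back
    to means computed with the log2 pseudocount (+1) scale; a fold change
    is NaN only when both group means are zero.
    """
    labels = labels.reindex(matrix.columns)
    mask2 = _binary_mask(labels.to_numpy())
    m1 = matrix.loc[:, ~mask2].mean(axis=1)
    m2 = matrix.loc[:, mask2].mean(axis=1)
    num, den = m2.copy(), m1.copy()
    zero_den = (den == 0) & (num > 0)
    zero_num = (num == 0) & (den > 0)
    num[zero_den | zero_num] += 1.0
    den[zero_den | zero_num] += 1.0
    r = num / den
    out = np.where(r >= 1.0, r, -1.0 / r)
    out[(m1 == 0) & (m2 == 0)] = np.nan
    return pd.Series(out, index=matrix.index, name="fold_change")


def _permutation_masks(n: int, n2: int, n_permutations: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Distinct two-class assignments as a (B, n) boolean matrix."""
    total = comb(n, n2)
    if total <= n_permutations:
        masks = np.zeros((total, n), dtype=bool)
        for b, pos in enumerate(combinations(range(n), n2)):
            masks[b, list(pos)] = True
        return masks
    seen: set[tuple] = set()
    masks = np.zeros((n_permutations, n), dtype=bool)
    b = 0
    while b < n_permutations:
        pos = tuple(sorted(rng.choice(n, size=n2, replace=False)))
        if pos in seen:
            continue
        seen.add(pos)
        masks[b, list(pos)] = True
        b += 1
    return masks


@dataclass
class SAMResults:
    """Results of a SAM two-class fit."""

    table: pd.DataFrame        # per feature: d, s, fold_change?, q_value
    s0: float
    n_permutations: int
    q_threshold: float

    @property
    def significant(self) -> pd.DataFrame:
        """Features called at q < q_threshold, strongest first."""
        sig = self.table[self.table["q_value"] < self.q_threshold]
        return sig.reindex(sig["d"].abs().sort_values(ascending=False).index)

    def summary(self) -> str:
        lines = [
            "SAM two-class unpaired permutation test",
            f"  features:        {len(self.table)}",
            f"  permutations:    {self.n_permutations}",
            f"  s0 (fudge):      {self.s0:.4g}",
            f"  significant (q<{self.q_threshold:g}): "
            f"{len(self.significant)}",
        ]
        if len(self.significant):
            lines.append("")
            lines.append(self.significant.head(10).to_string())
        return "\n".join(lines)


class SAMTwoClass:
    """Two-class unpaired SAM model over a feature x sample matrix.

    Parameters
    ----------
    data : DataFrame (features x samples) of log2 expression.
    labels : Series mapping sample -> one of two class labels.
    unlogged : optional DataFrame on the normalized (un-logged) scale used
        for fold changes; when omitted fold changes are derived by
        un-logging `data` (2**x - 1).
    """

    def __init__(self, data: pd.DataFrame, labels: pd.Series,
                 unlogged: pd.DataFrame | None = None):
        labels = pd.Series(labels).reindex(data.columns)
        if labels.isna().any():
            raise ValueError("labels do not cover all samples")
        self.data = data
        self.labels = labels
        self.unlogged = unlogged if unlogged is not None \
            else (2.0 ** data) - 1.0
        self._mask2 = _binary_mask(labels.to_numpy())

    def fit(self, n_permutations: int = 10_000, s0: float | None = None,
            q_threshold: float = 0.05, seed: int = 0) -> SAMResults:
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < q_threshold < 1:
            raise ValueError("q_threshold must lie in (0, 1)")
        X = self.data.to_numpy(dtype=float)
        mask2 = self._mask2
        rng = np.random.default_rng(seed)

        diff, s = _group_stats(X, mask2)
        if s0 is None:
            s0 = choose_s0(diff, s)
        if s0 < 0:
            raise ValueError("s0 must be >= 0")
        d_obs = _safe_d(diff, s, s0)

        masks = _permutation_masks(len(mask2), int(mask2.sum()),
                                   n_permutations, rng)
        abs_obs = np.abs(d_obs)
        order = np.argsort(abs_obs)
        sorted_abs = abs_obs[order]
        # observed exceedances of each |d| threshold
        m = len(d_obs)
        obs_exceed = m - np.searchsorted(sorted_abs, sorted_abs,
                                         side="left")
        null_counts = np.empty((len(masks), m), dtype=np.int32)
        for b, pm in enumerate(masks):
            nd, ns = _group_stats(X, pm)
            null_abs = np.sort(np.abs(_safe_d(nd, ns, s0)))
            null_counts[b] = m - np.searchsorted(null_abs, sorted_abs,
                                                 side="left")
        med_null = np.median(null_counts, axis=0)
        q_sorted = np.minimum(med_null / np.maximum(obs_exceed, 1), 1.0)
        # q_i = best FDR among thresholds that still include feature i,
        # so q never increases as |d| grows
        q_sorted = np.minimum.accumulate(q_sorted)
        q = np.empty(m)
        q[order] = q_sorted

        table = pd.DataFrame({
            "d": d_obs, "s": s,
            "fold_change": fold_change(self.unlogged, self.labels),
            "q_value": q,
        }, index=self.data.index)
        return SAMResults(table, float(s0), len(masks), q_threshold)
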