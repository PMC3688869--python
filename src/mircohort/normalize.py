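"""Normalization, low-expression filtering and expression summaries.

Counts are scaled to reads-per-million on one of four denominators
(total reads; genome-aligned reads allowing multiple hits; uniquely
aligned reads; reads mapped to annotated mature miRNAs): the
normalization factor of a sample is ``denominator / 1e6`` and each raw
count is divided by it.  After normalization, miRNAs with fewer than 10
raw reads summed across all samples are set to zero ("not expressed").
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: The four normalization denominators, as columns of the factor table.
METHODS = ("total_reads", "genome_aligned_multi", "genome_aligned_unique",
           "mirna_mapped")


def normalization_factor(denominator_reads: float,
                         sample: str = "?") -> float:
    """Factor = denominator reads / 1e6 (so dividing yields RPM)."""
    if denominator_reads <= 0:
        raise ValueError(
            f"sample {sample!r}: normalization denominator is "
            f"{denominator_reads}; cannot normalize")
    return denominator_reads / 1e6


def factors_from_table(factor_table: pd.DataFrame,
                       method: str = "mirna_mapped") -> pd.Series:
    """Per-sample factors for one of the four methods."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    return pd.Series(
        {s: normalization_factor(v, s)
         for s, v in factor_table[method].items()}, name=method)


def normalize(matrix: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its normalization factor."""
    missing = [s for s in matrix.columns if s not in factors.index]
    if missing:
        raise ValueError(f"no normalization factor for samples: {missing}")
    return matrix.div(factors.reindex(matrix.columns), axis=1)


def low_count_filter(matrix: pd.DataFrame, threshold: float = 10,
                     raw: pd.DataFrame | None = None,
                     mode: str = "sum") -> tuple[pd.DataFrame, list[str]]:
    """Zero out miRNAs with fewer than `threshold` reads across samples.

    The filter statistic is computed on `raw` (un-normalized) counts when
    given, and the zeroing is applied to `matrix` — matching a filter that
    runs after normalization but is defined on read counts.

    mode="sum": a row is dropped when its summed reads are < threshold
    (default).  mode="all": dropped when every sample is < threshold
    (the laxer reading of "less than 10 reads across all samples").

    Returns the filtered matrix and the names of zeroed miRNAs; rows that
    remain nonzero are the "expressed" miRNAs.
    """
    basis = raw if raw is not None else matrix
    if mode == "sum":
        low = basis.sum(axis=1) < threshold
    elif mode == "all":
        low = (basis < threshold).all(axis=1)
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    out = matrix.copy()
    out.loc[low] = 0.0
    return out, list(basis.index[low])


def expressed_mirnas(matrix: pd.DataFrame) -> list[str]:
    """miRNAs with any nonzero value (the 'expressed' set after filtering)."""
    return list(matrix.index[(matrix != 0).any(axis=1)])


def log2_transform(matrix: pd.DataFrame,
                   pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(value + pseudocount); zero maps to zero with the default."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    return np.log2(matrix + pseudocount)


def top_n_share(matrix: pd.DataFrame, n: int,
                rank_by: str = "total") -> tuple[float, list[str]]:
    """Share (percent) of all miRNA reads carried by the top-n miRNAs.

    rank_by="total" ranks by summed expression across samples;
    "median" ranks by per-miRNA median.
    """
    total = matrix.sum(axis=1)
    if total.sum() == 0:
        raise ValueError("all-zero matrix has no expression shares")
    if rank_by == "total":
        ranking = total.sort_values(ascending=False)
    elif rank_by == "median":
        ranking = matrix.median(axis=1).sort_values(ascending=False)
    else:
        raise ValueError(f"unknown ranking {rank_by!r}")
    top = list(ranking.index[:n])
    share = 100.0 * total.loc[top].sum() / total.sum()
    return float(share), top


def compare_normalization_methods(matrix: pd.DataFrame,
                                  factor_table: pd.DataFrame
                                  ) -> pd.DataFrame:
    """Mean symmetric percent difference of per-miRNA totals between every
    pair of normalization methods.

    For methods a and b with per-miRNA totals a_i, b_i the per-miRNA
    difference is ``|a_i - b_i| / ((a_i + b_i)/2) * 100``; rows with
    a_i + b_i = 0 are skipped.
    """
    totals = {}
    for method in METHODS:
        f = factors_from_table(factor_table, method)
        totals[method] = normalize(matrix, f).sum(axis=1)
    rows = []
    for i, a in enumerate(METHODS):
        for b in METHODS[i + 1:]:
            ta, tb = totals[a], totals[b]
            denom = (ta + tb) / 2.0
            ok = denom > 0
            pct = (100.0 * (ta - tb).abs()[ok] / denom[ok]).mean()
            rows.append((a, b, float(pct) if ok.any() else np.nan))
    return pd.DataFrame(rows, columns=["method_a", "method_b",
                                       "mean_percent_difference"])
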