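"""Hierarchical clustering and cross-platform concordance.

Two-way clustering of an expression matrix means independent WPGMA
(weighted pair-group method with arithmetic mean) dendrograms on rows and
on columns using Euclidean distance, as drawn around a heatmap.  The
linkage update after merging A and B is

    d(A+B, C) = (d(A, C) + d(B, C)) / 2

and ties in the nearest-pair search are broken by the smallest pair of
node indices, which makes the merge history deterministic.

Concordance utilities cover technical-replicate regression of per-miRNA
totals and the qRT-PCR comparison (2^-dCt relative expression, OLS R^2
between platforms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress


def euclidean_distances(matrix: pd.DataFrame,
                        axis: str = "rows") -> pd.DataFrame:
    """Pairwise Euclidean distances between rows or columns."""
    if axis == "columns":
        matrix = matrix.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 items to compute distances")
    if matrix.isna().any().any():
        raise ValueError("distance matrix input contains missing values")
    D = squareform(pdist(matrix.to_numpy(dtype=float)))
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


@dataclass
class Dendrogram:
    """Full merge history of an agglomerative clustering.

    merges: list of (node_a, node_b, height, new_node_id); leaves are
    numbered 0..n-1 in label order and internal nodes n, n+1, ...
    """

    merges: list[tuple[int, int, float, int]]
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_scipy_linkage(self) -> np.ndarray:
        """(n-1) x 4 linkage array compatible with scipy dendrogram plots."""
        sizes = {i: 1 for i in range(self.n_leaves)}
        Z = np.zeros((len(self.merges), 4))
        for r, (a, b, h, new) in enumerate(self.merges):
            sizes[new] = sizes[a] + sizes[b]
            Z[r] = (a, b, h, sizes[new])
        return Z

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        height = {i: 0.0 for i in range(self.n_leaves)}
        text = {i: lab for i, lab in enumerate(self.labels)}
        for a, b, h, new in self.merges:
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            text[new] = f"({text[a]}:{la:g},{text[b]}:{lb:g})"
            height[new] = h
        root = self.merges[-1][3] if self.merges else 0
        return text[root] + ";"


def wpgma_cluster(distances: pd.DataFrame) -> Dendrogram:
    """Agglomerative WPGMA clustering of a symmetric distance matrix."""
    D = distances.to_numpy(dtype=float).copy()
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    labels = [str(x) for x in distances.index]
    np.fill_diagonal(D, np.inf)
    node_id = list(range(n))
    active = np.ones(n, dtype=bool)
    merges: list[tuple[int, int, float, int]] = []
    for step in range(n - 1):
        mask = np.where(active, 1.0, np.nan)
        M = mask[:, None] * D * mask[None, :]
        # nearest active pair; exact ties resolve to the smallest pair of
        # node ids so the merge history is deterministic
        h = np.nanmin(M)
        ties = np.argwhere(M == h)
        ties = ties[ties[:, 0] < ties[:, 1]]
        ids = np.asarray(node_id)
        lo = np.minimum(ids[ties[:, 0]], ids[ties[:, 1]])
        hi = np.maximum(ids[ties[:, 0]], ids[ties[:, 1]])
        best = np.lexsort((hi, lo))[0]
        i, j = int(ties[best, 0]), int(ties[best, 1])
        h = float(D[i, j])
        new = n + step
        a, b = sorted((node_id[i], node_id[j]))
        merges.append((a, b, h, new))
        # WPGMA update, stored in slot i
        D[i, :] = (D[i, :] + D[j, :]) / 2.0
        D[:, i] = D[i, :]
        D[i, i] = np.inf
        active[j] = False
        node_id[i] = new
    return Dendrogram(merges, labels)


def two_way_cluster(matrix: pd.DataFrame) -> tuple[Dendrogram, Dendrogram]:
    """WPGMA dendrograms of the rows and of the columns of `matrix`."""
    rows = wpgma_cluster(euclidean_distances(matrix, "rows"))
    cols = wpgma_cluster(euclidean_distances(matrix, "columns"))
    return rows, cols


# ---------------------------------------------------------------------------
# concordance


def replicate_concordance(totals_run1: pd.Series, totals_run2: pd.Series
                          ) -> dict[str, float]:
    """OLS of run-2 on run-1 per-miRNA totals (already normalized+log2).

    Returns slope, intercept and R^2; identical replicates give (1, 0, 1).
    """
    x = totals_run1.to_numpy(dtype=float)
    y = totals_run2.reindex(totals_run1.index).to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points for a regression")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and np.allclose(x, y):
        return {"slope": 1.0, "intercept": 0.0, "r_squared": 1.0}
    fit = linregress(x, y)
    return {"slope": float(fit.slope), "intercept": float(fit.intercept),
            "r_squared": float(fit.rvalue ** 2)}


def delta_ct_expression(ct_target, ct_reference):
    """Relative expression 2^-(Ct_target - Ct_reference).

    Undetected (NaN) targets propagate as NaN — missing, not zero.
    """
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    out = 2.0 ** -(ct_target - ct_reference)
    if out.ndim == 0:
        return float(out)
    return out


def platform_regression(qpcr: pd.DataFrame, seq: pd.DataFrame
                        ) -> pd.DataFrame:
    """Per-assay OLS R^2 between qRT-PCR values and log2 sequencing counts.

    Both inputs are sample x assay tables over paired samples; assays with
    fewer than 3 complete pairs are skipped with a NaN row.  Also reports
    each platform's summed expression per assay (bar-plot style summary).
    """
    rows = []
    for assay in qpcr.columns:
        if assay not in seq.columns:
            continue
        pair = pd.concat([qpcr[assay], seq[assay]], axis=1,
                         keys=["q", "s"]).dropna()
        total_q = float(qpcr[assay].sum(skipna=True))
        total_s = float(seq[assay].sum(skipna=True))
        if len(pair) < 3 or np.ptp(pair["q"].to_numpy()) == 0:
            rows.append((assay, np.nan, len(pair), total_q, total_s))
            continue
        if np.ptp(pair["s"].to_numpy()) == 0:
            rows.append((assay, 0.0, len(pair), total_q, total_s))
            continue
        fit = linregress(pair["q"], pair["s"])
        rows.append((assay, float(fit.rvalue ** 2), len(pair),
                     total_q, total_s))
    return pd.DataFrame(rows, columns=["assay", "r_squared", "n_pairs",
                                       "qpcr_total", "seq_total"]
                        ).set_index("assay")
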