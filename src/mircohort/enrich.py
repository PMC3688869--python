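"""Gene-set over-representation for miRNA target lists.

A transparent hypergeometric test standing in for web-tool pathway
analysis: for each gene set, the one-sided tail probability of drawing at
least the observed overlap when the target list is sampled from the
background universe, BH-adjusted across sets.  An EASE-style variant
(overlap reduced by one before taking the tail) is available as a flag.
The background universe defaults to all genes appearing in the gene-set
collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .survcox import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe.

    Sets are intersected with the universe on construction so every set is
    a subset of it.
    """

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.sets.values()) \
                if self.sets else set()
        self.sets = {name: genes & self.universe
                     for name, genes in self.sets.items()}

    @classmethod
    def from_gmt(cls, path: str | Path,
                 universe: set[str] | None = None) -> "GeneSetCollection":
        sets = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[fields[0]] = {g for g in fields[2:] if g}
        return cls(sets, universe or set())

    def to_gmt(self, path: str | Path) -> None:
        lines = [f"{name}\tna\t" + "\t".join(sorted(genes))
                 for name, genes in self.sets.items()]
        Path(path).write_text("\n".join(lines) + "\n")


def enrich(targets, collection: GeneSetCollection,
           min_overlap: int = 2, ease: bool = False) -> pd.DataFrame:
    """Hypergeometric over-representation of `targets` in each gene set.

    Returns a table (term, set_size, overlap, p_value, p_adjusted) sorted
    by p-value; sets overlapping fewer than `min_overlap` targets are
    excluded before BH adjustment.  ``ease=True`` applies the EASE
    penalty, scoring the tail at overlap - 1.
    """
    targets = set(targets)
    if not targets:
        raise ValueError("empty target list")
    if not collection.universe:
        raise ValueError("empty background universe")
    dropped = targets - collection.universe
    if dropped:
        logger.warning("%d target gene(s) not in the universe were "
                       "dropped", len(dropped))
    targets &= collection.universe
    if not targets:
        raise ValueError("no target genes remain inside the universe")

    M = len(collection.universe)
    N = len(targets)
    rows = []
    for term, genes in collection.sets.items():
        k = len(genes & targets)
        if k < min_overlap:
            continue
        score_k = k - 1 if ease else k
        p = float(hypergeom.sf(score_k - 1, M, len(genes), N))
        rows.append((term, len(genes), k, p))
    table = pd.DataFrame(rows, columns=["term", "set_size", "overlap",
                                        "p_value"])
    if len(table):
        table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
        table = table.sort_values("p_value", ignore_index=True)
    else:
        table["p_adjusted"] = []
    return table
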