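"""Genomic feature annotation for small-RNA quantification.

An :class:`AnnotationSet` holds the intervals of mature miRNAs, their
enclosing hairpin precursors ("premature" miRNAs), snoRNAs and any other
annotated small-RNA species.  Coordinates are 0-based, half-open
(BED convention) throughout the in-memory representation; the GFF3 writer
converts to 1-based closed coordinates on output.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

# Feature classes recognised by the quantifier, in counting priority order
# (a read contained in a mature interval is a mature hit even though it is
# also contained in the enclosing hairpin).
CLASS_PRIORITY = ("mature", "premature", "snoRNA", "snRNA", "miscRNA",
                  "tRNA", "rRNA", "mRNA")
INTERGENIC = "intronic/intergenic"

_COLUMNS = ["chrom", "start", "end", "strand", "name", "feature_class"]


@dataclass
class AnnotationSet:
    """A table of classified genomic intervals.

    Parameters
    ----------
    features : pandas.DataFrame
        Columns ``chrom, start, end, strand, name, feature_class``;
        coordinates 0-based half-open.
    chrom_sizes : mapping of chromosome name to length in nt.
    """

    features: pd.DataFrame
    chrom_sizes: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.features.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        f = self.features
        if (f["start"] >= f["end"]).any():
            raise ValueError("annotation has intervals with start >= end")
        self.features = f.reset_index(drop=True)

    # -- accessors ---------------------------------------------------------

    def of_class(self, feature_class: str) -> pd.DataFrame:
        return self.features[self.features["feature_class"] == feature_class]

    @property
    def mature(self) -> pd.DataFrame:
        return self.of_class("mature")

    @property
    def mirna_names(self) -> list[str]:
        return list(self.mature["name"])

    def __len__(self) -> int:
        return len(self.features)

    # -- IO ----------------------------------------------------------------

    def to_bed(self, path: str | Path) -> None:
        """Write BED6 plus a 7th column carrying the feature class."""
        f = self.features
        bed = pd.DataFrame({
            "chrom": f["chrom"], "start": f["start"], "end": f["end"],
            "name": f["name"], "score": 0, "strand": f["strand"],
            "feature_class": f["feature_class"],
        })
        bed.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path: str | Path,
                 chrom_sizes: Mapping[str, int] | None = None) -> "AnnotationSet":
        bed = pd.read_csv(path, sep="\t", header=None,
                          names=["chrom", "start", "end", "name", "score",
                                 "strand", "feature_class"])
        feats = bed[["chrom", "start", "end", "strand", "name",
                     "feature_class"]].copy()
        return cls(feats, chrom_sizes or {})

    def to_gff3(self, path: str | Path) -> None:
        """Write miRBase-style GFF3 (1-based closed coordinates).

        Mature features use type ``miRNA``, hairpins
        ``miRNA_primary_transcript``; other classes keep their class label
        as the type column.
        """
        type_map = {"mature": "miRNA", "premature": "miRNA_primary_transcript"}
        buf = io.StringIO()
        buf.write("##gff-version 3\n")
        for row in self.features.itertuples(index=False):
            ftype = type_map.get(row.feature_class, row.feature_class)
            attrs = f"ID={row.name};Name={row.name}"
            buf.write(f"{row.chrom}\t.\t{ftype}\t{row.start + 1}\t{row.end}"
                      f"\t.\t{row.strand}\t.\t{attrs}\n")
        Path(path).write_text(buf.getvalue())

    @classmethod
    def from_gff3(cls, path: str | Path,
                  chrom_sizes: Mapping[str, int] | None = None) -> "AnnotationSet":
        inv_type = {"miRNA": "mature", "miRNA_primary_transcript": "premature"}
        rows = []
        for line in Path(path).read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = line.split("\t")
            name = ""
            for kv in attrs.split(";"):
                if kv.startswith("Name="):
                    name = kv[5:]
            rows.append((chrom, int(start) - 1, int(end), strand, name,
                         inv_type.get(ftype, ftype)))
        feats = pd.DataFrame(rows, columns=_COLUMNS)
        return cls(feats, chrom_sizes or {})


class ContainmentIndex:
    """Vectorised full-containment lookup against non-overlapping intervals.

    Intervals of one feature class must not overlap on the same
    (chromosome, strand); the generator guarantees this and the constructor
    enforces it.  Queries map each (chrom, start, end, strand) to the name
    of the interval that fully contains it, or ``None``.
    """

    def __init__(self, intervals: pd.DataFrame, stranded: bool = True):
        self.stranded = stranded
        self._index: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        keys = ["chrom", "strand"] if stranded else ["chrom"]
        for key, grp in intervals.groupby(keys, observed=True):
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(
                    f"overlapping intervals within one class at {key}")
            self._index[key if stranded else (key[0] if isinstance(key, tuple) else key,)] = (
                starts, ends, grp["name"].to_numpy())

    def lookup(self, chrom: np.ndarray, start: np.ndarray, end: np.ndarray,
               strand: np.ndarray) -> np.ndarray:
        """Return an object array of containing-feature names (None = miss)."""
        out = np.full(len(start), None, dtype=object)
        df = pd.DataFrame({"chrom": chrom, "start": start, "end": end,
                           "strand": strand, "pos": np.arange(len(start))})
        keys = ["chrom", "strand"] if self.stranded else ["chrom"]
        for key, grp in df.groupby(keys, observed=True):
            key = key if isinstance(key, tuple) else (key,)
            entry = self._index.get(key if self.stranded else key[:1])
            if entry is None:
                continue
            starts, ends, names = entry
            qs = grp["start"].to_numpy()
            qe = grp["end"].to_numpy()
            idx = np.searchsorted(starts, qs, side="right") - 1
            ok = idx >= 0
            hit = np.zeros(len(qs), dtype=bool)
            hit[ok] = ends[idx[ok]] >= qe[ok]
            pos = grp["pos"].to_numpy()
            out[pos[hit]] = names[idx[hit]]
        return out


def build_class_indexes(annotation: AnnotationSet) -> dict[str, ContainmentIndex]:
    """One containment index per feature class present in the annotation."""
    indexes = {}
    for cls_name in annotation.features["feature_class"].unique():
        indexes[cls_name] = ContainmentIndex(annotation.of_class(cls_name))
    return indexes


def intergenic_gaps(annotation: AnnotationSet) -> pd.DataFrame:
    """Intervals of each chromosome not covered by any feature."""
    rows = []
    for chrom, size in annotation.chrom_sizes.items():
        feats = annotation.features[annotation.features["chrom"] == chrom]
        feats = feats.sort_values("start")
        cursor = 0
        for s, e in zip(feats["start"], feats["end"]):
            if s > cursor:
                rows.append((chrom, cursor, s))
            cursor = max(cursor, e)
        if cursor < size:
            rows.append((chrom, cursor, size))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
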