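"""Post-alignment miRNA quantification.

Counting rules, applied per sample in this order:

1.  Reads aligning to 10 or more distinct genomic loci are excluded.
2.  If a read has any perfect (0-mismatch) alignment, its mismatched
    alignments are discarded (perfect-match precedence).
3.  An alignment is a mature-miRNA hit when its interval is fully
    contained in a mature miRNA interval on the same strand with at most
    one mismatch.
4.  Reads hitting exactly one mature miRNA count 1 for it; reads hitting
    several are pooled per hit-set and divided in proportion to the
    miRNAs' unique-read counts (equal split when no member has unique
    reads), keeping counts fractional so read mass is conserved.

Non-miRNA reads are classified by containment with priority
mature > premature > other annotated classes > intronic/intergenic.

Two equivalent code paths exist: per-read operations on
:class:`AlignedRead` objects (the rule-level API) and a vectorised
table pipeline in :func:`build_count_matrix` used at cohort scale; the
test suite checks they agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (AnnotationSet, CLASS_PRIORITY, INTERGENIC,
                         ContainmentIndex, build_class_indexes)
from .samio import ALIGNMENT_COLUMNS, read_sam

logger = logging.getLogger(__name__)

DEFAULT_MAX_LOCI = 10
DEFAULT_MAX_MISMATCH = 1


@dataclass(frozen=True)
class AlignmentRecord:
    """One genomic alignment of a read (0-based half-open)."""
    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("alignment with start >= end")
        if self.mismatches < 0:
            raise ValueError("negative mismatch count")

    @property
    def locus(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class AlignedRead:
    """A read together with all its alignments."""
    read_id: object
    length: int
    alignments: tuple[AlignmentRecord, ...]

    @property
    def n_loci(self) -> int:
        return len({a.locus for a in self.alignments})


# ---------------------------------------------------------------------------
# rule-level operations


def exclude_multilocus_reads(reads: Iterable[AlignedRead],
                             max_loci: int = DEFAULT_MAX_LOCI
                             ) -> tuple[list[AlignedRead], int]:
    """Drop reads mapping to `max_loci` or more distinct genomic loci.

    Returns (retained reads, number excluded).  A read at exactly
    ``max_loci - 1`` loci is retained.
    """
    kept, excluded = [], 0
    for read in reads:
        if read.n_loci >= max_loci:
            excluded += 1
        else:
            kept.append(read)
    return kept, excluded


def apply_perfect_match_precedence(read: AlignedRead) -> AlignedRead:
    """Keep only perfect alignments when at least one exists."""
    if any(a.mismatches == 0 for a in read.alignments):
        perfect = tuple(a for a in read.alignments if a.mismatches == 0)
        return AlignedRead(read.read_id, read.length, perfect)
    return read


def annotate_read(read: AlignedRead, annotation: AnnotationSet,
                  max_mismatch: int = DEFAULT_MAX_MISMATCH) -> set[str]:
    """Mature miRNAs hit by the read's surviving alignments.

    A hit requires full containment in a mature interval on the same
    strand and at most `max_mismatch` mismatches.
    """
    mature = annotation.mature
    hits: set[str] = set()
    for a in read.alignments:
        if a.mismatches > max_mismatch:
            continue
        sel = mature[(mature["chrom"] == a.chrom)
                     & (mature["strand"] == a.strand)
                     & (mature["start"] <= a.start)
                     & (mature["end"] >= a.end)]
        hits.update(sel["name"])
    return hits


def assign_multimapped(unique_counts: Mapping[str, float],
                       multimap_groups: Sequence[tuple[Iterable[str], float]]
                       ) -> dict[str, float]:
    """Divide each group's shared reads among its miRNAs in proportion to
    their unique-read counts.

    For a group G with shared count n and unique counts u_i, miRNA i
    receives ``n * u_i / sum(u)``; when no member has unique reads the n
    reads are split equally.  Returns the fractional counts added per
    miRNA (zero-filled for miRNAs in no group).
    """
    assigned = {m: 0.0 for m in unique_counts}
    for members, shared in multimap_groups:
        members = list(members)
        unknown = [m for m in members if m not in unique_counts]
        if unknown:
            raise ValueError(f"multimap group names unknown miRNAs: "
                             f"{unknown}")
        if shared < 0:
            raise ValueError("negative shared read count")
        u = np.array([unique_counts[m] for m in members], dtype=float)
        if u.sum() > 0:
            share = shared * u / u.sum()
        else:
            logger.warning("multimap group %s has no unique reads; "
                           "splitting %s reads equally", members, shared)
            share = np.full(len(members), shared / len(members))
        for m, x in zip(members, share):
            assigned[m] += float(x)
    return assigned


def count_reads(reads: Iterable[AlignedRead], annotation: AnnotationSet,
                max_loci: int = DEFAULT_MAX_LOCI,
                max_mismatch: int = DEFAULT_MAX_MISMATCH
                ) -> tuple[dict[str, float], dict]:
    """Reference (per-read) counting path for one sample.

    Returns per-miRNA fractional counts and a stats dict.  Used by the
    tests as the slow mirror of the vectorised pipeline.
    """
    retained, n_excluded = exclude_multilocus_reads(list(reads), max_loci)
    unique: dict[str, float] = {m: 0.0 for m in annotation.mirna_names}
    shared: dict[frozenset, float] = {}
    n_unique_reads = 0
    for read in retained:
        read = apply_perfect_match_precedence(read)
        hits = annotate_read(read, annotation, max_mismatch)
        if len(hits) == 1:
            unique[next(iter(hits))] += 1.0
            n_unique_reads += 1
        elif len(hits) > 1:
            key = frozenset(hits)
            shared[key] = shared.get(key, 0.0) + 1.0
    assigned = assign_multimapped(unique,
                                  [(sorted(k), v) for k, v in
                                   sorted(shared.items(),
                                          key=lambda kv: sorted(kv[0]))])
    counts = {m: unique[m] + assigned[m] for m in unique}
    stats = {"excluded": n_excluded, "unique_reads": n_unique_reads,
             "multimapped_reads": sum(shared.values())}
    return counts, stats


# ---------------------------------------------------------------------------
# vectorised pipeline


@dataclass
class QuantifyResult:
    """Counts and summaries produced by :func:`build_count_matrix`."""

    counts: pd.DataFrame          # miRNA x sample fractional read counts
    class_freq: pd.DataFrame      # sample x class fraction, rows sum to 1
    factors: pd.DataFrame         # per-sample normalization denominators
    excluded: pd.Series           # reads dropped by the >=10-locus rule
    stats: pd.DataFrame = field(default=None)


def reads_to_table(reads: Iterable[AlignedRead]) -> pd.DataFrame:
    rows = [(r.read_id, a.chrom, a.start, a.end, a.strand, a.mismatches)
            for r in reads for a in r.alignments]
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def table_to_reads(table: pd.DataFrame) -> list[AlignedRead]:
    reads = []
    for rid, grp in table.groupby("read_id", sort=False):
        alns = tuple(AlignmentRecord(r.chrom, int(r.start), int(r.end),
                                     r.strand, int(r.nm))
                     for r in grp.itertuples(index=False))
        reads.append(AlignedRead(rid, int(grp["end"].iat[0]
                                          - grp["start"].iat[0]), alns))
    return reads


def _quantify_sample(table: pd.DataFrame, annotation: AnnotationSet,
                     indexes: dict[str, ContainmentIndex],
                     max_loci: int, max_mismatch: int):
    """Vectorised exclusion -> precedence -> annotation -> counting for one
    sample's alignment table."""
    n_total = table["read_id"].nunique()

    # merge identical coordinates (keep the best mismatch count), then
    # count distinct loci per read
    t = (table.groupby(["read_id", "chrom", "start", "end", "strand"],
                       sort=False, observed=True)["nm"].min().reset_index())
    loci = t.groupby("read_id", sort=False)["nm"].size()
    excluded_ids = loci.index[loci.to_numpy() >= max_loci]
    n_excluded = len(excluded_ids)
    t = t[~t["read_id"].isin(excluded_ids)]

    n_unique_locus = int((loci.to_numpy() == 1).sum())

    # perfect-match precedence
    min_nm = t.groupby("read_id", sort=False)["nm"].transform("min")
    t = t[(min_nm > 0) | (t["nm"] == 0)]

    # mature hits
    mat_hit = indexes["mature"].lookup(
        t["chrom"].to_numpy(), t["start"].to_numpy(),
        t["end"].to_numpy(), t["strand"].to_numpy())
    mat_hit[t["nm"].to_numpy() > max_mismatch] = None
    t = t.assign(mirna=mat_hit)

    hit_rows = t[t["mirna"].notna()]
    by_read = hit_rows.groupby("read_id", sort=False)["mirna"]
    n_hits = by_read.nunique()
    unique_ids = n_hits.index[n_hits.to_numpy() == 1]
    multi_ids = n_hits.index[n_hits.to_numpy() > 1]

    unique = {m: 0.0 for m in annotation.mirna_names}
    first_hit = by_read.first()
    for m, c in first_hit.loc[unique_ids].value_counts().items():
        unique[m] += float(c)
    multi_rows = hit_rows[hit_rows["read_id"].isin(multi_ids)]
    hit_sets = multi_rows.groupby("read_id", sort=False)["mirna"].agg(
        lambda s: frozenset(s))
    shared = {k: float(v) for k, v in hit_sets.value_counts().items()}
    assigned = assign_multimapped(
        unique, [(sorted(k), v) for k, v in
                 sorted(shared.items(), key=lambda kv: sorted(kv[0]))])
    counts = {m: unique[m] + assigned[m] for m in unique}

    # class assignment for every retained read
    read_class = pd.Series(INTERGENIC, index=loci.index[
        loci.to_numpy() < max_loci], dtype=object)
    mirna_read_ids = n_hits.index
    read_class.loc[mirna_read_ids] = "mature"
    remaining = t[~t["read_id"].isin(mirna_read_ids)]
    for cls_name in CLASS_PRIORITY[1:]:
        if cls_name not in indexes or remaining.empty:
            continue
        hit = indexes[cls_name].lookup(
            remaining["chrom"].to_numpy(), remaining["start"].to_numpy(),
            remaining["end"].to_numpy(), remaining["strand"].to_numpy())
        got = remaining["read_id"].to_numpy()[hit != None]  # noqa: E711
        if len(got):
            read_class.loc[np.unique(got)] = cls_name
            remaining = remaining[~remaining["read_id"].isin(got)]

    class_counts = read_class.value_counts().to_dict()
    mirna_mapped = sum(counts.values())
    factors = {
        "total_reads": n_total,
        "genome_aligned_multi": n_total,
        "genome_aligned_unique": n_unique_locus,
        "mirna_mapped": mirna_mapped,
    }
    return counts, class_counts, factors, n_excluded


def build_count_matrix(sample_alignments: Mapping[str, pd.DataFrame],
                       annotation: AnnotationSet,
                       max_loci: int = DEFAULT_MAX_LOCI,
                       max_mismatch: int = DEFAULT_MAX_MISMATCH
                       ) -> QuantifyResult:
    """Quantify all samples against one annotation.

    Parameters
    ----------
    sample_alignments : mapping of sample id to alignment table
        Tables as produced by the simulator or :func:`mircohort.samio.read_sam`.
    """
    samples = list(sample_alignments)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")
    indexes = build_class_indexes(annotation)
    if "mature" not in indexes:
        indexes["mature"] = ContainmentIndex(annotation.mature)

    all_classes = [c for c in CLASS_PRIORITY
                   if c in set(annotation.features["feature_class"])]
    count_cols, class_rows, factor_rows, excl = {}, [], [], []
    for sample in samples:
        counts, class_counts, factors, n_excluded = _quantify_sample(
            sample_alignments[sample], annotation, indexes, max_loci,
            max_mismatch)
        count_cols[sample] = counts
        class_rows.append(class_counts)
        factor_rows.append(factors)
        excl.append(n_excluded)

    counts = pd.DataFrame(count_cols,
                          index=pd.Index(annotation.mirna_names,
                                         name="mirna")).fillna(0.0)
    counts.columns.name = "sample"

    class_freq = pd.DataFrame(class_rows, index=samples).fillna(0.0)
    for c in all_classes + [INTERGENIC]:
        if c not in class_freq.columns:
            class_freq[c] = 0.0
    class_freq = class_freq[all_classes + [INTERGENIC]]
    totals = class_freq.sum(axis=1)
    class_freq = class_freq.div(totals.where(totals > 0, 1.0), axis=0)
    class_freq.index.name = "sample"

    factors = pd.DataFrame(factor_rows, index=samples)
    factors.index.name = "sample"
    return QuantifyResult(counts, class_freq, factors,
                          pd.Series(excl, index=samples, name="excluded"))


def quantify_sam_dir(sam_dir: str | Path, annotation: AnnotationSet,
                     pattern: str = "*.sam", **kwargs) -> QuantifyResult:
    """Quantify every SAM/BAM file in a directory (sample id = file stem)."""
    paths = sorted(Path(sam_dir).glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no {pattern} files under {sam_dir}")
    tables = {p.stem: read_sam(p) for p in paths}
    return build_count_matrix(tables, annotation, **kwargs)
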