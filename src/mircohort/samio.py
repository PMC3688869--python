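"""Reading and writing alignment sets as SAM.

Alignments travel through the pipeline as flat per-sample tables with
columns ``read_id, chrom, start, end, strand, nm`` (0-based half-open).
Reads are unspliced small-RNA alignments, so the CIGAR is a single match
run and the read length equals ``end - start``.  The ``NM`` tag carries the
mismatch count; on input a missing NM is treated as 0 with a warning, since
the downstream hit rule needs a mismatch count for every alignment.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

ALIGNMENT_COLUMNS = ["read_id", "chrom", "start", "end", "strand", "nm"]


def write_sam(alignments: pd.DataFrame, path: str | Path,
              chrom_sizes: Mapping[str, int], sample: str = "sample") -> None:
    """Write one sample's alignment table as SAM.

    The first alignment of each read is written as primary, additional
    loci as secondary records (flag 0x100).
    """
    chroms = list(chrom_sizes)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(chrom_sizes[c])} for c in chroms],
        "RG": [{"ID": sample, "SM": sample}],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    df = alignments.sort_values(["read_id", "chrom", "start"], kind="stable")
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        prev = None
        for row in df.itertuples(index=False):
            aln = pysam.AlignedSegment()
            aln.query_name = f"{sample}.{row.read_id}"
            length = int(row.end - row.start)
            flag = 0x10 if row.strand == "-" else 0
            if row.read_id == prev:
                flag |= 0x100  # secondary
            aln.flag = flag
            aln.reference_id = tid[row.chrom]
            aln.reference_start = int(row.start)
            aln.mapping_quality = 255
            aln.cigarstring = f"{length}M"
            aln.query_sequence = None
            aln.set_tag("NM", int(row.nm))
            aln.set_tag("RG", sample)
            out.write(aln)
            prev = row.read_id


def read_sam(path: str | Path) -> pd.DataFrame:
    """Read a SAM/BAM file into the flat alignment table.

    Unmapped records are skipped.  Secondary/supplementary records are kept:
    they are the extra loci of multi-mapped reads.
    """
    rows = []
    missing_nm = 0
    with pysam.AlignmentFile(str(path), "r") as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            if aln.has_tag("NM"):
                nm = aln.get_tag("NM")
            else:
                nm = 0
                missing_nm += 1
            rows.append((aln.query_name, aln.reference_name,
                         aln.reference_start, aln.reference_end,
                         "-" if aln.is_reverse else "+", nm))
    if missing_nm:
        logger.warning("%d alignments lacked an NM tag; mismatches "
                       "treated as 0", missing_nm)
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
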