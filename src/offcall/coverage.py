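"""Per-bin aligned-base coverage from alignment files.

The per-bin statistic is the total number of aligned bases falling in
the bin (mean depth x bin length), counting only reads at or above the
mapping-quality threshold (default 50) and excluding unmapped,
secondary, supplementary, duplicate-flagged and QC-fail records.
Reference-consuming CIGAR deletions (D) count as covered, insertions
and soft clips contribute nothing, and N skips are uncovered — the
semantics of a standard depth summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import BinSet

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 50

# CIGAR operations that consume the reference and count as covered
_COVERED_OPS = {0, 2, 7, 8}  # M, D, =, X
_REF_OPS = {0, 2, 3, 7, 8}   # + N


@dataclass
class CoverageMatrix:
    """bins x samples matrix of total aligned-base counts."""

    values: np.ndarray
    bin_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (bins x samples)")
        if self.values.shape != (len(self.bin_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.bin_ids)} bins x {len(self.sample_ids)} samples")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicated sample id")
        if (self.values < 0).any():
            raise ValueError("negative coverage values")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.bin_ids,
                            columns=self.sample_ids)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "bin"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CoverageMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df.to_numpy(dtype=np.int64),
                   bin_ids=[str(i) for i in df.index],
                   sample_ids=[str(c) for c in df.columns])


def _covered_segments(read) -> list[tuple[int, int]]:
    """Reference intervals covered by one read (M/D/=/X ops), merged."""
    segs: list[tuple[int, int]] = []
    pos = read.reference_start
    for op, length in read.cigartuples:
        if op in _COVERED_OPS:
            if segs and segs[-1][1] == pos:
                segs[-1] = (segs[-1][0], pos + length)
            else:
                segs.append((pos, pos + length))
        if op in _REF_OPS:
            pos += length
    return segs


def _qualifies(read, min_mapq: int) -> bool:
    return not (read.is_unmapped or read.is_secondary or read.is_supplementary
                or read.is_duplicate or read.is_qcfail) \
        and read.mapping_quality >= min_mapq


def bin_coverage(alignments, bins: BinSet,
                 min_mapq: int = DEFAULT_MIN_MAPQ) -> np.ndarray:
    """Total aligned bases per bin for one sample.

    ``alignments`` is a path to a coordinate-sorted, indexed BAM/CRAM or
    an open :class:`pysam.AlignmentFile`.  Bins are processed chromosome
    by chromosome with a single pass over the reads; each qualifying
    read adds the length of its overlap with every bin it touches.
    """
    import pysam

    own = isinstance(alignments, (str, bytes))
    af = pysam.AlignmentFile(str(alignments)) if own else alignments
    try:
        if not af.has_index():
            raise ValueError(f"alignment file {af.filename!r} has no index; "
                             "sort and index it first")
        refs = set(af.references)
        chroms = sorted({b.chrom for b in bins})
        missing = [c for c in chroms if c not in refs]
        if missing:
            stripped = {c.removeprefix("chr") for c in missing}
            hint = (" (naming mismatch: the file uses e.g. "
                    f"'{next(iter(refs))}' — harmonise 'chr' prefixes)"
                    if stripped & refs or {f"chr{c}" for c in missing} & refs
                    else "")
            raise ValueError(
                f"chromosomes absent from alignment file: {missing}{hint}")
        totals = np.zeros(len(bins), dtype=np.int64)
        index_of: dict[str, list[int]] = {}
        for i, b in enumerate(bins):
            index_of.setdefault(b.chrom, []).append(i)
        for chrom in chroms:
            idx = index_of[chrom]
            starts = np.array([bins[i].start for i in idx])
            ends = np.array([bins[i].end for i in idx])
            for read in af.fetch(chrom):
                if not _qualifies(read, min_mapq):
                    continue
                for s, e in _covered_segments(read):
                    lo = int(np.searchsorted(ends, s, side="right"))
                    hi = int(np.searchsorted(starts, e, side="left"))
                    for j in range(lo, hi):
                        totals[idx[j]] += min(e, ends[j]) - max(s, starts[j])
        return totals
    finally:
        if own:
            af.close()


def assemble_matrix(per_sample_vectors, bin_ids: list[str],
                    sample_ids: list[str]) -> CoverageMatrix:
    """Stack per-sample coverage vectors into a CoverageMatrix, column
    order following the declared sample order."""
    if len(per_sample_vectors) != len(sample_ids):
        raise ValueError("one coverage vector required per sample")
    cols = []
    for sid, vec in zip(sample_ids, per_sample_vectors):
        vec = np.asarray(vec)
        if vec.shape != (len(bin_ids),):
            raise ValueError(
                f"sample {sid}: vector length {vec.shape} does not match "
                f"{len(bin_ids)} bins")
        cols.append(vec)
    return CoverageMatrix(values=np.column_stack(cols), bin_ids=list(bin_ids),
                          sample_ids=list(sample_ids))


def count_batch(bam_table: list[tuple[str, str]], bins: BinSet,
                min_mapq: int = DEFAULT_MIN_MAPQ) -> CoverageMatrix:
    """Count a whole batch: ``bam_table`` is a list of (path, sample_id)."""
    sample_ids = [sid for _, sid in bam_table]
    vectors = []
    for path, sid in bam_table:
        logger.info("counting %s (%s)", sid, path)
        vectors.append(bin_coverage(path, bins, min_mapq=min_mapq))
    return assemble_matrix(vectors, bins.bin_ids, sample_ids)


def read_bam_list(path) -> list[tuple[str, str]]:
    """Parse a one- or two-column TSV of BAM paths and optional sample
    ids (default: file stem)."""
    import os

    table: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            f = line.split("\t")
            sid = f[1] if len(f) > 1 else os.path.basename(f[0]).rsplit(".", 1)[0]
            table.append((f[0], sid))
    return table
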