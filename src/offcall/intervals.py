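"""Partition the genome into on-target and off-target bins.

Capture kits define the targeted intervals; everything else on the
analysable chromosomes is potential off-target territory.  Because
off-target reads arrive at roughly 1/80 of the on-target per-base depth,
off-target bins are made much larger than on-target ones so that every
bin collects a comparable number of aligned bases.  A padding zone
around each target is excluded from the off-target set: capture
spillover inflates depth immediately next to probes and would mask the
true intronic copy-number signal.

All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

ON_TARGET = "on_target"
OFF_TARGET = "off_target"

#: Chromosome sizes for the two common human builds (primary autosomes + X).
#: chrY, chrM and alternate/decoy contigs are excluded from analysis by
#: default; pass a custom genome map to override.
HG19_SIZES = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430,
    "chr4": 191154276, "chr5": 180915260, "chr6": 171115067,
    "chr7": 159138663, "chr8": 146364022, "chr9": 141213431,
    "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392,
    "chr16": 90354753, "chr17": 81195210, "chr18": 78077248,
    "chr19": 59128983, "chr20": 63025520, "chr21": 48129895,
    "chr22": 51304566, "chrX": 155270560,
}
HG38_SIZES = {
    "chr1": 248956422, "chr2": 242193529, "chr3": 198295559,
    "chr4": 190214555, "chr5": 181538259, "chr6": 170805979,
    "chr7": 159345973, "chr8": 145138636, "chr9": 138394717,
    "chr10": 133797422, "chr11": 135086622, "chr12": 133275309,
    "chr13": 114364328, "chr14": 107043718, "chr15": 101991189,
    "chr16": 90338345, "chr17": 83257441, "chr18": 80373285,
    "chr19": 58617616, "chr20": 64444167, "chr21": 46709983,
    "chr22": 50818468, "chrX": 156040895,
}

BUILTIN_GENOMES = {"hg19": HG19_SIZES, "hg38": HG38_SIZES}

_AUTOSOME_NAMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}
_CHRX_NAMES = {"chrX", "X"}


def chrom_class(chrom: str) -> str:
    """Classify a chromosome as ``autosome`` or ``chrX`` (anything else
    is reported as ``other`` and normally excluded upstream)."""
    if chrom in _CHRX_NAMES:
        return "chrX"
    if chrom in _AUTOSOME_NAMES or chrom.startswith("chr") or chrom.isdigit():
        # synthetic chromosomes from the simulator count as autosomes
        return "autosome"
    return "other"


@dataclass
class GenomicBin:
    """One on- or off-target interval.

    ``gc`` is the G+C fraction of the non-N reference bases, NaN until
    computed (or if the sequence is unusable, i.e. >50% N).
    """

    chrom: str
    start: int
    end: int
    kind: str
    exonic: bool = False
    gc: float = float("nan")
    id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"invalid bin {self.chrom}:{self.start}-{self.end}: end <= start"
            )
        if not self.id:
            prefix = "on" if self.kind == ON_TARGET else "off"
            self.id = f"{prefix}:{self.chrom}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def chrom_class(self) -> str:
        return chrom_class(self.chrom)


@dataclass
class PartitionParams:
    min_on_target: int = 100
    max_on_target: int = 300
    padding_off_target: int = 300
    max_off_target: int = 50_000
    min_off_target: int = 1


@dataclass
class BinSet:
    """The ordered, disjoint partition of the genome into analysable bins."""

    bins: list[GenomicBin]
    genome: dict[str, int]
    params: PartitionParams = field(default_factory=PartitionParams)

    def __len__(self) -> int:
        return len(self.bins)

    def __iter__(self):
        return iter(self.bins)

    def __getitem__(self, i):
        return self.bins[i]

    @property
    def bin_ids(self) -> list[str]:
        return [b.id for b in self.bins]

    def validate(self) -> None:
        """Assert the partition invariants (sortedness, disjointness,
        padding exclusion, off-target size bounds)."""
        p = self.params
        prev: GenomicBin | None = None
        for b in self.bins:
            if prev is not None and prev.chrom == b.chrom:
                if b.start < prev.end:
                    raise AssertionError(f"bins overlap: {prev.id} / {b.id}")
                if (prev.chrom, prev.start) > (b.chrom, b.start):
                    raise AssertionError("bins not sorted")
            if b.end > self.genome.get(b.chrom, b.end):
                raise AssertionError(f"bin {b.id} exceeds chromosome bounds")
            if b.kind == OFF_TARGET:
                if not (p.min_off_target <= b.length <= p.max_off_target):
                    raise AssertionError(f"off-target bin {b.id} violates size bounds")
            prev = b
        # padding exclusion: off bins disjoint from padded on bins
        on = [(b.chrom, b.start - p.padding_off_target, b.end + p.padding_off_target)
              for b in self.bins if b.kind == ON_TARGET]
        off = [(b.chrom, b.start, b.end) for b in self.bins if b.kind == OFF_TARGET]
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c, s, e in on:
            by_chrom.setdefault(c, []).append((s, e))
        for c, s, e in off:
            for s2, e2 in by_chrom.get(c, []):
                if s < e2 and s2 < e:
                    raise AssertionError(
                        f"off-target bin {c}:{s}-{e} intersects padded on-target {c}:{s2}-{e2}"
                    )

    # ------------------------------------------------------------------ I/O
    def to_bed(self, path) -> None:
        """Write the processed-bins BED (chrom, start, end, id, kind,
        exonic, gc); deterministic ordering and formatting."""
        with open(path, "w") as fh:
            for b in self.bins:
                gc = "NA" if math.isnan(b.gc) else f"{b.gc:.6f}"
                fh.write(
                    f"{b.chrom}\t{b.start}\t{b.end}\t{b.id}\t{b.kind}\t"
                    f"{int(b.exonic)}\t{gc}\n"
                )

    @classmethod
    def from_bed(cls, path, genome: dict[str, int] | None = None,
                 params: PartitionParams | None = None) -> "BinSet":
        bins: list[GenomicBin] = []
        max_end: dict[str, int] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                f = line.split("\t")
                if len(f) < 7:
                    raise ValueError(f"{path}:{ln}: expected 7 columns, got {len(f)}")
                chrom, start, end, bid, kind, exonic, gc = f[:7]
                b = GenomicBin(
                    chrom=chrom, start=int(start), end=int(end), kind=kind,
                    exonic=bool(int(exonic)),
                    gc=float("nan") if gc == "NA" else float(gc), id=bid,
                )
                bins.append(b)
                max_end[chrom] = max(max_end.get(chrom, 0), b.end)
        if genome is None:
            genome = max_end
        return cls(bins=bins, genome=genome, params=params or PartitionParams())


# --------------------------------------------------------------------------
# raw capture-target handling


def load_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column chrom<TAB>length table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.split()
            if len(f) < 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns")
            sizes[f[0]] = int(f[1])
    return sizes


def merge_intervals(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Sort and merge overlapping or book-ended intervals."""
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], end))
        else:
            out.append((chrom, start, end))
    return out


def read_capture_bed(path, genome: dict[str, int]) -> list[tuple[str, int, int]]:
    """Read a vendor capture BED (3+ columns), returning merged, sorted
    intervals clipped to chromosome bounds.

    Lines on chromosomes absent from ``genome`` are dropped with a
    warning (this is how chrY/chrM/alt contigs are excluded).  Malformed
    lines raise with the offending line number.
    """
    raw: list[tuple[str, int, int]] = []
    dropped: set[str] = set()
    n_lines = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: expected >=3 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{ln}: invalid interval {f[0]}:{start}-{end}")
            n_lines += 1
            chrom = f[0]
            if chrom not in genome:
                dropped.add(chrom)
                continue
            raw.append((chrom, max(0, start), min(end, genome[chrom])))
    if dropped:
        logger.warning("dropped targets on chromosomes absent from genome: %s",
                       ", ".join(sorted(dropped)))
    if n_lines == 0:
        raise ValueError(f"{path}: no target intervals found")
    return merge_intervals([iv for iv in raw if iv[2] > iv[1]])


def _split_equal(start: int, end: int, max_len: int) -> list[tuple[int, int]]:
    """Split [start, end) into ceil(len/max_len) parts whose lengths
    differ by at most 1 bp; remainder bases go one each to the leftmost
    parts."""
    length = end - start
    k = math.ceil(length / max_len)
    base, rem = divmod(length, k)
    parts = []
    pos = start
    for i in range(k):
        step = base + (1 if i < rem else 0)
        parts.append((pos, pos + step))
        pos += step
    return parts


def build_on_targets(raw: list[tuple[str, int, int]], genome: dict[str, int],
                     min_on_target: int = 100,
                     max_on_target: int = 300) -> list[GenomicBin]:
    """Resize merged capture intervals into on-target bins.

    Intervals shorter than ``min_on_target`` are extended symmetrically
    about their midpoint to exactly that length (the odd base goes to
    the right; extension clipped at a chromosome end is completed on the
    opposite side).  Intervals longer than ``max_on_target`` are split
    into near-equal parts.  Extension can create overlaps between
    neighbouring targets; those are re-merged before splitting so that
    the final bins are disjoint.
    """
    if not (0 < min_on_target <= max_on_target):
        raise ValueError("require 0 < min_on_target <= max_on_target")
    extended: list[tuple[str, int, int]] = []
    for chrom, start, end in raw:
        length = end - start
        clen = genome[chrom]
        if length < min_on_target:
            if clen < min_on_target:
                logger.warning(
                    "chromosome %s shorter than min_on_target; target spans it fully",
                    chrom)
                start, end = 0, clen
            else:
                deficit = min_on_target - length
                left = deficit // 2
                right = deficit - left
                start -= left
                end += right
                if start < 0:
                    end += -start
                    start = 0
                if end > clen:
                    start -= end - clen
                    end = clen
                start = max(start, 0)
        extended.append((chrom, start, end))
    bins: list[GenomicBin] = []
    for chrom, start, end in merge_intervals(extended):
        if end - start > max_on_target:
            for s, e in _split_equal(start, end, max_on_target):
                bins.append(GenomicBin(chrom, s, e, ON_TARGET))
        else:
            bins.append(GenomicBin(chrom, start, end, ON_TARGET))
    return bins


def build_off_targets(on_bins: list[GenomicBin], genome: dict[str, int],
                      padding_off_target: int = 300,
                      max_off_target: int = 50_000,
                      min_off_target: int = 1) -> list[GenomicBin]:
    """Complement of the padded on-target set within each chromosome.

    Gaps longer than ``max_off_target`` are equal-split; gaps shorter
    than ``min_off_target`` are discarded.
    """
    padded: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    for b in on_bins:
        padded.setdefault(b.chrom, []).append(
            (max(0, b.start - padding_off_target),
             min(genome[b.chrom], b.end + padding_off_target)))
    out: list[GenomicBin] = []
    for chrom in genome:
        merged = merge_intervals([(chrom, s, e) for s, e in padded[chrom]])
        cursor = 0
        gaps: list[tuple[int, int]] = []
        for _, s, e in merged:
            if s > cursor:
                gaps.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < genome[chrom]:
            gaps.append((cursor, genome[chrom]))
        for gs, ge in gaps:
            if ge - gs < min_off_target:
                continue
            if ge - gs > max_off_target:
                for s, e in _split_equal(gs, ge, max_off_target):
                    out.append(GenomicBin(chrom, s, e, OFF_TARGET))
            else:
                out.append(GenomicBin(chrom, gs, ge, OFF_TARGET))
    return out


def build_binset(raw_targets: list[tuple[str, int, int]], genome: dict[str, int],
                 params: PartitionParams | None = None) -> BinSet:
    """Run the whole partition: resize targets, complement to off-target
    bins, merge into one sorted BinSet."""
    params = params or PartitionParams()
    on = build_on_targets(raw_targets, genome, params.min_on_target,
                          params.max_on_target)
    off = build_off_targets(on, genome, params.padding_off_target,
                            params.max_off_target, params.min_off_target)
    bins = sorted(on + off, key=lambda b: (b.chrom, b.start))
    return BinSet(bins=bins, genome=dict(genome), params=params)


# --------------------------------------------------------------------------
# annotation


def annotate_exons(binset: BinSet, exon_bed) -> BinSet:
    """Flag every bin that overlaps >=1 bp of an exon interval.

    The annotation is optional: a missing file leaves all flags False
    with a warning.
    """
    import os

    if exon_bed is None or not os.path.exists(str(exon_bed)):
        logger.warning("exon annotation missing (%s): all bins non-exonic", exon_bed)
        for b in binset.bins:
            b.exonic = False
        return binset
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(exon_bed) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{exon_bed}:{ln}: expected >=3 BED columns")
            exons.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    merged = {c: merge_intervals([(c, s, e) for s, e in ivs])
              for c, ivs in exons.items()}
    for b in binset.bins:
        b.exonic = False
        for _, s, e in merged.get(b.chrom, []):
            if s < b.end and b.start < e:
                b.exonic = True
                break
            if s >= b.end:
                break
    return binset


def compute_gc(binset: BinSet, fasta) -> BinSet:
    """Fill per-bin GC fractions from an indexed reference FASTA.

    gc = (#G + #C) / (#non-N bases), case-insensitive; bins that are
    more than 50% N (or all-N) keep gc = NaN and are flagged unusable
    downstream by that NaN.
    """
    from pyfaidx import Fasta

    ref = fasta if not isinstance(fasta, (str, bytes)) else Fasta(str(fasta))
    for b in binset.bins:
        if b.chrom not in ref:
            raise KeyError(f"chromosome {b.chrom} missing from reference FASTA")
        seq = str(ref[b.chrom][b.start:b.end]).upper()
        n_n = seq.count("N")
        denom = len(seq) - n_n
        if denom == 0 or n_n > 0.5 * len(seq):
            b.gc = float("nan")
        else:
            b.gc = (seq.count("G") + seq.count("C")) / denom
    return binset


# --------------------------------------------------------------------------
# sizing advice


def recommend_max_offtarget(max_on_target: int, depth_ratio: float) -> int:
    """Recommended off-target bin size: 2 * max_on_target * depth_ratio,
    rounded to the nearest 1,000 bp.

    ``depth_ratio`` is the on/off per-base depth ratio (~80 for typical
    exomes); the factor 2 is a safety margin for the higher variability
    of off-target coverage.  At the defaults this lands on ~50 kbp.
    """
    if max_on_target <= 0 or depth_ratio <= 0:
        raise ValueError("max_on_target and depth_ratio must be positive")
    return int(round(2 * max_on_target * depth_ratio / 1000.0)) * 1000


def offtarget_depth_fraction(pct_on: float = 47.2, pct_near: float = 33.6,
                             pct_off: float = 18.0,
                             captured_genome_fraction: float = 0.057) -> float:
    """Expected off/on per-base depth fraction from read-mapping
    percentages.

    With pct_on of reads on target, pct_near in the padded vicinity, and
    pct_off elsewhere, while targets plus vicinity cover only
    ``captured_genome_fraction`` of the genome, off-target depth is
    pct_off/(pct_on+pct_near) * captured_genome_fraction of on-target
    depth — about 1/80 for typical whole-exome runs.
    """
    if min(pct_on, pct_near, pct_off) < 0 or pct_on + pct_near <= 0:
        raise ValueError("invalid read percentages")
    return pct_off / (pct_on + pct_near) * captured_genome_fraction
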