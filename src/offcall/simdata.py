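"""Synthetic bin sets, coverage matrices and mini alignment files.

The generator emulates the structure of a real capture batch: small
exonic on-target bins interleaved with large non-exonic off-target
bins, per-base off-target depth ~80x lower than on-target, a log-linear
GC bias, low-rank multiplicative batch noise shared across samples,
negative-binomial counting noise, and injected CNVs of known ploidy
(optionally covering only a fraction of their terminal bin, to mimic
partial-exon events).  It does not attempt to model capture chemistry,
fragment-size distributions or mappability artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import CoverageMatrix
from .intervals import OFF_TARGET, ON_TARGET, BinSet, GenomicBin, PartitionParams

logger = logging.getLogger(__name__)


@dataclass
class CnvSpec:
    """One injected CNV: ``fraction`` < 1 confines the event to that
    fraction of each affected bin (partial-bin event)."""

    sample: str
    first_bin: int
    n_bins: int
    ploidy: int
    fraction: float = 1.0


@dataclass
class SimConfig:
    n_samples: int = 20
    n_on_bins: int = 180
    n_off_bins: int = 60
    #: mean per-base depth of on-target bins
    depth_mean: float = 200.0
    #: off-target to on-target per-base depth ratio
    off_on_depth_ratio: float = 1.0 / 80.0
    #: log-linear GC bias: expected depth scaled by exp(slope * (gc - mean_gc))
    gc_bias_slope: float = 0.5
    #: rank of the shared multiplicative batch noise
    n_batch_factors: int = 3
    #: per-bin SD of the leading batch-factor pattern (log scale)
    factor_sd: float = 0.02
    #: geometric decay of successive factor strengths; real coverage
    #: batches show a dominant first component with a fast-decaying tail
    factor_decay: float = 0.4
    #: negative-binomial overdispersion alpha (variance = mu + alpha*mu^2);
    #: 0 gives Poisson counts.  4e-4 puts ~2% extra CV on deep bins.
    count_noise: float = 4e-4
    cnv_spec: list[CnvSpec] = field(default_factory=list)
    seed: int = 0
    n_chroms: int = 2
    include_chrx: bool = True
    on_size_range: tuple[int, int] = (100, 300)
    off_size_range: tuple[int, int] = (1000, 50_000)
    padding: int = 300

    def __post_init__(self) -> None:
        if not (0 < self.off_on_depth_ratio <= 1):
            raise ValueError("off_on_depth_ratio must lie in (0, 1]")
        if self.n_batch_factors >= self.n_samples:
            raise ValueError("n_batch_factors must be smaller than n_samples")


def simulate_bins(config: SimConfig) -> BinSet:
    """Alternating exonic on-target and non-exonic off-target bins on
    synthetic chromosomes, with padding-sized gaps so the partition
    invariants hold; per-bin GC drawn from Beta(10, 14) (mean ~0.42)."""
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    if config.include_chrx:
        chroms.append("chrX")
    n_ch = len(chroms)
    on_per = [config.n_on_bins // n_ch] * n_ch
    off_per = [config.n_off_bins // n_ch] * n_ch
    on_per[0] += config.n_on_bins - sum(on_per)
    off_per[0] += config.n_off_bins - sum(off_per)
    bins: list[GenomicBin] = []
    genome: dict[str, int] = {}
    for chrom, n_on, n_off in zip(chroms, on_per, off_per):
        cursor = 1000
        total = max(n_on, n_off) * 2
        placed_on = placed_off = 0
        for i in range(total):
            if i % 2 == 0 and placed_off < n_off:
                length = int(rng.integers(config.off_size_range[0],
                                          config.off_size_range[1] + 1))
                bins.append(GenomicBin(chrom, cursor, cursor + length,
                                       OFF_TARGET, exonic=False,
                                       gc=float(rng.beta(10, 14))))
                placed_off += 1
                cursor += length + config.padding
            elif i % 2 == 1 and placed_on < n_on:
                length = int(rng.integers(config.on_size_range[0],
                                          config.on_size_range[1] + 1))
                bins.append(GenomicBin(chrom, cursor, cursor + length,
                                       ON_TARGET, exonic=True,
                                       gc=float(rng.beta(10, 14))))
                placed_on += 1
                cursor += length + config.padding
        genome[chrom] = cursor + 1000
    params = PartitionParams(padding_off_target=config.padding,
                             max_off_target=config.off_size_range[1],
                             min_off_target=1)
    return BinSet(bins=bins, genome=genome, params=params)


def expected_counts(bins: BinSet, config: SimConfig) -> np.ndarray:
    """Expected aligned-base count per bin for a diploid sample with no
    batch noise (the generative mean before noise and CNVs)."""
    gc = np.array([b.gc for b in bins])
    length = np.array([b.length for b in bins], dtype=float)
    on = np.array([b.kind == ON_TARGET for b in bins])
    depth = np.where(on, config.depth_mean,
                     config.depth_mean * config.off_on_depth_ratio)
    bias = np.exp(config.gc_bias_slope * (gc - gc.mean()))
    return depth * length * bias


def simulate_matrix(bins: BinSet, config: SimConfig,
                    ) -> tuple[CoverageMatrix, pd.DataFrame]:
    """Draw the batch coverage matrix and return it with the CNV truth
    table.

    Expected count per bin and sample:
    depth * length * gc_bias * exp(loading . factor) * cn_factor, with
    cn_factor = (1-f) + f * ploidy/2 for an injected CNV covering
    fraction f of the bin.  Counts are negative-binomial around that
    mean (Poisson when ``count_noise`` is 0).
    """
    rng = np.random.default_rng(config.seed + 1)
    sample_ids = [f"S{i:03d}" for i in range(config.n_samples)]
    mu0 = expected_counts(bins, config)
    n_bins = len(bins)

    loadings = rng.normal(size=(config.n_samples, config.n_batch_factors))
    strengths = config.factor_sd * config.factor_decay ** np.arange(
        config.n_batch_factors)
    factors = rng.normal(size=(config.n_batch_factors, n_bins)) \
        * strengths[:, None]
    log_noise = loadings @ factors  # samples x bins

    cn = np.ones((config.n_samples, n_bins))
    truth_rows = []
    for spec in config.cnv_spec:
        s = sample_ids.index(spec.sample)
        lo, hi = spec.first_bin, spec.first_bin + spec.n_bins - 1
        if hi >= n_bins:
            raise ValueError(f"CNV spec {spec} exceeds bin count")
        f = spec.fraction
        cn[s, lo:hi + 1] *= (1 - f) + f * spec.ploidy / 2.0
        truth_rows.append({
            "sample": spec.sample, "chrom": bins[lo].chrom,
            "start": bins[lo].start, "end": bins[hi].end,
            "first_bin": lo, "last_bin": hi, "n_bins": spec.n_bins,
            "ploidy": spec.ploidy, "fraction": f,
            "type": "deletion" if spec.ploidy < 2 else "duplication",
            "bin_ids": ";".join(b.id for b in bins[lo:hi + 1]),
        })

    mu = mu0[None, :] * np.exp(log_noise) * cn
    if config.count_noise > 0:
        r = 1.0 / config.count_noise
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mu)
    matrix = CoverageMatrix(values=counts.T.astype(np.int64),
                            bin_ids=bins.bin_ids, sample_ids=sample_ids)
    truth = pd.DataFrame(truth_rows, columns=[
        "sample", "chrom", "start", "end", "first_bin", "last_bin",
        "n_bins", "ploidy", "fraction", "type", "bin_ids"])
    return matrix, truth


# --------------------------------------------------------------------------
# mini alignment files


@dataclass
class ReadSpec:
    chrom: str
    start: int
    length: int = 100
    mapq: int = 60
    cigar: str | None = None  # defaults to f"{length}M"
    is_duplicate: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    is_qcfail: bool = False
    is_unmapped: bool = False
    name: str = ""


def simulate_mini_bam(path, genome: dict[str, int],
                      reads: list[ReadSpec]) -> str:
    """Write a coordinate-sorted, indexed BAM with the given read
    placements (<= 10,000 reads) for exercising the coverage counter."""
    import pysam

    if len(reads) > 10_000:
        raise ValueError("mini alignment files are capped at 10,000 reads")
    chroms = list(genome)
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": c, "LN": int(genome[c])} for c in chroms]}
    path = str(path)
    tmp = path + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        for i, spec in enumerate(reads):
            a = pysam.AlignedSegment()
            a.query_name = spec.name or f"read{i:05d}"
            a.query_sequence = "A" * spec.length
            a.query_qualities = pysam.qualitystring_to_array("I" * spec.length)
            a.flag = 0
            a.is_duplicate = spec.is_duplicate
            a.is_secondary = spec.is_secondary
            a.is_supplementary = spec.is_supplementary
            a.is_qcfail = spec.is_qcfail
            if spec.is_unmapped:
                a.is_unmapped = True
            else:
                a.reference_id = chroms.index(spec.chrom)
                a.reference_start = spec.start
                a.mapping_quality = spec.mapq
                a.cigarstring = spec.cigar or f"{spec.length}M"
            out.write(a)
    pysam.sort("-o", path, tmp)
    pysam.index(path)
    import os
    os.unlink(tmp)
    return path


def random_read_specs(bins: BinSet, n_reads: int, seed: int,
                      read_length: int = 50) -> list[ReadSpec]:
    """Random reads around the bin territory, mixing mapping qualities
    and filter flags, for fuzzing the coverage counter."""
    rng = np.random.default_rng(seed)
    chroms = sorted({b.chrom for b in bins})
    specs = []
    for _ in range(n_reads):
        chrom = chroms[int(rng.integers(len(chroms)))]
        clen = bins.genome[chrom]
        start = int(rng.integers(0, max(clen - read_length, 1)))
        length = int(rng.integers(20, read_length + 1))
        cigar = None
        style = rng.random()
        if style < 0.2:  # deletion inside the read
            d = int(rng.integers(1, 10))
            half = length // 2
            cigar = f"{half}M{d}D{length - half}M"
        elif style < 0.35:  # soft-clipped head
            s = int(rng.integers(1, 10))
            cigar = f"{s}S{length - s}M"
        elif style < 0.45:  # insertion
            half = length // 2
            ins = int(rng.integers(1, 5))
            cigar = f"{half}M{ins}I{length - half - ins}M"
        specs.append(ReadSpec(
            chrom=chrom, start=start, length=length,
            mapq=int(rng.choice([0, 30, 49, 50, 60])),
            cigar=cigar,
            is_duplicate=bool(rng.random() < 0.1),
            is_secondary=bool(rng.random() < 0.05),
            is_qcfail=bool(rng.random() < 0.05),
        ))
    return specs
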