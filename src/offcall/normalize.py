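"""Control selection and coverage normalization for one test sample.

Copy number is inferred from the ratio of the test sample's coverage to
the average of a panel of controls drawn from the same batch.  Controls
are the batch samples whose coverage profiles correlate best with the
test sample (Pearson on log-scaled counts over up to 10,000 probe
bins); at least 15 and at most 96 are used.  Coverage is scaled by each
sample's total (so sequencing depth cancels), the ratio is regressed
against bin GC content and the fitted trend removed, and bins with
insufficient signal or excessive control variance are dropped.
Autosomes and chrX are treated independently throughout, so a
hemizygous X never contaminates the autosomal fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import CoverageMatrix
from .intervals import BinSet

logger = logging.getLogger(__name__)

MIN_CONTROLS = 15
MAX_CONTROLS = 96


@dataclass
class NormalizeParams:
    mincor: float = 0.9
    n_probe_bins: int = 10_000
    minsignal: float = 2500.0
    #: threshold on log10(variance of control ratios); bins above are dropped
    maxvar: float = -0.2
    #: analysis-bin size floor for non-exonic bins
    min_off_bin: int = 1000
    gc_mode: str = "additive"  # or "divisive"
    seed: int = 2024


@dataclass
class NormalizedProfile:
    """GC- and depth-normalized coverage ratios for one test sample."""

    test_id: str
    control_ids: list[str]
    bins: pd.DataFrame  # chrom, start, end, id, kind, exonic, gc, chrom_class
    ratio: np.ndarray  # per-bin test / mean-control ratio, GC-corrected
    control_ratios: np.ndarray  # bins x controls, same normalization
    control_mean_cov: np.ndarray  # raw mean control coverage per bin
    correlations: dict[str, float] = field(default_factory=dict)
    filter_report: dict[str, int] = field(default_factory=dict)

    @property
    def bin_ids(self) -> list[str]:
        return list(self.bins["id"])

    @property
    def chrom_class(self) -> np.ndarray:
        return self.bins["chrom_class"].to_numpy()

    @property
    def max_control_correlation(self) -> float:
        return max(self.correlations.values()) if self.correlations else float("nan")

    def to_tsv(self, path) -> None:
        df = self.bins[["id", "chrom", "start", "end", "kind", "exonic"]].copy()
        df["ratio"] = self.ratio
        df["control_mean"] = self.control_ratios.mean(axis=1)
        df["control_var"] = self.control_ratios.var(axis=1, ddof=1)
        df.to_csv(path, sep="\t", index=False)


def binset_frame(bins: BinSet) -> pd.DataFrame:
    df = pd.DataFrame(
        {"chrom": [b.chrom for b in bins], "start": [b.start for b in bins],
         "end": [b.end for b in bins], "id": [b.id for b in bins],
         "kind": [b.kind for b in bins], "exonic": [b.exonic for b in bins],
         "gc": [b.gc for b in bins],
         "chrom_class": [b.chrom_class for b in bins]})
    df["length"] = df["end"] - df["start"]
    return df


# --------------------------------------------------------------------------
# control selection


def select_controls(matrix: CoverageMatrix, bins: pd.DataFrame | BinSet,
                    test_id: str, mincor: float = 0.9,
                    n_probe_bins: int = 10_000, minsignal: float = 2500.0,
                    maxvar: float = -0.2, seed: int = 2024,
                    ) -> tuple[list[str], dict[str, float]]:
    """Pick control samples by coverage correlation with the test sample.

    Correlation is Pearson on log2(count+1) over up to ``n_probe_bins``
    autosomal on-target bins that pass the signal and variance
    requirements, sampled without replacement with the given seed.
    Samples at or above ``mincor`` are retained, floored at 15 (top-15
    by correlation if fewer pass, or all others in batches smaller than
    16) and capped at 96.
    """
    if isinstance(bins, BinSet):
        bins = binset_frame(bins)
    if matrix.n_samples < 2:
        raise ValueError("no controls available: batch has a single sample")
    if test_id not in matrix.sample_ids:
        raise KeyError(f"unknown sample {test_id}")

    vals = matrix.values.astype(float)
    on_auto = ((bins["kind"].to_numpy() == "on_target")
               & (bins["chrom_class"].to_numpy() == "autosome"))
    mean_cov = vals.mean(axis=1)
    colsum = vals.sum(axis=0)
    norm = vals / colsum * colsum.mean()
    row_mean = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(row_mean[:, None] > 0,
                         norm / np.where(row_mean > 0, row_mean, 1)[:, None],
                         np.nan)
        logvar = np.log10(np.nanvar(ratio, axis=1, ddof=1))
    eligible = on_auto & (mean_cov >= minsignal) & (logvar <= maxvar)
    if not eligible.any():
        logger.warning("no probe bins pass signal/variance requirements; "
                       "falling back to all autosomal on-target bins")
        eligible = on_auto
    idx = np.flatnonzero(eligible)
    rng = np.random.default_rng(seed)
    if idx.size > n_probe_bins:
        idx = rng.choice(idx, size=n_probe_bins, replace=False)
        idx.sort()

    logcov = np.log2(vals[idx] + 1.0)
    t = matrix.sample_ids.index(test_id)
    x = logcov[:, t]
    cors: dict[str, float] = {}
    for j, sid in enumerate(matrix.sample_ids):
        if j == t:
            continue
        y = logcov[:, j]
        if x.std() == 0 or y.std() == 0:
            cors[sid] = 0.0
        else:
            cors[sid] = float(np.corrcoef(x, y)[0, 1])
    # descending correlation, sample id breaks ties deterministically
    ranked = sorted(cors, key=lambda s: (-cors[s], s))
    passing = [s for s in ranked if cors[s] >= mincor]
    floor = min(MIN_CONTROLS, len(ranked))
    if len(passing) < floor:
        passing = ranked[:floor]
    selected = passing[:MAX_CONTROLS]
    return selected, cors


# --------------------------------------------------------------------------
# bin selection and normalization


def select_analysis_bins(bins: pd.DataFrame | BinSet,
                         min_off_bin: int = 1000) -> np.ndarray:
    """Boolean mask of analysable bins: exonic, or at least
    ``min_off_bin`` bp long."""
    if isinstance(bins, BinSet):
        bins = binset_frame(bins)
    length = (bins["end"] - bins["start"]).to_numpy()
    return bins["exonic"].to_numpy().astype(bool) | (length >= min_off_bin)


def depth_normalize(values: np.ndarray, chrom_class: np.ndarray,
                    sample_ids: list[str] | None = None) -> np.ndarray:
    """Scale each sample's column by its total coverage so that depth
    differences cancel, then restore the batch-mean scale; autosomes and
    chrX are normalized independently."""
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for cls in np.unique(chrom_class):
        m = chrom_class == cls
        tot = values[m].sum(axis=0)
        if (tot == 0).any():
            j = int(np.argmax(tot == 0))
            sid = sample_ids[j] if sample_ids else f"column {j}"
            raise ValueError(f"zero total coverage ({cls}) for sample {sid}")
        out[m] = values[m] / tot * tot.mean()
    return out


def gc_normalize(ratio: np.ndarray, gc: np.ndarray, chrom_class: np.ndarray,
                 mode: str = "additive") -> np.ndarray:
    """Remove the linear GC trend from a coverage ratio.

    A least-squares line ratio ~ gc is fitted separately for autosomes
    and chrX; the fitted deviation from the class mean is subtracted
    (additive mode, default) or divided out (divisive mode).  A constant
    GC vector leaves the ratio unchanged.
    """
    ratio = np.asarray(ratio, dtype=float)
    out = ratio.copy()
    for cls in np.unique(chrom_class):
        m = (chrom_class == cls) & np.isfinite(gc) & np.isfinite(ratio)
        if m.sum() < 3 or np.ptp(gc[m]) < 1e-12:
            logger.warning("GC correction skipped for %s (constant or sparse GC)", cls)
            continue
        slope, intercept = np.polyfit(gc[m], ratio[m], 1)
        fitted = slope * gc[m] + intercept
        if mode == "additive":
            out[m] = ratio[m] - (fitted - ratio[m].mean())
        elif mode == "divisive":
            safe = np.where(np.abs(fitted) < 1e-6, 1e-6, fitted)
            out[m] = ratio[m] / safe * ratio[m].mean()
        else:
            raise ValueError(f"unknown GC mode {mode!r}")
    return out


def filter_bins(control_ratios: np.ndarray, control_mean_cov: np.ndarray,
                minsignal: float = 2500.0, maxvar: float = -0.2,
                ) -> tuple[np.ndarray, dict[str, int]]:
    """Mask of bins passing the signal and variance filters.

    Drops bins whose mean raw control coverage is below ``minsignal``
    and bins whose control-ratio variance exceeds 10**maxvar (bins with
    zero variance pass).  Returns the keep mask and per-rule counts.
    """
    var = control_ratios.var(axis=1, ddof=1)
    with np.errstate(divide="ignore"):
        logvar = np.where(var > 0, np.log10(np.where(var > 0, var, 1.0)), -np.inf)
    low_signal = control_mean_cov < minsignal
    high_var = logvar > maxvar
    keep = ~(low_signal | high_var)
    report = {"low_signal": int(low_signal.sum()),
              "high_variance": int((high_var & ~low_signal).sum()),
              "kept": int(keep.sum())}
    if not keep.any():
        raise ValueError("no analysable bins survive the signal/variance filters")
    return keep, report


# --------------------------------------------------------------------------
# orchestration


def normalize_sample(matrix: CoverageMatrix, bins: BinSet | pd.DataFrame,
                     test_id: str, params: NormalizeParams | None = None,
                     control_ids: list[str] | None = None) -> NormalizedProfile:
    """Full normalization of one test sample against its control panel.

    Steps: control selection (unless ``control_ids`` is given), analysis
    bin restriction, per-sample depth scaling, test/mean-control ratio,
    GC regression per sample, then the signal/variance bin filters.
    """
    params = params or NormalizeParams()
    frame = binset_frame(bins) if isinstance(bins, BinSet) else bins.copy()
    if list(frame["id"]) != list(matrix.bin_ids):
        raise ValueError("bin ids of matrix and bin set disagree")

    cors: dict[str, float] = {}
    if control_ids is None:
        control_ids, cors = select_controls(
            matrix, frame, test_id, mincor=params.mincor,
            n_probe_bins=params.n_probe_bins, minsignal=params.minsignal,
            maxvar=params.maxvar, seed=params.seed)
    sel = {sid: cors.get(sid, float("nan")) for sid in control_ids}

    mask = select_analysis_bins(frame, params.min_off_bin)
    frame = frame.loc[mask].reset_index(drop=True)
    cls = frame["chrom_class"].to_numpy()
    gc = frame["gc"].to_numpy()

    cols = [test_id] + list(control_ids)
    jidx = [matrix.sample_ids.index(s) for s in cols]
    vals = matrix.values[np.asarray(mask)][:, jidx].astype(float)
    raw_ctrl_mean = vals[:, 1:].mean(axis=1)

    norm = depth_normalize(vals, cls, cols)
    ctrl_mean = norm[:, 1:].mean(axis=1)
    safe = np.where(ctrl_mean > 0, ctrl_mean, np.nan)
    ratios = norm / safe[:, None]

    corrected = np.column_stack([
        gc_normalize(ratios[:, j], gc, cls, mode=params.gc_mode)
        for j in range(ratios.shape[1])])

    # re-centre every sample at its median ratio per chromosome class:
    # dividing by the sample total makes a large CNV deflate/inflate all
    # other bins of its carrier, and the median is insensitive to that
    # mass shift while the mean is not
    for c in np.unique(cls):
        mcls = cls == c
        med = np.nanmedian(corrected[mcls], axis=0)
        corrected[mcls] /= np.where(np.abs(med) > 0.1, med, 1.0)

    good = np.isfinite(corrected).all(axis=1)
    keep, report = filter_bins(corrected[good][:, 1:], raw_ctrl_mean[good],
                               minsignal=params.minsignal, maxvar=params.maxvar)
    report["nonfinite"] = int((~good).sum())
    full_keep = np.zeros(len(frame), dtype=bool)
    full_keep[np.flatnonzero(good)[keep]] = True

    return NormalizedProfile(
        test_id=test_id, control_ids=list(control_ids),
        bins=frame.loc[full_keep].reset_index(drop=True),
        ratio=corrected[full_keep, 0],
        control_ratios=corrected[full_keep, 1:],
        control_mean_cov=raw_ctrl_mean[full_keep],
        correlations=sel, filter_report=report)
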