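"""CNV calling from a denoised coverage profile.

Multi-bin events come from Viterbi decoding of a 3-state hidden Markov
model (deletion / normal / duplication) over the ordered analysis bins
of each chromosome.  The transition structure is sparse: leaving the
normal state costs p_enter = 5e-5 per CNV state, staying inside a CNV
state has probability 0.5.  Emissions are state-conditional Gaussians
on the denoised ratio, centred at 0.5 / 1.0 / 1.5 with per-bin
standard deviations estimated from the (outlier-trimmed) controls.
Bins not covered by a multi-bin event can still be called as single-bin
events when their |Z| exceeds minZ (default 4).  Each event then gets
an integer ploidy: the copy number whose expected ratio p/expected
minimizes the event-level |Z|.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DELETION, NORMAL, DUPLICATION = 0, 1, 2
STATE_NAMES = ("deletion", "normal", "duplication")
STATE_MEANS = (0.5, 1.0, 1.5)


@dataclass
class HmmSpec:
    p_enter: float = 0.00005
    p_stay: float = 0.5
    sd_floor: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.p_enter < 0.5):
            raise ValueError("p_enter must lie in (0, 0.5)")
        if not (0 < self.p_stay < 1) or self.p_stay + self.p_enter >= 1:
            raise ValueError("p_stay must lie in (0,1) with p_stay+p_enter<1")

    def transition_matrix(self) -> np.ndarray:
        pe, ps = self.p_enter, self.p_stay
        T = np.array([
            [ps, 1 - ps - pe, pe],          # deletion ->
            [pe, 1 - 2 * pe, pe],           # normal ->
            [pe, 1 - ps - pe, ps],          # duplication ->
        ])
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)
        return T

    def initial_distribution(self) -> np.ndarray:
        pe = self.p_enter
        return np.array([pe, 1 - 2 * pe, pe])


@dataclass
class CnvCall:
    sample: str
    chrom: str
    start: int
    end: int
    bin_ids: list[str]
    type: str  # deletion | duplication
    ploidy: int
    n_bins: int
    mean_z: float
    mean_ratio: float
    quality: float
    hq: bool = False
    genes: str = ""
    population_overlap: float = 0.0
    pathogenic: str = ""
    single_bin: bool = False


# --------------------------------------------------------------------------
# control trimming and Z-scores


def exclude_outlier_controls(control_ratios: np.ndarray,
                             n_sd: float = 2.0) -> np.ndarray:
    """Per-bin boolean keep-mask over controls.

    A control is dropped at a bin when its ratio lies outside mean +/- 2 SD
    of the controls at that bin (single pass, not iterated).  At least 3
    controls are always retained — the closest to the mean if trimming
    would leave fewer.  With SD = 0 all controls are kept.
    """
    R = np.asarray(control_ratios, dtype=float)
    if R.shape[1] < 3:
        raise ValueError("need at least 3 controls to trim outliers")
    mean = R.mean(axis=1, keepdims=True)
    sd = R.std(axis=1, ddof=1, keepdims=True)
    dev = np.abs(R - mean)
    keep = (dev <= n_sd * sd) | (sd == 0)
    short = keep.sum(axis=1) < 3
    if short.any():
        order = np.argsort(dev[short], axis=1)
        fix = np.zeros_like(keep[short])
        np.put_along_axis(fix, order[:, :3], True, axis=1)
        keep[short] = fix
    return keep


def trimmed_moments(control_ratios: np.ndarray, keep: np.ndarray,
                    sd_floor: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Mean and (floored) SD over the kept controls of each bin."""
    R = np.asarray(control_ratios, dtype=float)
    n = keep.sum(axis=1)
    mean = np.where(keep, R, 0).sum(axis=1) / n
    var = np.where(keep, (R - mean[:, None]) ** 2, 0).sum(axis=1) / np.maximum(n - 1, 1)
    sd = np.maximum(np.sqrt(var), sd_floor)
    return mean, sd


def zscores(test: np.ndarray, control_ratios: np.ndarray,
            keep: np.ndarray | None = None,
            sd_floor: float = 0.01) -> np.ndarray:
    """Per-bin Z = (test - trimmed control mean) / trimmed control SD."""
    if keep is None:
        keep = np.ones(control_ratios.shape, dtype=bool)
    mean, sd = trimmed_moments(control_ratios, keep, sd_floor)
    return (np.asarray(test, float) - mean) / sd


# --------------------------------------------------------------------------
# Viterbi decoding


def _log_emissions(ratio: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """bins x 3 matrix of Gaussian log-densities at the state means."""
    x = np.asarray(ratio, float)[:, None]
    mu = np.asarray(STATE_MEANS)[None, :]
    s = np.asarray(sd, float)[:, None]
    return -0.5 * ((x - mu) / s) ** 2 - np.log(s) - 0.5 * math.log(2 * math.pi)


def viterbi_path(log_emis: np.ndarray, hmm: HmmSpec) -> np.ndarray:
    """Maximum-probability state sequence, computed in log space."""
    n = log_emis.shape[0]
    logT = np.log(hmm.transition_matrix())
    logpi = np.log(hmm.initial_distribution())
    # plain-float DP over 3 states: faster than numpy at this width
    t = [[float(logT[i, j]) for j in range(3)] for i in range(3)]
    e = log_emis
    v = [float(logpi[s] + e[0, s]) for s in range(3)]
    back = np.empty((n, 3), dtype=np.int8)
    for i in range(1, n):
        e0, e1, e2 = float(e[i, 0]), float(e[i, 1]), float(e[i, 2])
        nv = [0.0, 0.0, 0.0]
        for j, ej in ((0, e0), (1, e1), (2, e2)):
            b, bv = 0, v[0] + t[0][j]
            c = v[1] + t[1][j]
            if c > bv:
                b, bv = 1, c
            c = v[2] + t[2][j]
            if c > bv:
                b, bv = 2, c
            nv[j] = bv + ej
            back[i, j] = b
        v = nv
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(v))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def viterbi_segment(ratio: np.ndarray, sd: np.ndarray, chrom: np.ndarray,
                    hmm: HmmSpec | None = None,
                    ) -> list[tuple[int, int, int]]:
    """Decode per chromosome and return candidate multi-bin events as
    (first_bin_index, last_bin_index_inclusive, state) with >=2 bins.

    Single-bin non-normal runs are left to the Z-score rule.
    """
    hmm = hmm or HmmSpec()
    chrom = np.asarray(chrom)
    events: list[tuple[int, int, int]] = []
    start = 0
    for c in pd.unique(chrom):
        m = chrom == c
        idx = np.flatnonzero(m)
        path = viterbi_path(_log_emissions(ratio[m], sd[m]), hmm)
        i = 0
        while i < len(path):
            s = path[i]
            j = i
            while j + 1 < len(path) and path[j + 1] == s:
                j += 1
            if s != NORMAL and j - i + 1 >= 2:
                events.append((int(idx[i]), int(idx[j]), int(s)))
            i = j + 1
        start += m.sum()
    return events


def single_bin_events(z: np.ndarray, multi_events: list[tuple[int, int, int]],
                      min_z: float = 4.0) -> list[tuple[int, int, int]]:
    """Single-bin events from |Z| >= min_z, suppressed inside multi-bin
    events."""
    covered = np.zeros(len(z), dtype=bool)
    for lo, hi, _ in multi_events:
        covered[lo:hi + 1] = True
    out = []
    for i in np.flatnonzero((np.abs(z) >= min_z) & ~covered):
        out.append((int(i), int(i), DELETION if z[i] < 0 else DUPLICATION))
    return out


# --------------------------------------------------------------------------
# ploidy, quality, HQ


def assign_ploidy(event_ratios: np.ndarray, event_sds: np.ndarray,
                  expected_ploidy: int = 2, max_ploidy: int = 6) -> int:
    """Integer copy number whose expected ratio p/expected_ploidy gives
    the smallest event-level |Z|; ties resolve toward the expected
    ploidy."""
    r = np.asarray(event_ratios, float)
    sd = np.asarray(event_sds, float)
    se = math.sqrt(float(np.mean(sd**2)) / r.size)
    mean_ratio = float(r.mean())
    best_p, best = None, None
    for p in range(0, max_ploidy + 1):
        zz = abs(mean_ratio - p / expected_ploidy) / se
        key = (zz, abs(p - expected_ploidy))
        if best is None or key < best:
            best, best_p = key, p
    return int(best_p)


def event_quality(ratio: np.ndarray, sd: np.ndarray, lo: int, hi: int,
                  state: int, hmm: HmmSpec | None = None) -> float:
    """Log-probability contrast (nats) of the decoded event path against
    the forced all-normal path over the event's bins, transitions
    included."""
    hmm = hmm or HmmSpec()
    e = _log_emissions(ratio[lo:hi + 1], sd[lo:hi + 1])
    n = hi - lo + 1
    logT = np.log(hmm.transition_matrix())
    ev = e[:, state].sum() + logT[NORMAL, state] + (n - 1) * logT[state, state] \
        + logT[state, NORMAL]
    nn = e[:, NORMAL].sum() + (n + 1) * logT[NORMAL, NORMAL]
    return float(ev - nn)


@dataclass
class HqThresholds:
    """High-confidence (HQ) call filter.

    An event is high quality when its evidence is strong (|mean Z| >= min_abs_z
    or >= min_bins supporting bins), its decoding contrast reaches
    min_quality nats, and the sample itself is well matched to the batch
    (max pairwise correlation >= min_corr).  These defaults are this
    implementation's own calibration.
    """

    min_abs_z: float = 5.0
    min_bins: int = 3
    min_quality: float = 10.0
    min_corr: float = 0.9


def hq_filter(events: list[CnvCall], sample_max_corr: float,
              thresholds: HqThresholds | None = None) -> list[CnvCall]:
    """Set the hq flag in place; every event stays reported."""
    th = thresholds or HqThresholds()
    corr_ok = (math.isnan(sample_max_corr)
               or sample_max_corr >= th.min_corr)
    for ev in events:
        strong = abs(ev.mean_z) >= th.min_abs_z or ev.n_bins >= th.min_bins
        ev.hq = bool(strong and ev.quality >= th.min_quality and corr_ok)
    return events


# --------------------------------------------------------------------------
# assembly


def call_events(profile_bins: pd.DataFrame, ratio: np.ndarray,
                control_ratios: np.ndarray, sample: str,
                hmm: HmmSpec | None = None, min_z: float = 4.0,
                expected_ploidy_x: int = 2,
                sample_max_corr: float = float("nan"),
                hq_thresholds: HqThresholds | None = None) -> tuple[list[CnvCall], np.ndarray]:
    """Full segmentation of one denoised profile into CnvCall records.

    Returns the calls and the per-bin Z vector used for single-bin
    calling.
    """
    hmm = hmm or HmmSpec()
    keep = exclude_outlier_controls(control_ratios)
    mean, sd = trimmed_moments(control_ratios, keep, hmm.sd_floor)
    z = (ratio - mean) / sd
    chrom = profile_bins["chrom"].to_numpy()
    cls = profile_bins["chrom_class"].to_numpy()
    multi = viterbi_segment(ratio, sd, chrom, hmm)
    single = single_bin_events(z, multi, min_z)
    calls: list[CnvCall] = []
    for lo, hi, state in multi + single:
        exp = expected_ploidy_x if cls[lo] == "chrX" else 2
        ploidy = assign_ploidy(ratio[lo:hi + 1], sd[lo:hi + 1], exp)
        etype = STATE_NAMES[state]
        # ploidy must agree with the event direction; rails at the boundary
        if etype == "deletion" and ploidy >= exp:
            ploidy = exp - 1
        elif etype == "duplication" and ploidy <= exp:
            ploidy = exp + 1
        calls.append(CnvCall(
            sample=sample,
            chrom=str(chrom[lo]),
            start=int(profile_bins["start"].iloc[lo]),
            end=int(profile_bins["end"].iloc[hi]),
            bin_ids=list(profile_bins["id"].iloc[lo:hi + 1]),
            type=etype,
            ploidy=ploidy,
            n_bins=hi - lo + 1,
            mean_z=float(z[lo:hi + 1].mean()),
            mean_ratio=float(ratio[lo:hi + 1].mean()),
            quality=event_quality(ratio, sd, lo, hi, state, hmm),
            single_bin=(hi == lo),
        ))
    hq_filter(calls, sample_max_corr, hq_thresholds)
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls, z


def events_to_frame(events: list[CnvCall]) -> pd.DataFrame:
    cols = ["sample", "chrom", "start", "end", "type", "ploidy", "n_bins",
            "mean_z", "mean_ratio", "quality", "hq", "genes",
            "population_overlap", "pathogenic"]
    return pd.DataFrame([{c: getattr(ev, c) for c in cols} for ev in events],
                        columns=cols)
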