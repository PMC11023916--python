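"""Annotation of CNV calls against user-supplied tracks and plotting.

Tracks are plain BED4+ files: gene-labelled exons, population (benign)
CNVs with a type/frequency label, and pathogenic CNVs with a clinical
label.  All tracks are optional; absent tracks simply leave the
corresponding columns empty.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .normalize import NormalizedProfile
from .segment import CnvCall, events_to_frame

logger = logging.getLogger(__name__)


def _load_track(path) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    if path is None:
        return trees
    if not os.path.exists(str(path)):
        logger.warning("annotation track missing: %s", path)
        return trees
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                if end <= start:
                    raise ValueError
            except (ValueError, IndexError):
                logger.warning("%s:%d: skipping malformed track line", path, ln)
                continue
            label = f[3] if len(f) > 3 else ""
            trees.setdefault(chrom, IntervalTree()).addi(start, end, label)
    return trees


def _label_type(label: str) -> str:
    low = label.lower()
    if "del" in low or "loss" in low:
        return "deletion"
    if "dup" in low or "gain" in low:
        return "duplication"
    return "mixed"


@dataclass
class AnnotationTracks:
    """Optional exon / population-CNV / pathogenic-CNV interval tracks."""

    exons: dict[str, IntervalTree] = field(default_factory=dict)
    population_cnvs: dict[str, IntervalTree] = field(default_factory=dict)
    pathogenic_cnvs: dict[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def from_files(cls, exon_bed=None, population_bed=None,
                   pathogenic_bed=None) -> "AnnotationTracks":
        return cls(exons=_load_track(exon_bed),
                   population_cnvs=_load_track(population_bed),
                   pathogenic_cnvs=_load_track(pathogenic_bed))


def annotate_calls(events: list[CnvCall],
                   tracks: AnnotationTracks) -> list[CnvCall]:
    """Fill gene symbols, population-CNV overlap fraction (matching type
    only) and pathogenic labels on each call; coordinates, ploidy and hq
    flags are never touched."""
    for ev in events:
        hits = tracks.exons.get(ev.chrom, IntervalTree()).overlap(ev.start, ev.end)
        ev.genes = ",".join(sorted({h.data for h in hits if h.data}))
        frac = 0.0
        for h in tracks.population_cnvs.get(ev.chrom, IntervalTree()).overlap(
                ev.start, ev.end):
            if _label_type(h.data) not in (ev.type, "mixed"):
                continue
            ov = min(ev.end, h.end) - max(ev.start, h.begin)
            frac = max(frac, ov / (ev.end - ev.start))
        ev.population_overlap = frac
        path_hits = tracks.pathogenic_cnvs.get(ev.chrom, IntervalTree()).overlap(
            ev.start, ev.end)
        ev.pathogenic = ",".join(sorted({h.data for h in path_hits if h.data}))
    return events


# --------------------------------------------------------------------------
# tabular exports


def write_events_tsv(events: list[CnvCall], path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False,
                                   float_format="%.4f")


def write_annotsv_bed(events: list[CnvCall], path) -> None:
    """BED-like export consumable by downstream structural-variant
    annotators (chrom, start, end, type in DEL/DUP nomenclature)."""
    with open(path, "w") as fh:
        for ev in events:
            sv = "DEL" if ev.type == "deletion" else "DUP"
            fh.write(f"{ev.chrom}\t{ev.start}\t{ev.end}\t{sv}\t{ev.sample}\n")


def write_igv_seg(profile: NormalizedProfile, denoised: np.ndarray, path) -> None:
    """Per-bin segment file (log2 ratio) loadable in genome viewers."""
    with np.errstate(divide="ignore"):
        log2 = np.log2(np.maximum(denoised, 1e-6))
    with open(path, "w") as fh:
        fh.write("Sample\tChromosome\tStart\tEnd\tNum_Probes\tSegment_Mean\n")
        for i, row in profile.bins.iterrows():
            fh.write(f"{profile.test_id}\t{row.chrom}\t{row.start}\t{row.end}"
                     f"\t1\t{log2[i]:.4f}\n")


# --------------------------------------------------------------------------
# plotting


def _bin_window(profile: NormalizedProfile, event: CnvCall,
                flank: int = 10) -> np.ndarray:
    ids = profile.bins["id"]
    pos = ids[ids.isin(event.bin_ids)].index.to_numpy()
    if pos.size == 0:
        raise ValueError("event bins not present in profile window")
    chrom_mask = (profile.bins["chrom"] == event.chrom).to_numpy()
    lo = max(int(pos.min()) - flank, int(np.flatnonzero(chrom_mask).min()))
    hi = min(int(pos.max()) + flank, int(np.flatnonzero(chrom_mask).max()))
    return np.arange(lo, hi + 1)


def plot_cnv(event: CnvCall, profile: NormalizedProfile,
             denoised: np.ndarray, path, flank: int = 10) -> None:
    """Per-CNV strip plot: test ratio vs the control envelope, event
    span shaded, on/off-target bins distinguishable by marker."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    idx = _bin_window(profile, event, flank)
    x = np.arange(idx.size)
    ctrl = profile.control_ratios[idx]
    lo, hi = ctrl.min(axis=1), ctrl.max(axis=1)
    on = (profile.bins["kind"].iloc[idx] == "on_target").to_numpy()

    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.fill_between(x, lo, hi, color="0.8", label="control range")
    for mask, marker, lab in ((on, "s", "on-target"), (~on, "o", "off-target")):
        if mask.any():
            ax.plot(x[mask], denoised[idx][mask], marker, color="crimson",
                    ms=5, lw=0, label=f"test ({lab})")
    ax.plot(x, denoised[idx], color="crimson", lw=0.8)
    in_ev = profile.bins["id"].iloc[idx].isin(event.bin_ids).to_numpy()
    if in_ev.any():
        ax.axvspan(x[in_ev].min() - 0.5, x[in_ev].max() + 0.5,
                   color="steelblue", alpha=0.15,
                   label=f"{event.type} (CN={event.ploidy})")
    ax.axhline(1.0, color="k", lw=0.5, ls=":")
    ax.set_xlabel(f"analysis bins around {event.chrom}:{event.start}-{event.end}")
    ax.set_ylabel("normalized ratio")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_chromosome(profile: NormalizedProfile, denoised: np.ndarray,
                    chrom: str, path) -> None:
    """Whole-chromosome profile over every analysis bin."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = (profile.bins["chrom"] == chrom).to_numpy()
    if not m.any():
        raise ValueError(f"no analysis bins on {chrom}")
    x = np.arange(m.sum())
    fig, ax = plt.subplots(figsize=(9, 3))
    ctrl = profile.control_ratios[m]
    ax.fill_between(x, ctrl.min(axis=1), ctrl.max(axis=1), color="0.85")
    ax.plot(x, denoised[m], ".", ms=2, color="crimson")
    ax.axhline(1.0, color="k", lw=0.5, ls=":")
    ax.set_xlabel(f"analysis bins on {chrom}")
    ax.set_ylabel("normalized ratio")
    ax.set_title(profile.test_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
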