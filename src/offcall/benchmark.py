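"""Recovery benchmarks on simulated batches.

These harnesses measure the caller's event-level sensitivity, ploidy
accuracy and single-bin recovery against the generator's truth table,
and compare leave-one-out PCA with standard test-included PCA on
artificial-CNV retrieval — the in-silico analogues of validating
against experimentally confirmed CNVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import BinSet
from .normalize import normalize_sample, select_analysis_bins
from .pipeline import RunConfig, call_sample
from .simdata import CnvSpec, SimConfig, expected_counts, simulate_bins, simulate_matrix

logger = logging.getLogger(__name__)


def callable_bin_mask(bins: BinSet, config: SimConfig,
                      minsignal: float = 2500.0,
                      margin: float = 1.3) -> np.ndarray:
    """Bins where injected CNVs are detectable in principle: analysis
    bins whose expected diploid coverage clears the signal filter with
    some margin."""
    mask = select_analysis_bins(bins)
    mu = expected_counts(bins, config)
    return mask & (mu >= margin * minsignal)


def random_cnv_specs(bins: BinSet, config: SimConfig, samples: list[str],
                     rng: np.random.Generator, events_per_sample: int = 3,
                     max_span: int = 30) -> list[CnvSpec]:
    """Draw non-overlapping CNVs of 1..max_span callable bins per test
    sample: heterozygous and homozygous deletions plus duplications,
    with occasional partial-bin single-bin deletions."""
    ok = callable_bin_mask(bins, config)
    chrom = np.array([b.chrom for b in bins])
    specs: list[CnvSpec] = []
    for sample in samples:
        taken: list[tuple[int, int]] = []
        attempts = 0
        while len([s for s in specs if s.sample == sample]) < events_per_sample:
            attempts += 1
            if attempts > 500:
                raise RuntimeError("could not place CNVs; too few callable bins")
            if rng.random() < 0.4:
                span = 1
            else:
                span = int(rng.integers(2, max_span + 1))
            start = int(rng.integers(0, len(bins) - span))
            sl = slice(start, start + span)
            if not ok[sl].all() or len(set(chrom[sl])) != 1:
                continue
            if any(start <= hi + 5 and start + span + 5 >= lo
                   for lo, hi in taken):
                continue
            u = rng.random()
            ploidy = 1 if u < 0.6 else (0 if u < 0.8 else 3)
            fraction = 1.0
            if span == 1 and ploidy == 1 and rng.random() < 0.35:
                fraction = float(rng.uniform(0.6, 0.9))
            specs.append(CnvSpec(sample=sample, first_bin=start, n_bins=span,
                                 ploidy=ploidy, fraction=fraction))
            taken.append((start, start + span - 1))
    return specs


@dataclass
class RecoveryTally:
    n_truth: int = 0
    n_detected: int = 0
    n_ploidy_correct: int = 0
    n_single_high_z: int = 0
    n_single_high_z_recovered: int = 0
    per_batch: list[dict] = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        return self.n_detected / self.n_truth if self.n_truth else float("nan")

    @property
    def ploidy_accuracy(self) -> float:
        return (self.n_ploidy_correct / self.n_detected
                if self.n_detected else float("nan"))

    @property
    def single_bin_recovery(self) -> float:
        return (self.n_single_high_z_recovered / self.n_single_high_z
                if self.n_single_high_z else float("nan"))

    def summary(self) -> dict[str, float]:
        return {"sensitivity": self.sensitivity,
                "ploidy_accuracy": self.ploidy_accuracy,
                "single_bin_recovery": self.single_bin_recovery,
                "n_truth": self.n_truth, "n_detected": self.n_detected}


def evaluate_batch(seed: int, n_samples: int = 20, n_on_bins: int = 3800,
                   n_off_bins: int = 1200, test_samples: int = 3,
                   events_per_sample: int = 3,
                   tally: RecoveryTally | None = None,
                   run_config: RunConfig | None = None) -> RecoveryTally:
    """Simulate one batch with known CNVs, call the carrier samples and
    score detection (same-type overlap), ploidy and single-bin recovery."""
    tally = tally if tally is not None else RecoveryTally()
    base = SimConfig(n_samples=n_samples, n_on_bins=n_on_bins,
                     n_off_bins=n_off_bins, seed=seed)
    bins = simulate_bins(base)
    rng = np.random.default_rng(seed + 10_000)
    carriers = [f"S{i:03d}" for i in
                rng.choice(n_samples, size=test_samples, replace=False)]
    specs = random_cnv_specs(bins, base, carriers, rng,
                             events_per_sample=events_per_sample)
    cfg = SimConfig(**{**base.__dict__, "cnv_spec": specs})
    matrix, truth = simulate_matrix(bins, cfg)
    config = run_config or RunConfig(seed=seed)

    batch = {"seed": seed, "n_truth": len(truth), "n_detected": 0}
    for sample in carriers:
        result = call_sample(matrix, bins, sample, config)
        calls = result.calls
        id_to_idx = {bid: i for i, bid in
                     enumerate(result.profile.bins["id"])}
        for _, t in truth[truth["sample"] == sample].iterrows():
            tally.n_truth += 1
            hits = [c for c in calls if c.type == t.type
                    and c.chrom == t.chrom
                    and c.start < t.end and c.end > t.start]
            if hits:
                tally.n_detected += 1
                batch["n_detected"] += 1
                best = max(hits, key=lambda c: c.n_bins)
                if best.ploidy == t.ploidy:
                    tally.n_ploidy_correct += 1
            if t.n_bins == 1:
                idx = id_to_idx.get(t.bin_ids)
                if idx is not None and abs(result.denoised.z[idx]) >= 6:
                    tally.n_single_high_z += 1
                    if hits:
                        tally.n_single_high_z_recovered += 1
    tally.per_batch.append(batch)
    return tally


def run_recovery_study(n_batches: int = 50, seed: int = 0,
                       **kwargs) -> RecoveryTally:
    """Aggregate CNV recovery across independent simulated batches."""
    tally = RecoveryTally()
    for b in range(n_batches):
        evaluate_batch(seed * 100_000 + b, tally=tally, **kwargs)
        logger.info("batch %d/%d: sensitivity so far %.3f", b + 1, n_batches,
                    tally.sensitivity)
    return tally


def run_loo_benchmark(n_samples: int, seed: int, n_on_bins: int = 2400,
                      n_off_bins: int = 600, factor_sd: float = 0.05,
                      k_grid=range(0, 11),
                      n_artificial: int = 1000) -> pd.DataFrame:
    """Simulate a batch, normalize one test sample against all others,
    and tabulate artificial-CNV AUC against k for LOO-PCA vs PCA."""
    from .denoise import benchmark_pca_vs_loopca

    cfg = SimConfig(n_samples=n_samples, n_on_bins=n_on_bins,
                    n_off_bins=n_off_bins, factor_sd=factor_sd, seed=seed)
    bins = simulate_bins(cfg)
    matrix, _ = simulate_matrix(bins, cfg)
    controls = [s for s in matrix.sample_ids if s != "S000"]
    profile = normalize_sample(matrix, bins, "S000", control_ids=controls)
    return benchmark_pca_vs_loopca(profile.ratio, profile.control_ratios,
                                   seed=seed + 1, k_grid=k_grid,
                                   n_artificial=n_artificial)
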