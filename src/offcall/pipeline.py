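"""Per-sample CNV-calling pipeline: normalize -> denoise -> segment."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import CoverageMatrix
from .denoise import DenoisedProfile
from .intervals import BinSet, PartitionParams
from .normalize import NormalizedProfile, NormalizeParams, normalize_sample
from .segment import CnvCall, HmmSpec, HqThresholds, call_events

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters, at their standard defaults."""

    partition: PartitionParams = field(default_factory=PartitionParams)
    normalize: NormalizeParams = field(default_factory=NormalizeParams)
    hmm: HmmSpec = field(default_factory=HmmSpec)
    hq: HqThresholds = field(default_factory=HqThresholds)
    min_mapq: int = 50
    min_z: float = 4.0
    expected_ploidy_x: int = 2
    n_artificial: int = 1000
    k_grid_max: int = 20
    seed: int = 2024

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


@dataclass
class SampleResult:
    profile: NormalizedProfile
    denoised: DenoisedProfile
    calls: list[CnvCall]

    @property
    def k_removed(self) -> int:
        return self.denoised.k_removed


def call_sample(matrix: CoverageMatrix, bins: BinSet | pd.DataFrame,
                test_id: str, config: RunConfig | None = None,
                control_ids: list[str] | None = None) -> SampleResult:
    """Run the full per-sample analysis and return calls plus the
    intermediate profiles."""
    from .denoise import (choose_k, fit_control_pcs, inject_artificial_cnvs,
                          recalibrate_controls, remove_pcs, remove_pcs_matrix)

    config = config or RunConfig()
    profile = normalize_sample(matrix, bins, test_id,
                               params=config.normalize,
                               control_ids=control_ids)
    n_ctrl = len(profile.control_ids)
    k_grid = range(0, min(config.k_grid_max, max(n_ctrl - 1, 0)) + 1)
    basis = fit_control_pcs(profile.control_ratios)
    modified, art = inject_artificial_cnvs(profile.ratio, seed=config.seed,
                                           n_cnvs=config.n_artificial)
    k_best, auc_table = choose_k(modified, basis, profile.control_ratios, art,
                                 k_grid=k_grid, sd_floor=config.hmm.sd_floor)
    denoised = DenoisedProfile(
        ratio_denoised=remove_pcs(profile.ratio, basis, k_best),
        z=np.zeros(len(profile.ratio)), k_removed=k_best, auc_by_k=auc_table)
    ctrl_denoised = recalibrate_controls(
        remove_pcs_matrix(profile.control_ratios, basis, k_best), k_best,
        n_ctrl)
    calls, z = call_events(
        profile.bins, denoised.ratio_denoised, ctrl_denoised,
        sample=test_id, hmm=config.hmm, min_z=config.min_z,
        expected_ploidy_x=config.expected_ploidy_x,
        sample_max_corr=profile.max_control_correlation,
        hq_thresholds=config.hq)
    denoised.z = z
    logger.info("%s: %d controls, k=%d, %d calls", test_id, n_ctrl,
                denoised.k_removed, len(calls))
    return SampleResult(profile=profile, denoised=denoised, calls=calls)


def call_batch(matrix: CoverageMatrix, bins: BinSet | pd.DataFrame,
               config: RunConfig | None = None,
               sample_ids: list[str] | None = None) -> dict[str, SampleResult]:
    """Analyse every (or the named) sample of a batch against the rest."""
    results: dict[str, SampleResult] = {}
    for sid in sample_ids or matrix.sample_ids:
        results[sid] = call_sample(matrix, bins, sid, config)
    return results
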