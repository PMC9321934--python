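"""End-to-end orchestration: volume in, morphometry record and stats out.

Stage order mirrors the acquisition-to-analysis workflow: reorientation,
three-class segmentation, vascular leak removal, compartment separation,
morphometry, and finally the group statistics over the per-sample table.
A failure in one sample is recorded and the run continues with the rest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage

from . import morphometry
from .compartments import derive_compartments
from .config import RunConfig
from .phantom import StudySample, generate_phantom
from .preprocess import apply_pose_and_crop, estimate_long_axis
from .segmentation import segment_volume
from .stats import StatsReport, run_stats
from .vessel_enhance import remove_leaks, tubeness
from .volume_io import BONE, VESSEL, Volume, read_volume

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    records: pd.DataFrame
    stats_report: StatsReport | None
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def nothing_to_do(self) -> bool:
        return len(self.records) == 0 and not self.failures


def process_sample(vol: Volume, config: RunConfig, sample_id: str = "",
                   group: str = "") -> morphometry.MorphometryRecord:
    """Run the full single-sample chain and return its morphometry record."""
    from skimage import filters

    data = vol.data
    if config.do_preprocess:
        # orientation is estimated on the whole specimen (bone + marrow +
        # vessels, i.e. everything above background): a hollow cortical tube
        # alone can have larger transverse than longitudinal inertia
        cuts = filters.threshold_multiotsu(np.asarray(data, dtype=np.float32),
                                           classes=4)
        pose = estimate_long_axis(data > cuts[0])
        if not pose.is_identity(tol_deg=0.5):
            logger.info("%s: reorienting by %s", sample_id, pose.euler_angles_deg)
            vol = apply_pose_and_crop(vol, pose, target_dims=config.target_dims)
            data = vol.data

    labels = segment_volume(
        data,
        wavelengths=config.pa_wavelengths,
        noise_factor=config.pa_noise_factor,
        strict_markers=config.strict_markers,
        background_margin=config.background_margin,
        intensity_bias=config.intensity_bias,
    )
    bone = labels == BONE
    vessel = labels == VESSEL

    if vessel.any():
        roi = ndimage.binary_dilation(vessel, iterations=2)
        tb = tubeness(data, config.tubeness_sigmas, roi_mask=roi)
        vessel = remove_leaks(vessel, tb, config.keep_fraction)

    comp = derive_compartments(bone, vol.voxel_size_um, config.keyslice_step)
    return morphometry.compute_record(
        bone_mask=bone, vessel_mask=vessel,
        tv_mask=comp.tv_mask, marrow_mask=comp.marrow_mask,
        trabecular_mask=comp.trabecular_mask,
        voxel_size_um=vol.voxel_size_um,
        box_sizes=config.box_sizes,
        sample_id=sample_id, group=group,
    )


def _iter_samples(samples) -> Iterable[tuple[str, str, Volume]]:
    if isinstance(samples, pd.DataFrame):
        for _, row in samples.iterrows():
            yield str(row["sample_id"]), str(row.get("group", "")), \
                read_volume(row["path"])
        return
    for item in samples:
        if isinstance(item, StudySample):
            vol, _ = generate_phantom(item.spec)
            yield item.sample_id, item.group, vol
        else:
            yield item  # (sample_id, group, Volume)


def run_pipeline(config: RunConfig, samples) -> PipelineResult:
    """Process every sample of a study and run the group statistics.

    ``samples`` may be a manifest DataFrame (columns sample_id, group,
    path), a list of phantom StudySample objects (volumes generated on the
    fly), or an iterable of (sample_id, group, Volume) tuples.  Statistics
    are computed when at least two groups have two or more successful
    records; otherwise only the per-sample table is returned.
    """
    rows = []
    failures: dict[str, str] = {}
    for sample_id, group, vol in _iter_samples(samples):
        try:
            rec = process_sample(vol, config, sample_id, group)
            rows.append(asdict(rec))
        except Exception as exc:  # noqa: BLE001 - isolate per-sample failures
            logger.error("sample %s failed: %s", sample_id, exc)
            failures[sample_id] = str(exc)
    records = pd.DataFrame(
        rows, columns=["sample_id", "group", *morphometry.MorphometryRecord.PARAMETERS])
    report = None
    if len(records) > 0:
        counts = records.groupby("group").size()
        if (counts >= 2).sum() >= 2:
            report = run_stats(records.drop(columns=["sample_id"]),
                               alpha=config.alpha, seed=config.seed + 12345)
    return PipelineResult(records=records, stats_report=report, failures=failures)
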