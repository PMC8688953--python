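"""End-to-end orchestration: segment -> delimit -> morphometry -> compare."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .delimitation import RegionSegmentation, AxialProfile, delimit
from .io import read_volume, write_labels, write_report
from .morphometry import MorphometryReport, morphometry_report
from .segmentation import endocortical_fill, segment_volume
from .stats import compare_table
from .volume import AttenuationVolume, TissueLabelVolume

__all__ = ["SampleResult", "run_sample", "run_study"]

log = logging.getLogger(__name__)


@dataclass
class SampleResult:
    sample_id: str
    report: MorphometryReport
    segmentation: RegionSegmentation
    profile: AxialProfile
    labels: TissueLabelVolume
    otsu_threshold: float
    flagged_slices: list


def run_sample(config: RunConfig, volume: AttenuationVolume | str | Path,
               sample_id: str = "sample", labels: TissueLabelVolume | None = None,
               out_dir: str | Path | None = None) -> SampleResult:
    """Process one sample deterministically under a config.

    ``volume`` may be an in-memory volume or a path (TIFF stack / NRRD);
    intermediate artifacts (labels, profile, variation, segmentation,
    report) are persisted when ``out_dir`` is given.
    """
    if not isinstance(volume, AttenuationVolume):
        volume = read_volume(volume, spacing_override=config.spacing_um)
    if config.flip_orientation:
        volume = volume.flipped()
        if labels is not None:
            labels = labels.flipped()
    if labels is None:
        labels, thr = segment_volume(volume, config.segmentation)
    else:
        thr = float("nan")
    sc_mask, flagged = endocortical_fill(
        labels, close_radius_um=2 * config.segmentation.morph_radius_close_um)
    if flagged:
        log.warning("%s: %d slices needed the unclosed-cortex fallback fill",
                    sample_id, len(flagged))
    seg, profile, variation = delimit(
        volume, labels, section_thickness_um=config.section_thickness_um,
        threshold_pct=config.variation_threshold_pct,
        persistence=config.persistence, sc_mask=sc_mask)
    report = morphometry_report(
        volume, labels, seg, profile, sample_id=sample_id, sc_mask=sc_mask,
        mid_diaphysis_window_um=config.mid_diaphysis_window_um,
        distal_epiphysis_window_um=config.distal_epiphysis_window_um,
        ct_th_mode=config.ct_th_mode)
    log.info("%s: boundaries at %.1f%% / %.1f%% of length, %d sections",
             sample_id, seg.prox_offset_pct, seg.dist_offset_pct,
             profile.n_sections)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_labels(labels, out / f"{sample_id}_labels.nrrd")
        write_report(report, out / f"{sample_id}_report.csv")
        write_report(report, out / f"{sample_id}_report.json")
        prof_df = pd.DataFrame({
            "z_start_um": profile.z_start_um, "z_end_um": profile.z_end_um,
            "mean_ct_mu": profile.mean_ct_mu, "cn_fraction": profile.cn_fraction,
            "n_cortical_voxels": profile.n_cortical_voxels,
            "variation_pct": variation.values,
        })
        prof_df.to_csv(out / f"{sample_id}_profile.csv", index=False)
        import json
        with open(out / f"{sample_id}_segmentation.json", "w") as fh:
            json.dump(seg.to_dict(profile), fh, indent=2)
    return SampleResult(sample_id, report, seg, profile, labels, thr, flagged)


def _reports_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        if isinstance(r, SampleResult):
            rows.append(r.report.to_flat_dict())
        elif isinstance(r, dict):
            rows.append(r)
        else:
            rows.append(r.to_flat_dict())
    return pd.DataFrame(rows)


def run_study(config: RunConfig, control_results, flight_results,
              parameters=None) -> pd.DataFrame:
    """Group comparison across two lists of per-sample results/reports.

    Samples whose id appears in ``config.exclude_samples`` are dropped
    before statistics; each group must retain >= 3 samples.
    """
    control = _reports_frame(control_results)
    flight = _reports_frame(flight_results)
    excl = set(config.exclude_samples)
    if excl:
        control = control[~control["sample_id"].isin(excl)]
        flight = flight[~flight["sample_id"].isin(excl)]
    if len(control) < 3 or len(flight) < 3:
        raise ValueError(f"need >= 3 samples per group after exclusions "
                         f"(got {len(control)}, {len(flight)})")
    return compare_table(control, flight, parameters=parameters,
                         alpha=config.alpha)
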