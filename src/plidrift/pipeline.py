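"""End-to-end orchestration of the analysis stages.

``run_synthetic`` / ``run_files`` produce, per band: every subject's
edge-trend table and gated edge set (the IN analysis), the prevalence
table and >= threshold shared-edge set, the subject-averaged global
network with its own gated edge set (the GN analysis), and the IN/GN
overlap summary.  ``write_outputs`` serializes the lot as CSV + JSON
plus a run manifest with checksums.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, filters, io
from .config import PipelineConfig
from .connectivity import PLINetworkStack, build_stacks, pairwise_pli
from .group import (OverlapSummary, SharedEdgeSet, band_report, gn_average,
                    gn_significant, in_gn_overlap, prevalence, shared_edges)
from .montage import MontageSpec
from .preprocess import (band_decompose, bandpass_fir, baseline_correct, epoch,
                         notch, qc_reject, rereference, resample)
from .simulate import SimulationConfig, simulate_subject
from .trend import EdgeSet, ThresholdConfig, expected_null_hits, per_subject_trends

logger = logging.getLogger("plidrift")


@dataclass
class AnalysisResult:
    """Everything the group analysis produces, keyed by band."""

    montage: MontageSpec
    n_subjects: int
    trend_tables: pd.DataFrame
    in_sets: dict[str, dict[str, EdgeSet]] = field(default_factory=dict)
    gn_sets: dict[str, EdgeSet] = field(default_factory=dict)
    shared: dict[str, SharedEdgeSet] = field(default_factory=dict)
    overlaps: dict[str, OverlapSummary] = field(default_factory=dict)
    report: dict = field(default_factory=dict)


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def simulate_dataset(sim: SimulationConfig) -> dict[str, dict]:
    """Simulate all subjects and band-decompose their epochs.

    Materializes every subject's five band copies at once; fine for test
    scale.  For full sessions use :func:`simulate_stacks`, which streams
    one subject (and one band-filtered epoch) at a time.
    """
    t0 = _stage("simulate+decompose")
    per_subject = {}
    for s in range(sim.n_subjects):
        es = simulate_subject(sim, s)
        es = baseline_correct(es)
        per_subject[es.subject_id] = band_decompose(es, sim.bands)
    logger.info("simulated %d subjects in %.1f s", sim.n_subjects, time.perf_counter() - t0)
    return per_subject


def _band_weights(epochs: np.ndarray, taps_by_band: dict[str, np.ndarray],
                  n_edges: int) -> dict[str, np.ndarray]:
    """Per-band PLI weight matrices for one subject's broadband epochs,
    filtering one epoch at a time to bound memory."""
    out = {}
    for band, taps in taps_by_band.items():
        w = np.empty((epochs.shape[0], n_edges))
        for i in range(epochs.shape[0]):
            w[i] = pairwise_pli(filters.apply_zero_phase(epochs[i], taps))
        out[band] = w
    return out


def simulate_stacks(sim: SimulationConfig) -> list[PLINetworkStack]:
    """Simulate, band-filter and network-ize all subjects, one at a time."""
    t0 = _stage("simulate+connectivity (streaming)")
    taps_by_band = {
        b.name: filters.design_bandpass(b.low, b.high, sim.sampling_rate)
        for b in sim.bands
    }
    stacks: list[PLINetworkStack] = []
    indices = np.arange(sim.n_epochs)
    for s in range(sim.n_subjects):
        es = baseline_correct(simulate_subject(sim, s))
        weights = _band_weights(es.epochs, taps_by_band, sim.montage.n_edges)
        for band, w in weights.items():
            stacks.append(PLINetworkStack(
                subject_id=es.subject_id, band=band, epoch_indices=indices,
                weights=w, montage=sim.montage,
            ))
        logger.info("subject %d/%d done (%.1f s elapsed)", s + 1,
                    sim.n_subjects, time.perf_counter() - t0)
    return stacks


def preprocess_recording(recording, cfg: PipelineConfig, subject_id: str) -> dict:
    """Real-data path: resample, notch, band-pass, re-reference, epoch, QC."""
    p = cfg.preprocessing
    rec = resample(recording, p.target_rate)
    if p.notch_hz:
        rec = notch(rec, p.notch_hz)
    rec = bandpass_fir(rec, p.band_low, p.band_high)
    rec = rereference(rec, tuple(p.reference_labels))
    es = epoch(rec, window=p.epoch_window_s, step=p.epoch_step_s,
               trim=p.epoch_trim_s, subject_id=subject_id)
    es = baseline_correct(es)
    es = qc_reject(es, threshold_db=p.qc_threshold_db)
    return band_decompose(es, cfg.band_definitions())


def analyze_stacks(
    stacks: list[PLINetworkStack],
    thresholds: ThresholdConfig,
    shared_fraction: float,
) -> AnalysisResult:
    """IN + GN analysis over precomputed PLI network stacks."""
    montage = stacks[0].montage
    subjects = sorted({s.subject_id for s in stacks})
    bands = sorted({s.band for s in stacks})
    by_band: dict[str, list[PLINetworkStack]] = {b: [] for b in bands}
    for s in stacks:
        by_band[s.band].append(s)

    t0 = _stage("edge trend regression")
    tables = []
    in_sets: dict[str, dict[str, EdgeSet]] = {b: {} for b in bands}
    for band in bands:
        for stack in sorted(by_band[band], key=lambda s: s.subject_id):
            table, edge_set = per_subject_trends(stack, thresholds)
            tables.append(table)
            in_sets[band][stack.subject_id] = edge_set
    trend_tables = pd.concat(tables, ignore_index=True)
    logger.info("fitted %d edge trends in %.1f s", len(trend_tables),
                time.perf_counter() - t0)

    result = AnalysisResult(
        montage=montage, n_subjects=len(subjects), trend_tables=trend_tables,
        in_sets=in_sets,
    )
    n_ep = stacks[0].n_epochs
    result.report = {
        "n_subjects": len(subjects),
        "n_edges": montage.n_edges,
        "n_epochs": n_ep,
        "thresholds": {"r2_min": thresholds.r2_min, "alpha": thresholds.alpha},
        "expected_null_hits_per_subject_band": expected_null_hits(
            montage.n_edges, n_ep, thresholds
        ),
        "bands": {},
    }
    _stage("group analysis")
    for band in bands:
        gn = gn_average(sorted(by_band[band], key=lambda s: s.subject_id))
        gn_set = gn_significant(gn, thresholds)
        prev = prevalence(in_sets[band], len(subjects), band=band)
        shared_set = shared_edges(prev, shared_fraction)
        overlap = in_gn_overlap(in_sets[band], gn_set)
        result.gn_sets[band] = gn_set
        result.shared[band] = shared_set
        result.overlaps[band] = overlap
        result.report["bands"][band] = band_report(
            band, in_sets[band], len(subjects), gn_set, overlap, shared_set
        )
    return result


def run_synthetic(cfg: PipelineConfig) -> tuple[list[PLINetworkStack], AnalysisResult]:
    """Full pipeline on the built-in generator."""
    sim = cfg.simulation_config()
    stacks = simulate_stacks(sim)
    result = analyze_stacks(stacks, cfg.threshold_config(),
                            cfg.group.shared_threshold_fraction)
    return stacks, result


def run_files(cfg: PipelineConfig) -> tuple[list[PLINetworkStack], AnalysisResult]:
    """Full pipeline on EDF/BDF/BrainVision recordings listed in the config."""
    from .montage import make_default_montage

    montage = make_default_montage()
    per_subject = {}
    for i, path in enumerate(cfg.input.paths):
        subject_id = Path(path).stem
        rec = io.read_recording(path, montage)
        per_subject[subject_id] = preprocess_recording(rec, cfg, subject_id)
    stacks = build_stacks(per_subject, montage)
    result = analyze_stacks(stacks, cfg.threshold_config(),
                            cfg.group.shared_threshold_fraction)
    return stacks, result


def write_outputs(
    cfg: PipelineConfig,
    stacks: list[PLINetworkStack],
    result: AnalysisResult,
    out_dir: str | Path,
    write_networks: bool = False,
) -> Path:
    """Serialize trend tables, shared edges, report and manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    trends_path = out / "edge_trends.csv"
    result.trend_tables.to_csv(trends_path, index=False)
    outputs["edge_trends"] = trends_path

    from .group import shared_edges_frame
    shared_frames = [f for f in (shared_edges_frame(s) for s in result.shared.values())
                     if not f.empty]
    shared_path = out / "shared_edges.csv"
    if shared_frames:
        shared_table = pd.concat(shared_frames, ignore_index=True)
    else:
        shared_table = shared_edges_frame(next(iter(result.shared.values())))
    shared_table.to_csv(shared_path, index=False)
    outputs["shared_edges"] = shared_path

    report_path = out / "report.json"
    io.write_json_atomic(result.report, report_path)
    outputs["report"] = report_path

    if write_networks:
        nets_path = out / "networks.csv"
        io.stacks_to_frame(stacks).to_csv(nets_path, index=False)
        outputs["networks"] = nets_path
        npz_path = out / "networks.npz"
        io.save_stacks_npz(stacks, npz_path)
        outputs["networks_npz"] = npz_path

    manifest = io.build_manifest(
        config_snapshot=cfg.snapshot(),
        seeds={"master_seed": cfg.master_seed},
        outputs=outputs,
        version=__version__,
    )
    io.write_json_atomic(manifest, out / "manifest.json")
    return out
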