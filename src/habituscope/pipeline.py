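"""End-to-end orchestration of the screen and imaging analyses.

Both runners are deterministic in (config, seed): a single global seed fans
out to per-stage seeds by fixed offsets so individual stages can be re-run
reproducibly in isolation.  Every run writes a provenance record with the
config (including every threshold), the derived stage seeds, and a content
hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from . import brainspace, embedded, fingerprint as fp, funcluster, synth
from .protocol import (DarkFlashProtocol, build_regressors, gcamp_kernel,
                       imaging_protocol, IMAGING_N_PLANES, IMAGING_Z_STEP_UM)

__all__ = ["RunConfig", "run_screen_pipeline", "run_imaging_pipeline"]

# fixed per-stage seed offsets (all results stay below 2**31)
_STAGE_OFFSET = {"screen_sim": 101, "roi_sim": 202, "motion_sim": 303,
                 "two_channel": 404, "markers": 505, "bootstrap": 606,
                 "ap": 0}


def _stage_seed(seed: int, stage: str) -> int:
    return (int(seed) + _STAGE_OFFSET[stage]) % (2 ** 31)


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults are the study's printed values."""

    seed: int = 0
    # imaging-arm thresholds
    tuned_corr_thresh: float = 0.25
    crossfish_corr_thresh: float = 0.3
    crossfish_min_matches: int = 5
    ap_damping: float = 0.9
    ap_preference: float = -9.0
    reassign_corr_thresh: float = 0.3
    motion_z_thresh: float = 3.0
    motion_window_s: float = 10.0
    zdrift_max_um: float = 3.0
    voxel_edge_um: float = 10.0
    marker_corr_thresh: float = 0.15
    gad_ratio_thresh: float = 0.25
    n_boot: int = 5000
    kernel_tau_s: float = 3.5
    n_planes: int = IMAGING_N_PLANES
    z_step_um: float = IMAGING_Z_STEP_UM
    # screen-arm thresholds
    hit_ssmd_thresh: float = 2.0
    fingerprint_cluster_thresh: float = 9.5
    response_window_s: float = 1.0
    viability_floor: float = 0.0
    # synthetic-data scale
    n_plates: int = 1
    sim_n_per_type: int = 150
    sim_n_fish: int = 6
    sim_snr: float = 3.0
    sim_frac_motor: float = 0.1
    sim_frac_untuned: float = 0.2
    effect_map: Dict = field(default_factory=dict)

    @property
    def axial_coverage_um(self) -> float:
        return self.n_planes * self.z_step_um

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in names})

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _write_provenance(outdir: Path, config: RunConfig, stage_seeds: Dict,
                      extra: Dict) -> None:
    rec = {"config": json.loads(config.to_json()),
           "config_hash": config.digest(),
           "stage_seeds": stage_seeds, **extra}
    (outdir / "provenance.json").write_text(json.dumps(rec, indent=2,
                                                       default=str))


def run_screen_pipeline(config: RunConfig, outdir) -> Dict:
    """Simulate (or load) screen plates, assemble fingerprints, call and
    cluster hits, and write all tabular outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    protocol = DarkFlashProtocol()
    schedule = fp.ScreenSchedule.from_protocol(protocol)
    spec = fp.MeasureSpec()
    seeds = {"screen_sim": _stage_seed(config.seed, "screen_sim")}

    values: List[pd.DataFrame] = []
    viable: List[pd.Series] = []
    for p in range(config.n_plates):
        layout = fp.default_layout(
            compounds=[f"P{p + 1}C{i + 1:03d}" for i in range(40)])
        effects = {c: e for c, e in config.effect_map.items()
                   if c in layout.compounds}
        events, _ = synth.simulate_screen(
            layout, effects, protocol=protocol, schedule=schedule,
            spec=spec, seed=seeds["screen_sim"] + p)
        mat = fp.assemble_fingerprint(
            events, layout, schedule, spec,
            window=config.response_window_s,
            viability_floor=config.viability_floor,
            hit_threshold=config.hit_ssmd_thresh)
        values.append(mat.values)
        viable.append(mat.viable)
    all_values = pd.concat(values)
    all_viable = pd.concat(viable)
    hits = fp.call_hits(all_values, config.hit_ssmd_thresh)
    hit_values = all_values.loc[hits[hits].index]

    all_values.to_csv(outdir / "fingerprints.tsv", sep="\t",
                      index_label="compound")
    hits.rename("hit").to_csv(outdir / "hits.csv", index_label="compound")
    result = {"fingerprints": all_values, "viable": all_viable,
              "hits": hits, "n_hits": int(hits.sum())}
    if len(hit_values) >= 2:
        link, flat, order = fp.cluster_fingerprints(
            hit_values, config.fingerprint_cluster_thresh)
        (outdir / "hit_linkage.json").write_text(
            json.dumps({"linkage": link.tolist(),
                        "compounds": list(hit_values.index),
                        "flat_clusters": flat.tolist()}))
        result["hit_clusters"] = flat
    if len(hit_values) >= 3:
        corr, order, _ = fp.measure_correlogram(hit_values)
        corr.to_csv(outdir / "measure_correlogram.tsv", sep="\t")
        result["correlogram"] = corr
    _write_provenance(outdir, config, seeds,
                      {"arm": "screen", "n_compounds": len(all_viable),
                       "n_viable": int(all_viable.sum()),
                       "n_hits": int(hits.sum())})
    return result


def run_imaging_pipeline(config: RunConfig, outdir,
                         roi_table: synth.RoiTable | None = None) -> Dict:
    """Regressors -> filters -> affinity propagation -> taxonomy ->
    reassignment -> proportions -> spatial analyses, on simulated or
    provided ROI tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    protocol = imaging_protocol()
    rate = protocol.sample_rate
    kernel = gcamp_kernel(tau=config.kernel_tau_s, rate=rate)
    regressors = build_regressors(protocol, kernel, rate)
    seeds = {k: _stage_seed(config.seed, k)
             for k in ("roi_sim", "motion_sim", "bootstrap", "ap")}

    if roi_table is None:
        roi_table, truth = synth.simulate_roi_traces(
            n_per_type=config.sim_n_per_type, n_fish=config.sim_n_fish,
            snr=config.sim_snr, frac_motor=config.sim_frac_motor,
            frac_untuned=config.sim_frac_untuned, protocol=protocol,
            kernel=kernel, seed=seeds["roi_sim"])
    else:
        truth = None
    if roi_table.n_rois == 0:
        raise ValueError("empty ROI table")

    # movement inference from a simulated registration-correlation trace
    planted_flags = np.arange(protocol.flashes_per_block) < 30
    corr_trace = synth.simulate_motion_trace(protocol, planted_flags,
                                             seed=seeds["motion_sim"])
    power = embedded.motion_power(corr_trace)
    onsets = protocol.flash_onsets[:protocol.flashes_per_block]
    resp_flags = embedded.detect_embedded_responses(
        power, onsets, rate, config.motion_z_thresh, config.motion_window_s)
    hab = embedded.habituation_index(resp_flags)
    motion_reg = funcluster.build_motion_regressor(resp_flags, protocol,
                                                   kernel, rate)

    corr = funcluster.correlate_rois(roi_table.traces, regressors)
    tuned = funcluster.filter_stimulus_tuned(corr, config.tuned_corr_thresh)
    candidates = roi_table.select(tuned)
    repro = funcluster.cross_fish_filter(
        candidates.traces, candidates.fish_id,
        config.crossfish_corr_thresh, config.crossfish_min_matches)
    kept = candidates.select(repro)

    labels, exemplars = funcluster.affinity_propagation_cluster(
        kept.traces, damping=config.ap_damping,
        preference=config.ap_preference, random_state=seeds["ap"])
    model = funcluster.order_and_name_clusters(kept.traces, labels,
                                               protocol, rate)
    assignments = funcluster.reassign_all_rois(
        roi_table.traces, model.mean_traces, config.reassign_corr_thresh)
    motor = funcluster.motor_correlation_by_cluster(
        assignments, roi_table.traces, motion_reg,
        n_boot=min(config.n_boot * 20, 100_000), seed=seeds["bootstrap"])

    props = None
    if len(set(roi_table.treatment)) >= 2:
        props = funcluster.cluster_proportions_by_treatment(
            assignments, roi_table.treatment, n_boot=config.n_boot,
            seed=seeds["bootstrap"])
        (outdir / "proportions.json").write_text(json.dumps(
            {g: {"clusters": d["clusters"], "proportion": d["proportion"],
                 "n": d["n"]} for g, d in props.items()}, indent=2))

    assigned = assignments["cluster"].to_numpy() >= 0
    cluster_maps = []
    extent = tuple((0.0, e) for e in synth.ATLAS_EXTENT_UM)
    for k in range(model.n_clusters):
        sel = assigned & (assignments["cluster"].to_numpy() == k)
        cluster_maps.append(brainspace.voxelize_centroids(
            roi_table.centroids[sel], config.voxel_edge_um, extent))
    correlogram, order, _ = brainspace.spatial_correlogram(
        cluster_maps, names=model.names)

    pd.DataFrame({"cluster": assignments["cluster"],
                  "corr": assignments["corr"]}).to_csv(
        outdir / "assignments.csv", index_label="roi")
    pd.DataFrame(model.mean_traces.T, columns=model.names).to_csv(
        outdir / "cluster_means.tsv", sep="\t", index=False)
    correlogram.to_csv(outdir / "spatial_correlogram.tsv", sep="\t")
    motor.to_csv(outdir / "motor_correlation.csv")

    _write_provenance(outdir, config, seeds, {
        "arm": "imaging",
        "n_rois": roi_table.n_rois,
        "n_tuned": int(tuned.sum()),
        "n_reproducible": int(repro.sum()),
        "n_clusters": model.n_clusters,
        "cluster_names": model.names,
        "percent_habituation": hab.percent,
        "axial_coverage_um": config.axial_coverage_um})
    return {"model": model, "assignments": assignments, "truth": truth,
            "habituation": hab, "motor": motor, "proportions": props,
            "spatial_correlogram": correlogram, "regressors": regressors,
            "n_tuned": int(tuned.sum()), "n_reproducible": int(repro.sum()),
            "kept_index": np.flatnonzero(tuned)[repro],
            "labels_provisional": labels}
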