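"""End-to-end orchestration: simulate → analyze → report.

Stages communicate only through written tables, so every stage is
independently testable and replaceable; a JSON manifest records the
config snapshot, input digests, seeds and output paths of a run, and a
rerun with the same manifest and seeds reproduces byte-identical result
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .hmm import DiffusiveStateHMM
from .io import read_localizations, read_trajectories, write_table
from .msd import MobilityModel
from .cluster import NanoclusterModel
from .tracks import group_by_field

log = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_pipeline", "compare_conditions"]

ALL_STAGES = ("msd", "hmm", "cluster")


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    inputs: dict                 # path -> sha256
    outputs: dict = field(default_factory=dict)   # stage/name -> path
    seed: int = 0
    version: str = ""
    label: str = ""
    timestamp: str = ""

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir, traj_path=None, locs_path=None,
                 stages=None, seed: int = None, label: str = "",
                 fiducials_path=None) -> RunManifest:
    """Run the requested analysis stages and write all result tables.

    ``traj_path`` feeds the mobility (``msd``) and diffusive-state
    (``hmm``) stages; ``locs_path`` feeds the ``cluster`` stage. When
    ``stages`` is None the stages matching the provided inputs run;
    explicitly requested stages with missing inputs raise with the name
    of the producing stage/simulator.
    """
    if stages is None:
        stages = tuple(
            s for s in ALL_STAGES
            if (s == "cluster" and locs_path is not None)
            or (s in ("msd", "hmm") and traj_path is not None)
        )
        if not stages:
            raise ValueError("no inputs: pass traj_path and/or locs_path")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed if seed is None else seed
    manifest = RunManifest(
        config=config.to_dict(),
        inputs={},
        seed=seed,
        version=__version__,
        label=label,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    stages = tuple(stages)

    tracks = None
    if traj_path is not None:
        tracks = read_trajectories(traj_path, dt=config.dt)
        manifest.inputs[str(traj_path)] = _digest(traj_path)

    if "msd" in stages or "hmm" in stages:
        if tracks is None:
            raise ValueError("stages msd/hmm need a trajectory table "
                             "(produce one with 'synaptrack simulate-traj')")

    if "msd" in stages:
        res = MobilityModel(tracks, config=config).fit()
        p = out_dir / "per_track_estimates.csv"
        write_table(res.estimates_frame(), p)
        manifest.outputs["msd/estimates"] = str(p)
        p = out_dir / "field_summaries.csv"
        write_table(res.summary_frame(), p)
        manifest.outputs["msd/summaries"] = str(p)
        p = out_dir / "ensemble_msd.csv"
        write_table(res.ensemble, p)
        manifest.outputs["msd/ensemble"] = str(p)
        log.info("msd: %d tracks analysed", res.n_analyzed_tracks)

    if "hmm" in stages:
        model_rows, pooled_rows, path_frames = [], [], []
        for fid, grp in sorted(group_by_field(tracks).items()):
            hres = DiffusiveStateHMM(
                grp.trajectories, max_states=config.hmm_max_states,
                dt=config.dt, immobile_cutoff=config.mobility_threshold,
            ).fit(seed=seed)
            mf = hres.hmm.to_frame()
            mf.insert(0, "field_id", fid)
            model_rows.append(mf)
            pooled = hres.pooled(field_id=fid)
            pooled_rows.append(pooled.to_frame())
            for sp in hres.annotate():
                path_frames.append(sp.to_frame())
            log.info("hmm: field %s -> K=%d", fid, hres.K)
        p = out_dir / "hmm_models.csv"
        write_table(pd.concat(model_rows, ignore_index=True), p)
        manifest.outputs["hmm/models"] = str(p)
        p = out_dir / "pooled_occupancy.csv"
        write_table(pd.concat(pooled_rows, ignore_index=True), p)
        manifest.outputs["hmm/pooled"] = str(p)
        p = out_dir / "state_paths.tsv"
        write_table(pd.concat(path_frames, ignore_index=True), p)
        manifest.outputs["hmm/paths"] = str(p)

    if "cluster" in stages:
        if locs_path is None:
            raise ValueError("stage cluster needs a localization table "
                             "(produce one with 'synaptrack simulate-locs')")
        locs = read_localizations(locs_path)
        manifest.inputs[str(locs_path)] = _digest(locs_path)
        if fiducials_path is not None:
            from .cluster import correct_drift
            fid_df = pd.read_csv(fiducials_path)
            locs = correct_drift(locs, fid_df)
            manifest.inputs[str(fiducials_path)] = _digest(fiducials_path)
        extent = min(locs.fov[1] - locs.fov[0], locs.fov[3] - locs.fov[2])
        cres = NanoclusterModel(
            locs, r_max=min(1000.0, 0.45 * extent),
            bin_width=config.render_pixel, render_pixel=config.render_pixel,
            frame_gap=config.consolidation_frame_gap,
            distance_px=config.consolidation_distance,
        ).fit()
        p = out_dir / "autocorrelation.csv"
        write_table(cres.ac, p)
        manifest.outputs["cluster/gr"] = str(p)
        p = out_dir / "cluster_fit.csv"
        fitf = cres.fit.to_frame()
        fitf["measured_density_um2"] = cres.density_um2
        write_table(fitf, p)
        manifest.outputs["cluster/fit"] = str(p)
        p = out_dir / "ripley.csv"
        write_table(cres.ripley(), p)
        manifest.outputs["cluster/ripley"] = str(p)
        log.info("cluster: xi=%.1f nm, %d consolidated localizations",
                 cres.xi, len(cres.consolidated))

    manifest.save(out_dir / "manifest.json")
    return manifest


_LABEL_KEYS = {"label"}


def compare_conditions(manifest_a: RunManifest, manifest_b: RunManifest,
                       label_a: str = None, label_b: str = None) -> dict:
    """Side-by-side descriptive comparison of two analyzed runs.

    Both runs must share an identical config (labels excepted); returns a
    dict of DataFrames: ensemble MSD curves, mobility ratios, pooled
    occupancies and cluster metrics, with per-field n so s.e.m.s are
    recomputable. No significance testing.
    """
    if manifest_a.config != manifest_b.config:
        diff = {
            k: (manifest_a.config.get(k), manifest_b.config.get(k))
            for k in set(manifest_a.config) | set(manifest_b.config)
            if manifest_a.config.get(k) != manifest_b.config.get(k)
        }
        raise ValueError(f"run configs differ beyond labels: {diff}")
    la = label_a or manifest_a.label or "A"
    lb = label_b or manifest_b.label or "B"
    out = {}

    def _load(man, key):
        path = man.outputs.get(key)
        return pd.read_csv(path, sep="\t" if str(path).endswith(".tsv")
                           else ",") if path else None

    for key, name in (("msd/ensemble", "ensemble_msd"),
                      ("msd/summaries", "mobility"),
                      ("hmm/pooled", "occupancy"),
                      ("cluster/fit", "cluster")):
        a = _load(manifest_a, key)
        b = _load(manifest_b, key)
        if a is None or b is None:
            continue
        a = a.copy()
        b = b.copy()
        a.insert(0, "condition", la)
        b.insert(0, "condition", lb)
        out[name] = pd.concat([a, b], ignore_index=True)
    return out
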