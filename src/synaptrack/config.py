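"""Run configuration shared by all analysis stages.

All stages read their defaults from a single :class:`RunConfig` so that a
run is fully described by one flat key–value mapping (YAML or JSON file, or
CLI flags that override file values).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Analysis parameters with the pipeline's standard defaults.

    Parameters
    ----------
    dt : float
        Frame interval in seconds (default 1/33 s, i.e. 33 Hz acquisition).
    min_track_len : int
        Minimum number of localizations per track kept for mobility
        analysis (default 8; the boundary length is kept).
    mobility_threshold : float
        Diffusion-coefficient threshold (μm² s⁻¹) separating mobile from
        immobile tracks; a track is mobile iff D > threshold.
    msd_fit_points : int
        Number of initial MSD lags used in the linear diffusion fit.
    msd_report_points : int
        Number of MSD lags averaged into the ensemble curve.
    hmm_max_states : int
        Largest candidate state count for diffusive-state model selection.
    render_pixel : float
        Super-resolved reconstruction pixel size in nm.
    consolidation_frame_gap : int
        Maximum frame gap for merging repeated localizations.
    consolidation_distance : float
        Maximum merge distance in camera pixels.
    pixel_size_camera : float
        Camera pixel size in nm (converts the consolidation distance).
    rng_seed : int
        Seed for every stochastic step of a run.
    """

    dt: float = 1.0 / 33.0
    min_track_len: int = 8
    mobility_threshold: float = 0.021
    msd_fit_points: int = 4
    msd_report_points: int = 8
    hmm_max_states: int = 5
    render_pixel: float = 10.0
    consolidation_frame_gap: int = 1
    consolidation_distance: float = 1.0
    pixel_size_camera: float = 100.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        for name in ("min_track_len", "msd_fit_points", "msd_report_points",
                     "hmm_max_states", "consolidation_frame_gap"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.mobility_threshold <= 0:
            raise ValueError("mobility_threshold must be > 0")
        if self.render_pixel <= 0:
            raise ValueError("render_pixel must be > 0")
        if self.consolidation_distance < 0:
            raise ValueError("consolidation_distance must be >= 0")
        if self.pixel_size_camera <= 0:
            raise ValueError("pixel_size_camera must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_config(path=None, **overrides) -> RunConfig:
    """Load a :class:`RunConfig` from YAML/JSON, applying keyword overrides.

    Unknown keys in the file raise ``ValueError`` (silent typos in a config
    file are worse than a hard failure). ``overrides`` with value ``None``
    are ignored so CLI flags can pass through unset options.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, val in overrides.items():
        if val is None:
            continue
        if key not in valid:
            raise ValueError(f"unknown config key: {key}")
        data[key] = val
    return RunConfig(**data)
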