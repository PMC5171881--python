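"""Single-particle trajectories: the unit of all mobility analysis.

Positions are stored in μm, frame indices are 0-based integers, and the
frame interval ``dt`` is in seconds. A trajectory may contain frame gaps
(missed detections); operations that need contiguous steps split tracks
into gap-free segments via :meth:`Trajectory.segments`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory", "FieldGroup"]

DEFAULT_DT = 1.0 / 33.0


@dataclass
class Trajectory:
    """One track: ordered localizations of a single molecule.

    Attributes
    ----------
    track_id : str
        Identifier, unique within a field.
    frames : ndarray of int
        Strictly increasing frame indices.
    x, y : ndarray of float
        Positions in μm, same length as ``frames``.
    dt : float
        Frame interval in seconds.
    field_id : str
        Imaging field (e.g. one NMJ chain) the track belongs to.
    """

    track_id: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dt: float = DEFAULT_DT
    field_id: str = "field0"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        n = len(self.frames)
        if n < 2:
            raise ValueError(f"track {self.track_id}: needs >= 2 points, got {n}")
        if len(self.x) != n or len(self.y) != n:
            raise ValueError(f"track {self.track_id}: x/y length mismatch")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"track {self.track_id}: frames not strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError(f"track {self.track_id}: non-finite positions")
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ValueError(f"track {self.track_id}: dt must be finite and > 0")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_points(self) -> int:
        return len(self.frames)

    def segments(self):
        """Split into gap-free runs of consecutive frames.

        Returns a list of ``(x, y)`` coordinate-array pairs, each covering a
        stretch where every frame is present. Runs of a single point carry
        no step information and are dropped.
        """
        breaks = np.flatnonzero(np.diff(self.frames) != 1)
        starts = np.concatenate(([0], breaks + 1))
        stops = np.concatenate((breaks + 1, [len(self.frames)]))
        return [
            (self.x[a:b], self.y[a:b])
            for a, b in zip(starts, stops)
            if b - a >= 2
        ]

    def squared_steps(self):
        """Per-step squared displacements (μm²) of gap-free segments.

        Returns a list of 1-D arrays, one per contiguous segment; steps that
        would bridge a missing frame are excluded.
        """
        return [
            np.diff(sx) ** 2 + np.diff(sy) ** 2
            for sx, sy in self.segments()
        ]


@dataclass
class FieldGroup:
    """Everything recorded from one imaging field (one NMJ chain).

    Groups trajectories and/or localization tables that share a ``field_id``
    together with free-text condition labels (temperature, genotype, ...).
    """

    field_id: str
    trajectories: list = field(default_factory=list)
    localizations: object = None
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tr in self.trajectories:
            if tr.field_id != self.field_id:
                raise ValueError(
                    f"track {tr.track_id} has field_id {tr.field_id!r}, "
                    f"expected {self.field_id!r}"
                )

    @property
    def n_tracks(self) -> int:
        return len(self.trajectories)


def group_by_field(tracks) -> dict:
    """Partition trajectories into ``{field_id: FieldGroup}``."""
    out: dict = {}
    for tr in tracks:
        out.setdefault(tr.field_id, []).append(tr)
    return {
        fid: FieldGroup(field_id=fid, trajectories=trs)
        for fid, trs in out.items()
    }
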