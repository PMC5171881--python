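"""Synthetic data with full ground truth.

Two generators mirror the two analysis arms:

* :func:`simulate_trajectories` — 2D Markov-switching Brownian motion at
  the acquisition frame rate, with static Gaussian localization error and
  geometric (memoryless photobleaching) track lengths. Defaults are the
  study scale: ~3,500 tracks per field of mean length ~11 steps at 33 Hz.
* :func:`simulate_clustered_localizations` — clustered point patterns with
  finite localization precision, repeated blinking (over-counting) and
  background molecules; the default cluster profile is constructed so that
  the within-cluster pair-separation density is exactly
  exp(−r/ξ)/(2πξ²), i.e. the clustering term of the pair-correlation
  model the analysis fits, making ξ a genuine ground-truth parameter.

Everything is reproducible bit-for-bit under a fixed ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .locs import LocalizationTable
from .tracks import Trajectory

__all__ = [
    "TrajectorySimParams",
    "ClusterSimParams",
    "TrajectoryGroundTruth",
    "ClusterGroundTruth",
    "simulate_trajectories",
    "simulate_clustered_localizations",
    "simulate_csr",
    "rest_trajectory_params",
    "stimulated_trajectory_params",
    "rest_cluster_params",
    "stimulated_cluster_params",
]


# ---------------------------------------------------------------------------
# trajectory simulation


@dataclass
class TrajectorySimParams:
    """Markov-switching Brownian motion parameters.

    ``states`` lists the true diffusion coefficients (μm² s⁻¹); the chain
    switches between them per frame according to ``transition_matrix``.
    ``loc_noise_sd`` is the static localization error per coordinate (μm).
    Track lengths (in steps) are geometric with mean ``mean_track_len``.
    """

    n_tracks: int = 3500
    mean_track_len: float = 11.0
    dt: float = 1.0 / 33.0
    states: tuple = (0.005, 0.06, 0.35)
    transition_matrix: np.ndarray = None
    initial_occupancy: np.ndarray = None
    loc_noise_sd: float = 0.02
    fov: tuple = (0.0, 20.0, 0.0, 20.0)
    rng_seed: int = 0
    field_id: str = "sim"

    def __post_init__(self) -> None:
        self.states = tuple(float(d) for d in self.states)
        k = len(self.states)
        if any(d < 0 for d in self.states):
            raise ValueError("diffusion coefficients must be >= 0")
        if self.loc_noise_sd < 0:
            raise ValueError("loc_noise_sd must be >= 0")
        if self.n_tracks < 1 or self.mean_track_len < 1 or self.dt <= 0:
            raise ValueError("n_tracks, mean_track_len >= 1 and dt > 0 required")
        if self.transition_matrix is None:
            # mild default switching: 5% chance of leaving the state per frame
            tm = np.full((k, k), 0.05 / max(k - 1, 1))
            np.fill_diagonal(tm, 0.95 if k > 1 else 1.0)
            self.transition_matrix = tm
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.transition_matrix.shape != (k, k):
            raise ValueError("transition_matrix must be K x K")
        if np.any(self.transition_matrix < 0) or np.any(
            np.abs(self.transition_matrix.sum(axis=1) - 1.0) > 1e-12
        ):
            raise ValueError("transition_matrix rows must be probabilities summing to 1")
        if self.initial_occupancy is None:
            self.initial_occupancy = stationary_distribution(self.transition_matrix)
        self.initial_occupancy = np.asarray(self.initial_occupancy, dtype=float)
        if self.initial_occupancy.shape != (k,) or np.any(self.initial_occupancy < 0) \
                or abs(self.initial_occupancy.sum() - 1.0) > 1e-10:
            raise ValueError("initial_occupancy must be a length-K probability vector")


@dataclass
class TrajectoryGroundTruth:
    """True per-step states of every simulated track."""

    params: TrajectorySimParams
    states_per_track: list = field(default_factory=list)  # int arrays, len = steps

    def pooled_states(self) -> np.ndarray:
        return np.concatenate(self.states_per_track) if self.states_per_track \
            else np.empty(0, dtype=np.int64)

    def occupancy(self) -> np.ndarray:
        pooled = self.pooled_states()
        k = len(self.params.states)
        return np.bincount(pooled, minlength=k) / max(len(pooled), 1)


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    tm = np.asarray(transition_matrix, dtype=float)
    vals, vecs = np.linalg.eig(tm.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_trajectories(params: TrajectorySimParams):
    """Simulate Markov-switching Brownian tracks.

    Per step the state evolves by the Markov chain and each coordinate
    moves by N(0, 2·D_state·dt); reported positions add independent
    N(0, loc_noise_sd²) per coordinate (static localization error).

    Returns
    -------
    (list of Trajectory, TrajectoryGroundTruth)
    """
    rng = np.random.default_rng(params.rng_seed)
    k = len(params.states)
    n = params.n_tracks
    # geometric number of steps, mean = mean_track_len, support {1, 2, ...}
    n_steps = rng.geometric(1.0 / params.mean_track_len, size=n)
    max_steps = int(n_steps.max())

    # state chains, batched over tracks across time
    states = np.empty((n, max_steps), dtype=np.int64)
    cum_init = np.cumsum(params.initial_occupancy)
    states[:, 0] = np.searchsorted(cum_init, rng.random(n), side="right")
    cum_tm = np.cumsum(params.transition_matrix, axis=1)
    for t in range(1, max_steps):
        u = rng.random(n)
        states[:, t] = (u[:, None] > cum_tm[states[:, t - 1]]).sum(axis=1)
    np.clip(states, 0, k - 1, out=states)

    d_arr = np.asarray(params.states)
    step_sd = np.sqrt(2.0 * d_arr[states] * params.dt)
    dx = rng.standard_normal((n, max_steps)) * step_sd
    dy = rng.standard_normal((n, max_steps)) * step_sd

    xmin, xmax, ymin, ymax = params.fov
    x0 = rng.uniform(xmin, xmax, size=n)
    y0 = rng.uniform(ymin, ymax, size=n)
    start_frames = rng.integers(0, 10_000, size=n)

    noise_sd = params.loc_noise_sd
    tracks = []
    gt_states = []
    for i in range(n):
        m = int(n_steps[i])
        xs = x0[i] + np.concatenate(([0.0], np.cumsum(dx[i, :m])))
        ys = y0[i] + np.concatenate(([0.0], np.cumsum(dy[i, :m])))
        if noise_sd > 0:
            xs = xs + rng.normal(0.0, noise_sd, size=m + 1)
            ys = ys + rng.normal(0.0, noise_sd, size=m + 1)
        frames = start_frames[i] + np.arange(m + 1)
        tracks.append(Trajectory(
            track_id=f"t{i:06d}", frames=frames, x=xs, y=ys,
            dt=params.dt, field_id=params.field_id,
        ))
        gt_states.append(states[i, :m].copy())
    return tracks, TrajectoryGroundTruth(params=params, states_per_track=gt_states)


# ---------------------------------------------------------------------------
# clustered localization simulation


@dataclass
class ClusterSimParams:
    """Clustered SMLM point-pattern parameters (nm / μm⁻² units).

    ``cluster_radius_xi`` is the correlation length ξ: with the default
    ``profile="exp-correlation"`` the separation of two molecules of the
    same cluster has 2D density exp(−r/ξ)/(2πξ²), exactly the exponential
    clustering term of the pair-correlation model. Alternative profiles
    ('exponential' = exponential radial *density*, 'gaussian') are provided
    for robustness tests. ``blinks_per_molecule_mean`` is the mean of a
    geometric blink count on {1, 2, ...}; blinks land on uniformly random
    frames with Gaussian localization error ``loc_precision_sd``.
    """

    fov: tuple = (0.0, 10_000.0, 0.0, 10_000.0)   # nm
    cluster_center_density: float = 1.5           # μm⁻²
    molecules_per_cluster_mean: float = 40.0
    cluster_radius_xi: float = 83.5               # nm
    background_density: float = 5.0               # μm⁻²
    blinks_per_molecule_mean: float = 2.0
    loc_precision_sd: float = 20.0                # nm
    frames_total: int = 15_000
    profile: str = "exp-correlation"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cluster_center_density, self.molecules_per_cluster_mean,
               self.cluster_radius_xi, self.background_density,
               self.loc_precision_sd) < 0:
            raise ValueError("densities, radii and precisions must be >= 0")
        if self.blinks_per_molecule_mean < 1:
            raise ValueError("blinks_per_molecule_mean must be >= 1")
        if self.frames_total < 1:
            raise ValueError("frames_total must be >= 1")
        if self.profile not in ("exp-correlation", "exponential", "gaussian"):
            raise ValueError(f"unknown cluster profile {self.profile!r}")
        xmin, xmax, ymin, ymax = self.fov
        if xmax - xmin < 10 or ymax - ymin < 10:
            raise ValueError("fov smaller than one render pixel")


@dataclass
class ClusterGroundTruth:
    """Cluster centers, true molecule positions and blink assignments."""

    params: ClusterSimParams
    cluster_centers: np.ndarray = None       # (n_clusters, 2) nm
    molecule_xy: np.ndarray = None           # (n_molecules, 2) nm
    molecule_cluster: np.ndarray = None      # cluster index, -1 = background
    blink_molecule: np.ndarray = None        # molecule index per localization

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_centers)

    @property
    def molecule_density_um2(self) -> float:
        """True molecule density inside the fov (centers may lie outside)."""
        xmin, xmax, ymin, ymax = self.params.fov
        xy = self.molecule_xy
        inside = ((xy[:, 0] >= xmin) & (xy[:, 0] <= xmax)
                  & (xy[:, 1] >= ymin) & (xy[:, 1] <= ymax))
        return inside.sum() / ((xmax - xmin) * (ymax - ymin) * 1e-6)

    def mean_molecules_per_cluster(self) -> float:
        clustered = self.molecule_cluster >= 0
        if self.n_clusters == 0:
            return 0.0
        return float(clustered.sum()) / self.n_clusters


def _cluster_offsets(rng, n, xi, profile):
    """Isotropic 2D offsets around a cluster center, scale ξ (nm)."""
    if profile == "exp-correlation":
        # Gaussian scale mixture with s ~ Gamma(3/4, 2ξ²): the difference of
        # two such offsets has density exp(−r/ξ)/(2πξ²) exactly.
        s = rng.gamma(shape=0.75, scale=2.0 * xi * xi, size=n)
        return np.sqrt(s)[:, None] * rng.standard_normal((n, 2))
    if profile == "exponential":
        # radial pdf ∝ r·exp(−r/ξ): Gamma(2, ξ)
        r = rng.gamma(shape=2.0, scale=xi, size=n)
    elif profile == "gaussian":
        # isotropic Gaussian with per-coordinate sd ξ
        r = rng.rayleigh(scale=xi, size=n)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack((r * np.cos(theta), r * np.sin(theta)))


def simulate_clustered_localizations(params: ClusterSimParams):
    """Simulate a clustered, blinking SMLM localization table.

    Cluster centers are Poisson in the fov; molecule counts per cluster are
    Poisson; background molecules are an independent Poisson pattern; each
    molecule emits a geometric number of blinks at uniformly random frames,
    each displaced by N(0, loc_precision_sd²) per coordinate.

    Returns
    -------
    (LocalizationTable, ClusterGroundTruth)
    """
    rng = np.random.default_rng(params.rng_seed)
    xmin, xmax, ymin, ymax = params.fov
    area_um2 = (xmax - xmin) * (ymax - ymin) * 1e-6

    # centers are sampled in an expanded window so clusters straddling the
    # border contribute molecules into the fov (stationary pattern)
    margin = 8.0 * params.cluster_radius_xi + 4.0 * params.loc_precision_sd
    ext_area_um2 = ((xmax - xmin + 2 * margin)
                    * (ymax - ymin + 2 * margin)) * 1e-6
    n_clusters = rng.poisson(params.cluster_center_density * ext_area_um2)
    centers = np.column_stack((
        rng.uniform(xmin - margin, xmax + margin, size=n_clusters),
        rng.uniform(ymin - margin, ymax + margin, size=n_clusters),
    ))
    mols = []
    mol_cluster = []
    if n_clusters:
        counts = rng.poisson(params.molecules_per_cluster_mean, size=n_clusters)
        for ci in range(n_clusters):
            if counts[ci] == 0:
                continue
            offs = _cluster_offsets(rng, int(counts[ci]),
                                    params.cluster_radius_xi, params.profile)
            mols.append(centers[ci] + offs)
            mol_cluster.append(np.full(int(counts[ci]), ci, dtype=np.int64))
    n_bg = rng.poisson(params.background_density * area_um2)
    if n_bg:
        mols.append(np.column_stack((
            rng.uniform(xmin, xmax, size=n_bg),
            rng.uniform(ymin, ymax, size=n_bg),
        )))
        mol_cluster.append(np.full(n_bg, -1, dtype=np.int64))

    if mols:
        molecule_xy = np.concatenate(mols)
        molecule_cluster = np.concatenate(mol_cluster)
    else:
        molecule_xy = np.empty((0, 2))
        molecule_cluster = np.empty(0, dtype=np.int64)
    n_mol = len(molecule_xy)

    if params.blinks_per_molecule_mean > 1:
        blinks = rng.geometric(1.0 / params.blinks_per_molecule_mean, size=n_mol)
    else:
        blinks = np.ones(n_mol, dtype=np.int64)
    blink_mol = np.repeat(np.arange(n_mol), blinks)
    n_loc = len(blink_mol)
    xy = molecule_xy[blink_mol]
    if params.loc_precision_sd > 0:
        xy = xy + rng.normal(0.0, params.loc_precision_sd, size=(n_loc, 2))
    frames = rng.integers(0, params.frames_total, size=n_loc)

    # cluster offsets and precision can land blinks outside the window;
    # drop them (clipping would pile artefactual density on the borders)
    inside = ((xy[:, 0] >= xmin) & (xy[:, 0] <= xmax)
              & (xy[:, 1] >= ymin) & (xy[:, 1] <= ymax))
    xy, frames, blink_mol = xy[inside], frames[inside], blink_mol[inside]
    n_loc = len(blink_mol)

    order = np.argsort(frames, kind="stable")
    df = pd.DataFrame({
        "frame": frames[order],
        "x": xy[order, 0],
        "y": xy[order, 1],
        "precision": np.full(n_loc, max(params.loc_precision_sd, 1e-9)),
    })
    table = LocalizationTable(df=df, fov=params.fov)
    gt = ClusterGroundTruth(
        params=params,
        cluster_centers=centers,
        molecule_xy=molecule_xy,
        molecule_cluster=molecule_cluster,
        blink_molecule=blink_mol[order],
    )
    return table, gt


def simulate_csr(density_um2: float, fov, rng_seed: int = 0) -> LocalizationTable:
    """Homogeneous Poisson (complete spatial randomness) localization table.

    One blink per point; frames assigned uniformly at random. The null
    model for the pair-correlation and Ripley statistics.
    """
    if density_um2 < 0:
        raise ValueError("density must be >= 0")
    rng = np.random.default_rng(rng_seed)
    xmin, xmax, ymin, ymax = fov
    area_um2 = (xmax - xmin) * (ymax - ymin) * 1e-6
    n = rng.poisson(density_um2 * area_um2)
    df = pd.DataFrame({
        "frame": rng.integers(0, 15_000, size=n),
        "x": rng.uniform(xmin, xmax, size=n),
        "y": rng.uniform(ymin, ymax, size=n),
    })
    return LocalizationTable(df=df, fov=tuple(fov))


# ---------------------------------------------------------------------------
# study-condition presets


def rest_trajectory_params(seed: int = 0, **overrides) -> TrajectorySimParams:
    """Resting-terminal preset: mostly immobile, modest fast occupancy."""
    kw = dict(
        states=(0.005, 0.06, 0.35),
        transition_matrix=np.array([
            [0.92, 0.06, 0.02],
            [0.10, 0.82, 0.08],
            [0.04, 0.16, 0.80],
        ]),
        rng_seed=seed,
        field_id="rest",
    )
    kw.update(overrides)
    return TrajectorySimParams(**kw)


def stimulated_trajectory_params(seed: int = 0, **overrides) -> TrajectorySimParams:
    """Stimulated preset: occupancy shifted from immobile toward fast."""
    kw = dict(
        states=(0.005, 0.06, 0.35),
        transition_matrix=np.array([
            [0.85, 0.09, 0.06],
            [0.08, 0.80, 0.12],
            [0.02, 0.10, 0.88],
        ]),
        rng_seed=seed,
        field_id="stim",
    )
    kw.update(overrides)
    return TrajectorySimParams(**kw)


def rest_cluster_params(seed: int = 0, **overrides) -> ClusterSimParams:
    """Resting-terminal nanocluster preset (ξ ≈ 83.5 nm, ~60 μm⁻²)."""
    kw = dict(
        cluster_center_density=1.4,
        molecules_per_cluster_mean=40.0,
        cluster_radius_xi=83.5,
        background_density=5.0,
        rng_seed=seed,
    )
    kw.update(overrides)
    return ClusterSimParams(**kw)


def stimulated_cluster_params(seed: int = 0, **overrides) -> ClusterSimParams:
    """Stimulated preset: smaller, sparser clusters with fewer molecules."""
    kw = dict(
        cluster_center_density=1.1,
        molecules_per_cluster_mean=31.5,
        cluster_radius_xi=60.1,
        background_density=4.0,
        rng_seed=seed,
    )
    kw.update(overrides)
    return ClusterSimParams(**kw)
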