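"""Hidden-Markov inference of discrete diffusive states.

A molecule switching between K diffusive states produces, in state k,
isotropic 2D Gaussian steps whose squared displacement r² is exponential
with mean 4·D_k·Δt. The chain over states is first-order Markov per
frame. Fitting is Baum–Welch EM over all (gap-free) track segments of a
field, batched across tracks; the state count is chosen by BIC over
candidates K = 1..max_states (default 5), each started from a quantile
split of the step lengths plus random restarts. Localization error is not
modeled separately — the fitted coefficients are *apparent* D values.

Per-step annotation uses the Viterbi algorithm; fitted states are pooled
into immobile / slow mobile / fast mobile classes by their apparent D.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import stationary_distribution
from .tracks import Trajectory

log = logging.getLogger(__name__)

__all__ = [
    "HMMModel",
    "StatePath",
    "PooledOccupancy",
    "fit_hmm",
    "annotate_steps",
    "pool_states",
    "compare_occupancies",
    "DiffusiveStateHMM",
    "HMMResults",
]

_D_FLOOR = 1e-9          # μm² s⁻¹, keeps emission means strictly positive
_PROB_FLOOR = 1e-12


@dataclass
class HMMModel:
    """Fitted K-state diffusive HMM (states sorted by ascending D)."""

    K: int
    D_app: np.ndarray            # μm² s⁻¹, ascending
    occupancy: np.ndarray        # posterior-weighted empirical step fractions
    occupancy_stationary: np.ndarray
    transitions: np.ndarray      # K×K per-frame probabilities
    initial: np.ndarray          # track-birth state distribution
    dt: float
    loglik: float
    selection_scores: dict       # candidate K -> BIC
    n_steps: int
    converged: bool = True
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.D_app) >= 0), "states must be sorted by D"
        assert np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-10)
        assert abs(self.occupancy.sum() - 1.0) < 1e-10

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in range(self.K):
            row = {
                "state": k,
                "D_app_um2_s": self.D_app[k],
                "occupancy": self.occupancy[k],
                "occupancy_stationary": self.occupancy_stationary[k],
            }
            for j in range(self.K):
                row[f"p_to_state{j}"] = self.transitions[k, j]
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class StatePath:
    """Most-likely state index per step of one track (−1 = gap step)."""

    track_id: str
    states: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "track_id": self.track_id,
            "step": np.arange(len(self.states)),
            "state": self.states,
        })


@dataclass
class PooledOccupancy:
    """Occupancy pooled into immobile / slow mobile / fast mobile."""

    immobile: float
    slow: float
    fast: float
    state_class: list            # per model state: 'immobile'|'slow'|'fast'
    field_id: str = "field0"

    def as_array(self) -> np.ndarray:
        return np.array([self.immobile, self.slow, self.fast])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "field_id": self.field_id, "immobile": self.immobile,
            "slow": self.slow, "fast": self.fast,
        }])


# ---------------------------------------------------------------------------
# data preparation


def _collect_segments(tracks):
    """Squared-step arrays of every gap-free segment, one entry each."""
    segs = []
    for tr in tracks:
        segs.extend(tr.squared_steps())
    return [s for s in segs if len(s) > 0]


def _pad(segs):
    """Pad segments to a matrix, sorted by descending length.

    Sorting means the sequences still active at time t always occupy the
    leading rows, so the forward–backward recursions can run on array
    prefixes instead of masked full arrays (~10× less work at the study's
    short mean track length).
    """
    lengths = np.array([len(s) for s in segs], dtype=np.int64)
    order = np.argsort(-lengths, kind="stable")
    lengths = lengths[order]
    tmax = int(lengths.max())
    r2 = np.zeros((len(segs), tmax))
    for i, oi in enumerate(order):
        r2[i, : lengths[i]] = segs[oi]
    # n_active[t] = number of sequences with length > t
    n_active = np.searchsorted(-lengths, -np.arange(tmax), side="left")
    return r2, lengths, n_active


# ---------------------------------------------------------------------------
# EM core (scaled forward–backward, batched over segments)


def _e_step(r2, n_active, d_app, trans, pi, dt):
    """One scaled forward–backward sweep over length-sorted sequences.

    At time t only the leading ``n_active[t]`` rows are alive; sequences
    of length t+1 occupy the block [n_active[t+1], n_active[t]) thanks to
    the descending-length sort.
    """
    means = 4.0 * np.maximum(d_app, _D_FLOOR) * dt
    s_n, tmax = r2.shape
    k = len(d_app)
    alpha = np.zeros((s_n, tmax, k))
    c = np.ones((s_n, tmax))
    b_store = [None] * tmax

    def emis(t, na):
        b = np.exp(-r2[:na, t, None] / means[None, :]) / means[None, :]
        return np.maximum(b, _PROB_FLOOR)

    b0 = emis(0, s_n)
    b_store[0] = b0
    a0 = pi[None, :] * b0
    c0 = a0.sum(axis=1)
    c[:, 0] = np.where(c0 > 0, c0, 1.0)
    alpha[:, 0, :] = a0 / c[:, 0][:, None]
    loglik = float(np.log(c[:, 0]).sum())
    for t in range(1, tmax):
        na = n_active[t]
        bt = emis(t, na)
        b_store[t] = bt
        a_t = (alpha[:na, t - 1, :] @ trans) * bt
        ct = a_t.sum(axis=1)
        ct = np.where(ct > 0, ct, 1.0)
        alpha[:na, t, :] = a_t / ct[:, None]
        c[:na, t] = ct
        loglik += float(np.log(ct).sum())

    gamma_sum = np.zeros(k)
    gamma_r2 = np.zeros(k)
    gamma0 = np.zeros(k)
    xi_sum = np.zeros((k, k))
    beta = np.zeros((s_n, k))
    for t in range(tmax - 1, -1, -1):
        na = n_active[t]
        na_next = n_active[t + 1] if t + 1 < tmax else 0
        beta[na_next:na] = 1.0          # sequences ending exactly at t
        g = alpha[:na, t, :] * beta[:na]
        gamma_sum += g.sum(axis=0)
        gamma_r2 += g.T @ r2[:na, t]
        if t == 0:
            gamma0 = g.sum(axis=0)
        else:
            bb = b_store[t] * beta[:na] / c[:na, t][:, None]
            xi_sum += trans * (alpha[:na, t - 1, :].T @ bb)
            beta[:na] = bb @ trans.T
    return loglik, gamma_sum, gamma_r2, gamma0, xi_sum


def _em(r2, n_active, d0, trans0, pi0, dt, max_iter, tol=1e-8):
    d_app = np.array(d0, dtype=float)
    trans = np.array(trans0, dtype=float)
    pi = np.array(pi0, dtype=float)
    n_seq = r2.shape[0]
    ll_prev = -np.inf
    ll_trace = []
    converged = False
    for _ in range(max_iter):
        ll, gamma_sum, gamma_r2, gamma0, xi_sum = _e_step(
            r2, n_active, d_app, trans, pi, dt)
        ll_trace.append(ll)
        if ll - ll_prev < tol * (1.0 + abs(ll)) and np.isfinite(ll_prev):
            converged = True
            break
        ll_prev = ll
        # M-step
        denom = np.maximum(gamma_sum, _PROB_FLOOR)
        d_app = np.maximum(gamma_r2 / (4.0 * dt * denom), _D_FLOOR)
        if len(d_app) > 1:
            rows = xi_sum.sum(axis=1, keepdims=True)
            trans = np.where(rows > 0, xi_sum / np.maximum(rows, _PROB_FLOOR),
                             1.0 / len(d_app))
            trans = trans / trans.sum(axis=1, keepdims=True)
        pi = np.maximum(gamma0 / n_seq, _PROB_FLOOR)
        pi = pi / pi.sum()
    occupancy = gamma_sum / gamma_sum.sum()
    return {
        "D_app": d_app, "transitions": trans, "initial": pi,
        "occupancy": occupancy, "loglik": ll_trace[-1],
        "ll_trace": np.array(ll_trace), "converged": converged,
    }


def _n_params(k: int) -> int:
    # K emission means + K(K−1) free transition entries + (K−1) initial probs
    return k + k * (k - 1) + (k - 1)


def _inits(r2_pooled, k, dt, n_restarts, rng):
    """Initial parameter sets: quantile split plus random restarts."""
    inits = []
    pos = r2_pooled[r2_pooled > 0]
    if len(pos) == 0:
        pos = np.array([4.0 * _D_FLOOR * dt])
    qs = np.quantile(pos, np.linspace(0, 1, k + 1))
    d_quant = []
    for i in range(k):
        sel = pos[(pos >= qs[i]) & (pos <= qs[i + 1])]
        m = sel.mean() if len(sel) else pos.mean()
        d_quant.append(max(m / (4.0 * dt), _D_FLOOR))
    trans0 = np.full((k, k), 0.1 / max(k - 1, 1))
    np.fill_diagonal(trans0, 0.9 if k > 1 else 1.0)
    inits.append((np.sort(d_quant), trans0, np.full(k, 1.0 / k)))
    scale = pos.mean() / (4.0 * dt)
    for _ in range(n_restarts):
        d_r = np.sort(scale * rng.lognormal(0.0, 1.5, size=k))
        off = rng.uniform(0.02, 0.3)
        t_r = np.full((k, k), off / max(k - 1, 1))
        np.fill_diagonal(t_r, 1.0 - off if k > 1 else 1.0)
        p_r = rng.dirichlet(np.ones(k))
        inits.append((d_r, t_r, p_r))
    return inits


def fit_hmm(tracks, max_states: int = 5, rng_seed: int = 0, dt: float = None,
            n_restarts: int = 10, max_iter: int = 300) -> HMMModel:
    """Fit candidate diffusive-state HMMs and select K by BIC.

    Each candidate K = 1..max_states is fitted by EM from a quantile-split
    initialization plus ``n_restarts`` random restarts (short runs, then
    the incumbent is run to convergence); the model with the lowest BIC
    wins. Deterministic under fixed ``rng_seed``.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no tracks to fit")
    if max_states < 1:
        raise ValueError("max_states must be >= 1")
    if dt is None:
        dt = tracks[0].dt
    segs = _collect_segments(tracks)
    if not segs:
        raise ValueError("tracks contain no usable (gap-free) steps")
    r2, lengths, n_active = _pad(segs)
    n_steps = int(lengths.sum())
    pooled = np.concatenate(segs)

    flags = []
    if np.all(pooled <= 0):
        log.warning("degenerate data: all steps are zero; returning K=1 floor model")
        return HMMModel(
            K=1, D_app=np.array([_D_FLOOR]), occupancy=np.array([1.0]),
            occupancy_stationary=np.array([1.0]),
            transitions=np.array([[1.0]]), initial=np.array([1.0]), dt=dt,
            loglik=float("nan"), selection_scores={}, n_steps=n_steps,
            converged=True, flags=["degenerate_zero_steps"],
        )
    # keep candidate complexity supported by the data (≥10 steps/parameter)
    kmax = max_states
    while kmax > 1 and n_steps < 10 * _n_params(kmax):
        kmax -= 1
    if kmax < max_states:
        flags.append(f"max_states_reduced_to_{kmax}")
        log.warning("only %d steps: candidate states capped at %d", n_steps, kmax)

    rng = np.random.default_rng(rng_seed)
    scores = {}
    best = None
    for k in range(1, kmax + 1):
        fits = []
        restarts = 0 if k == 1 else n_restarts
        for d0, t0, p0 in _inits(pooled, k, dt, restarts, rng):
            fits.append(_em(r2, n_active, d0, t0, p0, dt, max_iter=25,
                            tol=1e-6))
        incumbent = max(fits, key=lambda f: f["loglik"])
        fit = _em(r2, n_active, incumbent["D_app"], incumbent["transitions"],
                  incumbent["initial"], dt, max_iter=max_iter)
        bic = -2.0 * fit["loglik"] + _n_params(k) * np.log(n_steps)
        scores[k] = bic
        if best is None or bic < best[1]["bic"]:
            fit["bic"] = bic
            best = (k, fit)
        else:
            fit["bic"] = bic
    k_sel, fit = best
    if not fit["converged"]:
        flags.append("em_not_converged")

    order = np.argsort(fit["D_app"])
    d_sorted = fit["D_app"][order]
    trans = fit["transitions"][np.ix_(order, order)]
    return HMMModel(
        K=k_sel,
        D_app=d_sorted,
        occupancy=fit["occupancy"][order],
        occupancy_stationary=stationary_distribution(trans),
        transitions=trans,
        initial=fit["initial"][order],
        dt=dt,
        loglik=fit["loglik"],
        selection_scores=scores,
        n_steps=n_steps,
        converged=fit["converged"],
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Viterbi annotation


def _viterbi_segment(r2, d_app, trans, pi, dt):
    means = 4.0 * np.maximum(d_app, _D_FLOOR) * dt
    logb = -np.log(means)[None, :] - r2[:, None] / means[None, :]
    log_a = np.log(np.maximum(trans, _PROB_FLOOR))
    t_n, k = logb.shape
    delta = np.log(np.maximum(pi, _PROB_FLOOR)) + logb[0]
    psi = np.zeros((t_n, k), dtype=np.int64)
    for t in range(1, t_n):
        scores = delta[:, None] + log_a
        psi[t] = np.argmax(scores, axis=0)
        delta = scores[psi[t], np.arange(k)] + logb[t]
    path = np.empty(t_n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(t_n - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


def annotate_steps(model: HMMModel, track: Trajectory) -> StatePath:
    """Most-likely joint state sequence (Viterbi) over a track's steps.

    Gap-free segments are decoded independently; a step bridging missing
    frames is annotated −1.
    """
    if len(track) < 2:
        raise ValueError("track must have >= 2 points")
    states = np.full(len(track) - 1, -1, dtype=np.int64)
    breaks = np.flatnonzero(np.diff(track.frames) != 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks + 1, [len(track)]))
    for a, b in zip(starts, stops):
        if b - a < 2:
            continue
        r2 = np.diff(track.x[a:b]) ** 2 + np.diff(track.y[a:b]) ** 2
        states[a:b - 1] = _viterbi_segment(
            r2, model.D_app, model.transitions, model.initial, model.dt)
    return StatePath(track_id=track.track_id, states=states)


# ---------------------------------------------------------------------------
# pooling and comparison


def pool_states(model: HMMModel, immobile_cutoff: float = 0.021,
                fast_cutoff: float = 0.15, field_id: str = "field0",
                use_stationary: bool = False) -> PooledOccupancy:
    """Pool model states into immobile / slow / fast classes by D_app.

    A state is immobile when D ≤ ``immobile_cutoff``, fast when
    D ≥ ``fast_cutoff``, slow otherwise; occupancies are summed by class.
    """
    if not immobile_cutoff < fast_cutoff:
        raise ValueError("cutoffs must be ascending")
    occ = model.occupancy_stationary if use_stationary else model.occupancy
    classes = []
    sums = {"immobile": 0.0, "slow": 0.0, "fast": 0.0}
    for k in range(model.K):
        if model.D_app[k] <= immobile_cutoff:
            cls = "immobile"
        elif model.D_app[k] >= fast_cutoff:
            cls = "fast"
        else:
            cls = "slow"
        classes.append(cls)
        sums[cls] += float(occ[k])
    return PooledOccupancy(immobile=sums["immobile"], slow=sums["slow"],
                           fast=sums["fast"], state_class=classes,
                           field_id=field_id)


def compare_occupancies(group_a, group_b, label_a="A", label_b="B") -> pd.DataFrame:
    """Descriptive per-class occupancy comparison of two groups of fields.

    Returns mean ± s.e.m. per class and the B − A difference; significance
    testing is deliberately left to downstream statistics tools.
    """
    group_a, group_b = list(group_a), list(group_b)
    for name, grp in ((label_a, group_a), (label_b, group_b)):
        if len(grp) < 3:
            log.warning("group %s has %d field(s) (<3): descriptive only",
                        name, len(grp))
    arr_a = np.array([p.as_array() for p in group_a])
    arr_b = np.array([p.as_array() for p in group_b])

    def _sem(arr):
        if len(arr) < 2:
            return np.full(arr.shape[1], np.nan)
        return arr.std(axis=0, ddof=1) / np.sqrt(len(arr))

    return pd.DataFrame({
        "state_class": ["immobile", "slow", "fast"],
        f"mean_{label_a}": arr_a.mean(axis=0),
        f"sem_{label_a}": _sem(arr_a),
        f"n_{label_a}": len(arr_a),
        f"mean_{label_b}": arr_b.mean(axis=0),
        f"sem_{label_b}": _sem(arr_b),
        f"n_{label_b}": len(arr_b),
        "difference": arr_b.mean(axis=0) - arr_a.mean(axis=0),
    })


# ---------------------------------------------------------------------------
# model / results layer


class DiffusiveStateHMM:
    """Diffusive-state HMM for a field's trajectories.

    Parameters
    ----------
    tracks : sequence of Trajectory
        Typically all tracks of one imaging field (one model per field).
    max_states : int
        Candidate state-count cap (default 5).
    dt : float, optional
        Frame interval; defaults to the tracks' own.
    n_restarts : int
        Random EM restarts per candidate K besides the quantile init.
    """

    def __init__(self, tracks, max_states: int = 5, dt: float = None,
                 n_restarts: int = 10, immobile_cutoff: float = 0.021,
                 fast_cutoff: float = 0.15):
        self.tracks = list(tracks)
        self.max_states = max_states
        self.dt = dt if dt is not None else (self.tracks[0].dt if self.tracks
                                             else 1.0 / 33.0)
        self.n_restarts = n_restarts
        self.immobile_cutoff = immobile_cutoff
        self.fast_cutoff = fast_cutoff

    def fit(self, seed: int = 0) -> "HMMResults":
        model = fit_hmm(self.tracks, max_states=self.max_states,
                        rng_seed=seed, dt=self.dt, n_restarts=self.n_restarts)
        return HMMResults(model=self, hmm=model)


@dataclass
class HMMResults:
    """Fitted diffusive-state model with annotation and pooling helpers."""

    model: DiffusiveStateHMM
    hmm: HMMModel

    @property
    def K(self) -> int:
        return self.hmm.K

    @property
    def D_app(self) -> np.ndarray:
        return self.hmm.D_app

    @property
    def occupancy(self) -> np.ndarray:
        return self.hmm.occupancy

    @property
    def transitions(self) -> np.ndarray:
        return self.hmm.transitions

    def annotate(self, tracks=None):
        """Viterbi state paths for ``tracks`` (default: the fitted ones)."""
        tracks = self.model.tracks if tracks is None else tracks
        return [annotate_steps(self.hmm, tr) for tr in tracks]

    def pooled(self, field_id: str = "field0",
               use_stationary: bool = False) -> PooledOccupancy:
        return pool_states(self.hmm, self.model.immobile_cutoff,
                           self.model.fast_cutoff, field_id=field_id,
                           use_stationary=use_stationary)

    def selection_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "K": list(self.hmm.selection_scores),
            "BIC": list(self.hmm.selection_scores.values()),
        })

    def summary(self) -> str:
        m = self.hmm
        pooled = self.pooled()
        lines = [
            f"Diffusive-state HMM ({m.K} states, BIC-selected, "
            f"max {self.model.max_states})",
            "=" * 56,
            f"steps fitted      {m.n_steps}",
            f"log-likelihood    {m.loglik:.2f}",
            f"converged         {m.converged}   flags: {m.flags or 'none'}",
            "",
            m.to_frame().to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            "",
            f"pooled occupancy  immobile {pooled.immobile:.3f}  "
            f"slow {pooled.slow:.3f}  fast {pooled.fast:.3f}",
        ]
        return "\n".join(lines)
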