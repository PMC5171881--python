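"""Mean-squared-displacement analysis and mobile/immobile classification.

The per-track MSD uses the overlapping time-averaged estimator

    MSD(nΔt) = ⟨(x_{i+n} − x_i)² + (y_{i+n} − y_i)²⟩_i ,

the diffusion coefficient comes from an ordinary least-squares fit of the
first ``n_fit_points`` MSD lags against time,

    MSD(τ) = 4·D·τ + a ,

with the intercept ``a`` retained (it absorbs localization error and
finite camera exposure), and a track is classified mobile iff its fitted
D exceeds the mobility threshold (default 0.021 μm² s⁻¹; tracks shorter
than 8 localizations are excluded first).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .tracks import Trajectory

log = logging.getLogger(__name__)

__all__ = [
    "MSDCurve",
    "DiffusionEstimate",
    "MobilitySummary",
    "filter_tracks",
    "compute_msd",
    "ensemble_msd",
    "fit_diffusion",
    "classify_mobility",
    "summarize_field",
    "remove_outlier_fields",
    "MobilityModel",
    "MobilityResults",
]

# fixed log10-D histogram bins so distributions are comparable across runs
HIST_EDGES = np.arange(-5.0, 1.0 + 1e-9, 0.2)
# floor applied before taking log10 for the histogram (clamped-zero D)
_LOG_FLOOR = 1e-5


@dataclass
class MSDCurve:
    """MSD versus lag for one track (or the track ensemble)."""

    lags: np.ndarray           # seconds, τ = n·Δt
    msd: np.ndarray            # μm²
    n_pairs: np.ndarray        # displacement pairs per lag
    track_id: str = "ensemble"
    sem: np.ndarray = None     # only populated for ensemble curves
    n_tracks: np.ndarray = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=np.int64)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd must be >= 0")
        if np.any(self.n_pairs < 1):
            raise ValueError("every reported lag needs >= 1 pair")

    def __len__(self) -> int:
        return len(self.lags)

    def to_frame(self) -> pd.DataFrame:
        data = {"track_id": self.track_id, "lag_s": self.lags,
                "msd_um2": self.msd, "n_pairs": self.n_pairs}
        if self.sem is not None:
            data["sem_um2"] = self.sem
        if self.n_tracks is not None:
            data["n_tracks"] = self.n_tracks
        return pd.DataFrame(data)


@dataclass
class DiffusionEstimate:
    """Linear-fit diffusion coefficient for one track."""

    D: float                   # μm² s⁻¹, clamped at 0
    offset_a: float            # μm², intercept
    n_fit_points: int
    track_id: str
    field_id: str = "field0"
    slope_raw: float = None    # unclamped slope/4 (can be negative)
    clamped: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "track_id": self.track_id, "field_id": self.field_id,
            "D_um2_s": self.D, "offset_a_um2": self.offset_a,
            "n_fit_points": self.n_fit_points, "clamped": self.clamped,
        }])


@dataclass
class MobilitySummary:
    """Per-field mobile/immobile counts, ratio and log₁₀-D histogram."""

    field_id: str
    n_mobile: int
    n_immobile: int
    threshold_used: float
    hist_edges: np.ndarray = field(default_factory=lambda: HIST_EDGES.copy())
    hist_rel_freq: np.ndarray = None

    @property
    def n_tracks(self) -> int:
        return self.n_mobile + self.n_immobile

    @property
    def mobile_immobile_ratio(self) -> float:
        """n_mobile / n_immobile; NaN (flagged undefined) when no immobile."""
        if self.n_immobile == 0:
            return float("nan")
        return self.n_mobile / self.n_immobile

    @property
    def ratio_defined(self) -> bool:
        return self.n_immobile > 0

    @property
    def mobile_fraction(self) -> float:
        return self.n_mobile / self.n_tracks if self.n_tracks else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "field_id": self.field_id,
            "n_mobile": self.n_mobile,
            "n_immobile": self.n_immobile,
            "mobile_immobile_ratio": self.mobile_immobile_ratio,
            "mobile_fraction": self.mobile_fraction,
            "threshold_um2_s": self.threshold_used,
        }])


def filter_tracks(tracks, min_len: int = 8):
    """Keep tracks with at least ``min_len`` localizations (boundary kept)."""
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    kept = [t for t in tracks if len(t) >= min_len]
    if len(kept) < len(tracks):
        log.info("filter_tracks: removed %d of %d tracks shorter than %d frames",
                 len(tracks) - len(kept), len(tracks), min_len)
    return kept


def compute_msd(track: Trajectory, n_max: int = None) -> MSDCurve:
    """Time-averaged MSD of one track over lags n = 1..n_max.

    All overlapping pairs (i, i+n) in *frame* units contribute; lags where
    frame gaps leave no pair are omitted from the curve. ``n_max`` defaults
    to (and is truncated at) the largest available frame lag.
    """
    frames = track.frames
    span = int(frames[-1] - frames[0])
    if n_max is None:
        n_max = span
    elif n_max > span:
        log.warning("track %s: n_max %d exceeds frame span %d, truncated",
                    track.track_id, n_max, span)
        n_max = span
    if n_max < 1:
        raise ValueError("n_max must be >= 1")

    lags, msds, npairs = [], [], []
    for n in range(1, n_max + 1):
        # indices i where frame[i] + n is also observed
        j = np.searchsorted(frames, frames + n)
        valid = (j < len(frames)) & (frames[np.minimum(j, len(frames) - 1)] == frames + n)
        if not valid.any():
            continue
        i_idx = np.flatnonzero(valid)
        j_idx = j[valid]
        d2 = (track.x[j_idx] - track.x[i_idx]) ** 2 \
            + (track.y[j_idx] - track.y[i_idx]) ** 2
        lags.append(n * track.dt)
        msds.append(float(d2.mean()))
        npairs.append(len(d2))
    return MSDCurve(lags=np.array(lags), msd=np.array(msds),
                    n_pairs=np.array(npairs), track_id=track.track_id)


def ensemble_msd(curves, n_points: int = 8, dt: float = None) -> MSDCurve:
    """Unweighted per-lag mean of MSD curves across tracks.

    The first ``n_points`` lags are averaged; tracks shorter than
    ``n_points`` contribute the lags they have, and the per-lag number of
    contributing tracks is reported alongside the s.e.m.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("ensemble_msd needs at least one curve")
    if dt is None:
        dt = float(curves[0].lags[0])
    sums = np.zeros(n_points)
    sqsums = np.zeros(n_points)
    counts = np.zeros(n_points, dtype=np.int64)
    pair_counts = np.zeros(n_points, dtype=np.int64)
    for c in curves:
        # map each curve lag onto the common grid n = 1..n_points
        n_idx = np.rint(c.lags / dt).astype(int) - 1
        sel = (n_idx >= 0) & (n_idx < n_points)
        sums[n_idx[sel]] += c.msd[sel]
        sqsums[n_idx[sel]] += c.msd[sel] ** 2
        counts[n_idx[sel]] += 1
        pair_counts[n_idx[sel]] += c.n_pairs[sel]
    have = counts > 0
    mean = np.full(n_points, np.nan)
    mean[have] = sums[have] / counts[have]
    var = np.full(n_points, np.nan)
    multi = counts > 1
    var[multi] = (sqsums[multi] - counts[multi] * mean[multi] ** 2) \
        / (counts[multi] - 1)
    sem = np.where(multi, np.sqrt(np.maximum(var, 0.0) / counts), np.nan)
    lags = dt * np.arange(1, n_points + 1)
    return MSDCurve(
        lags=lags[have], msd=np.maximum(mean[have], 0.0),
        n_pairs=pair_counts[have], track_id="ensemble",
        sem=sem[have], n_tracks=counts[have],
    )


def fit_diffusion(curve: MSDCurve, n_fit_points: int = 4) -> DiffusionEstimate:
    """OLS fit of the first ``n_fit_points`` MSD lags: D = slope/4.

    A negative fitted slope (offset-dominated short tracks) yields D
    clamped to 0 and flagged; classification treats such tracks as
    immobile.
    """
    n = min(n_fit_points, len(curve.lags))
    if n < 2:
        raise ValueError(
            f"track {curve.track_id}: need >= 2 usable lags, have {len(curve.lags)}"
        )
    slope, intercept = np.polyfit(curve.lags[:n], curve.msd[:n], 1)
    d_raw = slope / 4.0
    clamped = d_raw < 0
    return DiffusionEstimate(
        D=max(d_raw, 0.0), offset_a=float(intercept), n_fit_points=n,
        track_id=curve.track_id, slope_raw=float(d_raw), clamped=bool(clamped),
    )


def classify_mobility(est, threshold: float = 0.021) -> str:
    """'mobile' iff D > threshold, else 'immobile' (tie → immobile)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    d = est.D if isinstance(est, DiffusionEstimate) else float(est)
    return "mobile" if d > threshold else "immobile"


def summarize_field(estimates, threshold: float = 0.021,
                    hist_edges: np.ndarray = None) -> MobilitySummary:
    """Counts, mobile:immobile ratio and relative-frequency log₁₀-D
    histogram for the estimates of one field.

    D values are floored at 1e−5 μm² s⁻¹ before the log so clamped-zero
    tracks land in the lowest bin; the histogram is normalized to sum 1.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("summarize_field needs >= 1 estimate")
    if hist_edges is None:
        hist_edges = HIST_EDGES
    field_id = estimates[0].field_id
    ds = np.array([e.D for e in estimates])
    n_mobile = int((ds > threshold).sum())
    logd = np.log10(np.clip(ds, _LOG_FLOOR, None))
    logd = np.clip(logd, hist_edges[0], hist_edges[-1] - 1e-12)
    hist, _ = np.histogram(logd, bins=hist_edges)
    rel = hist / hist.sum()
    return MobilitySummary(
        field_id=field_id, n_mobile=n_mobile,
        n_immobile=len(ds) - n_mobile, threshold_used=threshold,
        hist_edges=np.asarray(hist_edges, dtype=float), hist_rel_freq=rel,
    )


def remove_outlier_fields(values, q: float = 0.01):
    """ROUT-style outlier flagging of a per-field summary metric.

    Robust location (median) and scale (68.27th percentile of absolute
    residuals, small-sample corrected), two-sided t p-values on the
    scaled residuals, Benjamini–Hochberg selection at FDR ``q``. Off by
    default in the pipeline; order-invariant.

    Returns
    -------
    (retained_values, outlier_flags) : (ndarray, bool ndarray)
    """
    values = np.asarray(values, dtype=float)
    if not (0 < q <= 0.5):
        raise ValueError("q must be in (0, 0.5]")
    n = len(values)
    if n < 3:
        log.warning("remove_outlier_fields: need >= 3 values, got %d; no-op", n)
        return values, np.zeros(n, dtype=bool)
    resid = values - np.median(values)
    scale = np.percentile(np.abs(resid), 68.27) * math.sqrt(n / max(n - 1, 1))
    if scale == 0:
        return values, np.zeros(n, dtype=bool)
    t = resid / scale
    pvals = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    # Benjamini–Hochberg step-up
    order = np.argsort(pvals)
    thresh = q * (np.arange(1, n + 1)) / n
    passed = pvals[order] <= thresh
    flags = np.zeros(n, dtype=bool)
    if passed.any():
        k = int(np.max(np.flatnonzero(passed)))
        flags[order[: k + 1]] = True
    return values[~flags], flags


# ---------------------------------------------------------------------------
# model / results layer


class MobilityModel:
    """MSD-based mobility analysis of a set of trajectories.

    Parameters
    ----------
    tracks : sequence of Trajectory
    config : RunConfig, optional
        Supplies the track-length filter, fit/report lag counts and the
        mobility threshold.

    Examples
    --------
    >>> res = MobilityModel(tracks).fit()
    >>> res.summary()          # doctest: +SKIP
    """

    def __init__(self, tracks, config: RunConfig = None):
        self.tracks = list(tracks)
        self.config = config or RunConfig()

    @classmethod
    def from_dataframe(cls, df, dt=None, units="um", config=None):
        """Build from a long-format table (track_id, frame, x, y[, field_id])."""
        cfg = config or RunConfig()
        dt = dt if dt is not None else cfg.dt
        scale = 1e-3 if units == "nm" else 1.0
        tracks = []
        has_field = "field_id" in df.columns
        for tid, grp in df.groupby("track_id", sort=False):
            grp = grp.sort_values("frame")
            tracks.append(Trajectory(
                track_id=str(tid),
                frames=grp["frame"].to_numpy(dtype=np.int64),
                x=grp["x"].to_numpy(dtype=float) * scale,
                y=grp["y"].to_numpy(dtype=float) * scale,
                dt=dt,
                field_id=str(grp["field_id"].iloc[0]) if has_field else "field0",
            ))
        return cls(tracks, config=cfg)

    def fit(self) -> "MobilityResults":
        cfg = self.config
        kept = filter_tracks(self.tracks, cfg.min_track_len)
        if not kept:
            raise ValueError("no tracks survive the minimum-length filter")
        curves = []
        estimates = []
        for tr in kept:
            curve = compute_msd(tr, n_max=min(cfg.msd_report_points,
                                              int(tr.frames[-1] - tr.frames[0])))
            if len(curve) < 2:
                continue
            est = fit_diffusion(curve, cfg.msd_fit_points)
            est.field_id = tr.field_id
            curves.append(curve)
            estimates.append(est)
        ens = ensemble_msd(curves, n_points=cfg.msd_report_points, dt=cfg.dt)
        by_field = {}
        for est in estimates:
            by_field.setdefault(est.field_id, []).append(est)
        summaries = {
            fid: summarize_field(ests, threshold=cfg.mobility_threshold)
            for fid, ests in by_field.items()
        }
        return MobilityResults(
            model=self, n_input_tracks=len(self.tracks),
            n_analyzed_tracks=len(estimates),
            curves=curves, estimates=estimates,
            ensemble=ens, field_summaries=summaries,
        )


@dataclass
class MobilityResults:
    """Fitted mobility analysis: per-track estimates, ensemble MSD and
    per-field mobile/immobile summaries."""

    model: MobilityModel
    n_input_tracks: int
    n_analyzed_tracks: int
    curves: list
    estimates: list
    ensemble: MSDCurve
    field_summaries: dict

    @property
    def d_values(self) -> np.ndarray:
        return np.array([e.D for e in self.estimates])

    def estimates_frame(self) -> pd.DataFrame:
        return pd.concat([e.to_frame() for e in self.estimates],
                         ignore_index=True)

    def summary_frame(self) -> pd.DataFrame:
        return pd.concat([s.to_frame() for s in self.field_summaries.values()],
                         ignore_index=True)

    def pooled_summary(self) -> MobilitySummary:
        return summarize_field(self.estimates,
                               threshold=self.model.config.mobility_threshold)

    def summary(self) -> str:
        cfg = self.model.config
        pooled = self.pooled_summary()
        lines = [
            "Mobility analysis (MSD linear fit)",
            "=" * 44,
            f"tracks analysed        {self.n_analyzed_tracks} "
            f"(of {self.n_input_tracks}, min length {cfg.min_track_len})",
            f"fit lags / report lags {cfg.msd_fit_points} / {cfg.msd_report_points}",
            f"threshold              {cfg.mobility_threshold:g} um^2/s",
            f"median D               {np.median(self.d_values):.4f} um^2/s",
            f"mobile fraction        {pooled.mobile_fraction:.3f}",
            f"mobile:immobile ratio  {pooled.mobile_immobile_ratio:.3f}",
            "",
            "per-field summaries:",
            self.summary_frame().to_string(index=False),
        ]
        return "\n".join(lines)

    def plot_msd(self, ax=None):
        """Ensemble MSD with s.e.m. error bars."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ens = self.ensemble
        ax.errorbar(ens.lags, ens.msd, yerr=ens.sem, fmt="o-", capsize=3)
        ax.set_xlabel("lag (s)")
        ax.set_ylabel("MSD (μm²)")
        return ax

    def plot_histogram(self, ax=None):
        """Relative-frequency distribution of log₁₀ D (pooled)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        pooled = self.pooled_summary()
        centers = 0.5 * (pooled.hist_edges[:-1] + pooled.hist_edges[1:])
        ax.bar(centers, pooled.hist_rel_freq, width=np.diff(pooled.hist_edges),
               edgecolor="k", linewidth=0.3)
        ax.set_xlabel("log10 D (μm² s⁻¹)")
        ax.set_ylabel("relative frequency")
        return ax
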