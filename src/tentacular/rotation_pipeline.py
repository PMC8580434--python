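"""Analysis of rotating-stimulus trials: tracking by waves of extension.

Each trial is a time series of landmark frames (nominally 1 fps, about
130 frames, stimulus rotating at about 0.5 r.p.m. = 3 deg/s).  The
pipeline:

1. downsamples the raw frame rate to 1 fps (first frame per interval);
2. normalises each tentacle's length by its own across-trial mean to get
   relative lengths (the extension wave is a pattern in relative length,
   not absolute length);
3. fits, per frame, a length-weighted von Mises to the extended-tentacle
   angles, giving a mean direction phi1(t) and concentration kappa1(t);
4. converts (kappa1, phi1) to Cartesian components for plotting alongside
   the unit-circle stimulus track;
5. classifies whether the animal tracked the stimulus: Fisher–Lee
   circular-circular correlation between phi1(t) and the stimulus angle
   over confidently fitted frames, plus a lag found by maximising mean
   circular agreement over a bounded stimulus-leads window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import circstats
from .circstats import VectorSample, fisher_lee_correlation
from .errors import EmptySampleError, SchemaError
from .geometry import unit_circle_point, wrap_deg
from .landmark_io import Trial, TrialMeta

__all__ = [
    "TentacleTimeSeries",
    "StimulusTrack",
    "TrackingSeries",
    "TrackingVerdict",
    "downsample",
    "relative_lengths",
    "frame_fits",
    "stimulus_track",
    "classify_tracking",
    "analyze_rotating_trial",
]

logger = logging.getLogger(__name__)

DEG_PER_SEC_PER_RPM = 6.0  # 360 deg / 60 s


@dataclass
class TentacleTimeSeries:
    """One tentacle's lengths and angles across the frames it was extended."""

    tentacle_id: str
    frame_indices: np.ndarray  # frames where the tentacle was observed
    lengths: np.ndarray  # pixels
    angles_body: np.ndarray  # degrees, per observed frame
    mean_length: float

    @property
    def relative_lengths(self) -> np.ndarray:
        return self.lengths / self.mean_length


@dataclass
class StimulusTrack:
    """Stimulus direction per frame, from the rotation metadata."""

    theta_deg: np.ndarray  # body frame, per frame
    times_s: np.ndarray
    angular_velocity: float  # deg/s, signed

    @property
    def xy(self) -> np.ndarray:
        rad = np.deg2rad(self.theta_deg)
        return np.column_stack([np.cos(rad), np.sin(rad)])


@dataclass
class TrackingSeries:
    """Per-frame von Mises fits of the extension field."""

    frame_indices: np.ndarray
    times_s: np.ndarray
    phi1_deg: np.ndarray  # NaN where too few tentacles
    kappa1: np.ndarray
    n_extended: np.ndarray

    @property
    def x(self) -> np.ndarray:
        return self.kappa1 * np.cos(np.deg2rad(self.phi1_deg))

    @property
    def y(self) -> np.ndarray:
        return self.kappa1 * np.sin(np.deg2rad(self.phi1_deg))

    def table(self, track: StimulusTrack | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "frame": self.frame_indices,
            "time_s": self.times_s,
            "n_extended": self.n_extended,
            "phi1_deg": self.phi1_deg,
            "kappa1": self.kappa1,
            "x": self.x,
            "y": self.y,
        })
        if track is not None:
            df["stim_deg"] = track.theta_deg
            df["stim_x"] = track.xy[:, 0]
            df["stim_y"] = track.xy[:, 1]
        return df


@dataclass
class TrackingVerdict:
    tracked: bool
    circ_corr: float
    lag_s: float
    angular_velocity: float  # deg/s recovered from phi1(t)
    n_valid_frames: int
    classifiable: bool = True
    reason: str = ""


# ---------------------------------------------------------------------------
# Downsampling and normalisation
# ---------------------------------------------------------------------------

def downsample(trial: Trial, target_fps: float = 1.0) -> Trial:
    """Reduce a rotating trial to ``target_fps`` by keeping the first frame
    of each interval; frame indices are renumbered 0..m-1."""
    if not trial.frames:
        raise SchemaError("cannot downsample an empty trial")
    raw = trial.meta.frame_rate_raw
    if raw < target_fps:
        raise ValueError("target frame rate exceeds the raw frame rate")
    step = raw / target_fps
    keep = []
    next_pick = 0.0
    for f in trial.frames:
        if f.frame_index >= next_pick:
            keep.append(f)
            next_pick = math.floor(f.frame_index / step + 1.0) * step
    new_meta = TrialMeta(**{**trial.meta.to_dict(),
                            "frame_rate_raw": target_fps})
    frames = []
    for i, f in enumerate(keep):
        g = type(f)(frame_index=i, centre=f.centre, axis_ref=f.axis_ref,
                    stimulus=f.stimulus, tentacles=dict(f.tentacles))
        frames.append(g)
    return Trial(meta=new_meta, frames=frames)


def relative_lengths(trial: Trial, angle_mode: str = "position"
                     ) -> list[TentacleTimeSeries]:
    """Per-tentacle time series with lengths normalised by the tentacle's
    own mean over the frames where it was extended."""
    obs_by_tentacle: dict[str, list] = {}
    for f in trial.frames:
        for o in trial.frame_observations(f):
            obs_by_tentacle.setdefault(o.tentacle_id, []).append(o)
    out = []
    for tid in sorted(obs_by_tentacle):
        obs = obs_by_tentacle[tid]
        lengths = np.array([o.length for o in obs])
        out.append(TentacleTimeSeries(
            tentacle_id=tid,
            frame_indices=np.array([o.frame_index for o in obs]),
            lengths=lengths,
            angles_body=np.array([o.angle(angle_mode) for o in obs]),
            mean_length=float(np.mean(lengths)),
        ))
    return out


# ---------------------------------------------------------------------------
# Per-frame fits and the stimulus track
# ---------------------------------------------------------------------------

def frame_fits(series: list[TentacleTimeSeries], n_frames: int,
               min_per_frame: int = 3, target_fps: float = 1.0
               ) -> TrackingSeries:
    """Weighted von Mises fit per frame (weights = relative lengths).

    Frames with fewer than ``min_per_frame`` extended tentacles carry NaN
    fits — missingness, not failure.
    """
    angles: list[list[float]] = [[] for _ in range(n_frames)]
    weights: list[list[float]] = [[] for _ in range(n_frames)]
    for s in series:
        rel = s.relative_lengths
        for k, fidx in enumerate(s.frame_indices):
            angles[fidx].append(s.angles_body[k])
            weights[fidx].append(rel[k])
    phi = np.full(n_frames, np.nan)
    kappa = np.full(n_frames, np.nan)
    n_ext = np.zeros(n_frames, dtype=int)
    for i in range(n_frames):
        n_ext[i] = len(angles[i])
        if n_ext[i] < min_per_frame:
            continue
        fit = circstats.vonmises_fit(
            VectorSample(np.array(angles[i]), np.array(weights[i])),
            weighted=True,
        )
        phi[i] = fit.mu_deg
        kappa[i] = fit.kappa
    idx = np.arange(n_frames)
    return TrackingSeries(frame_indices=idx, times_s=idx / target_fps,
                          phi1_deg=phi, kappa1=kappa, n_extended=n_ext)


def stimulus_track(meta: TrialMeta, n_frames: int,
                   target_fps: float = 1.0) -> StimulusTrack:
    """Stimulus direction per frame computed from the rotation metadata:
    theta_s(t) = start + direction * 6 * rpm * t (degrees, t in seconds)."""
    if meta.experiment != "rotating":
        raise ValueError("stimulus_track applies to rotating trials")
    if meta.rotation_rpm is None or meta.rotation_direction is None \
            or meta.rotation_start_angle_body is None:
        raise SchemaError(f"trial {meta.trial_id}: rotation parameters "
                         "missing")
    t = np.arange(n_frames) / target_fps
    omega = meta.rotation_direction * DEG_PER_SEC_PER_RPM * meta.rotation_rpm
    theta = wrap_deg(meta.rotation_start_angle_body + omega * t)
    return StimulusTrack(theta_deg=np.atleast_1d(theta), times_s=t,
                         angular_velocity=float(omega))


def observed_stimulus_track(trial: Trial, target_fps: float = 1.0
                            ) -> StimulusTrack:
    """Stimulus track from per-frame stimulus landmarks (when digitised)."""
    theta = []
    for f in trial.frames:
        a = trial.stimulus_angle_body(f)
        theta.append(np.nan if a is None else a)
    theta = np.asarray(theta, dtype=float)
    t = np.arange(len(theta)) / target_fps
    ok = np.isfinite(theta)
    if ok.sum() >= 2:
        unwrapped = np.unwrap(np.deg2rad(theta[ok]))
        slope = np.polyfit(t[ok], unwrapped, 1)[0]
        omega = math.degrees(slope)
    else:
        omega = float("nan")
    return StimulusTrack(theta_deg=theta, times_s=t, angular_velocity=omega)


# ---------------------------------------------------------------------------
# Tracking classification
# ---------------------------------------------------------------------------

def _recovered_velocity(times: np.ndarray, phi_deg: np.ndarray) -> float:
    """Angular velocity (deg/s) of phi(t) by linear fit on unwrapped angles."""
    if times.size < 2:
        return float("nan")
    unwrapped = np.unwrap(np.deg2rad(phi_deg))
    slope = np.polyfit(times, unwrapped, 1)[0]
    return math.degrees(slope)


def classify_tracking(
    series: TrackingSeries,
    track: StimulusTrack,
    corr_threshold: float = 0.5,
    kappa_floor: float = 0.5,
    max_lag_s: float = 60.0,
    lag_step_s: float = 1.0,
    min_frames: int = 10,
) -> TrackingVerdict:
    """Decide whether the extension wave followed the rotating stimulus.

    Frames with a defined fit and kappa1 >= ``kappa_floor`` are compared
    with the stimulus track.  The verdict requires a Fisher–Lee circular
    correlation of at least ``corr_threshold`` and rotation of phi1(t) in
    the stimulus direction.  The lag (stimulus leading) maximises the mean
    circular agreement cos(phi1(t) - theta_s(t - lag)) over a 0..max_lag_s
    grid.
    """
    valid = np.isfinite(series.phi1_deg) & (series.kappa1 >= kappa_floor)
    n_valid = int(valid.sum())
    if n_valid < min_frames:
        return TrackingVerdict(tracked=False, circ_corr=float("nan"),
                               lag_s=float("nan"),
                               angular_velocity=float("nan"),
                               n_valid_frames=n_valid, classifiable=False,
                               reason=f"only {n_valid} confidently fitted "
                                      f"frames (< {min_frames})")
    t = series.times_s[valid]
    phi = series.phi1_deg[valid]
    theta = track.theta_deg[valid]
    corr = fisher_lee_correlation(phi, theta)
    velocity = _recovered_velocity(t, phi)

    lags = np.arange(0.0, max_lag_s + lag_step_s / 2, lag_step_s)
    omega = track.angular_velocity
    # theta_s(t - L) = theta_s(t) - omega * L for a uniform rotation
    agree = [
        float(np.mean(np.cos(np.deg2rad(phi - (theta - omega * lag)))))
        for lag in lags
    ]
    lag_s = float(lags[int(np.argmax(agree))])

    same_direction = (np.sign(velocity) == np.sign(omega)) and velocity != 0
    tracked = bool(np.isfinite(corr) and corr >= corr_threshold
                   and same_direction)
    return TrackingVerdict(tracked=tracked,
                           circ_corr=float(corr),
                           lag_s=lag_s,
                           angular_velocity=velocity,
                           n_valid_frames=n_valid)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class RotatingTrialResult:
    trial_id: str
    series: TrackingSeries
    track: StimulusTrack
    verdict: TrackingVerdict
    tentacles: list[TentacleTimeSeries] = field(repr=False, default_factory=list)

    def table(self) -> pd.DataFrame:
        return self.series.table(self.track)


def analyze_rotating_trial(
    trial: Trial,
    angle_mode: str = "position",
    min_per_frame: int = 3,
    corr_threshold: float = 0.5,
    kappa_floor: float = 0.5,
    target_fps: float = 1.0,
    stimulus_source: str = "metadata",
) -> RotatingTrialResult:
    """Full rotating-trial analysis from an assembled Trial."""
    if trial.meta.is_static:
        raise ValueError("analyze_rotating_trial applies to rotating trials")
    ds = trial if trial.meta.frame_rate_raw == target_fps \
        else downsample(trial, target_fps)
    series = relative_lengths(ds, angle_mode=angle_mode)
    if not series:
        raise EmptySampleError(
            f"trial {trial.meta.trial_id}: no extended tentacles"
        )
    fits = frame_fits(series, n_frames=ds.n_frames,
                      min_per_frame=min_per_frame, target_fps=target_fps)
    if stimulus_source == "landmarks":
        track = observed_stimulus_track(ds, target_fps)
    else:
        track = stimulus_track(ds.meta, ds.n_frames, target_fps)
    verdict = classify_tracking(fits, track, corr_threshold=corr_threshold,
                                kappa_floor=kappa_floor)
    return RotatingTrialResult(trial_id=trial.meta.trial_id, series=fits,
                               track=track, verdict=verdict,
                               tentacles=series)


def plot_tracking(result: RotatingTrialResult, ax=None):
    """Line plot of the Cartesian components of the fitted extension wave
    against the unit-circle stimulus components."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    s, tr = result.series, result.track
    ax.plot(s.frame_indices, s.x, color="0.6", label="x (fit)")
    ax.plot(s.frame_indices, s.y, color="black", label="y (fit)")
    ax.plot(s.frame_indices, tr.xy[:, 0], color="0.6", ls="--",
            label="x (stimulus)")
    ax.plot(s.frame_indices, tr.xy[:, 1], color="black", ls="--",
            label="y (stimulus)")
    ax.set_xlabel("frame")
    ax.set_ylabel("Cartesian component")
    ax.legend(fontsize="small", ncol=2)
    return ax
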