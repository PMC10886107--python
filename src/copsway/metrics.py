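"""Stabilometric feature extraction from centre-of-pressure trajectories.

During quiet standing the centre of pressure (COP) — the point of
application of the ground reaction force on the support surface — traces a
planar path, the *stabilogram*. This module turns one trial's sampled COP
path into the 16 classical stabilometric summary variables used in
force-plate posturography:

* distance measures — mean distance (MD) and root-mean-square distance
  (RMS) from the central point of the stabilogram, for the resultant COP
  and its anterior–posterior (AP) and medial–lateral (ML) components [mm];
* path measures — total excursion (ESC, summed distance between
  consecutive samples) and mean velocity (VEL = ESC / T) [mm, mm/s];
* sway area rate (SWAY) — area swept about the central point per unit
  time [mm²/s];
* mean rotational frequency (FREQ) — the rotation rate at which a point
  travelling at the trial's mean velocity at its mean distance would
  circle the central point [Hz].

The central point is the trial-mean COP position; all distance, area and
frequency measures are computed after subtracting it, which makes every
feature invariant to where the subject stood on the platform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "FEATURE_NAMES",
    "NOMINAL_TRIAL_DURATION_S",
    "InvalidTrajectoryError",
    "CopTrajectory",
    "CenteredTrajectory",
    "DistanceMetrics",
    "PathMetrics",
    "FrequencyMetrics",
    "TrialFeatures",
    "center_stabilogram",
    "distance_metrics",
    "path_metrics",
    "sway_area_rate",
    "mean_frequency",
    "extract_features",
]

logger = logging.getLogger(__name__)

#: Canonical order of the 16 stabilometric outcome variables.
FEATURE_NAMES: tuple[str, ...] = (
    "MD_COP", "MD_AP", "MD_ML",
    "RMS_COP", "RMS_AP", "RMS_ML",
    "ESC_COP", "ESC_AP", "ESC_ML",
    "VEL_COP", "VEL_AP", "VEL_ML",
    "SWAY",
    "FREQ_COP", "FREQ_AP", "FREQ_ML",
)

#: Protocol trial length; trials of any length are accepted but a deviation
#: of more than 1 s from this is logged as a protocol warning.
NOMINAL_TRIAL_DURATION_S = 60.0

_DT_RTOL = 1e-9  # relative tolerance on sampling-step uniformity


class InvalidTrajectoryError(ValueError):
    """A COP time series violates the trajectory contract."""


def _validated_1d(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise InvalidTrajectoryError(f"{name} must be one-dimensional")
    if arr.size < 2:
        raise InvalidTrajectoryError(
            f"{name} needs at least 2 samples, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise InvalidTrajectoryError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class CopTrajectory:
    """One quiet-standing trial: uniformly sampled COP displacement.

    Parameters
    ----------
    time
        Sample times in seconds, strictly increasing with a uniform step.
    ap, ml
        Anterior–posterior and medial–lateral COP displacement in mm.
    """

    time: np.ndarray
    ap: np.ndarray
    ml: np.ndarray

    def __post_init__(self) -> None:
        time = _validated_1d(self.time, "time")
        ap = _validated_1d(self.ap, "ap")
        ml = _validated_1d(self.ml, "ml")
        if not (len(time) == len(ap) == len(ml)):
            raise InvalidTrajectoryError(
                "time, ap and ml must have equal length"
            )
        steps = np.diff(time)
        if np.any(steps <= 0):
            raise InvalidTrajectoryError("time must be strictly increasing")
        dt = float(steps[0])
        if np.any(np.abs(steps - dt) > _DT_RTOL * dt):
            raise InvalidTrajectoryError(
                "sampling step is not uniform (relative tolerance 1e-9)"
            )
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "ap", ap)
        object.__setattr__(self, "ml", ml)

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def dt(self) -> float:
        """Sampling step in seconds."""
        return float(self.time[1] - self.time[0])

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        """Analysed temporal interval T = (N − 1)·dt in seconds."""
        return float(self.time[-1] - self.time[0])


@dataclass(frozen=True)
class CenteredTrajectory:
    """COP displacements after subtraction of the trial-mean position."""

    ap_c: np.ndarray
    ml_c: np.ndarray
    dt: float
    duration: float

    @property
    def n_samples(self) -> int:
        return len(self.ap_c)


def center_stabilogram(traj: CopTrajectory) -> CenteredTrajectory:
    """Re-express a trajectory about the central point of the stabilogram.

    The central point is the trial-mean COP position; centering removes the
    (arbitrary) stance location on the platform while leaving the path
    shape untouched.
    """
    return CenteredTrajectory(
        ap_c=traj.ap - traj.ap.mean(),
        ml_c=traj.ml - traj.ml.mean(),
        dt=traj.dt,
        duration=traj.duration,
    )


class DistanceMetrics(NamedTuple):
    MD_COP: float
    MD_AP: float
    MD_ML: float
    RMS_COP: float
    RMS_AP: float
    RMS_ML: float


class PathMetrics(NamedTuple):
    ESC_COP: float
    ESC_AP: float
    ESC_ML: float
    VEL_COP: float
    VEL_AP: float
    VEL_ML: float


class FrequencyMetrics(NamedTuple):
    FREQ_COP: float
    FREQ_AP: float
    FREQ_ML: float
    #: names of the components whose frequency is undefined (zero mean
    #: distance or velocity); the corresponding value is NaN
    undefined: tuple[str, ...]


def distance_metrics(c: CenteredTrajectory) -> DistanceMetrics:
    """Mean and RMS displacement from the central point.

    With r[n] the planar distance of sample n from the central point:
    MD_COP = mean(r), RMS_COP = sqrt(mean(r²)); the AP and ML variants use
    the absolute 1-D displacements.
    """
    r_sq = c.ap_c ** 2 + c.ml_c ** 2
    r = np.sqrt(r_sq)
    return DistanceMetrics(
        MD_COP=float(r.mean()),
        MD_AP=float(np.abs(c.ap_c).mean()),
        MD_ML=float(np.abs(c.ml_c).mean()),
        RMS_COP=float(np.sqrt(r_sq.mean())),
        RMS_AP=float(np.sqrt((c.ap_c ** 2).mean())),
        RMS_ML=float(np.sqrt((c.ml_c ** 2).mean())),
    )


def path_metrics(c: CenteredTrajectory) -> PathMetrics:
    """Total excursion (path length) and mean velocity.

    ESC sums the distance between consecutive COP samples; VEL divides it
    by the analysed temporal interval T = (N − 1)·dt.
    """
    if c.n_samples < 2:
        raise InvalidTrajectoryError("path metrics need at least 2 samples")
    d_ap = np.diff(c.ap_c)
    d_ml = np.diff(c.ml_c)
    esc_cop = float(np.sqrt(d_ap ** 2 + d_ml ** 2).sum())
    esc_ap = float(np.abs(d_ap).sum())
    esc_ml = float(np.abs(d_ml).sum())
    t = c.duration
    return PathMetrics(
        ESC_COP=esc_cop,
        ESC_AP=esc_ap,
        ESC_ML=esc_ml,
        VEL_COP=esc_cop / t,
        VEL_AP=esc_ap / t,
        VEL_ML=esc_ml / t,
    )


def sway_area_rate(c: CenteredTrajectory) -> float:
    """Sway area enclosed by the COP path per unit time [mm²/s].

    Summed area of the triangles formed by consecutive centered COP samples
    and the central point:

        SWAY = (1 / 2T) · Σ |ap[n+1]·ml[n] − ap[n]·ml[n+1]|
    """
    cross = c.ap_c[1:] * c.ml_c[:-1] - c.ap_c[:-1] * c.ml_c[1:]
    return float(np.abs(cross).sum() / (2.0 * c.duration))


def mean_frequency(
    md_triplet: Sequence[float],
    vel_triplet: Sequence[float],
    component_form: str = "prieto",
) -> FrequencyMetrics:
    """Mean rotational frequency of the COP and its components [Hz].

    The resultant frequency is the rotation rate of a point circling the
    central point at the trial's mean distance with its mean velocity,
    FREQ_COP = VEL_COP / (2π·MD_COP). For the 1-D components two
    conventions exist:

    * ``"prieto"`` (default) — FREQ_x = VEL_x / (4·MD_x), the frequency of
      a 1-D oscillation of amplitude MD_x travelled at VEL_x;
    * ``"rotational"`` — FREQ_x = VEL_x / (2π·MD_x), the same form as the
      resultant.

    A zero denominator (motionless component) yields NaN, with the
    component named in ``undefined``.
    """
    md_cop, md_ap, md_ml = (float(v) for v in md_triplet)
    vel_cop, vel_ap, vel_ml = (float(v) for v in vel_triplet)
    for name, value in (
        ("MD_COP", md_cop), ("MD_AP", md_ap), ("MD_ML", md_ml),
        ("VEL_COP", vel_cop), ("VEL_AP", vel_ap), ("VEL_ML", vel_ml),
    ):
        if value < 0:
            raise ValueError(f"{name} must be nonnegative, got {value}")
    if component_form == "prieto":
        denom_1d = 4.0
    elif component_form == "rotational":
        denom_1d = 2.0 * np.pi
    else:
        raise ValueError(
            f"component_form must be 'prieto' or 'rotational', "
            f"got {component_form!r}"
        )

    undefined: list[str] = []

    def _ratio(name: str, vel: float, scale: float, md: float) -> float:
        if md == 0.0 or vel == 0.0:
            undefined.append(name)
            return float("nan")
        return vel / (scale * md)

    freq_cop = _ratio("FREQ_COP", vel_cop, 2.0 * np.pi, md_cop)
    freq_ap = _ratio("FREQ_AP", vel_ap, denom_1d, md_ap)
    freq_ml = _ratio("FREQ_ML", vel_ml, denom_1d, md_ml)
    return FrequencyMetrics(freq_cop, freq_ap, freq_ml, tuple(undefined))


@dataclass(frozen=True)
class TrialFeatures:
    """The 16 stabilometric outcome variables for one trial.

    Distances in mm, excursions in mm, velocities in mm/s, SWAY in mm²/s,
    frequencies in Hz. ``undefined_freqs`` names any frequency reported as
    NaN because the trial had no motion in that component.
    """

    MD_COP: float
    MD_AP: float
    MD_ML: float
    RMS_COP: float
    RMS_AP: float
    RMS_ML: float
    ESC_COP: float
    ESC_AP: float
    ESC_ML: float
    VEL_COP: float
    VEL_AP: float
    VEL_ML: float
    SWAY: float
    FREQ_COP: float
    FREQ_AP: float
    FREQ_ML: float
    fs_hz: float
    duration_s: float
    undefined_freqs: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        """The 16 features keyed by their canonical names."""
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def _lowpass(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    from scipy.signal import butter, filtfilt

    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(
            f"low-pass cutoff must lie in (0, fs/2) = (0, {fs / 2}), "
            f"got {cutoff_hz}"
        )
    b, a = butter(4, cutoff_hz, btype="low", fs=fs)
    return filtfilt(b, a, x)


def extract_features(
    traj: CopTrajectory,
    *,
    lowpass_hz: float | None = None,
    freq_component_form: str = "prieto",
) -> TrialFeatures:
    """Compute all 16 stabilometric variables for one trial.

    The trajectory is optionally low-pass filtered (4th-order zero-phase
    Butterworth; off by default — no filtering beyond mean-centering is
    applied otherwise), centered on the trial-mean COP, and summarised.
    Deterministic; degenerate zero-motion trials yield zero distance/path
    metrics and NaN-flagged frequencies rather than an error.
    """
    if abs(traj.duration - NOMINAL_TRIAL_DURATION_S) > 1.0:
        logger.warning(
            "trial duration %.2f s deviates from the %.0f s protocol",
            traj.duration, NOMINAL_TRIAL_DURATION_S,
        )
    if lowpass_hz is not None:
        traj = CopTrajectory(
            time=traj.time,
            ap=_lowpass(traj.ap, traj.fs, lowpass_hz),
            ml=_lowpass(traj.ml, traj.fs, lowpass_hz),
        )
    c = center_stabilogram(traj)
    dist = distance_metrics(c)
    path = path_metrics(c)
    sway = sway_area_rate(c)
    freq = mean_frequency(
        (dist.MD_COP, dist.MD_AP, dist.MD_ML),
        (path.VEL_COP, path.VEL_AP, path.VEL_ML),
        component_form=freq_component_form,
    )
    return TrialFeatures(
        **dist._asdict(),
        **path._asdict(),
        SWAY=sway,
        FREQ_COP=freq.FREQ_COP,
        FREQ_AP=freq.FREQ_AP,
        FREQ_ML=freq.FREQ_ML,
        fs_hz=traj.fs,
        duration_s=traj.duration,
        undefined_freqs=freq.undefined,
    )
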