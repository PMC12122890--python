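"""Reach-to-grasp kinematics: curves, phase segmentation, feature extraction.

A trial consists of three optoelectronic markers (wrist, thumbnail, index
nail) sampled at a fixed rate (120 Hz by default) in millimetres.  The wrist
marker carries the *reaching* (transport) component; the thumb-index distance
carries the *grasping* (grip aperture) component.  Reach and grasp phases are
delimited with displacement-threshold criteria (per-frame displacement of
more than 0.3 mm sustained for at least 3 consecutive frames marks movement;
the converse marks rest), and 17 spatiotemporal parameters are extracted
from the segmented curves: 9 for grip aperture, 7 for reaching, plus the
vertical hand position on the object at contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    DegeneratePhaseError,
    InsufficientDataError,
    InvalidInputError,
    NoGraspError,
    NoMovementError,
)

#: canonical parameter names, in reporting order (9 grasp + 7 reach + HandPos)
FEATURE_NAMES: tuple[str, ...] = (
    "GRange",
    "GTotDur",
    "GOpenDur",
    "GCloseDur",
    "MeanGVel",
    "GOpenPVel",
    "GOpenPDec",
    "GClosePVel",
    "GClosePDec",
    "RTotDur",
    "RAmplitude",
    "RPSpeed",
    "RTimeToPSpeed",
    "RPAcc",
    "RPDec",
    "RMeanSpeed",
    "HandPos",
)

#: additional peak-acceleration values computed but not part of the canonical 17
EXTRA_FEATURE_NAMES: tuple[str, ...] = ("GOpenPAcc", "GClosePAcc")

#: names of the eight kinematic curves, in canonical order
CURVE_NAMES: tuple[str, ...] = (
    "GA",
    "VelGA",
    "AccGA",
    "Rx",
    "Ry",
    "Rz",
    "SpeedR",
    "AccR",
)

DEFAULT_SIGMA = 0.93  # Gaussian smoothing sigma, in samples
DEFAULT_THRESHOLD_MM = 0.3  # per-frame displacement criterion
DEFAULT_RUN_FRAMES = 3  # consecutive frames required to open/close a phase


@dataclass(frozen=True)
class MarkerTrial:
    """One recorded trial: wrist/thumb/index positions in mm, plus labels.

    Arrays are (n_frames, 3) with columns x, y, z; y is vertical (up).
    """

    trial_id: str
    sampling_rate: float
    wrist: np.ndarray
    thumb: np.ndarray
    index: np.ndarray
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("wrist", "thumb", "index"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise InvalidInputError(f"{name} must be an (n, 3) array")
            if not np.all(np.isfinite(arr)):
                raise InvalidInputError(f"{name} contains non-finite values")
            object.__setattr__(self, name, arr)
        if self.sampling_rate <= 0:
            raise InvalidInputError("sampling_rate must be positive")
        n = self.wrist.shape[0]
        if self.thumb.shape[0] != n or self.index.shape[0] != n:
            raise InvalidInputError("marker arrays must share the frame count")
        if n < 4:
            raise InsufficientDataError("a trial needs at least 4 frames")

    @property
    def n_frames(self) -> int:
        return self.wrist.shape[0]


@dataclass(frozen=True)
class KinematicCurves:
    """Per-frame kinematic curves derived from one trial.

    ga            grip aperture, thumb-index distance (mm)
    vel_ga/acc_ga its first and second derivatives (mm/s, mm/s^2)
    rx, ry, rz    smoothed wrist coordinates (mm)
    speed_r       wrist speed, Euclidean norm of the wrist velocity (mm/s)
    acc_r         derivative of the wrist speed (mm/s^2)
    thumb_y/index_y  smoothed vertical finger coordinates, kept for the
                  hand-position-at-contact parameter
    """

    sampling_rate: float
    ga: np.ndarray
    vel_ga: np.ndarray
    acc_ga: np.ndarray
    rx: np.ndarray
    ry: np.ndarray
    rz: np.ndarray
    speed_r: np.ndarray
    acc_r: np.ndarray
    thumb_y: np.ndarray
    index_y: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.ga.shape[0]

    def curve(self, name: str) -> np.ndarray:
        mapping = {
            "GA": self.ga,
            "VelGA": self.vel_ga,
            "AccGA": self.acc_ga,
            "Rx": self.rx,
            "Ry": self.ry,
            "Rz": self.rz,
            "SpeedR": self.speed_r,
            "AccR": self.acc_r,
        }
        return mapping[name]


@dataclass(frozen=True)
class PhaseSegmentation:
    """Frame indices delimiting the reach and grasp phases of one trial."""

    reach_onset: int
    reach_end: int
    grasp_onset: int
    max_aperture_frame: int
    grasp_end: int
    contact_frame: int
    ambiguous_reach_end: bool = False

    def __post_init__(self) -> None:
        if not self.reach_onset < self.reach_end:
            raise InvalidInputError("reach_onset must precede reach_end")
        if not (self.grasp_onset <= self.max_aperture_frame <= self.grasp_end):
            raise InvalidInputError("grasp frames out of order")


def smooth_curve(series: Sequence[float], sigma: float = DEFAULT_SIGMA) -> np.ndarray:
    """Low-pass Gaussian smoothing (default sigma 0.93 samples).

    The kernel is truncated at +/- 4 sigma and renormalised near the edges so
    a constant series is preserved exactly everywhere.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise InvalidInputError("series must be a non-empty 1-D sequence")
    if sigma <= 0:
        raise InvalidInputError("sigma must be positive")
    radius = int(np.ceil(4.0 * sigma))
    offsets = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (offsets / sigma) ** 2)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def _gradient(y: np.ndarray, dt: float) -> np.ndarray:
    # central differences at interior frames, one-sided at the ends
    return np.gradient(y, dt)


def compute_curves(trial: MarkerTrial, sigma: float = DEFAULT_SIGMA) -> KinematicCurves:
    """Build the eight kinematic curves for a trial.

    Positions and the aperture series are smoothed before differencing;
    derivatives use central differences (one-sided at the ends).
    """
    if trial.n_frames < 4:
        raise InsufficientDataError("need at least 4 frames to differentiate")
    dt = 1.0 / trial.sampling_rate

    wrist = np.column_stack([smooth_curve(trial.wrist[:, k], sigma) for k in range(3)])
    ga_raw = np.linalg.norm(trial.thumb - trial.index, axis=1)
    ga = smooth_curve(ga_raw, sigma)

    vel_ga = _gradient(ga, dt)
    acc_ga = _gradient(vel_ga, dt)

    wrist_vel = np.column_stack([_gradient(wrist[:, k], dt) for k in range(3)])
    speed_r = np.linalg.norm(wrist_vel, axis=1)
    acc_r = _gradient(speed_r, dt)

    return KinematicCurves(
        sampling_rate=trial.sampling_rate,
        ga=ga,
        vel_ga=vel_ga,
        acc_ga=acc_ga,
        rx=wrist[:, 0],
        ry=wrist[:, 1],
        rz=wrist[:, 2],
        speed_r=speed_r,
        acc_r=acc_r,
        thumb_y=smooth_curve(trial.thumb[:, 1], sigma),
        index_y=smooth_curve(trial.index[:, 1], sigma),
    )


def _first_run_start(mask: np.ndarray, run_length: int, start: int = 0) -> int | None:
    """Index of the first position >= start opening a run of True of the
    given length, or None."""
    n = mask.size
    count = 0
    for i in range(start, n):
        count = count + 1 if mask[i] else 0
        if count >= run_length:
            return i - run_length + 1
    return None


def detect_reach_phase(
    curves: KinematicCurves,
    displacement_threshold: float = DEFAULT_THRESHOLD_MM,
    run_length: int = DEFAULT_RUN_FRAMES,
    grasp_end: int | None = None,
) -> tuple[int, int]:
    """Reach onset and end by the wrist displacement-threshold criterion.

    Onset: first frame opening a run of >= run_length frames whose per-frame
    displacement exceeds the threshold on at least one axis (strict
    inequality).  End: per axis, the first frame after onset opening a run of
    >= run_length sub-threshold frames; among per-axis candidates, the frame
    nearest ``grasp_end`` is chosen (when no grasp reference is given, the
    rule falls back to requiring all axes simultaneously sub-threshold).
    """
    disp = np.abs(
        np.diff(np.column_stack([curves.rx, curves.ry, curves.rz]), axis=0)
    )  # disp[i] = movement into frame i+1, shape (n-1, 3)
    supra_any = (disp > displacement_threshold).any(axis=1)
    onset_d = _first_run_start(supra_any, run_length)
    if onset_d is None:
        raise NoMovementError("no supra-threshold wrist displacement run")
    onset = onset_d + 1  # displacement index i marks frame i+1

    sub = disp <= displacement_threshold
    candidates = []
    for axis in range(3):
        c = _first_run_start(sub[:, axis], run_length, start=onset)
        if c is not None:
            candidates.append(c + 1)
    if grasp_end is not None and candidates:
        end = min(candidates, key=lambda c: abs(c - grasp_end))
    else:
        c = _first_run_start(sub.all(axis=1), run_length, start=onset)
        end = c + 1 if c is not None else (curves.n_frames - 1)
    if end <= onset:
        end = curves.n_frames - 1
    return onset, end


def _reach_end_candidates(
    curves: KinematicCurves,
    onset: int,
    displacement_threshold: float,
    run_length: int,
) -> list[int]:
    disp = np.abs(
        np.diff(np.column_stack([curves.rx, curves.ry, curves.rz]), axis=0)
    )
    sub = disp <= displacement_threshold
    out = []
    for axis in range(3):
        c = _first_run_start(sub[:, axis], run_length, start=onset)
        if c is not None:
            out.append(c + 1)
    return out


def detect_grasp_phase(
    curves: KinematicCurves,
    threshold: float = DEFAULT_THRESHOLD_MM,
    run_length: int = DEFAULT_RUN_FRAMES,
) -> tuple[int, int, int]:
    """Grasp onset, maximum-aperture frame and grasp end.

    Onset: first frame opening a run of >= run_length frames in which the
    aperture grows by more than the threshold.  The maximum-aperture frame is
    the argmax of the aperture after onset.  End: first frame, after finger
    closure has started (a supra-threshold closing run past the maximum),
    opening a run of >= run_length frames whose absolute aperture change
    stays below the threshold (the plateau at object contact); if the
    recording is truncated before a plateau, the last frame is used.
    """
    dga = np.diff(curves.ga)
    opening = dga > threshold
    onset_d = _first_run_start(opening, run_length)
    if onset_d is None:
        raise NoGraspError("no finger-opening run in the aperture curve")
    onset = onset_d + 1
    max_ap = onset + int(np.argmax(curves.ga[onset:]))
    close_d = _first_run_start(dga < -threshold, run_length, start=max_ap)
    search_from = close_d + run_length if close_d is not None else max_ap
    plateau = np.abs(dga) < threshold
    end_d = _first_run_start(plateau, run_length, start=search_from)
    end = end_d + 1 if end_d is not None else (curves.n_frames - 1)
    if end < max_ap:
        end = curves.n_frames - 1
    return onset, max_ap, end


def segment_trial(
    curves: KinematicCurves,
    threshold: float = DEFAULT_THRESHOLD_MM,
    run_length: int = DEFAULT_RUN_FRAMES,
    ambiguity_span: int = 5,
) -> PhaseSegmentation:
    """Full segmentation: grasp phase first, then reach with the grasp end as
    the reference for choosing among per-axis reach-end candidates.

    ``ambiguous_reach_end`` is set when the per-axis candidates span more than
    ``ambiguity_span`` frames.
    """
    g_onset, max_ap, g_end = detect_grasp_phase(curves, threshold, run_length)
    r_onset, r_end = detect_reach_phase(curves, threshold, run_length, grasp_end=g_end)
    cands = _reach_end_candidates(curves, r_onset, threshold, run_length)
    ambiguous = bool(cands) and (max(cands) - min(cands) > ambiguity_span)
    return PhaseSegmentation(
        reach_onset=r_onset,
        reach_end=r_end,
        grasp_onset=g_onset,
        max_aperture_frame=max_ap,
        grasp_end=g_end,
        contact_frame=g_end,
        ambiguous_reach_end=ambiguous,
    )


def extract_features(
    curves: KinematicCurves,
    seg: PhaseSegmentation,
    include_extras: bool = False,
) -> dict[str, float]:
    """The 17 canonical spatiotemporal parameters of one segmented trial.

    Open-phase peaks are taken on [grasp_onset, max_aperture_frame],
    close-phase peaks on [max_aperture_frame, grasp_end], reach parameters on
    [reach_onset, reach_end]; peak decelerations are reported as magnitudes.
    Durations are in ms, distances in mm, velocities mm/s, accelerations
    mm/s^2.  With ``include_extras`` the two non-canonical peak accelerations
    (GOpenPAcc, GClosePAcc) are appended.
    """
    n = curves.n_frames
    for name, idx in (
        ("reach_onset", seg.reach_onset),
        ("reach_end", seg.reach_end),
        ("grasp_onset", seg.grasp_onset),
        ("grasp_end", seg.grasp_end),
    ):
        if not 0 <= idx < n:
            raise InvalidInputError(f"{name} outside curve range")
    ms_per_frame = 1000.0 / curves.sampling_rate

    open_sl = slice(seg.grasp_onset, seg.max_aperture_frame + 1)
    close_sl = slice(seg.max_aperture_frame, seg.grasp_end + 1)
    grasp_sl = slice(seg.grasp_onset, seg.grasp_end + 1)
    reach_sl = slice(seg.reach_onset, seg.reach_end + 1)
    for sl, what in ((open_sl, "opening"), (close_sl, "closing"), (reach_sl, "reach")):
        if sl.stop - sl.start < 2:
            raise DegeneratePhaseError(f"{what} window shorter than 2 frames")

    ga, vga, aga = curves.ga, curves.vel_ga, curves.acc_ga

    feats: dict[str, float] = {}
    feats["GRange"] = float(np.max(ga[grasp_sl]))
    feats["GTotDur"] = (seg.grasp_end - seg.grasp_onset) * ms_per_frame
    feats["GOpenDur"] = (seg.max_aperture_frame - seg.grasp_onset) * ms_per_frame
    feats["GCloseDur"] = (seg.grasp_end - seg.max_aperture_frame) * ms_per_frame
    feats["MeanGVel"] = float(np.mean(np.abs(vga[grasp_sl])))
    feats["GOpenPVel"] = float(np.max(vga[open_sl]))
    open_p_acc = float(np.max(aga[open_sl]))
    feats["GOpenPDec"] = float(abs(np.min(aga[open_sl])))
    feats["GClosePVel"] = float(abs(np.min(vga[close_sl])))
    # during closure vel_ga < 0: negative acc_ga speeds the closure,
    # positive acc_ga brakes it
    close_p_acc = float(abs(np.min(aga[close_sl])))
    feats["GClosePDec"] = float(np.max(aga[close_sl]))

    speed, acc = curves.speed_r, curves.acc_r
    start_pos = np.array(
        [curves.rx[seg.reach_onset], curves.ry[seg.reach_onset], curves.rz[seg.reach_onset]]
    )
    end_pos = np.array(
        [curves.rx[seg.reach_end], curves.ry[seg.reach_end], curves.rz[seg.reach_end]]
    )
    feats["RTotDur"] = (seg.reach_end - seg.reach_onset) * ms_per_frame
    feats["RAmplitude"] = float(np.linalg.norm(end_pos - start_pos))
    peak_idx = seg.reach_onset + int(np.argmax(speed[reach_sl]))
    feats["RPSpeed"] = float(speed[peak_idx])
    feats["RTimeToPSpeed"] = (peak_idx - seg.reach_onset) * ms_per_frame
    feats["RPAcc"] = float(np.max(acc[reach_sl]))
    feats["RPDec"] = float(abs(np.min(acc[reach_sl])))
    feats["RMeanSpeed"] = float(np.mean(speed[reach_sl]))

    feats["HandPos"] = float(
        0.5 * (curves.thumb_y[seg.contact_frame] + curves.index_y[seg.contact_frame])
    )

    if include_extras:
        feats["GOpenPAcc"] = open_p_acc
        feats["GClosePAcc"] = close_p_acc
    return feats


def analyze_trial(
    trial: MarkerTrial,
    sigma: float = DEFAULT_SIGMA,
    threshold: float = DEFAULT_THRESHOLD_MM,
    run_length: int = DEFAULT_RUN_FRAMES,
) -> tuple[KinematicCurves, PhaseSegmentation, dict[str, float]]:
    """Curves + segmentation + features for a trial, in one call."""
    curves = compute_curves(trial, sigma)
    seg = segment_trial(curves, threshold, run_length)
    return curves, seg, extract_features(curves, seg)
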