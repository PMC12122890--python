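"""Synthetic data with known ground truth for every pipeline stage.

Three generators:

* ``gen_kinematic_trials`` — 3-marker (wrist, thumb, index) reach-to-grasp
  trajectories at 120 Hz in mm.  The wrist follows a minimum-jerk path (the
  standard model of point-to-point transport, producing the bell-shaped
  speed profile of natural reaching); grip aperture opens along a raised
  cosine to a maximum and closes onto the object.  PASS and PLACE goals
  differ by configurable multiplicative effects on the planned movement
  parameters (duration, amplitude, maximum aperture, contact height).
* ``gen_observer_responses`` — simulated observers who weigh standardized
  kinematic features into a noisy evidence variable, answer PASS/PLACE
  against a criterion, rate confidence from the evidence magnitude and
  produce log-normally jittered reaction times.  Negating the weights turns
  a "good" decoder into a "counter" decoder; zero weights give chance.
* ``gen_gaze_stream`` — gaze samples alternating noisy fixation clusters on
  dynamic area-of-interest reference points with brief saccadic ramps.

Every generator is a pure function of its config's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import kinematics as kin
from .errors import InvalidConfigError, InvalidInputError, SchemaError

GOALS = ("PASS", "PLACE")
AOI_NAMES = ("Face", "Hand", "Arm")


# --------------------------------------------------------------------------
# kinematic trials
# --------------------------------------------------------------------------

#: default PASS-vs-PLACE multiplicative effects on planned parameters:
#: passing takes longer, is slightly smaller in amplitude and aperture
#: (hence slower at peak), and grasps the object lower.
DEFAULT_GOAL_EFFECTS = {
    "RTotDur": 1.15,
    "RAmplitude": 0.95,
    "GRange": 0.95,
    "HandPos": 0.75,
}

_PLAN_KEYS = ("RTotDur", "RAmplitude", "GRange", "HandPos")


@dataclass(frozen=True)
class KinConfig:
    """Configuration of the kinematic-trial generator.

    ``reach_distance`` is the planned start-to-object wrist displacement for
    PLACE trials (mm); ``object_width`` the grasped dimension of the block
    (53 mm); ``goal_effects`` maps canonical parameter names to PASS/PLACE
    multiplicative ratios; ``noise_sd`` is i.i.d. Gaussian marker noise per
    axis per frame (half the 0.3 mm spatial resolution by default).
    """

    sampling_rate: float = 120.0
    reach_distance: float = 335.0
    object_width: float = 53.0
    goal_effects: dict = field(default_factory=lambda: dict(DEFAULT_GOAL_EFFECTS))
    noise_sd: float = 0.15
    seed: int = 0
    n_agents: int = 8
    base_reach_ms: float = 650.0
    base_contact_height: float = 55.0
    aperture_margin: float = 25.0
    lead_in_ms: float = 250.0
    hold_ms: float = 250.0
    trial_jitter_sd: float = 0.07
    agent_jitter_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise InvalidConfigError("sampling_rate must be positive")
        if self.reach_distance <= 0 or self.object_width <= 0:
            raise InvalidConfigError("geometry must be positive")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")
        bad = set(self.goal_effects) - set(_PLAN_KEYS)
        if bad:
            raise InvalidConfigError(
                f"goal_effects keyed by unknown parameters: {sorted(bad)}"
            )
        if self.n_agents < 1:
            raise InvalidConfigError("n_agents must be >= 1")


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk position profile on [0, 1]."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _raised_cosine(s: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(s, 0.0, 1.0)))


@dataclass(frozen=True)
class TrialTruth:
    """Noise-free ground truth for one generated trial."""

    trial_id: str
    plan: dict[str, float]
    segmentation: kin.PhaseSegmentation
    features: dict[str, float]
    labels: dict


def _build_trial(
    trial_id: str,
    cfg: KinConfig,
    plan: dict[str, float],
    labels: dict,
    rng: np.random.Generator,
) -> tuple[kin.MarkerTrial, TrialTruth]:
    fs = cfg.sampling_rate
    dt_ms = 1000.0 / fs
    reach_ms = plan["RTotDur"]
    n_lead = int(round(cfg.lead_in_ms / dt_ms))
    n_reach = max(int(round(reach_ms / dt_ms)), 8)
    n_hold = int(round(cfg.hold_ms / dt_ms))
    n = n_lead + n_reach + n_hold + 1
    t = np.arange(n)

    # wrist transport: minimum jerk from the start posture to the object
    start = np.array([0.0, 40.0, 0.0])
    wrist_end_y = plan["HandPos"] + 5.0  # wrist rides slightly above the grip
    horiz = np.array([-0.45, 0.0, 0.89])
    horiz /= np.linalg.norm(horiz)
    dy = wrist_end_y - start[1]
    d_horiz = np.sqrt(max(plan["RAmplitude"] ** 2 - dy**2, 1.0))
    target = start + horiz * d_horiz + np.array([0.0, dy, 0.0])

    tau = np.zeros(n)
    move = (t >= n_lead) & (t <= n_lead + n_reach)
    tau[move] = (t[move] - n_lead) / n_reach
    tau[t > n_lead + n_reach] = 1.0
    wrist = start[None, :] + _min_jerk(tau)[:, None] * (target - start)[None, :]

    # grip aperture: open with a raised cosine to the planned maximum,
    # close onto the object, then hold (the contact plateau)
    a0, a_max, a_contact = 12.0, plan["GRange"], cfg.object_width
    f_go = n_lead + 0.10 * n_reach
    f_max = n_lead + 0.65 * n_reach
    f_contact = n_lead + n_reach
    ap = np.full(n, a0)
    opening = (t >= f_go) & (t < f_max)
    ap[opening] = a0 + (a_max - a0) * _raised_cosine((t[opening] - f_go) / (f_max - f_go))
    closing = (t >= f_max) & (t < f_contact)
    ap[closing] = a_max - (a_max - a_contact) * _raised_cosine(
        (t[closing] - f_max) / (f_contact - f_max)
    )
    ap[t >= f_contact] = a_contact

    # fingers straddle a point ahead of and below the wrist; the grip axis
    # has a lateral orientation so thumb and index share the same height
    mid = wrist + np.array([0.0, -5.0, 60.0])[None, :]
    sep = np.array([0.94, 0.0, -0.34])
    thumb = mid - 0.5 * ap[:, None] * sep
    index = mid + 0.5 * ap[:, None] * sep

    clean = kin.MarkerTrial(
        trial_id=trial_id,
        sampling_rate=fs,
        wrist=wrist,
        thumb=thumb,
        index=index,
        labels=dict(labels),
    )
    _, seg, feats = kin.analyze_trial(clean)
    truth = TrialTruth(
        trial_id=trial_id,
        plan=dict(plan),
        segmentation=seg,
        features=feats,
        labels=dict(labels),
    )

    noisy = kin.MarkerTrial(
        trial_id=trial_id,
        sampling_rate=fs,
        wrist=wrist + rng.normal(0.0, cfg.noise_sd, size=wrist.shape),
        thumb=thumb + rng.normal(0.0, cfg.noise_sd, size=thumb.shape),
        index=index + rng.normal(0.0, cfg.noise_sd, size=index.shape),
        labels=dict(labels),
    )
    return noisy, truth


def gen_kinematic_trials(
    config: KinConfig, n_per_condition: int
) -> tuple[list[kin.MarkerTrial], list[TrialTruth]]:
    """Generate ``n_per_condition`` trials per goal per agent.

    Ground truth (``TrialTruth``) carries the planned movement parameters,
    plus the segmentation and the 17 features obtained from the noise-free
    trajectory — i.e. what a perfect measurement of the clean signal yields.
    """
    if n_per_condition < 1:
        raise InvalidConfigError("n_per_condition must be >= 1")
    rng = np.random.default_rng(config.seed)

    base_plan = {
        "RTotDur": config.base_reach_ms,
        "RAmplitude": config.reach_distance,
        "GRange": config.object_width + config.aperture_margin,
        "HandPos": config.base_contact_height,
    }
    agent_mult = {
        a: {k: float(np.exp(rng.normal(0.0, config.agent_jitter_sd))) for k in _PLAN_KEYS}
        for a in range(config.n_agents)
    }

    trials: list[kin.MarkerTrial] = []
    truths: list[TrialTruth] = []
    i = 0
    for agent in range(config.n_agents):
        gender = "F" if agent % 2 else "M"
        for goal in GOALS:
            for rep in range(n_per_condition):
                plan = {}
                for k in _PLAN_KEYS:
                    v = base_plan[k] * agent_mult[agent][k]
                    if goal == "PASS":
                        v *= config.goal_effects.get(k, 1.0)
                    v *= float(np.exp(rng.normal(0.0, config.trial_jitter_sd)))
                    plan[k] = v
                labels = {
                    "goal": goal,
                    "context": "social" if goal == "PASS" else ("alone", "social")[rep % 2],
                    "agent": f"A{agent:02d}",
                    "gender": gender,
                }
                trial, truth = _build_trial(f"T{i:04d}", config, plan, labels, rng)
                trials.append(trial)
                truths.append(truth)
                i += 1
    return trials, truths


def features_table(truths: list[TrialTruth], source: str = "features") -> pd.DataFrame:
    """Tabulate ground-truth features (or plans) with trial labels."""
    rows = []
    for tr in truths:
        row = {"trial_id": tr.trial_id, **tr.labels}
        row.update(tr.plan if source == "plan" else tr.features)
        rows.append(row)
    return pd.DataFrame(rows)


def trials_to_marker_frame(trials: list[kin.MarkerTrial]) -> pd.DataFrame:
    """Long-format marker table (one row per trial x frame x marker)."""
    parts = []
    for tr in trials:
        nf = tr.n_frames
        t_ms = np.arange(nf) * 1000.0 / tr.sampling_rate
        for marker, arr in (("wrist", tr.wrist), ("thumb", tr.thumb), ("index", tr.index)):
            parts.append(
                pd.DataFrame(
                    {
                        "trial_id": tr.trial_id,
                        "frame": np.arange(nf),
                        "t_ms": t_ms,
                        "marker": marker,
                        "x_mm": arr[:, 0],
                        "y_mm": arr[:, 1],
                        "z_mm": arr[:, 2],
                        "goal": tr.labels.get("goal"),
                        "context": tr.labels.get("context"),
                        "agent": tr.labels.get("agent"),
                        "gender": tr.labels.get("gender"),
                    }
                )
            )
    return pd.concat(parts, ignore_index=True)


def marker_frame_to_trials(df: pd.DataFrame, sampling_rate: float = 120.0) -> list[kin.MarkerTrial]:
    """Rebuild MarkerTrial objects from the long CSV dialect."""
    required = {"trial_id", "frame", "marker", "x_mm", "y_mm", "z_mm"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"marker table missing columns: {sorted(missing)}")
    out = []
    for tid, g in df.groupby("trial_id", sort=True):
        arrs = {}
        for marker, gm in g.groupby("marker"):
            gm = gm.sort_values("frame")
            arrs[marker] = gm[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
        labels = {
            k: g[k].iloc[0]
            for k in ("goal", "context", "agent", "gender")
            if k in g.columns
        }
        out.append(
            kin.MarkerTrial(
                trial_id=str(tid),
                sampling_rate=sampling_rate,
                wrist=arrs["wrist"],
                thumb=arrs["thumb"],
                index=arrs["index"],
                labels=labels,
            )
        )
    return out


# --------------------------------------------------------------------------
# observer responses
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ObserverProfile:
    """A simulated observer mapping kinematic evidence to responses.

    ``weights`` combine standardized features into a scalar evidence value;
    the decision variable adds unit-scaled internal noise and is compared to
    ``criterion``.  Confidence ratings 1-4 come from the decision variable's
    magnitude against three ascending cuts; RT decreases linearly with that
    magnitude (``rt_slope`` < 0) and carries log-normal noise so it stays
    positive.
    """

    weights: dict[str, float]
    criterion: float = 0.0
    confidence_cuts: tuple[float, float, float] = (0.5, 1.0, 1.5)
    rt_base: float = 900.0
    rt_slope: float = -120.0
    noise_sd: float = 1.0
    rt_noise_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        cuts = tuple(self.confidence_cuts)
        if len(cuts) != 3 or not (cuts[0] < cuts[1] < cuts[2]):
            raise InvalidConfigError("confidence_cuts must be 3 strictly ascending values")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")

    def negated(self, seed: int | None = None) -> "ObserverProfile":
        """The weight-negation of this profile (a 'counter' observer)."""
        return replace(
            self,
            weights={k: -v for k, v in self.weights.items()},
            seed=self.seed if seed is None else seed,
        )

    @classmethod
    def chance(cls, seed: int = 0, **kw) -> "ObserverProfile":
        return cls(weights={}, seed=seed, **kw)


def gen_observer_responses(
    features: pd.DataFrame,
    profile: ObserverProfile,
    participant_id: str = "P00",
) -> pd.DataFrame:
    """Simulate one observer's responses to a stimulus feature table.

    ``features`` needs a ``goal`` column plus every feature named in the
    profile's weights; features are z-scored across the given stimuli so the
    weights act on comparable scales.
    """
    if "goal" not in features.columns:
        raise SchemaError("features table needs a 'goal' column")
    missing = set(profile.weights) - set(features.columns)
    if missing:
        raise SchemaError(f"weights refer to absent features: {sorted(missing)}")
    n = len(features)
    rng = np.random.default_rng(profile.seed)

    evidence = np.zeros(n)
    for name, w in profile.weights.items():
        col = features[name].to_numpy(float)
        sd = col.std(ddof=0)
        z = (col - col.mean()) / sd if sd > 0 else np.zeros(n)
        evidence += w * z

    dv = evidence + rng.normal(0.0, profile.noise_sd, size=n)
    choice = np.where(dv > profile.criterion, "PASS", "PLACE")
    strength = np.abs(dv - profile.criterion)
    confidence = 1 + np.searchsorted(np.asarray(profile.confidence_cuts), strength)
    rt = (
        profile.rt_base
        + profile.rt_slope * strength
        + profile.rt_base * (np.exp(rng.normal(0.0, profile.rt_noise_sigma, size=n)) - 1.0) * 0.2
    )
    rt = np.maximum(rt, 1.0)

    if "perspective" in features.columns:
        persp = features["perspective"].to_numpy()
    else:
        persp = np.where(np.arange(n) % 2 == 0, "2nd", "3rd")

    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "trial_id": features["trial_id"].to_numpy()
            if "trial_id" in features.columns
            else [f"T{i:04d}" for i in range(n)],
            "true_goal": features["goal"].to_numpy(),
            "perspective": persp,
            "choice": choice,
            "confidence": confidence.astype(int),
            "rt_ms": rt,
        }
    )


# --------------------------------------------------------------------------
# gaze streams
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GazeConfig:
    """Configuration of the synthetic gaze generator.

    ``aoi_allocation`` maps a condition name to a probability vector over
    (Face, Hand, Arm, background); fixation durations are drawn uniformly
    from ``fixation_duration_range`` (ms); successive fixations are joined by
    linear saccadic ramps of ``saccade_duration`` ms; sample noise is
    isotropic Gaussian in pixels.
    """

    sampling_rate: float = 120.0
    aoi_allocation: dict = field(
        default_factory=lambda: {"default": (0.6, 0.2, 0.1, 0.1)}
    )
    fixation_duration_range: tuple[float, float] = (150.0, 400.0)
    saccade_duration: float = 40.0
    noise_sd: float = 3.0
    frame_size: tuple[float, float] = (1920.0, 1080.0)
    fixation_scatter_px: float = 15.0
    min_refixation_px: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        for cond, p in self.aoi_allocation.items():
            p = np.asarray(p, float)
            if p.size != 4 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise InvalidConfigError(
                    f"allocation for {cond!r} must be 4 non-negative probs summing to 1"
                )
        lo, hi = self.fixation_duration_range
        if not (0 < lo <= hi):
            raise InvalidConfigError("fixation durations must be positive")
        if self.saccade_duration <= 0 or self.sampling_rate <= 0:
            raise InvalidConfigError("rates and durations must be positive")


def make_aoi_timeline(
    n_frames: int,
    frame_rate: float = 120.0,
    frame_size: tuple[float, float] = (1920.0, 1080.0),
) -> pd.DataFrame:
    """A plausible dynamic AOI reference-point timeline for one trial.

    The face stays near the top of the actor; the hand travels along the
    reach; the arm (elbow) follows the hand at half amplitude.
    """
    if n_frames < 1:
        raise InvalidInputError("timeline needs at least one frame")
    w, h = frame_size
    f = np.arange(n_frames)
    prog = f / max(n_frames - 1, 1)
    rows = []
    face = np.column_stack([np.full(n_frames, 0.62 * w), np.full(n_frames, 0.25 * h)])
    hand = np.column_stack(
        [0.62 * w - 0.25 * w * prog, 0.70 * h - 0.12 * h * np.sin(np.pi * prog)]
    )
    arm = np.column_stack([0.62 * w - 0.12 * w * prog, 0.58 * h + 0.05 * h * prog])
    for name, xy in (("Face", face), ("Hand", hand), ("Arm", arm)):
        rows.append(
            pd.DataFrame(
                {"frame": f, "aoi": name, "ref_x": xy[:, 0], "ref_y": xy[:, 1]}
            )
        )
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class PlannedFixation:
    start_ms: float
    end_ms: float
    x: float
    y: float
    aoi: str


def gen_gaze_stream(
    trial_timeline: pd.DataFrame,
    config: GazeConfig,
    condition: str = "default",
    frame_rate: float = 120.0,
) -> tuple[pd.DataFrame, list[PlannedFixation]]:
    """Synthesise one trial's gaze samples over a dynamic-AOI timeline.

    Returns ``(samples, truth)`` where samples has columns t_ms, x_px, y_px,
    valid, and truth lists each planted fixation's interval, centre and AOI.
    """
    if trial_timeline is None or len(trial_timeline) == 0:
        raise InvalidInputError("trial timeline is empty")
    rng = np.random.default_rng(config.seed)
    alloc = np.asarray(
        config.aoi_allocation.get(condition, config.aoi_allocation["default"]), float
    )
    n_frames = int(trial_timeline["frame"].max()) + 1
    total_ms = n_frames * 1000.0 / frame_rate

    refs = {
        name: g.sort_values("frame")[["ref_x", "ref_y"]].to_numpy(float)
        for name, g in trial_timeline.groupby("aoi")
    }
    w, h = config.frame_size

    # plan fixations back to back with saccade gaps until the trial ends;
    # successive fixations keep a minimum separation so each re-fixation is
    # a genuine, detectable gaze shift even within the same AOI
    plans: list[PlannedFixation] = []
    t = 0.0
    lo, hi = config.fixation_duration_range
    prev_xy: tuple[float, float] | None = None
    while total_ms - t >= 100.0:  # no ground-truth stubs too brief to count
        dur = float(rng.uniform(lo, hi))
        end = min(t + dur, total_ms)
        choice = int(rng.choice(4, p=alloc))
        mid_frame = min(int((t + end) / 2 * frame_rate / 1000.0), n_frames - 1)
        for _ in range(30):
            if choice < 3:
                aoi = AOI_NAMES[choice]
                bx, by = refs[aoi][mid_frame]
                x = bx + rng.normal(0, config.fixation_scatter_px)
                y = by + rng.normal(0, config.fixation_scatter_px)
            else:
                aoi = "background"
                x = rng.uniform(0.05 * w, 0.35 * w)
                y = rng.uniform(0.1 * h, 0.9 * h)
            if prev_xy is None or np.hypot(
                x - prev_xy[0], y - prev_xy[1]
            ) >= config.min_refixation_px:
                break
        plans.append(PlannedFixation(t, end, float(x), float(y), aoi))
        prev_xy = (float(x), float(y))
        t = end + config.saccade_duration

    dt = 1000.0 / config.sampling_rate
    t_ms = np.arange(0.0, total_ms, dt)
    x = np.empty_like(t_ms)
    y = np.empty_like(t_ms)
    for i, ti in enumerate(t_ms):
        k = np.searchsorted([p.end_ms for p in plans], ti)
        k = min(k, len(plans) - 1)
        p = plans[k]
        if ti >= p.start_ms or k == 0:
            x[i], y[i] = p.x, p.y
        else:  # saccadic ramp between fixation k-1 and k
            prev = plans[k - 1]
            s = (ti - prev.end_ms) / (p.start_ms - prev.end_ms)
            x[i] = prev.x + s * (p.x - prev.x)
            y[i] = prev.y + s * (p.y - prev.y)
    x += rng.normal(0.0, config.noise_sd, size=x.shape)
    y += rng.normal(0.0, config.noise_sd, size=y.shape)

    samples = pd.DataFrame(
        {"t_ms": t_ms, "x_px": x, "y_px": y, "valid": True}
    )
    return samples, plans
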