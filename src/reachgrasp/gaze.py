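"""Fixation detection by two-means clustering and dynamic-AOI assignment.

Fixations are identified with a sliding-window two-means procedure robust to
noisy head-mounted eye-tracking data: within each window the gaze samples
are split into two clusters in (x, y); samples at cluster transitions
receive a weight normalized by the number of transitions in the window
(isolated, sharp transitions weigh heavily; jitter-induced ones weigh
little).  Samples whose averaged weight exceeds mean + k*SD mark saccadic
boundaries, inter-boundary runs of sufficient duration become fixations,
and nearby fixations are merged.

Areas of interest (Face, Hand, Arm) are axis-aligned rectangles rebuilt on
every video frame around moving reference points (head centre, fingertips,
elbow), so a fixation is assigned to the AOI that contains its centroid in
the majority of the frames it spans; ties or containment in no AOI fall to
background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, MissingReferenceError, NoDataError

AOI_NAMES = ("Face", "Hand", "Arm")

#: AOI half-extent defaults as fractions of the frame height, used when no
#: measured stimulus dimensions are supplied
DEFAULT_AOI_SIZE_FRAC = {
    "Face": (0.18, 0.18),
    "Hand": (0.12, 0.12),
    "Arm": (0.12, 0.30),
}

#: assignment precedence when rectangles overlap at a centroid
DEFAULT_PRECEDENCE = ("Hand", "Face", "Arm")


@dataclass(frozen=True)
class Fixation:
    start_ms: float
    end_ms: float
    x: float
    y: float
    n_samples: int

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


def _two_means(xy: np.ndarray, max_iter: int = 25) -> np.ndarray:
    """Deterministic 2-means labels: centres start at the two samples
    farthest apart, then standard Lloyd iterations."""
    n = xy.shape[0]
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    centres = xy[[i, j]].astype(float)
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        dist = ((xy[:, None, :] - centres[None, :, :]) ** 2).sum(-1)
        new = np.argmin(dist, axis=1)
        if np.array_equal(new, labels) and _ > 0:
            break
        labels = new
        for k in (0, 1):
            if (labels == k).any():
                centres[k] = xy[labels == k].mean(axis=0)
    return labels


def detect_fixations(
    samples: pd.DataFrame,
    window_ms: float = 200.0,
    step_ms: float = 20.0,
    weight_cutoff_sd: float = 2.0,
    min_fix_ms: float = 40.0,
    merge_gap_ms: float = 30.0,
    merge_dist_px: float = 30.0,
    max_dispersion_px: float = 35.0,
) -> list[Fixation]:
    """Two-means-clustering fixation detection on one trial's gaze stream.

    ``samples`` needs columns t_ms, x_px, y_px and optionally valid.  Any
    sampling rate is accepted; windowing is done in sample counts derived
    from the stream's median sampling interval.  Candidate runs whose median
    distance from their median centre exceeds ``max_dispersion_px`` are
    treated as drift/pursuit rather than fixation and discarded (the median
    keeps stray saccade-edge samples from disqualifying a true fixation).
    """
    df = samples
    if "valid" in df.columns:
        df = df[df["valid"].astype(bool)]
    if len(df) == 0:
        raise NoDataError("no valid gaze samples")
    t = df["t_ms"].to_numpy(float)
    xy = df[["x_px", "y_px"]].to_numpy(float)
    n = t.size
    dt = float(np.median(np.diff(t))) if n > 1 else window_ms
    win = max(int(round(window_ms / dt)), 4)
    step = max(int(round(step_ms / dt)), 1)
    if n < win:
        win = n

    wsum = np.zeros(n)
    wcnt = np.zeros(n)
    for start in range(0, n - win + 1, step):
        sl = slice(start, start + win)
        labels = _two_means(xy[sl])
        switches = np.flatnonzero(np.diff(labels) != 0) + 1  # local indices
        wcnt[sl] += 1
        if switches.size:
            wsum[start + switches] += 1.0 / switches.size
    seen = wcnt > 0
    weights = np.zeros(n)
    weights[seen] = wsum[seen] / wcnt[seen]
    cutoff = weights[seen].mean() + weight_cutoff_sd * weights[seen].std(ddof=0)
    boundary = weights > cutoff

    fixations: list[Fixation] = []
    run_start = None
    for i in range(n + 1):
        inside = i < n and not boundary[i]
        if inside and run_start is None:
            run_start = i
        elif not inside and run_start is not None:
            lo, hi = run_start, i - 1
            seg = xy[lo : hi + 1]
            centre = np.median(seg, axis=0)
            disp_med = float(np.median(np.hypot(*(seg - centre).T)))
            if t[hi] - t[lo] >= min_fix_ms and disp_med <= max_dispersion_px:
                fixations.append(
                    Fixation(
                        start_ms=float(t[lo]),
                        end_ms=float(t[hi]),
                        x=float(xy[lo : hi + 1, 0].mean()),
                        y=float(xy[lo : hi + 1, 1].mean()),
                        n_samples=hi - lo + 1,
                    )
                )
            run_start = None

    merged: list[Fixation] = []
    for f in fixations:
        if merged:
            prev = merged[-1]
            gap = f.start_ms - prev.end_ms
            dist = float(np.hypot(f.x - prev.x, f.y - prev.y))
            if gap <= merge_gap_ms and dist <= merge_dist_px:
                ntot = prev.n_samples + f.n_samples
                merged[-1] = Fixation(
                    start_ms=prev.start_ms,
                    end_ms=f.end_ms,
                    x=(prev.x * prev.n_samples + f.x * f.n_samples) / ntot,
                    y=(prev.y * prev.n_samples + f.y * f.n_samples) / ntot,
                    n_samples=ntot,
                )
                continue
        merged.append(f)
    return merged


@dataclass(frozen=True)
class AoiSet:
    """Per-frame axis-aligned AOI rectangles over the analysis epoch."""

    rects: pd.DataFrame  # columns frame, aoi, cx, cy, w, h
    frame_rate: float

    @property
    def frames(self) -> np.ndarray:
        return np.sort(self.rects["frame"].unique())


def build_aois(
    timeline: pd.DataFrame,
    sizes: dict[str, tuple[float, float]] | None = None,
    frame_height: float = 1080.0,
    frame_rate: float = 120.0,
) -> AoiSet:
    """Rectangular AOIs centred on per-frame reference points.

    ``timeline`` has columns frame, aoi, ref_x, ref_y; single-frame gaps in
    a reference track are linearly interpolated.  ``sizes`` maps AOI name to
    (width, height) in px; defaults are fractions of the frame height (to be
    replaced by measured stimulus dimensions on real data).
    """
    if sizes is None:
        sizes = {
            k: (fw * frame_height, fh * frame_height)
            for k, (fw, fh) in DEFAULT_AOI_SIZE_FRAC.items()
        }
    present = set(timeline["aoi"].unique())
    missing = set(AOI_NAMES) - present
    if missing:
        raise MissingReferenceError(f"missing AOI tracks: {sorted(missing)}")
    frames = np.arange(int(timeline["frame"].min()), int(timeline["frame"].max()) + 1)
    rows = []
    for aoi, grp in timeline.groupby("aoi"):
        g = grp.set_index("frame").reindex(frames)
        g[["ref_x", "ref_y"]] = g[["ref_x", "ref_y"]].interpolate(limit=1, limit_area="inside")
        if g[["ref_x", "ref_y"]].isna().any().any():
            raise MissingReferenceError(f"AOI {aoi!r} track has multi-frame gaps")
        w, h = sizes[aoi]
        rows.append(
            pd.DataFrame(
                {
                    "frame": frames,
                    "aoi": aoi,
                    "cx": g["ref_x"].to_numpy(),
                    "cy": g["ref_y"].to_numpy(),
                    "w": w,
                    "h": h,
                }
            )
        )
    return AoiSet(rects=pd.concat(rows, ignore_index=True), frame_rate=frame_rate)


def _aoi_at(
    aois_by_frame: dict[int, list[tuple[str, float, float, float, float]]],
    frame: int,
    x: float,
    y: float,
    precedence: tuple[str, ...],
) -> str:
    rects = aois_by_frame.get(frame)
    if not rects:
        return "background"
    hits = [
        name
        for name, cx, cy, w, h in rects
        if abs(x - cx) <= w / 2 and abs(y - cy) <= h / 2
    ]
    for name in precedence:
        if name in hits:
            return name
    return "background"


def assign_fixations(
    fixations: list[Fixation],
    aois: AoiSet,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> pd.DataFrame:
    """Assign each fixation to the AOI containing its centroid in the
    majority of its spanned frames.

    Fixation spans are clipped to the AOI frame range; ties and containment
    in no AOI go to background.  Returns one row per fixation with its
    assignment; aggregate with :func:`aoi_summary`.
    """
    lookup: dict[int, list] = {}
    for row in aois.rects.itertuples(index=False):
        lookup.setdefault(int(row.frame), []).append(
            (row.aoi, row.cx, row.cy, row.w, row.h)
        )
    frames = aois.frames
    f_lo, f_hi = int(frames.min()), int(frames.max())
    fr = aois.frame_rate

    rows = []
    for fix in fixations:
        lo = int(np.floor(fix.start_ms * fr / 1000.0))
        hi = int(np.ceil(fix.end_ms * fr / 1000.0))
        lo, hi = max(lo, f_lo), min(hi, f_hi)
        tally: dict[str, int] = {}
        for f in range(lo, hi + 1):
            name = _aoi_at(lookup, f, fix.x, fix.y, precedence)
            tally[name] = tally.get(name, 0) + 1
        if tally:
            best = max(tally.values())
            winners = [k for k, v in tally.items() if v == best]
            assigned = winners[0] if len(winners) == 1 else "background"
        else:
            assigned = "background"
        rows.append(
            {
                "start_ms": fix.start_ms,
                "end_ms": fix.end_ms,
                "duration_ms": fix.duration_ms,
                "x": fix.x,
                "y": fix.y,
                "aoi": assigned,
            }
        )
    return pd.DataFrame(
        rows, columns=["start_ms", "end_ms", "duration_ms", "x", "y", "aoi"]
    )


def aoi_summary(assignments: pd.DataFrame) -> pd.DataFrame:
    """Fixation counts and total dwell time per AOI (background included)."""
    cats = list(AOI_NAMES) + ["background"]
    if len(assignments) == 0:
        return pd.DataFrame({"aoi": cats, "count": 0, "dwell_ms": 0.0})
    g = assignments.groupby("aoi")
    out = pd.DataFrame(
        {
            "aoi": cats,
            "count": [int(g.size().get(c, 0)) for c in cats],
            "dwell_ms": [float(g["duration_ms"].sum().get(c, 0.0)) for c in cats],
        }
    )
    return out
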