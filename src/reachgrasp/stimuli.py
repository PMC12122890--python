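"""Stimulus selection: PCA on time-normalized kinematic curves and the
asymmetric SD-window filter for representative PASS/PLACE exemplars.

Each trial's eight curves (GA, VelGA, AccGA, Rx, Ry, Rz, SpeedR, AccR) are
linearly resampled over the movement window to a common length, z-scored
column-wise per curve block, concatenated and fed to a PCA.  Curve-level
loadings summarise which curve dominates each component.  Selection then
keys on the parameters tied to the first two components — grasp range of
motion (GRoM, the GRange feature) and peak reaching speed (RPSpeed) — with
asymmetric windows around each goal's own mean: PLACE keeps trials within
[-0.5, +1] SD, PASS within [-1, +0.5] SD, emphasising each intention's
characteristic direction (faster/larger for placing, the opposite for
passing) while allowing overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import (
    DegenerateInputError,
    DegeneratePhaseError,
    InvalidInputError,
    StratumError,
)
from .kinematics import CURVE_NAMES, KinematicCurves, PhaseSegmentation

DEFAULT_T = 101  # normalized time base, 0-100% of the movement


def time_normalize(
    curves: KinematicCurves, seg: PhaseSegmentation, T: int = DEFAULT_T
) -> dict[str, np.ndarray]:
    """Resample each curve linearly to T points over [reach_onset, grasp_end]."""
    if T < 8:
        raise InvalidInputError("T must be at least 8")
    lo, hi = seg.reach_onset, seg.grasp_end
    if hi - lo < 2:
        raise DegeneratePhaseError("movement window shorter than 2 frames")
    src = np.arange(lo, hi + 1, dtype=float)
    dst = np.linspace(lo, hi, T)
    return {
        name: np.interp(dst, src, curves.curve(name)[lo : hi + 1])
        for name in CURVE_NAMES
    }


@dataclass(frozen=True)
class CurveMatrix:
    """Trials x concatenated-normalized-curves matrix plus labels."""

    data: np.ndarray  # (n_trials, 8 * T), z-scored per column within blocks
    T: int
    trial_ids: list[str]
    labels: pd.DataFrame


def build_curve_matrix(
    per_trial: list[tuple[KinematicCurves, PhaseSegmentation]],
    labels: pd.DataFrame | None = None,
    trial_ids: list[str] | None = None,
    T: int = DEFAULT_T,
) -> CurveMatrix:
    """Assemble the PCA input from per-trial curves and segmentations.

    Each curve block is z-scored column-wise (per normalized time point)
    before concatenation, so curves on different scales contribute evenly.
    """
    rows = []
    for curves, seg in per_trial:
        norm = time_normalize(curves, seg, T)
        rows.append(np.concatenate([norm[name] for name in CURVE_NAMES]))
    data = np.asarray(rows, float)
    out = np.empty_like(data)
    for b in range(len(CURVE_NAMES)):
        block = data[:, b * T : (b + 1) * T]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        out[:, b * T : (b + 1) * T] = (block - mu) / sd
    n = data.shape[0]
    return CurveMatrix(
        data=out,
        T=T,
        trial_ids=trial_ids or [f"T{i:04d}" for i in range(n)],
        labels=labels if labels is not None else pd.DataFrame(index=range(n)),
    )


@dataclass(frozen=True)
class PcaResult:
    """Per-curve loadings, per-trial coordinates and variance fractions."""

    curve_loadings: pd.DataFrame  # rows = curves, cols = PC1..PCk
    coordinates: np.ndarray  # (n_trials, k)
    variance_fractions: np.ndarray  # length k, non-increasing


def pca_curves(matrix: CurveMatrix, n_components: int = 3) -> PcaResult:
    """PCA over the concatenated curve matrix.

    The curve-level loading of a component is the summed absolute weight of
    that curve's block, normalized across curves, so the dominant curve per
    component is directly readable.
    """
    data = matrix.data
    if np.allclose(data, data[0:1, :]):
        raise DegenerateInputError("all-constant curve matrix")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(data)
    T = matrix.T
    rows = {}
    for b, name in enumerate(CURVE_NAMES):
        block = pca.components_[:, b * T : (b + 1) * T]
        rows[name] = np.abs(block).sum(axis=1)
    loadings = pd.DataFrame(
        rows, index=[f"PC{i + 1}" for i in range(n_components)]
    ).T
    loadings = loadings / loadings.sum(axis=0)
    return PcaResult(
        curve_loadings=loadings,
        coordinates=coords,
        variance_fractions=pca.explained_variance_ratio_.copy(),
    )


@dataclass(frozen=True)
class SelectionWindow:
    """Asymmetric z-score window for one parameter within one goal."""

    parameter: str
    lower_sd: float
    upper_sd: float

    def __post_init__(self) -> None:
        if not self.lower_sd < self.upper_sd:
            raise InvalidInputError("lower_sd must be below upper_sd")

    def contains(self, z: float) -> bool:
        return self.lower_sd <= z <= self.upper_sd


#: default windows: placing tolerates higher-than-mean values, passing lower
DEFAULT_WINDOWS: dict[str, dict[str, SelectionWindow]] = {
    "PLACE": {
        "GRange": SelectionWindow("GRange", -0.5, 1.0),
        "RPSpeed": SelectionWindow("RPSpeed", -0.5, 1.0),
    },
    "PASS": {
        "GRange": SelectionWindow("GRange", -1.0, 0.5),
        "RPSpeed": SelectionWindow("RPSpeed", -1.0, 0.5),
    },
}


def select_stimuli(
    features: pd.DataFrame,
    windows: dict[str, dict[str, SelectionWindow]] | None = None,
) -> pd.DataFrame:
    """Flag trials whose GRoM and RPSpeed z-scores (within their own goal)
    both fall inside that goal's window.

    Returns the feature table augmented with z_GRoM, z_RPSpeed and a boolean
    ``selected`` column.
    """
    windows = windows or DEFAULT_WINDOWS
    if "goal" not in features.columns:
        raise StratumError("features table needs a 'goal' column")
    out = features.copy()
    out["z_GRoM"] = np.nan
    out["z_RPSpeed"] = np.nan
    out["selected"] = False
    for goal, grp in features.groupby("goal"):
        if len(grp) < 2:
            raise StratumError(f"goal stratum {goal!r} needs >= 2 trials")
        for param, col in (("GRange", "z_GRoM"), ("RPSpeed", "z_RPSpeed")):
            v = grp[param].to_numpy(float)
            sd = v.std(ddof=1)
            z = (v - v.mean()) / sd if sd > 0 else np.zeros(len(v))
            out.loc[grp.index, col] = z
        win = windows[goal]
        sel = [
            win["GRange"].contains(zg) and win["RPSpeed"].contains(zr)
            for zg, zr in zip(out.loc[grp.index, "z_GRoM"], out.loc[grp.index, "z_RPSpeed"])
        ]
        out.loc[grp.index, "selected"] = sel
    return out


def pick_exemplars(
    selection: pd.DataFrame,
    n_per_cell: int = 3,
    group_cols: tuple[str, ...] = ("agent", "goal", "perspective"),
) -> pd.DataFrame:
    """The n most central survivors (smallest |z_GRoM| + |z_RPSpeed|) per
    agent x goal x perspective cell."""
    present = [c for c in group_cols if c in selection.columns]
    surv = selection[selection["selected"]].copy()
    surv["_centrality"] = surv["z_GRoM"].abs() + surv["z_RPSpeed"].abs()
    picked = (
        surv.sort_values("_centrality")
        .groupby(list(present), sort=True, group_keys=False)
        .head(n_per_cell)
        .drop(columns="_centrality")
    )
    return picked.sort_index()
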