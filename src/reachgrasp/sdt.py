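"""Confidence-rating ROC analysis of PASS/PLACE intention decoding.

PASS actions are the signal, PLACE the noise.  A binary choice crossed with
a 4-level confidence rating gives 8 ordered response categories, from
most-confident-PASS to most-confident-PLACE; sweeping a criterion across the
7 interior cut points yields the empirical ROC.  The area under that curve
(AUC, as a percentage) indexes each observer's decoding sensitivity:
observers at or above 55 are "good" decoders, below 45 "counter" decoders
(they discriminate the kinematics but systematically invert the intention
labels), and the band between is "chance".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    InsufficientDataError,
    InternalConsistencyError,
    InvalidInputError,
    UndefinedRateError,
)

SIGNAL = "PASS"
NOISE = "PLACE"

#: the 8 response categories from strictest to most lenient PASS criterion
RESPONSE_ORDER: tuple[tuple[str, int], ...] = (
    ("PASS", 4),
    ("PASS", 3),
    ("PASS", 2),
    ("PASS", 1),
    ("PLACE", 1),
    ("PLACE", 2),
    ("PLACE", 3),
    ("PLACE", 4),
)

GOOD_CUT = 55.0
COUNTER_CUT = 45.0


@dataclass(frozen=True)
class RocResult:
    """7 interior (false-alarm, hit) points, AUC (%) and decoder category."""

    points: np.ndarray  # shape (7, 2): columns (fa_rate, hit_rate)
    auc: float | None = None
    category: str | None = None


def empirical_roc(responses: pd.DataFrame) -> RocResult:
    """Empirical confidence-rating ROC for one participant's responses.

    Requires columns true_goal, choice, confidence; timeout trials (missing
    rt_ms) are excluded.  Returns the 7 interior cumulative-rate points; the
    (0,0) and (1,1) anchors are implicit.
    """
    df = responses
    if "rt_ms" in df.columns:
        df = df[df["rt_ms"].notna()]
    sig = df[df["true_goal"] == SIGNAL]
    noi = df[df["true_goal"] == NOISE]
    n_sig, n_noi = len(sig), len(noi)
    if n_sig == 0 or n_noi == 0:
        raise UndefinedRateError("need at least one PASS and one PLACE trial")

    def counts(sub: pd.DataFrame) -> np.ndarray:
        c = np.zeros(len(RESPONSE_ORDER))
        tab = sub.groupby(["choice", "confidence"]).size()
        for k, (choice, conf) in enumerate(RESPONSE_ORDER):
            c[k] = tab.get((choice, conf), 0)
        return c

    hit_cum = np.cumsum(counts(sig))[:-1] / n_sig
    fa_cum = np.cumsum(counts(noi))[:-1] / n_noi
    return RocResult(points=np.column_stack([fa_cum, hit_cum]))


def auc(roc: RocResult) -> float:
    """Trapezoidal area (in %) under the 9-point curve (anchors added)."""
    pts = np.asarray(roc.points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("roc points must be (k, 2)")
    fa = np.concatenate([[0.0], pts[:, 0], [1.0]])
    hit = np.concatenate([[0.0], pts[:, 1], [1.0]])
    if np.any(np.diff(fa) < -1e-12) or np.any(np.diff(hit) < -1e-12):
        raise InternalConsistencyError("cumulative ROC rates must be non-decreasing")
    return float(np.trapezoid(hit, fa) * 100.0)


def categorize_decoder(auc_pct: float) -> str:
    """'good' at or above 55, 'counter' below 45, 'chance' between."""
    if not 0.0 <= auc_pct <= 100.0:
        raise InvalidInputError("AUC must lie in [0, 100]")
    if auc_pct >= GOOD_CUT:
        return "good"
    if auc_pct < COUNTER_CUT:
        return "counter"
    return "chance"


def analyze_participant(responses: pd.DataFrame) -> RocResult:
    """ROC points, AUC and category for one participant in one call."""
    roc = empirical_roc(responses)
    a = auc(roc)
    return RocResult(points=roc.points, auc=a, category=categorize_decoder(a))


@dataclass(frozen=True)
class GroupAucSummary:
    mean: float
    t: float
    df: int
    p: float
    ci_low: float
    ci_high: float
    counts: dict[str, int]
    sd_zero: bool = False


def group_auc_summary(aucs: list[float], chance: float = 50.0) -> GroupAucSummary:
    """One-sample t test of participant AUCs against chance, 95% CI, and
    decoder-category counts."""
    a = np.asarray(aucs, float)
    if a.size < 2:
        raise InsufficientDataError("need at least 2 AUC values")
    counts = {"good": 0, "chance": 0, "counter": 0}
    for v in a:
        counts[categorize_decoder(v)] += 1
    sd = a.std(ddof=1)
    n = a.size
    if sd == 0:
        return GroupAucSummary(
            mean=float(a.mean()), t=0.0, df=n - 1, p=1.0,
            ci_low=float(a.mean()), ci_high=float(a.mean()),
            counts=counts, sd_zero=True,
        )
    t, p = sps.ttest_1samp(a, chance)
    half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return GroupAucSummary(
        mean=float(a.mean()),
        t=float(t),
        df=n - 1,
        p=float(p),
        ci_low=float(a.mean() - half),
        ci_high=float(a.mean() + half),
        counts=counts,
    )
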