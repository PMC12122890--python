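"""Statistical procedures around the delegated linear-mixed-model fit.

The mixed-model optimiser itself is statsmodels' MixedLM (ML fits, so AIC
and likelihood-ratio comparisons across random structures are coherent);
this module owns the procedures built on top of it:

* reaction-time filtering (correct responses, 150 ms physical-feasibility
  floor),
* Complex Random Intercept (CRI) structure selection — start from the
  participant intercept plus a participant x within-factor intercept for
  every within-group fixed effect, and simplify iteratively on convergence
  or singularity failure, dropping the interaction intercept with the
  smallest variance component first,
* Nakagawa marginal/conditional R-squared from the fit's variance
  components,
* Bonferroni-corrected alpha for a family of m tests,
* Cook's-distance screening of influential observations (4/n cutoff by
  default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, NoModelError

RT_FLOOR_MS = 150.0


def filter_rts(responses: pd.DataFrame, floor: float = RT_FLOOR_MS) -> pd.DataFrame:
    """RT analysis set: correct responses with rt >= floor (150 ms default).

    Correctness is choice == true_goal; rows with missing RT (timeouts) are
    dropped.  The boundary value itself is retained ("minimum duration").
    """
    df = responses
    keep = (
        (df["choice"] == df["true_goal"])
        & df["rt_ms"].notna()
        & (df["rt_ms"] >= floor)
    )
    return df[keep]


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response, fixed effects and CRI random-term candidates.

    ``within_factors`` are the within-participant fixed factors each of which
    contributes a candidate participant x factor random intercept; the plain
    participant intercept is always present and never dropped.
    """

    response: str
    fixed_effects: tuple[str, ...]
    group: str = "participant_id"
    within_factors: tuple[str, ...] = ()

    def full_structure(self) -> tuple[str, ...]:
        terms = [f"1|{self.group}"]
        terms += [f"1|{self.group}:{f}" for f in self.within_factors]
        if len(set(terms)) != len(terms):
            raise InvalidInputError("duplicate random terms")
        return tuple(terms)


@dataclass(frozen=True)
class FitReport:
    """Delegated-fitter output: flags, information criteria and variances."""

    structure: tuple[str, ...]
    converged: bool
    singular: bool
    loglik: float
    aic: float
    var_fixed: float
    var_random: dict[str, float]  # keyed by random term
    var_resid: float
    coef: pd.DataFrame | None = None

    @property
    def clean(self) -> bool:
        return self.converged and not self.singular


Fitter = Callable[[tuple[str, ...]], FitReport]


def make_mixedlm_fitter(
    data: pd.DataFrame,
    spec: ModelSpec,
    singular_tol: float = 1e-4,
) -> Fitter:
    """A Fitter backed by statsmodels MixedLM (ML estimation).

    A fit is flagged singular when any random-effect variance collapses
    below ``singular_tol`` times the residual variance (the boundary of the
    parameter space, lme4's isSingular analogue).
    """
    import statsmodels.formula.api as smf

    formula = f"{spec.response} ~ {' + '.join(spec.fixed_effects)}"

    def fit(structure: tuple[str, ...]) -> FitReport:
        vc = {}
        for term in structure:
            if ":" in term:
                factor = term.split(":", 1)[1]
                vc[factor.replace(":", "_")] = f"0 + C({factor})"
        md = smf.mixedlm(
            formula,
            data=data,
            groups=data[spec.group],
            re_formula="1",
            vc_formula=vc or None,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = md.fit(reml=False, maxiter=200)
            except Exception:
                return FitReport(structure, False, False, -np.inf, np.inf, 0.0, {}, np.nan)
        converged = bool(getattr(res, "converged", False))
        var_resid = float(res.scale)
        var_random = {structure[0]: float(np.asarray(res.cov_re)[0, 0])}
        vc_names = list(vc)
        for name, v in zip(vc_names, np.atleast_1d(res.vcomp)):
            term = next(t for t in structure if ":" in t and t.split(":", 1)[1] == name)
            var_random[term] = float(v)
        singular = any(v < singular_tol * var_resid for v in var_random.values())
        var_fixed = float(np.var(np.asarray(res.predict(data)), ddof=0))
        coef = pd.DataFrame(
            {"estimate": res.fe_params, "se": res.bse_fe, "p": res.pvalues[res.fe_params.index]}
        )
        return FitReport(
            structure=structure,
            converged=converged,
            singular=singular,
            loglik=float(res.llf),
            aic=float(res.aic),
            var_fixed=var_fixed,
            var_random=var_random,
            var_resid=var_resid,
            coef=coef,
        )

    return fit


@dataclass(frozen=True)
class StructureSelection:
    chosen: FitReport
    trail: tuple[FitReport, ...]
    lrt: tuple[dict, ...]  # likelihood-ratio records for nested fit pairs


def _lrt_records(trail: Sequence[FitReport]) -> tuple[dict, ...]:
    from scipy import stats as sps

    recs = []
    for bigger, smaller in zip(trail[:-1], trail[1:]):
        if not (np.isfinite(bigger.loglik) and np.isfinite(smaller.loglik)):
            continue
        lr = 2.0 * (bigger.loglik - smaller.loglik)
        df = len(bigger.structure) - len(smaller.structure)
        recs.append(
            {
                "full": bigger.structure,
                "reduced": smaller.structure,
                "chi2": lr,
                "df": df,
                "p": float(sps.chi2.sf(max(lr, 0.0), max(df, 1))),
            }
        )
    return tuple(recs)


def select_cri_structure(
    spec: ModelSpec,
    fitter: Fitter,
    exhaustive: bool = False,
) -> StructureSelection:
    """CRI random-structure selection by iterative simplification.

    Starting from the full structure (participant intercept + one
    participant x factor intercept per within factor), the current model is
    refit after dropping the interaction intercept with the smallest
    variance component whenever the fit fails to converge or is singular.
    By default the procedure stops at the first clean fit; with
    ``exhaustive=True`` the entire simplification ladder is fit and the
    clean candidate with minimum AIC is chosen (nested LRTs are recorded
    either way).
    """
    structure = spec.full_structure()
    trail: list[FitReport] = []
    while True:
        report = fitter(structure)
        trail.append(report)
        interactions = [t for t in structure if ":" in t]
        done = report.clean if not exhaustive else not interactions
        if done or not interactions:
            break
        if report.var_random:
            drop = min(interactions, key=lambda t: report.var_random.get(t, np.inf))
        else:
            drop = interactions[-1]
        structure = tuple(t for t in structure if t != drop)

    clean = [r for r in trail if r.clean]
    if not clean:
        raise NoModelError("no candidate structure produced a usable fit")
    chosen = min(clean, key=lambda r: r.aic)
    return StructureSelection(chosen=chosen, trail=tuple(trail), lrt=_lrt_records(trail))


def r2_nakagawa(report: FitReport) -> tuple[float, float]:
    """Marginal and conditional R-squared from variance components.

    R2_marginal    = var_f / (var_f + sum var_random + var_resid)
    R2_conditional = (var_f + sum var_random) / (same denominator)
    """
    var_r = float(sum(report.var_random.values()))
    total = report.var_fixed + var_r + report.var_resid
    if not np.isfinite(total) or total <= 0:
        raise InvalidInputError("total variance is zero or undefined")
    return report.var_fixed / total, (report.var_fixed + var_r) / total


def bonferroni_threshold(alpha: float = 0.05, m: int = 17) -> float:
    """Family-wise corrected per-test alpha: alpha / m (exact quotient)."""
    if not 0.0 < alpha < 1.0:
        raise InvalidInputError("alpha must be in (0, 1)")
    if m < 1:
        raise InvalidInputError("m must be >= 1")
    return alpha / m


def cooks_distance(
    residuals: np.ndarray,
    leverage: np.ndarray,
    mse: float,
    n_params: int,
) -> np.ndarray:
    """Cook's D from raw residuals, leverages, residual MSE and parameter
    count: D_i = r_i^2 / (k * mse) * h_i / (1 - h_i)^2."""
    r = np.asarray(residuals, float)
    h = np.asarray(leverage, float)
    return (r**2 / (n_params * mse)) * h / (1.0 - h) ** 2


def cooks_exclusions(diagnostics, cutoff: float | None = None) -> np.ndarray:
    """Row indices with Cook's distance above the cutoff (default 4/n).

    ``diagnostics`` may be a vector of Cook's D values or a fitted
    statsmodels OLS results object (its influence measures are used).
    """
    if hasattr(diagnostics, "get_influence"):
        d = diagnostics.get_influence().cooks_distance[0]
    else:
        d = np.asarray(diagnostics, float)
    n = d.size
    if cutoff is None:
        cutoff = 4.0 / n
    return np.nonzero(d > cutoff)[0]
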