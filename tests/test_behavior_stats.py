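"""RT filtering, CRI structure selection, Nakagawa R2, Bonferroni, Cook's D."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from reachgrasp import behavior_stats as bs
from reachgrasp.errors import InvalidInputError, NoModelError


def _resp(rows):
    return pd.DataFrame(rows, columns=["true_goal", "choice", "rt_ms"])


class TestFilterRts:
    def test_floor_boundary(self):
        df = _resp([("PASS", "PASS", 149.0), ("PASS", "PASS", 150.0)])
        out = bs.filter_rts(df)
        assert list(out["rt_ms"]) == [150.0]

    def test_incorrect_responses_removed(self):
        df = _resp([("PASS", "PLACE", 400.0), ("PLACE", "PLACE", 400.0)])
        out = bs.filter_rts(df)
        assert len(out) == 1 and out.iloc[0]["true_goal"] == "PLACE"

    def test_timeouts_removed(self):
        df = _resp([("PASS", "PASS", np.nan), ("PASS", "PASS", 300.0)])
        assert len(bs.filter_rts(df)) == 1

    def test_empty_input_and_idempotence(self):
        df = _resp([("PASS", "PASS", 500.0), ("PASS", "PLACE", 500.0)])
        once = bs.filter_rts(df)
        assert bs.filter_rts(once).equals(once)
        assert len(bs.filter_rts(df.iloc[:0])) == 0
        assert set(once.index) <= set(df.index)


def stub_fitter(script):
    """Fitter whose reports are scripted per structure (the transcript
    oracle).  ``script`` maps structure -> (converged, singular, aic,
    var_random)."""

    def fit(structure):
        converged, singular, aic, var_random = script[structure]
        return bs.FitReport(
            structure=structure,
            converged=converged,
            singular=singular,
            loglik=-aic / 2,
            aic=aic,
            var_fixed=1.0,
            var_random=var_random,
            var_resid=1.0,
        )

    return fit


SPEC2 = bs.ModelSpec(
    response="y", fixed_effects=("goal", "perspective"),
    within_factors=("goal", "perspective"),
)
FULL = SPEC2.full_structure()


class TestSelectCriStructure:
    def test_clean_full_model_returned_with_trail_of_one(self):
        script = {FULL: (True, False, 100.0, {t: 1.0 for t in FULL})}
        sel = bs.select_cri_structure(SPEC2, stub_fitter(script))
        assert sel.chosen.structure == FULL
        assert len(sel.trail) == 1

    def test_singular_full_drops_smallest_variance_interaction(self):
        smallest = FULL[2]  # participant x perspective gets variance ~0
        reduced = tuple(t for t in FULL if t != smallest)
        script = {
            FULL: (True, True, 100.0, {FULL[0]: 1.0, FULL[1]: 0.5, smallest: 1e-9}),
            reduced: (True, False, 101.0, {t: 1.0 for t in reduced}),
        }
        sel = bs.select_cri_structure(SPEC2, stub_fitter(script))
        assert sel.chosen.structure == reduced
        assert [r.structure for r in sel.trail] == [FULL, reduced]

    def test_exhaustive_mode_prefers_lower_aic_clean_candidate(self):
        mid = tuple(t for t in FULL if t != FULL[2])
        small = (FULL[0],)
        script = {
            FULL: (True, True, 990.0, {FULL[0]: 1.0, FULL[1]: 0.6, FULL[2]: 1e-9}),
            mid: (True, False, 1000.0, {t: 1.0 for t in mid}),
            small: (True, False, 998.0, {FULL[0]: 1.0}),
        }
        sel = bs.select_cri_structure(SPEC2, stub_fitter(script), exhaustive=True)
        assert sel.chosen.aic == 998.0
        assert sel.chosen.structure == small
        assert len(sel.lrt) == 2

    def test_all_candidates_failing_raises(self):
        structures = [FULL, tuple(t for t in FULL if t != FULL[2]), (FULL[0],)]
        # drop order under failure follows the smallest variance component
        script = {
            structures[0]: (False, False, np.inf, {FULL[0]: 1.0, FULL[1]: 0.5, FULL[2]: 0.1}),
            structures[1]: (False, False, np.inf, {FULL[0]: 1.0, FULL[1]: 0.1}),
            structures[2]: (True, True, 50.0, {FULL[0]: 1e-12}),
        }
        with pytest.raises(NoModelError):
            bs.select_cri_structure(SPEC2, stub_fitter(script))

    def test_statsmodels_backend_on_hierarchical_data(self):
        rng = np.random.default_rng(8)
        rows = []
        for pid in range(24):
            b0 = rng.normal(0, 1.0)
            bg = {"PASS": rng.normal(0, 0.8), "PLACE": rng.normal(0, 0.8)}
            for r in range(16):
                goal = "PASS" if r % 2 else "PLACE"
                y = 1.0 + 0.5 * (goal == "PASS") + b0 + bg[goal] + rng.normal(0, 1)
                rows.append({"participant_id": f"P{pid}", "goal": goal, "y": y})
        df = pd.DataFrame(rows)
        spec = bs.ModelSpec(response="y", fixed_effects=("goal",), within_factors=("goal",))
        sel = bs.select_cri_structure(spec, bs.make_mixedlm_fitter(df, spec))
        assert sel.chosen.clean
        assert sel.chosen.var_random["1|participant_id"] == pytest.approx(1.0, abs=0.6)


class TestR2Nakagawa:
    def _report(self, vf, vr, ve):
        return bs.FitReport(
            structure=("1|id",), converged=True, singular=False, loglik=0.0,
            aic=0.0, var_fixed=vf, var_random={"1|id": vr}, var_resid=ve,
        )

    def test_formula_forced_cases(self):
        assert bs.r2_nakagawa(self._report(1.0, 0.0, 1.0)) == (0.5, 0.5)
        r2m, r2c = bs.r2_nakagawa(self._report(0.0, 2.0, 1.0))
        assert r2m == 0.0
        assert r2c == pytest.approx(2.0 / 3.0)

    def test_marginal_never_exceeds_conditional(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            vf, vr, ve = rng.uniform(0.01, 5, 3)
            r2m, r2c = bs.r2_nakagawa(self._report(vf, vr, ve))
            assert 0 <= r2m <= r2c <= 1

    def test_recovery_from_simulated_components(self):
        # within-subject design: generating variances are known exactly
        rng = np.random.default_rng(21)
        beta = 1.0
        rows = []
        for pid in range(60):
            b0 = rng.normal(0, np.sqrt(0.5))
            for r in range(20):
                x = r % 2
                rows.append(
                    {"participant_id": f"P{pid}", "x": x,
                     "y": beta * x + b0 + rng.normal(0, 1.0)}
                )
        df = pd.DataFrame(rows)
        spec = bs.ModelSpec(response="y", fixed_effects=("x",))
        rep = bs.make_mixedlm_fitter(df, spec)(spec.full_structure())
        r2m, r2c = bs.r2_nakagawa(rep)
        vf = beta**2 * 0.25  # variance of beta*x with balanced x in {0,1}
        want_m = vf / (vf + 0.5 + 1.0)
        want_c = (vf + 0.5) / (vf + 0.5 + 1.0)
        assert r2m == pytest.approx(want_m, abs=0.05)
        assert r2c == pytest.approx(want_c, abs=0.05)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(InvalidInputError):
            bs.r2_nakagawa(self._report(0.0, 0.0, 0.0))


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,want",
        [(0.05, 17, 0.05 / 17), (0.05, 1, 0.05), (0.05, 5, 0.01)],
    )
    def test_quotients(self, alpha, m, want):
        assert bs.bonferroni_threshold(alpha, m) == pytest.approx(want, rel=1e-15)

    def test_family_of_17_is_not_the_printed_rounding(self):
        # the exact quotient, 0.00294..., not a truncated 0.002
        assert bs.bonferroni_threshold(0.05, 17) == pytest.approx(0.0029411764705882353)

    def test_invalid_alpha(self):
        with pytest.raises(InvalidInputError):
            bs.bonferroni_threshold(1.5, 17)


class TestCooks:
    def _fit(self, x, y):
        return sm.OLS(y, sm.add_constant(x)).fit()

    def test_no_outliers_empty_exclusion(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 10, 80)
        y = 2 * x + rng.normal(0, 0.5, 80)
        res = self._fit(x, y)
        d = res.get_influence().cooks_distance[0]
        if (d > 4 / 80).any():  # tolerate benign random flags, but none gross
            assert d.max() < 20 / 80
        assert len(bs.cooks_exclusions(np.full(50, 1e-4))) == 0

    def test_planted_outlier_has_max_distance_and_is_excluded(self):
        rng = np.random.default_rng(4)
        x = np.linspace(0, 10, 60)
        y = 2 * x + rng.normal(0, 0.5, 60)
        y[37] += 25.0
        res = self._fit(x, y)
        excluded = bs.cooks_exclusions(res)
        d = res.get_influence().cooks_distance[0]
        assert int(np.argmax(d)) == 37
        assert 37 in excluded
        # agrees with the direct Cook's D formula
        infl = res.get_influence()
        manual = bs.cooks_distance(
            res.resid, infl.hat_matrix_diag, res.mse_resid, 2
        )
        np.testing.assert_allclose(manual, d, rtol=1e-8)

    def test_duplicate_point_barely_moves_coefficients(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 10, 60)
        y = 2 * x + rng.normal(0, 0.5, 60)
        res = self._fit(x, y)
        x2 = np.append(x, x[30])
        y2 = np.append(y, y[30])
        res2 = self._fit(x2, y2)
        np.testing.assert_allclose(res.params, res2.params, atol=0.05)
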