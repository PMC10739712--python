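import math

import numpy as np
import pytest

from epiland.effects import epistatic_effect
from epiland.global_epistasis import (
    LogisticParams,
    correct_global_epistasis,
    detect_degenerate,
    detilt,
    fit_additive_firstorder,
    fit_logistic,
    logistic,
    select_model,
)
from epiland.landscape_io import Landscape, average_replicates, normalize_and_log
from epiland.synthetic import SyntheticSpec, generate

from conftest import make_additive, make_random

PARAMS = LogisticParams(U=2.0, L=-2.0, m=0.0, s=1.5)


class TestLogisticParams:
    def test_bounds_ordering_enforced(self):
        with pytest.raises(ValueError):
            LogisticParams(U=-1.0, L=1.0, m=0.0, s=1.0)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            LogisticParams(U=1.0, L=-1.0, m=0.0, s=0.0)


class TestFirstOrderFit:
    def test_additive_landscape_fits_exactly(self):
        ls = make_additive(4, seed=0)
        assert np.allclose(fit_additive_firstorder(ls), ls.values, atol=1e-10)

    def test_null_landscape(self):
        ls = Landscape("z", "c", "f", ("a", "b"), np.zeros(4))
        assert np.allclose(fit_additive_firstorder(ls), 0.0)

    def test_toy_matches_normal_equations_oracle(self, toy2):
        # explicit 4x4 least squares on the +-1 design
        X = np.array([[1, -1, -1], [1, 1, -1], [1, -1, 1], [1, 1, 1]], float)
        beta = np.linalg.solve(X.T @ X, X.T @ toy2.values)
        assert np.allclose(fit_additive_firstorder(toy2), X @ beta, atol=1e-12)
        resid = toy2.values - X @ beta
        # residuals carry the single epistatic term, split +-EE/4
        ee = epistatic_effect(toy2, (0, 1))
        assert np.allclose(np.abs(resid), ee / 4, atol=1e-12)


class TestLogisticFit:
    def test_zero_noise_self_consistency(self):
        f_add = np.linspace(-3, 3, 25)
        f_obs = logistic(f_add, PARAMS)
        fit = fit_logistic(f_add, f_obs)
        assert fit.U == pytest.approx(PARAMS.U, abs=1e-4)
        assert fit.L == pytest.approx(PARAMS.L, abs=1e-4)
        assert fit.m == pytest.approx(PARAMS.m, abs=1e-4)
        assert fit.s == pytest.approx(PARAMS.s, abs=1e-4)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_logistic(np.arange(4.0), np.arange(4.0))


class TestModelSelection:
    def test_linear_data_prefers_linear(self):
        ls = make_additive(4, seed=5)
        sel = select_model(ls)
        assert sel.chosen == "linear"

    def test_squashed_data_prefers_logistic(self):
        table, _ = generate(SyntheticSpec(n=5, squash=PARAMS), seed=2)
        ls = normalize_and_log(average_replicates(table))
        assert select_model(ls).chosen == "logistic"

    def test_translation_invariance_of_choice(self):
        table, _ = generate(SyntheticSpec(n=5, squash=PARAMS), seed=3)
        ls = normalize_and_log(average_replicates(table))
        shifted = Landscape(
            ls.enzyme, ls.condition, ls.trait, ls.loci, ls.values + 0.8
        )
        assert select_model(ls).chosen == select_model(shifted).chosen

    def test_equal_rss_resolves_to_fewer_parameters(self):
        # a perfectly linear landscape: logistic can at best tie on RSS, so
        # the AIC penalty must pick linear
        ls = make_additive(5, effects=[0.4, 0.3, 0.2, 0.1, 0.05])
        assert select_model(ls).chosen == "linear"


class TestDetilt:
    def test_inverse_identity_within_bounds(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(-2.5, 2.5, 32)
        values[0] = 0.0
        ls = Landscape("t", "c", "f", tuple("abcde"), values)
        squashed = Landscape("t", "c", "f", ls.loci, np.asarray(logistic(values, PARAMS)))
        back = detilt(squashed, PARAMS, recenter=False)
        assert np.allclose(back.values, values, atol=1e-6)
        assert back.flags["n_clamped"] == 0

    def test_midpoint_fixed_point(self):
        mid = logistic(np.array([PARAMS.m]), PARAMS)
        ls = Landscape("t", "c", "f", tuple("abcde"),
                       np.full(32, float(mid[0])))
        back = detilt(ls, PARAMS, recenter=False)
        assert back.values[0] == pytest.approx(PARAMS.m, abs=1e-9)

    def test_out_of_bounds_clamped_and_flagged(self):
        values = np.array([0.0, 2.5, -3.0, 0.1])
        ls = Landscape("t", "c", "f", ("a", "b"), values)
        back = detilt(ls, PARAMS, recenter=False)
        assert back.flags["n_clamped"] == 2
        assert np.all(np.isfinite(back.values))

    def test_recenter_restores_wt_zero(self):
        table, _ = generate(SyntheticSpec(n=4, squash=PARAMS), seed=7)
        ls = normalize_and_log(average_replicates(table))
        out = detilt(ls, PARAMS)
        assert out.values[0] == 0.0


class TestDegeneracy:
    def test_binary_collapse_detected(self):
        values = np.array([PARAMS.L] * 8 + [PARAMS.U] * 8)
        ls = Landscape("t", "c", "f", tuple("abcd"), values)
        assert detect_degenerate(ls, PARAMS)

    def test_mild_squash_not_degenerate(self):
        table, _ = generate(SyntheticSpec(n=5, squash=PARAMS), seed=2)
        ls = normalize_and_log(average_replicates(table))
        assert not detect_degenerate(ls, PARAMS)

    def test_sixty_percent_at_bounds_below_threshold(self):
        values = np.concatenate([np.full(10, PARAMS.U), np.full(6, 0.0)])
        ls = Landscape("t", "c", "f", tuple("abcd"), values)
        assert not detect_degenerate(ls, PARAMS)  # 62.5% < 90%


class TestCorrectionPipeline:
    def test_squashed_additive_landscape_fully_corrected(self):
        # AIC must select the logistic and the refined inversion must remove
        # all epistasis of order >= 2 (only non-specific epistasis present)
        table, _ = generate(SyntheticSpec(n=5, squash=PARAMS), seed=13)
        ls = normalize_and_log(average_replicates(table))
        report = correct_global_epistasis(ls)
        assert report.selection.chosen == "logistic"
        assert not report.degenerate
        corrected = report.landscape
        from itertools import combinations

        for k in range(2, 6):
            for loci in combinations(range(5), k):
                assert abs(epistatic_effect(corrected, loci)) < 1e-6

    def test_refinement_recovers_true_bounds(self):
        table, _ = generate(SyntheticSpec(n=5, squash=PARAMS), seed=13)
        ls = normalize_and_log(average_replicates(table))
        report = correct_global_epistasis(ls)
        p = report.selection.params
        # bounds are shifted by the wt normalization but their span is not
        assert (p.U - p.L) == pytest.approx(PARAMS.U - PARAMS.L, abs=1e-6)

    def test_linear_landscape_left_untouched(self):
        ls = make_additive(4, seed=8)
        report = correct_global_epistasis(ls)
        assert report.selection.chosen == "linear"
        assert np.allclose(report.landscape.values, ls.values)
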