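"""Adaptive group-lasso learner: prox, FISTA, path and cross-validation."""

import math

import numpy as np
import pytest
import scipy.optimize
from hypothesis import given
from hypothesis import strategies as st

import fctbn
from fctbn import fixtures
from fctbn.ctmp import mle_intensities, sufficient_stats
from fctbn.design import compile_design
from fctbn.errors import DataError
from fctbn.learning import (
    DEFAULT_LAMBDA_GRID,
    FitOptions,
    adaptive_weights,
    cross_validate,
    fista_fit,
    fit_unpenalized,
    group_prox,
    make_penalty,
    regularization_path,
)
from fctbn.model import BASELINE, GAIN, LOSS


class TestGroupProx:
    @pytest.mark.parametrize(
        "v,thr,expected",
        [((3.0, 4.0), 5.0, (0.0, 0.0)),
         ((3.0, 4.0), 2.5, (1.5, 2.0)),
         ((3.0, 4.0), 0.0, (3.0, 4.0))],
    )
    def test_closed_form(self, v, thr, expected):
        np.testing.assert_allclose(group_prox(np.array(v), thr), expected)

    def test_matches_numerical_minimizer(self):
        """Prox equals argmin of 0.5||x-v||^2 + thr*||x|| on random instances."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            dim = rng.integers(1, 6)
            v = rng.normal(0, 2, dim)
            thr = float(rng.uniform(0, 3))
            obj = lambda x: 0.5 * np.sum((x - v) ** 2) + thr * np.linalg.norm(x)
            res = scipy.optimize.minimize(obj, v, method="Nelder-Mead",
                                          options={"xatol": 1e-10, "fatol": 1e-14,
                                                   "maxiter": 20000})
            got = group_prox(v, thr)
            assert obj(got) <= obj(res.x) + 1e-9
            np.testing.assert_allclose(got, res.x, atol=2e-4)

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=6), st.floats(0, 10))
    def test_never_increases_norm(self, v, thr):
        v = np.asarray(v)
        assert np.linalg.norm(group_prox(v, thr)) <= np.linalg.norm(v) + 1e-12


class TestAdaptiveWeights:
    def _table_with_norm(self, norm):
        table = fixtures.small_truth()
        for key in table.penalized_keys():
            table.groups[key][:] = 0.0
        table.groups[("B", GAIN, "A")][0] = norm
        return table

    def test_inverse_norm(self):
        w = adaptive_weights(self._table_with_norm(2.0))
        assert w[("B", "A")] == pytest.approx(0.5)

    def test_floor_applies_to_zero_groups(self):
        w = adaptive_weights(self._table_with_norm(2.0), floor=1e-4)
        assert w[("C", "A")] == pytest.approx(1e4)

    def test_doubling_estimates_halves_weights(self):
        t1 = self._table_with_norm(1.3)
        t2 = self._table_with_norm(2.6)
        w1, w2 = adaptive_weights(t1), adaptive_weights(t2)
        assert w2[("B", "A")] == pytest.approx(w1[("B", "A")] / 2)


class TestFitUnpenalized:
    def test_matches_closed_form_rates_without_covariates(self):
        """No-covariate, no-parent fit reproduces exp(b0) = M/T exactly."""
        from fctbn.model import CoefficientTable, NetworkStructure
        from fctbn.simulate import SimulationSpec, generate_cohort

        structure = NetworkStructure(("A", "B"), {"A": (), "B": ()})
        truth = CoefficientTable.zeros(structure, ())
        truth.groups[("A", GAIN, BASELINE)][0] = math.log(0.7)
        truth.groups[("B", GAIN, BASELINE)][0] = math.log(0.3)
        truth.groups[("A", LOSS, BASELINE)][0] = math.log(0.5)
        truth.groups[("B", LOSS, BASELINE)][0] = math.log(0.4)
        ds = generate_cohort(SimulationSpec(structure, truth, [], 300, 5.0, seed=4))
        fit = fit_unpenalized(structure, ds)
        est = mle_intensities(sufficient_stats(ds, structure))
        for node in ("A", "B"):
            assert math.exp(fit.groups[(node, GAIN, BASELINE)][0]) == pytest.approx(
                est[(node, 0, ())].rate, rel=1e-6
            )
            assert math.exp(fit.groups[(node, LOSS, BASELINE)][0]) == pytest.approx(
                est[(node, 1, ())].rate, rel=1e-6
            )

    def test_recovers_truth_on_simulated_cohort(self):
        """3-node cohort (n=2,000, seed 11): coefficient RMSE vs truth < 0.15."""
        spec = fixtures.small_sim_spec(n_subjects=2000, seed=11)
        ds = fctbn.generate_cohort(spec)
        fit = fit_unpenalized(spec.structure, ds).to_original_scale()
        truth = fixtures.small_truth()
        errs = np.concatenate(
            [fit.groups[k] - truth.groups[k] for k in sorted(truth.groups)]
        )
        assert float(np.sqrt(np.mean(errs**2))) < 0.15

    def test_objective_at_solution_beats_truth(self, small_spec, small_cohort,
                                               small_design, small_beta_tilde):
        x_fit = small_design.vector_from_table(small_beta_tilde)
        x_truth = small_design.vector_from_table(fixtures.small_truth())
        assert small_design.value(x_fit) <= small_design.value(x_truth)


class TestFista:
    def test_lambda_zero_matches_unpenalized(self, small_spec, small_design,
                                             small_beta_tilde):
        res = fista_fit(small_spec.structure, None, make_penalty(small_beta_tilde, 0.0),
                        FitOptions(tol=1e-11), design=small_design)
        f_opt = small_design.value(small_design.vector_from_table(small_beta_tilde))
        assert res.objective - f_opt < 1e-4
        assert res.objective >= f_opt - 1e-9

    def test_huge_lambda_zeroes_all_penalized_groups(self, small_spec, small_design,
                                                     small_beta_tilde):
        res = fista_fit(small_spec.structure, None, make_penalty(small_beta_tilde, 1e9),
                        design=small_design)
        for idx in small_design.penalty_group_indices().values():
            np.testing.assert_array_equal(res.vector[idx], 0.0)
        assert res.active_groups == set()

    def test_huge_lambda_baselines_reproduce_pooled_rates(self):
        """With all edges penalized away, baselines equal pooled M/T rates."""
        from fctbn.model import CoefficientTable, NetworkStructure
        from fctbn.simulate import SimulationSpec, generate_cohort

        structure = NetworkStructure.fully_connected(("A", "B"))
        truth = CoefficientTable.zeros(structure, ())
        truth.groups[("A", GAIN, BASELINE)][0] = math.log(0.6)
        truth.groups[("B", GAIN, BASELINE)][0] = math.log(0.3)
        truth.groups[("A", LOSS, BASELINE)][0] = math.log(0.2)
        truth.groups[("B", LOSS, BASELINE)][0] = math.log(0.2)
        truth.groups[("B", GAIN, "A")][0] = math.log(2.0)
        ds = generate_cohort(SimulationSpec(structure, truth, [], 400, 5.0, seed=21))
        design = compile_design(structure, ds, standardize=True)
        bt = fit_unpenalized(structure, design=design)
        res = fista_fit(structure, None, make_penalty(bt, 1e9),
                        FitOptions(tol=1e-11), design=design)
        # pooled (parent-ignoring) rates
        pooled = NetworkStructure(("A", "B"), {"A": (), "B": ()})
        est = mle_intensities(sufficient_stats(ds, pooled))
        for node in ("A", "B"):
            got = math.exp(res.coefficients.groups[(node, GAIN, BASELINE)][0])
            assert got == pytest.approx(est[(node, 0, ())].rate, rel=1e-3)

    def test_objective_trace_non_increasing(self, small_spec, small_design,
                                            small_beta_tilde):
        res = fista_fit(small_spec.structure, None, make_penalty(small_beta_tilde, 5.0),
                        design=small_design)
        trace = res.objective_trace
        assert np.all(np.diff(trace) <= 1e-12)
        assert res.objective <= trace[0]

    def test_structure_recovery_with_spurious_candidates(self):
        """2 true edges among 6 candidates (n=5,000, seed 23): truth kept,
        at least 3 of 4 spurious groups zeroed at the CV-selected lambda."""
        spec = fixtures.small_sim_spec(n_subjects=5000, seed=23)
        ds = fctbn.generate_cohort(spec)
        cv = cross_validate(spec.structure, ds, k_folds=3, seed=23)
        design = compile_design(spec.structure, ds, standardize=True)
        bt = fit_unpenalized(spec.structure, design=design)
        res = fista_fit(spec.structure, None, make_penalty(bt, cv.best_lambda),
                        design=design, init=bt)
        true_edges = {("B", "A"), ("C", "B")}  # (child, parent)
        assert true_edges <= res.active_groups
        spurious = {(c, p) for c, p in design.penalty_group_indices()} - true_edges
        zeroed = len(spurious) - len(res.active_groups - true_edges)
        assert zeroed >= 3


class TestRegularizationPath:
    def test_single_zero_lambda_grid(self, small_spec, small_design, small_beta_tilde):
        path = regularization_path(small_spec.structure, None, [0.0],
                                   design=small_design, beta_tilde=small_beta_tilde)
        assert len(path.results) == 1
        assert path.sparsity[0] == 0.0

    def test_sparsity_monotone_over_grid(self, small_spec, small_design,
                                         small_beta_tilde):
        path = regularization_path(small_spec.structure, None, DEFAULT_LAMBDA_GRID,
                                   design=small_design, beta_tilde=small_beta_tilde)
        assert np.all(np.diff(path.sparsity) >= 0)
        assert path.sparsity[-1] >= path.sparsity[0]
        assert path.sparsity[-1] == 1.0

    def test_coefficients_vary_continuously(self, small_spec, small_design,
                                            small_beta_tilde):
        """Adjacent-lambda solutions stay close on a fine sub-grid."""
        grid = [0.0, 2.0, 4.0, 6.0, 8.0]
        path = regularization_path(small_spec.structure, None, grid,
                                   design=small_design, beta_tilde=small_beta_tilde)
        vecs = [r.vector for r in path.results]
        scale = np.linalg.norm(vecs[0])
        for a, b in zip(vecs, vecs[1:]):
            assert np.linalg.norm(b - a) < 0.5 * scale


class TestCrossValidate:
    def test_default_grid_is_log_decades(self):
        assert DEFAULT_LAMBDA_GRID == (0.0, 1.0, 10.0, 1e2, 1e3, 1e4, 1e5, 1e6)

    def test_deterministic_given_seed(self, small_spec, small_cohort):
        a = cross_validate(small_spec.structure, small_cohort, [0.0, 10.0],
                           k_folds=3, seed=5)
        b = cross_validate(small_spec.structure, small_cohort, [0.0, 10.0],
                           k_folds=3, seed=5)
        assert a.best_lambda == b.best_lambda
        np.testing.assert_array_equal(a.cv_errors, b.cv_errors)

    def test_duplicated_halves_self_consistency(self, small_spec, small_cohort):
        """CV error on a dataset made of two identical halves approximates the
        training error per record of the unpenalized fit."""
        half = small_cohort.subset(range(150))
        doubled = half.concat(half)
        cv = cross_validate(small_spec.structure, doubled, [0.0], k_folds=2, seed=0)
        design = compile_design(small_spec.structure, half, standardize=True)
        bt = fit_unpenalized(small_spec.structure, design=design)
        train_err = design.value(design.vector_from_table(bt)) / design.n_records
        assert cv.cv_errors[0] == pytest.approx(train_err, rel=0.02)

    def test_empty_fold_rejected(self, small_spec, small_cohort):
        with pytest.raises(DataError):
            cross_validate(small_spec.structure, small_cohort.subset(range(2)),
                           [0.0], k_folds=3, seed=0)
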