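"""Conditional intensities, likelihood, gradient and parameter counting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fctbn.ctmp import validate_intensity
from fctbn.design import compile_design
from fctbn.errors import DataError, SchemaError
from fctbn.model import (
    BASELINE,
    GAIN,
    LOSS,
    CoefficientTable,
    NetworkStructure,
    Record,
    Subject,
    TrajectoryDataset,
    build_subject_cims,
    conditional_intensity,
    neg_log_likelihood,
    nll_gradient,
    parameter_count,
)


@pytest.fixture()
def two_parent_table():
    structure = NetworkStructure(("U1", "U2", "X"), {"U1": (), "U2": (), "X": ("U1", "U2")})
    return CoefficientTable.zeros(structure, ())


class TestConditionalIntensity:
    def test_all_zero_coefficients_give_rate_one(self, two_parent_table):
        assert conditional_intensity(two_parent_table, "X", GAIN, [], []) == pytest.approx(1.0)

    def test_baseline_intercept_log2(self, two_parent_table):
        two_parent_table.groups[("X", GAIN, BASELINE)][0] = math.log(2)
        assert conditional_intensity(two_parent_table, "X", GAIN, [], []) == pytest.approx(2.0)

    def test_multiplicative_parent_composition(self, two_parent_table):
        """Active parents multiply the baseline rate: 1 * 2 * 3 = 6."""
        two_parent_table.groups[("X", GAIN, "U1")][0] = math.log(2)
        two_parent_table.groups[("X", GAIN, "U2")][0] = math.log(3)
        q0 = conditional_intensity(two_parent_table, "X", GAIN, [], [])
        q12 = conditional_intensity(two_parent_table, "X", GAIN, ["U1", "U2"], [])
        assert q12 == pytest.approx(q0 * 6.0)

    def test_unknown_parent_raises(self, two_parent_table):
        with pytest.raises(SchemaError):
            conditional_intensity(two_parent_table, "X", GAIN, ["U3"], [])

    @given(beta=st.floats(-2, 2), z=st.floats(-2, 2))
    def test_one_active_parent_scales_by_its_factor(self, beta, z):
        structure = NetworkStructure(("P", "X"), {"P": (), "X": ("P",)})
        table = CoefficientTable.zeros(structure, ("z1",))
        table.groups[("X", GAIN, BASELINE)][:] = (0.4, -0.3)
        table.groups[("X", GAIN, "P")][:] = (beta, 0.5)
        base = conditional_intensity(table, "X", GAIN, [], [z])
        with_p = conditional_intensity(table, "X", GAIN, ["P"], [z])
        assert with_p == pytest.approx(base * math.exp(beta + 0.5 * z))

    def test_frozen_remission_rate(self):
        structure = NetworkStructure(("X",), {"X": ()})
        table = CoefficientTable.zeros(structure, (), remission=False)
        assert conditional_intensity(table, "X", LOSS, [], []) == 0.0


class TestBuildSubjectCims:
    def test_no_parent_node_matrix_form(self):
        structure = NetworkStructure(("X",), {"X": ()})
        table = CoefficientTable.zeros(structure, ())
        table.groups[("X", GAIN, BASELINE)][0] = math.log(2.0)
        table.groups[("X", LOSS, BASELINE)][0] = math.log(0.5)
        (cim,) = build_subject_cims(table, [])["X"]
        np.testing.assert_allclose(cim.matrix.rates, [[-2, 2], [0.5, -0.5]])

    def test_two_parents_give_four_matrices_all_valid(self, two_parent_table):
        cims = build_subject_cims(two_parent_table, [])["X"]
        assert len(cims) == 4
        assert {c.parent_config for c in cims} == {
            (("U1", 0), ("U2", 0)), (("U1", 0), ("U2", 1)),
            (("U1", 1), ("U2", 0)), (("U1", 1), ("U2", 1)),
        }
        for c in cims:
            assert validate_intensity(c.matrix).ok


def _single_record_dataset(q_log, duration, censored):
    structure = NetworkStructure(("A",), {"A": ()})
    table = CoefficientTable.zeros(structure, ())
    table.groups[("A", GAIN, BASELINE)][0] = q_log
    rec = (Record([0], duration, None, None, censored=True) if censored
           else Record([0], duration, "A", 1))
    ds = TrajectoryDataset(("A",), (), [Subject("s", np.empty(0), [rec])])
    return table, ds


class TestNegLogLikelihood:
    def test_single_noncensored_record(self):
        table, ds = _single_record_dataset(0.0, 1.0, censored=False)
        # -(log 1 - 1*1) = 1
        assert neg_log_likelihood(table, ds) == pytest.approx(1.0)

    def test_single_censored_record_exposure_only(self):
        table, ds = _single_record_dataset(math.log(2.0), 0.5, censored=True)
        assert neg_log_likelihood(table, ds) == pytest.approx(1.0)

    def test_matches_independent_record_loop(self, small_spec, small_cohort):
        """Vectorized NLL equals a term-by-term sum over records and nodes."""
        from fctbn import fixtures

        table = fixtures.small_truth()
        structure = small_spec.structure
        nidx = {n: i for i, n in enumerate(structure.nodes)}
        expected = 0.0
        subjects = small_cohort.subjects[:10]
        for s in subjects:
            for rec in s.records:
                for node in structure.nodes:
                    state = rec.states[nidx[node]]
                    direction = GAIN if state == 0 else LOSS
                    active = [p for p in structure.parents[node] if rec.states[nidx[p]] == 1]
                    q = conditional_intensity(table, node, direction, active, s.z)
                    expected += q * rec.duration
                    if not rec.censored and rec.node == node:
                        expected -= math.log(q)
        ds = TrajectoryDataset(small_cohort.nodes, small_cohort.covariates, subjects)
        assert neg_log_likelihood(table, ds) == pytest.approx(expected, rel=1e-10)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(DataError):
            Record([0], 0.0, "A", 1)

    def test_convex_along_random_segments(self, small_spec, small_cohort, small_design):
        """Midpoint objective never exceeds the chord average (convexity)."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            a = rng.normal(0, 0.5, small_design.n_params)
            b = rng.normal(0, 0.5, small_design.n_params)
            mid = small_design.value((a + b) / 2)
            assert mid <= (small_design.value(a) + small_design.value(b)) / 2 + 1e-9


class TestGradient:
    def test_zero_coefficients_single_record(self):
        table, ds = _single_record_dataset(0.0, 1.0, censored=False)
        grad = nll_gradient(table, ds)
        assert grad.groups[("A", GAIN, BASELINE)][0] == pytest.approx(0.0)

    def test_finite_difference_agreement(self, small_spec, small_cohort, small_design):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 0.3, small_design.n_params)
        _, g = small_design.value_grad(x)
        eps = 1e-6
        for i in rng.choice(small_design.n_params, size=12, replace=False):
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            fd = (small_design.value(xp) - small_design.value(xm)) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_zero_gradient_at_closed_form_mle(self):
        """With no covariates/parents the MLE exp(b0)=M/T zeroes the gradient."""
        rng = np.random.default_rng(2)
        recs = []
        state = 0
        for _ in range(30):
            recs.append(Record([state], rng.exponential(1.0), "A", 1 - state))
            state = 1 - state
        ds = TrajectoryDataset(("A",), (), [Subject("s", np.empty(0), recs)])
        structure = NetworkStructure(("A",), {"A": ()})
        from fctbn.ctmp import mle_intensities, sufficient_stats

        est = mle_intensities(sufficient_stats(ds, structure))
        table = CoefficientTable.zeros(structure, ())
        table.groups[("A", GAIN, BASELINE)][0] = math.log(est[("A", 0, ())].rate)
        table.groups[("A", LOSS, BASELINE)][0] = math.log(est[("A", 1, ())].rate)
        grad = nll_gradient(table, ds)
        for vec in grad.groups.values():
            np.testing.assert_allclose(vec, 0.0, atol=1e-9)


class TestParameterCount:
    @pytest.mark.parametrize(
        "n,m,mode,expected",
        [(5, 1, "multiplicative", 100), (5, 1, "full", 320), (1, 0, "multiplicative", 2),
         (1, 0, "full", 2)],
    )
    def test_formulas(self, n, m, mode, expected):
        nodes = tuple(f"N{i}" for i in range(n))
        structure = (NetworkStructure.fully_connected(nodes) if n > 1
                     else NetworkStructure(nodes, {nodes[0]: ()}))
        assert parameter_count(structure, m, mode) == expected


class TestSerialization:
    def test_round_trip_exact(self, small_beta_tilde, tmp_path):
        path = tmp_path / "model.json"
        small_beta_tilde.save(path)
        loaded = CoefficientTable.load(path)
        assert loaded.structure.nodes == small_beta_tilde.structure.nodes
        assert loaded.covariates == small_beta_tilde.covariates
        for key, vec in small_beta_tilde.groups.items():
            np.testing.assert_array_equal(loaded.groups[key], vec)
        np.testing.assert_array_equal(loaded.scaler[0], small_beta_tilde.scaler[0])

    def test_scale_conversion_preserves_rates(self, small_beta_tilde):
        """Standardized and original-scale tables give identical intensities."""
        orig = small_beta_tilde.to_original_scale()
        rng = np.random.default_rng(0)
        for _ in range(10):
            z = rng.normal(size=1)
            q1 = conditional_intensity(small_beta_tilde, "B", GAIN, ["A"], z)
            q2 = conditional_intensity(orig, "B", GAIN, ["A"], z)
            assert q1 == pytest.approx(q2, rel=1e-10)


class TestStructureValidation:
    def test_self_parent_rejected(self):
        with pytest.raises(SchemaError):
            NetworkStructure(("A",), {"A": ("A",)})

    def test_parent_cap_enforced(self):
        nodes = tuple("ABCDEF")
        with pytest.raises(SchemaError):
            NetworkStructure(nodes, {"A": tuple("BCDEF")}, max_parents=4)

    def test_dataset_state_consistency(self):
        recs = [Record([0, 0], 1.0, "A", 1), Record([0, 1], 1.0, None, None, censored=True)]
        ds = TrajectoryDataset(("A", "B"), (), [Subject("s", np.empty(0), recs)])
        with pytest.raises(DataError, match="inconsistent"):
            ds.validate()
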