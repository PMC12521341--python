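"""Structural model: multiplicative terms, synergies, validation, rescaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import celldose as cd
from celldose.model import fold_interaction_matrix

from _oracles import random_structured_model, two_population_printed_rhs


class TestLinearControlTerm:
    def test_zero_control_gives_zero(self, two_pop_model, rng):
        x = rng.uniform(0, 2, 2)
        assert np.all(cd.linear_control_term(two_pop_model, x, [0, 0]) == 0)

    def test_two_population_hand_expansion(self, two_pop_model):
        # cisplatin only, alpha = 0.5: +(1-alpha) N_A in eq A, -N_A in eq B
        out = cd.linear_control_term(two_pop_model, [1.0, 1.0], [1.0, 0.0])
        np.testing.assert_allclose(out, [0.5, -1.0], atol=1e-15)

    def test_zero_C_gives_zero(self, rng):
        model = cd.ControlledODEModel(
            np.eye(2), np.zeros((2, 3)), np.zeros((2, 2, 3)), np.zeros((2, 2, 3, 3))
        )
        assert np.all(
            cd.linear_control_term(model, rng.uniform(0, 1, 2), rng.uniform(0, 1, 3))
            == 0
        )


class TestInteractionTerm:
    def test_zero_D_gives_zero(self, two_pop_model, rng):
        out = cd.interaction_term(two_pop_model, rng.uniform(0, 2, 2), rng.uniform(0, 1, 2))
        assert np.all(out == 0)

    def test_neuroblastoma_synergy_hand_expansion(self, nb_reduced_model):
        # trk+NGF on a pure-I state: +delta u_trk u_NGF into I, -delta into N
        out = cd.interaction_term(nb_reduced_model, [1, 0, 0], [0, 0, 1, 1])
        np.testing.assert_allclose(out, [0.1, -0.1, 0.0], atol=1e-15)

    def test_single_drug_never_self_interacts(self, rng):
        model = random_structured_model(rng)
        for k in range(model.m):
            u = np.zeros(model.m)
            u[k] = rng.uniform(0.1, 1.0)
            out = cd.interaction_term(model, rng.uniform(0, 2, model.n), u)
            np.testing.assert_allclose(out, 0.0, atol=1e-15)


class TestRhs:
    def test_two_population_uncontrolled(self, two_pop_model):
        np.testing.assert_allclose(
            cd.rhs(two_pop_model, [1.0, 1.0], [0.0, 0.0]), [1.0, 0.0], atol=1e-15
        )

    def test_zero_state_zero_B(self, rng):
        model = random_structured_model(rng, with_B=False)
        out = cd.rhs(model, np.zeros(model.n), rng.uniform(0, 1, model.m))
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_neuroblastoma_uncontrolled_is_linear_flow(self, nb_reduced_model):
        x = np.ones(3)
        np.testing.assert_allclose(
            cd.rhs(nb_reduced_model, x, np.zeros(4)), nb_reduced_model.A @ x
        )

    def test_lqr_limit_exact(self, rng):
        n, m = 3, 2
        A, B = rng.uniform(-1, 1, (n, n)), rng.uniform(-1, 1, (n, m))
        model = cd.ControlledODEModel(A, B, np.zeros((n, n, m)), np.zeros((n, n, m, m)))
        x, u = rng.uniform(0, 2, n), rng.uniform(0, 1, m)
        np.testing.assert_array_equal(cd.rhs(model, x, u), A @ x + B @ u)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_linear_in_state_quadratic_in_control(self, seed):
        rng = np.random.default_rng(seed)
        model = random_structured_model(rng)
        u = rng.uniform(0, 1, model.m)
        x1, x2 = rng.uniform(0, 2, model.n), rng.uniform(0, 2, model.n)
        # superposition in x once the u-only (Bu) offset is removed
        lhs = cd.rhs(model, x1 + x2, u) + cd.rhs(model, np.zeros(model.n), u)
        rhs_ = cd.rhs(model, x1, u) + cd.rhs(model, x2, u)
        np.testing.assert_allclose(lhs, rhs_, atol=1e-12)
        # third difference along any control direction vanishes (quadratic)
        x = rng.uniform(0, 2, model.n)
        du = rng.uniform(-1, 1, model.m)
        vals = [cd.rhs(model, x, u + s * du) for s in (0.0, 1.0, 2.0, 3.0)]
        third = vals[3] - 3 * vals[2] + 3 * vals[1] - vals[0]
        np.testing.assert_allclose(third, 0.0, atol=1e-10)

    def test_matches_printed_equations_randomly(self, rng):
        alpha, beta = rng.uniform(0.05, 0.5, 2)
        model = cd.build_two_population(cd.TwoPopulationParams(alpha, beta))
        for _ in range(20):
            x, u = rng.uniform(0, 3, 2), rng.uniform(0, 1, 2)
            np.testing.assert_allclose(
                cd.rhs(model, x, u),
                two_population_printed_rhs(alpha, beta, x, u),
                atol=1e-12,
            )


class TestValidation:
    def test_well_formed_model_passes(self, two_pop_model):
        assert cd.validate_model(two_pop_model).ok

    def test_nonzero_D_diagonal_rejected(self):
        D = np.zeros((1, 1, 2, 2))
        D[0, 0, 1, 1] = 0.3
        with pytest.raises(cd.ModelValidationError, match=r"D\^\(0,0\).*diagonal"):
            cd.ControlledODEModel(np.zeros((1, 1)), np.zeros((1, 2)), np.zeros((1, 1, 2)), D)

    def test_upper_triangular_D_rejected(self):
        D = np.zeros((1, 1, 2, 2))
        D[0, 0, 0, 1] = 0.3
        with pytest.raises(cd.ModelValidationError, match="lower triangular"):
            cd.ControlledODEModel(np.zeros((1, 1)), np.zeros((1, 2)), np.zeros((1, 1, 2)), D)

    def test_wrong_C_count_rejected(self):
        with pytest.raises(cd.ModelValidationError):
            cd.ControlledODEModel.from_terms(
                np.eye(2), m=2, C=[np.zeros((2, 2))] * 3
            )

    def test_dimension_mismatch_names_offender(self, two_pop_model):
        with pytest.raises(cd.ModelValidationError, match="control"):
            cd.rhs(two_pop_model, [1.0, 1.0], [0.0, 0.0, 0.0])
        with pytest.raises(cd.ModelValidationError, match="state"):
            cd.rhs(two_pop_model, [1.0], [0.0, 0.0])


class TestInteractionFolding:
    def test_symmetric_spec_folds_to_lower(self):
        full = np.array([[0.0, 0.25], [0.35, 0.0]])
        folded = fold_interaction_matrix(full)
        np.testing.assert_allclose(folded, [[0.0, 0.0], [0.6, 0.0]])

    def test_diagonal_content_errors(self):
        with pytest.raises(cd.ModelValidationError, match="quadratic self-action"):
            fold_interaction_matrix(np.diag([0.0, 1.0]))

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_folded_model_matches_symmetric_specification(self, seed):
        # u' D u is invariant under moving weight between (k,l) and (l,k)
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 5))
        full = rng.uniform(-1, 1, (m, m))
        np.fill_diagonal(full, 0.0)
        folded = fold_interaction_matrix(full)
        u = rng.uniform(0, 1, m)
        assert u @ full @ u == pytest.approx(u @ folded @ u, abs=1e-12)


class TestRescaling:
    def test_rescaled_divides_rates_and_records_scale(self, rng):
        model = random_structured_model(rng)
        k = 2.5
        scaled = model.rescaled(k)
        np.testing.assert_allclose(scaled.A, model.A / k)
        np.testing.assert_allclose(scaled.D, model.D / k)
        assert scaled.time_scale == pytest.approx(k)

    def test_nonpositive_scale_rejected(self, two_pop_model):
        with pytest.raises(cd.ModelValidationError):
            two_pop_model.rescaled(0.0)


class TestNonnegativityDiagnostic:
    def test_roundoff_negativity_warns(self):
        with pytest.warns(RuntimeWarning):
            cd.model.check_state_nonnegative(np.array([1.0, -1e-12]))

    def test_genuine_negativity_raises(self):
        with pytest.raises(cd.ModelValidationError, match="negative"):
            cd.model.check_state_nonnegative(np.array([1.0, -1e-3]))
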