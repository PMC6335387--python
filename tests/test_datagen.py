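"""Generators: item response functions, ability draws, surface-LD rewrite."""

import numpy as np
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import expit

from raschfit.datagen import (
    GeneratingModelSpec,
    ItemParameters,
    ResponseMatrix,
    apply_surface_ld,
    draw_item_difficulties,
    generate,
    items_for_spec,
    response_probabilities,
    simulate_matrix,
)


class TestDrawItemDifficulties:
    def test_seed_contract(self):
        a = draw_item_difficulties(10, np.random.default_rng(7)).beta
        b = draw_item_difficulties(10, np.random.default_rng(7)).beta
        assert np.array_equal(a, b)

    def test_standard_normal_moments(self):
        # pooled draws behave like N(0,1) within 3 standard errors
        rng = np.random.default_rng(0)
        pool = np.concatenate([draw_item_difficulties(10, rng).beta
                               for _ in range(10_000)])
        m = pool.size
        assert abs(pool.mean()) < 3 / np.sqrt(m)
        assert abs(pool.std() - 1) < 3 / np.sqrt(2 * m)

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            draw_item_difficulties(1, np.random.default_rng(0))


class TestResponseProbabilities:
    def test_guessing_lower_asymptote(self):
        spec = GeneratingModelSpec(family="guessing", guess=0.25)
        items = ItemParameters(beta=np.zeros(3), gamma=np.full(3, 0.25))
        p = response_probabilities(spec, items, np.array([-20.0]))
        assert np.allclose(p, 0.25, atol=1e-6)

    def test_perfect_trait_correlation_collapses_to_rasch(self):
        # with r = 1 both traits coincide, so the probability matrix equals
        # the unidimensional one evaluated at the shared trait
        rng = np.random.default_rng(3)
        beta = rng.standard_normal(6)
        dim = np.array([1, 1, 1, 2, 2, 2])
        items = ItemParameters(beta=beta, dimension=dim)
        theta1 = rng.standard_normal(50)
        theta2 = np.column_stack([theta1, theta1])
        p_multi = response_probabilities(
            GeneratingModelSpec(family="multidim", trait_corr=1.0), items, theta2)
        p_rasch = response_probabilities(
            GeneratingModelSpec(family="rasch"), ItemParameters(beta=beta), theta1)
        assert np.allclose(p_multi, p_rasch)

    def test_unit_discrimination_twopl_equals_rasch(self):
        rng = np.random.default_rng(4)
        beta = rng.standard_normal(5)
        theta = rng.standard_normal(40)
        p_2pl = response_probabilities(
            GeneratingModelSpec(family="twopl", log_var=0.0),
            ItemParameters(beta=beta, alpha=np.ones(5)), theta)
        p_rasch = response_probabilities(
            GeneratingModelSpec(family="rasch"), ItemParameters(beta=beta), theta)
        assert np.allclose(p_2pl, p_rasch)

    def test_zero_dif_shift_equals_rasch(self):
        rng = np.random.default_rng(5)
        beta = rng.standard_normal(5)
        theta = rng.standard_normal(40)
        p_mixed = response_probabilities(
            GeneratingModelSpec(family="mixed_rasch"),
            ItemParameters(beta=beta, dif_shift=np.zeros(5)), theta,
            class_member=np.ones(40, dtype=int))
        p_rasch = response_probabilities(
            GeneratingModelSpec(family="rasch"), ItemParameters(beta=beta), theta)
        assert np.allclose(p_mixed, p_rasch)


class TestGenerate:
    def test_marginal_rate_matches_quadrature(self):
        # marginal P(X=1) over N(0,1) abilities by Gauss-Hermite vs simulation
        rng = np.random.default_rng(11)
        items = ItemParameters(beta=np.array([-0.626, 0.184, 1.0]))
        X = generate(GeneratingModelSpec("rasch"), 200_000, items, rng)
        z, w = hermegauss(61)
        w = w / w.sum()
        expected = np.array([w @ expit(z - b) for b in items.beta])
        observed = X.data.mean(axis=0)
        se = np.sqrt(expected * (1 - expected) / X.n_persons)
        assert np.all(np.abs(observed - expected) < 4 * se)

    def test_odd_item_count_rejected_for_multidim(self):
        items = ItemParameters(beta=np.zeros(5),
                               dimension=np.array([1, 1, 1, 2, 2]))
        with pytest.raises(ValueError, match="even"):
            generate(GeneratingModelSpec("multidim"), 10, items,
                     np.random.default_rng(0))

    def test_surface_ld_family_not_generated_directly(self):
        items = ItemParameters(beta=np.zeros(4))
        with pytest.raises(ValueError, match="apply_surface_ld"):
            generate(GeneratingModelSpec("surface_ld"), 10, items,
                     np.random.default_rng(0))

    def test_items_fixed_persons_redrawn(self):
        # one items draw reused over replications gives varying matrices
        spec = GeneratingModelSpec("rasch")
        items = items_for_spec(spec, 6, np.random.default_rng(1))
        rng = np.random.default_rng(2)
        X1 = generate(spec, 50, items, rng)
        X2 = generate(spec, 50, items, rng)
        assert not np.array_equal(X1.data, X2.data)

    def test_items_for_spec_places_surface_ld_difficulties(self):
        items = items_for_spec(GeneratingModelSpec("surface_ld"), 10,
                               np.random.default_rng(8))
        assert items.beta[0] == -0.626 and items.beta[1] == 0.184

    def test_items_for_spec_splits_dimensions_evenly(self):
        items = items_for_spec(GeneratingModelSpec("multidim"), 10,
                               np.random.default_rng(8))
        assert np.array_equal(items.dimension,
                              np.array([1] * 5 + [2] * 5))


class TestApplySurfaceLd:
    @pytest.fixture
    def base(self):
        rng = np.random.default_rng(21)
        items = ItemParameters(beta=np.array([-0.626, 0.184, 0.5]))
        return generate(GeneratingModelSpec("rasch"), 5000, items, rng), rng

    def test_complete_overwrite_removes_pattern(self, base):
        X, rng = base
        Y = apply_surface_ld(X, 0, 1, 1.0, rng)
        assert not np.any((Y.data[:, 1] == 1) & (Y.data[:, 0] == 0))

    def test_never_decreases_and_touches_only_target(self, base):
        X, rng = base
        Y = apply_surface_ld(X, 0, 1, 0.9, rng)
        assert np.all(Y.data >= X.data)
        changed = Y.data != X.data
        assert not np.any(changed[:, 1:])  # only the prerequisite column moves
        rows = np.flatnonzero(changed[:, 0])
        assert np.all((X.data[rows, 1] == 1) & (X.data[rows, 0] == 0))

    def test_same_item_rejected(self, base):
        X, rng = base
        with pytest.raises(ValueError):
            apply_surface_ld(X, 1, 1, 0.9, rng)


class TestResponseMatrixValidation:
    def test_non_binary_entries_rejected(self):
        with pytest.raises(ValueError):
            ResponseMatrix(data=np.array([[0, 2], [1, 0]]))

    def test_labels_must_match_shape(self):
        with pytest.raises(ValueError):
            ResponseMatrix(data=np.eye(2, dtype=int), items=["a"])


def test_simulate_matrix_covers_every_family():
    rng = np.random.default_rng(33)
    for family in ("rasch", "surface_ld", "multidim", "mixed_rasch",
                   "twopl", "guessing"):
        spec = GeneratingModelSpec(family=family)
        items = items_for_spec(spec, 10, rng)
        X = simulate_matrix(spec, 40, items, rng)
        assert X.data.shape == (40, 10)
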