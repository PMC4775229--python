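import numpy as np
import pytest

from adhevo import ModelParams
from adhevo.adaptive_dynamics import (
    SingularLabel,
    analytic_pip,
    critical_bc_ratio_limit,
    find_singular_points,
    invasion_fitness,
    selection_gradient,
    zstar_limit,
    zstar_threshold,
)
from adhevo.aggregation import h_sensitivity


class TestInvasionFitness:
    @pytest.mark.parametrize("variant", ["linear", "size_capped", "diverging_cost"])
    @pytest.mark.parametrize("z_hat", [0.1, 0.5, 0.9])
    def test_resident_vs_itself_is_zero(self, variant, z_hat):
        p = ModelParams(variant=variant)
        assert invasion_fitness(z_hat, z_hat, p) == 0.0

    def test_sign_below_and_above_threshold(self, params):
        # bistable regime: slightly stickier mutants fail below z*, win above
        assert invasion_fitness(0.06, 0.05, params) < 0
        assert invasion_fitness(0.51, 0.50, params) > 0

    def test_local_antisymmetry_near_diagonal(self, params):
        for z_hat in [0.2, 0.5, 0.8]:
            s_up = invasion_fitness(z_hat + 0.005, z_hat, params)
            s_dn = invasion_fitness(z_hat, z_hat + 0.005, params)
            assert np.sign(s_up) == -np.sign(s_dn)


class TestSelectionGradient:
    def test_closed_form_matches_numeric(self, params):
        for z_hat in np.linspace(0.02, 1.0, 25):
            closed = selection_gradient(z_hat, params)
            numeric = selection_gradient(z_hat, params, method="numeric")
            assert closed == pytest.approx(numeric, abs=1e-6)

    def test_approaches_minus_cost_at_low_adhesion(self, params):
        assert selection_gradient(1e-6, params) == pytest.approx(-params.c, abs=1e-3)

    def test_low_benefit_ratio_never_favors_adhesion(self):
        p = ModelParams(b=1.5)
        for z_hat in np.linspace(0.01, 1.0, 40):
            assert selection_gradient(z_hat, p) < 0

    def test_positive_in_bistable_upper_branch(self, params):
        assert selection_gradient(0.5, params) > 0

    def test_sufficient_condition_recruitment_term(self, params):
        # b * z * h(z) > c already guarantees a positive gradient
        for z_hat in np.linspace(0.01, 1.0, 50):
            if params.b * z_hat * h_sensitivity(z_hat, params) > params.c:
                assert selection_gradient(z_hat, params) > 0

    def test_rejects_boundary_resident(self, params):
        with pytest.raises(ValueError):
            selection_gradient(0.0, params)


class TestSingularPoints:
    def test_linear_reference_is_garden_of_eden(self, params):
        points = find_singular_points(params)
        assert len(points) == 1
        (pt,) = points
        assert pt.label is SingularLabel.GARDEN_OF_EDEN
        assert not pt.convergence_stable and not pt.invasible
        assert pt.z_star == pytest.approx(0.080792, abs=1e-4)
        # gradient vanishes at the root
        assert abs(selection_gradient(pt.z_star, params)) < 1e-7

    def test_bistability_structure(self, params):
        z_star = zstar_threshold(params)
        for z in np.linspace(0.01, z_star - 0.005, 10):
            assert selection_gradient(z, params) < 0
        for z in np.linspace(z_star + 0.005, 1.0, 10):
            assert selection_gradient(z, params) > 0

    def test_no_interior_point_below_critical_ratio(self):
        assert find_singular_points(ModelParams(b=1.5)) == []
        assert zstar_threshold(ModelParams(b=1.5)) is None

    def test_size_capped_adds_interior_attractor(self):
        p = ModelParams(variant="size_capped")  # default alpha
        points = find_singular_points(p)
        labels = [pt.label for pt in points]
        assert SingularLabel.GARDEN_OF_EDEN in labels
        css = [pt for pt in points if pt.convergence_stable]
        assert len(css) == 1 and css[0].label is SingularLabel.CSS
        assert points[0].z_star < css[0].z_star < 1

    def test_diverging_cost_adds_interior_attractor(self):
        p = ModelParams(variant="diverging_cost")
        points = find_singular_points(p)
        css = [pt for pt in points if pt.convergence_stable]
        assert len(css) == 1 and css[0].label is SingularLabel.CSS
        assert points[0].z_star < css[0].z_star < 1
        assert not points[0].convergence_stable

    def test_steep_size_cap_turns_attractor_into_branching_point(self):
        # with the cap high in the group-size distribution the attractor is
        # weakly invasible: convergence-stable but not a CSS
        p = ModelParams(variant="size_capped", alpha=0.8)
        css = [pt for pt in find_singular_points(p) if pt.convergence_stable]
        assert len(css) == 1
        assert css[0].label is SingularLabel.BRANCHING_CANDIDATE


class TestThreshold:
    def test_increases_with_patch_size_toward_limit(self):
        z20 = zstar_threshold(ModelParams(T=20))
        z100 = zstar_threshold(ModelParams(T=100))
        z10k = zstar_threshold(ModelParams(T=10_000))
        limit = zstar_limit(20, 1)
        assert z20 < z100 < z10k < limit
        assert limit == pytest.approx(0.1, abs=1e-12)
        assert z10k == pytest.approx(limit, abs=1e-3)

    def test_limit_at_critical_ratio_reaches_boundary(self):
        assert zstar_limit(2.0, 1.0) is None
        assert zstar_limit(2.0 + 1e-9, 1.0) == pytest.approx(1.0, rel=1e-6)

    def test_critical_ratio_is_two(self):
        assert critical_bc_ratio_limit() == pytest.approx(2.0, abs=1e-9)


class TestAnalyticPIP:
    def test_diagonal_is_neutral(self, params):
        grid = np.linspace(0.1, 0.9, 5)
        pip = analytic_pip(grid, grid, params)
        assert np.all(np.diag(pip.sign) == 0)

    def test_single_sign_change_column_near_threshold(self, params):
        residents = np.arange(0.02, 0.2, 0.01)
        signs = [
            np.sign(invasion_fitness(z + 0.005, z, params)) for z in residents
        ]
        flips = np.flatnonzero(np.diff(signs))
        assert len(flips) == 1
        z_star = zstar_threshold(params)
        assert abs(residents[flips[0]] - z_star) < 0.02

    def test_low_ratio_upper_triangle_all_negative(self):
        p = ModelParams(b=1.5)
        grid = np.linspace(0.05, 0.95, 6)
        pip = analytic_pip(grid, grid, p)
        upper = np.triu_indices(6, k=1)  # mutant > resident
        assert np.all(pip.sign.T[upper] == -1)
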