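import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poriaopt.dataset import ResponseTable
from poriaopt.design import build_bbd, default_factor_space
from poriaopt.rsm import (
    AliasingError,
    DesirabilityGoal,
    HierarchyError,
    TermBasis,
    anova_table,
    build_basis,
    composite_desirability,
    desirability,
    fit_rsm,
    goals_from_table,
    modified_cubic_basis,
    optimize_desirability,
    predict,
    quadratic_basis,
    select_terms,
    surface_grid,
)


def synth_table(coefs, basis, names=("Y1",), n_center=5):
    design = build_bbd(default_factor_space(), n_center=n_center)
    M = build_basis(design.coded_matrix, basis)
    Y = M @ np.atleast_2d(coefs).T
    return ResponseTable(
        design=design,
        response_names=tuple(names),
        means=Y,
        sds=np.zeros_like(Y),
    )


class TestBasis:
    def test_quadratic_has_ten_columns(self):
        design = build_bbd(default_factor_space())
        M = build_basis(design.coded_matrix, quadratic_basis())
        assert M.shape == (17, 10)
        assert np.linalg.matrix_rank(M) == 10

    def test_cross_cubic_orthogonal_to_intercept(self):
        design = build_bbd(default_factor_space())
        basis = TermBasis(quadratic_basis().terms + ((0, 0, 1),))
        M = build_basis(design.coded_matrix, basis)
        assert M[:, -1] @ M[:, 0] == 0

    def test_full_cubic_rank_on_bbd(self):
        """All six Xi²Xj orderings give 16 columns but rank ≤ 13 on a BBD."""
        design = build_bbd(default_factor_space())
        M = build_basis(design.coded_matrix, modified_cubic_basis(all_orderings=True))
        assert M.shape[1] == 16
        assert np.linalg.matrix_rank(M) <= 13

    def test_iltj_cubic_alias_identity(self):
        """X1²X3 + X2²X3 equals X3 on every BBD run (the aliasing relation)."""
        coded = build_bbd(default_factor_space()).coded_matrix
        np.testing.assert_array_equal(
            coded[:, 0] ** 2 * coded[:, 2] + coded[:, 1] ** 2 * coded[:, 2],
            coded[:, 2],
        )

    def test_hierarchy_enforced(self):
        with pytest.raises(HierarchyError):
            TermBasis(((), (0, 1)))  # interaction without linear parents
        with pytest.raises(HierarchyError):
            TermBasis(((), (0,), (2,), (0, 0, 2)))  # cross-cubic without X1^2
        with pytest.raises(HierarchyError):
            TermBasis(((0,),))  # no intercept


class TestFit:
    @pytest.mark.parametrize(
        "response,expected",
        [("PA", 422.08), ("TPs", 25.61)],
    )
    @pytest.mark.parametrize("mode", ["quadratic", "auto"])
    def test_center_prediction_equals_center_mean(self, poria, response, expected, mode):
        fit = fit_rsm(poria, response, select_terms(poria, response, mode))
        assert predict(fit, [50.0, 40.0, 40.0]) == pytest.approx(expected, abs=1e-8)

    def test_noiseless_coefficient_recovery(self):
        rng = np.random.default_rng(7)
        basis = TermBasis(quadratic_basis().terms + ((0, 0, 2),))
        coefs = rng.uniform(-5, 5, basis.n_terms)
        t = synth_table(coefs, basis)
        fit = fit_rsm(t, "Y1", basis)
        np.testing.assert_allclose(fit.coefficients, coefs, rtol=1e-8, atol=1e-8)

    def test_matches_statsmodels(self, poria):
        """Production lstsq solver agrees with the statsmodels OLS oracle."""
        sm = pytest.importorskip("statsmodels.api")
        basis = quadratic_basis()
        M = build_basis(poria.design.coded_matrix, basis)
        for resp in ("PA", "T_AOC"):
            ref = sm.OLS(poria.response(resp), M).fit()
            fit = fit_rsm(poria, resp, basis)
            np.testing.assert_allclose(fit.coefficients, ref.params, rtol=1e-8)

    def test_aliased_basis_raises_by_default(self, poria):
        with pytest.raises(AliasingError, match="X"):
            fit_rsm(poria, "PA", modified_cubic_basis())

    def test_alias_drop_preserves_projection(self, poria):
        fit = fit_rsm(poria, "PA", modified_cubic_basis(), on_alias="drop")
        assert fit.n_params == 12
        assert len(fit.dropped_terms) == 1
        # fitted + residuals reconstruct the data
        np.testing.assert_allclose(
            fit.fitted + fit.residuals, poria.response("PA"), atol=1e-9
        )

    def test_fitted_at_design_points_match_predict(self, poria):
        fit = fit_rsm(poria, "TA", quadratic_basis())
        pred = predict(fit, poria.design.actual_matrix)
        np.testing.assert_allclose(pred, fit.fitted, atol=1e-10)

    def test_intercept_theorem_any_hierarchical_basis(self, poria):
        """OLS center prediction equals the center-replicate mean for every
        response under bases containing all quadratic terms."""
        bases = [
            quadratic_basis(),
            TermBasis(quadratic_basis().terms + ((0, 0, 1),)),
            TermBasis(quadratic_basis().terms + ((2, 2, 0),)),
        ]
        for resp in poria.response_names:
            y = poria.response(resp)
            center_mean = y[poria.design.center_mask].mean()
            for basis in bases:
                fit = fit_rsm(poria, resp, basis)
                assert predict(fit, [50, 40, 40]) == pytest.approx(
                    center_mean, abs=1e-8
                ), f"{resp} / {basis.names}"

    def test_r2_nested_monotone(self, poria):
        for resp in ("DA", "TPs"):
            r2 = []
            for basis in (
                quadratic_basis(),
                TermBasis(quadratic_basis().terms + ((0, 0, 2),)),
            ):
                fit = fit_rsm(poria, resp, basis)
                an = anova_table(fit, poria)
                r2.append(an.r_squared)
            assert r2[1] >= r2[0] - 1e-12


class TestAnova:
    def test_ss_decomposition(self, poria):
        for resp in poria.response_names:
            fit = fit_rsm(poria, resp, select_terms(poria, resp, "auto"))
            an = anova_table(fit, poria)
            y = poria.response(resp)
            total = ((y - y.mean()) ** 2).sum()
            assert an.ss_model + an.ss_lack_of_fit + an.ss_pure_error == pytest.approx(
                total, rel=1e-8
            )
            assert an.df_lof + an.df_pe == an.df_residual
            assert 0 <= an.r_squared <= 1

    def test_df_structure_matches_published_layout(self, poria):
        """Auto selection reproduces the uniform 10-model-df ANOVA."""
        for resp in poria.response_names:
            fit = fit_rsm(poria, resp, select_terms(poria, resp, "auto"))
            an = anova_table(fit, poria)
            assert an.df_model == 10
            assert an.df_residual == 6
            assert an.df_pe == 4
            assert an.df_lof == 2

    def test_quadratic_lof_df(self, poria):
        fit = fit_rsm(poria, "PA", quadratic_basis())
        an = anova_table(fit, poria)
        assert an.df_lof == 3  # 13 distinct points - 10 parameters

    def test_perfect_fit_r2_is_one(self):
        basis = quadratic_basis()
        t = synth_table(np.arange(1.0, 11.0), basis)
        fit = fit_rsm(t, "Y1", basis)
        an = anova_table(fit, t)
        assert an.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_lof_not_testable_flag(self, poria):
        # 12-param alias-dropped fit leaves df_lof = 1 (still testable);
        # a 13-distinct-point saturated model is not constructible here, so
        # check the flag logic via the df arithmetic instead
        fit = fit_rsm(poria, "PA", modified_cubic_basis(), on_alias="drop")
        an = anova_table(fit, poria)
        assert an.df_lof == 1
        assert an.lof_testable


class TestDesirability:
    def test_endpoint_values(self):
        g = DesirabilityGoal("y", lower=0.0, upper=10.0)
        assert desirability(0.0, g) == 0.0
        assert desirability(10.0, g) == 1.0
        assert desirability(-5.0, g) == 0.0
        assert desirability(15.0, g) == 1.0
        assert desirability(5.0, g) == pytest.approx(0.5)

    def test_geometric_mean(self):
        goals = [DesirabilityGoal(f"y{i}", 0, 1) for i in range(2)]
        D = composite_desirability(np.array([[1.0, 0.81]]), goals)
        assert D == pytest.approx(0.9)

    def test_any_zero_kills_composite(self):
        goals = [DesirabilityGoal(f"y{i}", 0, 1) for i in range(3)]
        assert composite_desirability(np.array([[0.0, 0.9, 0.9]]), goals) == 0.0

    def test_invalid_goal(self):
        with pytest.raises(ValueError):
            DesirabilityGoal("y", lower=2.0, upper=1.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        y=st.floats(-5, 15, allow_nan=False),
        a=st.floats(0.1, 100, allow_nan=False),
        b=st.floats(-50, 50, allow_nan=False),
    )
    def test_scale_invariance(self, y, a, b):
        """Affinely rescaling a response and its goal leaves d unchanged."""
        g = DesirabilityGoal("y", 0.0, 10.0)
        g2 = DesirabilityGoal("y", b, a * 10.0 + b)
        assert desirability(y, g) == pytest.approx(
            desirability(a * y + b, g2), abs=1e-9
        )


class TestOptimize:
    def test_monotone_single_response_hits_bound(self):
        basis = quadratic_basis()
        coefs = np.zeros(10)
        coefs[0], coefs[3] = 10.0, 5.0  # increasing in X3 only
        t = synth_table(coefs, basis)
        fits = [fit_rsm(t, "Y1", basis)]
        goals = [DesirabilityGoal("Y1", 0.0, 20.0)]
        res = optimize_desirability(fits, goals)
        assert res.x_actual[2] == pytest.approx(60.0, abs=1e-4)

    def test_empty_goals_rejected(self, poria):
        fit = fit_rsm(poria, "PA", quadratic_basis())
        with pytest.raises(ValueError):
            optimize_desirability([fit], [])

    def test_group2_boundary_coordinates(self, poria, group2):
        fits = [
            fit_rsm(poria, m, select_terms(poria, m, "auto")) for m in group2.members
        ]
        res = optimize_desirability(fits, goals_from_table(poria, group2.members))
        assert res.x_actual[0] == pytest.approx(25.0, abs=1e-3)
        assert res.x_actual[2] == pytest.approx(20.0, abs=1e-3)
        assert 0.0 <= res.composite_desirability <= 1.0

    def test_interior_vertex_recovered(self):
        # concave quadratic with known vertex at coded (0.5, -0.25, 0)
        basis = quadratic_basis()
        coefs = np.zeros(10)
        coefs[0] = 50.0
        coefs[1], coefs[4] = 4.0, -4.0  # X1: vertex 0.5
        coefs[2], coefs[5] = -2.0, -4.0  # X2: vertex -0.25
        coefs[6] = -4.0
        t = synth_table(coefs, basis)
        fit = fit_rsm(t, "Y1", basis)
        res = optimize_desirability([fit], [DesirabilityGoal("Y1", 0.0, 51.0)])
        fs = default_factor_space()
        np.testing.assert_allclose(
            (res.x_actual - fs.center) / fs.half_range, [0.5, -0.25, 0.0], atol=1e-4
        )


class TestSurfaceGridAndSelect:
    def test_grid_shape_and_pointwise_agreement(self, poria):
        fit = fit_rsm(poria, "PA", quadratic_basis())
        grid = surface_grid(fit, free=(0, 2), fixed_value=0.0, resolution=21)
        assert len(grid) == 441
        sub = grid.iloc[[0, 220, 440]]
        for _, row in sub.iterrows():
            x = [row["ethanol"], row["time"], row["volume"]]
            assert predict(fit, x) == pytest.approx(row["prediction"], abs=1e-9)

    def test_grid_contains_center_prediction(self, poria):
        fit = fit_rsm(poria, "TPs", quadratic_basis())
        grid = surface_grid(fit, free=(0, 1), fixed_value=0.0, resolution=21)
        center = grid[(grid["ethanol"] == 50.0) & (grid["time"] == 40.0)]
        assert center["prediction"].iloc[0] == pytest.approx(25.61, abs=1e-8)

    def test_select_terms_modes(self, poria):
        assert select_terms(poria, "PA", "quadratic").n_terms == 10
        assert select_terms(poria, "PA", "full_modified_cubic").n_terms == 13
        auto = select_terms(poria, "PA", "auto")
        assert auto.n_terms in (10, 11)

    def test_auto_adds_cubic_on_all_poria_responses(self, poria):
        for resp in poria.response_names:
            assert select_terms(poria, resp, "auto").n_terms == 11

    def test_bad_mode(self, poria):
        with pytest.raises(ValueError):
            select_terms(poria, "PA", "cubic-ish")
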