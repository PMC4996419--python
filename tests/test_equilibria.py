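"""Fixed-point finding, linearization, and bifurcation boundaries."""

import numpy as np
import pytest

from crossfeed.equilibria import (
    bifurcation_scan,
    exclusion_threshold,
    find_equilibria,
    jacobian,
    jacobian_eigen,
    saddle_node_point,
)
from crossfeed.errors import BracketingError
from crossfeed.model import (
    ModelParams,
    PopulationState,
    monoculture_viability_threshold,
    rhs_xy,
)


def residual(pt, params):
    dX, dY = rhs_xy(pt.state.X, pt.state.Y, params)
    return max(abs(dX), abs(dY))


class TestFindEquilibria:
    @pytest.mark.parametrize("a", [0.0, 0.05, 0.09, 0.13, 0.23, 0.5, 0.9])
    def test_all_points_are_fixed_points(self, default_params, a):
        p = default_params.replace(a=a)
        pts = find_equilibria(p)
        assert pts, "origin must always be returned"
        for pt in pts:
            assert residual(pt, p) <= 1e-9

    def test_no_nutrient_leaves_only_stable_origin(self, default_params):
        pts = find_equilibria(default_params.replace(a=0.0))
        assert [pt.kind for pt in pts] == ["origin"]
        origin = pts[0]
        assert origin.stable
        assert np.real(origin.eigenvalues) == pytest.approx([-0.5, -0.5])

    def test_below_fold_no_stable_interior(self, default_params):
        pts = find_equilibria(default_params.replace(a=0.08))
        assert not any(p.kind == "interior" and p.stable for p in pts)
        assert next(p for p in pts if p.kind == "origin").stable

    def test_above_fold_stable_interior_plus_saddle(self, default_params):
        pts = find_equilibria(default_params.replace(a=0.09))
        interior = [p for p in pts if p.kind == "interior"]
        assert len(interior) == 2
        assert sorted(p.stable for p in interior) == [False, True]

    def test_interior_count_across_regimes(self, default_params):
        # two interior points in the obligate window, one after the saddle
        # merges with the X axis at the viability threshold, none beyond
        # exclusion
        count = {
            a: sum(p.kind == "interior" for p in
                   find_equilibria(default_params.replace(a=a)))
            for a in (0.05, 0.10, 0.13, 0.5, 0.9)
        }
        assert count == {0.05: 0, 0.10: 2, 0.13: 1, 0.5: 1, 0.9: 0}


class TestJacobian:
    def test_origin_eigenvalues_closed_form(self, default_params):
        # at the origin the Jacobian is diagonal: r * a/(a+kappa) - delta
        p = default_params.replace(a=0.13)
        _, w, _ = jacobian_eigen(PopulationState(0, 0), p)
        assert np.real(w) == pytest.approx([0.02, -0.019], abs=1e-12)

    @pytest.mark.parametrize("a, c", [(0.09, 1.0), (0.3, 1.0), (0.2, 0.6)])
    @pytest.mark.parametrize("X, Y", [(0.2, 0.3), (0.05, 0.0), (0.4, 0.4)])
    def test_matches_finite_differences(self, default_params, a, c, X, Y):
        p = default_params.replace(a=a, c=c)
        J = jacobian(X, Y, p)
        h = 1e-6
        num = np.empty((2, 2))
        for j, (dx, dy) in enumerate([(h, 0.0), (0.0, h)]):
            up = rhs_xy(X + dx, Y + dy, p)
            dn = rhs_xy(X - dx, Y - dy, p)
            num[0, j] = (up[0] - dn[0]) / (2 * h)
            num[1, j] = (up[1] - dn[1]) / (2 * h)
        assert J == pytest.approx(num, abs=1e-4)

    def test_eigen_ordering_and_unit_norm(self, default_params):
        p = default_params.replace(a=0.2)
        pts = [q for q in find_equilibria(p) if q.kind == "interior" and q.stable]
        _, w, V = jacobian_eigen(pts[0].state, p)
        assert np.real(w[0]) >= np.real(w[1])  # slow (closest to 0) first
        assert np.linalg.norm(V, axis=0) == pytest.approx([1.0, 1.0])


class TestBifurcationBoundaries:
    def test_saddle_node_in_reference_bracket(self, saddle_node_a):
        assert 0.08 < saddle_node_a < 0.09

    def test_slow_eigenvalue_vanishes_at_fold(self, default_params, saddle_node_a):
        pts = [
            q
            for q in find_equilibria(default_params.replace(a=saddle_node_a + 2e-8))
            if q.kind == "interior" and q.stable
        ]
        assert abs(np.real(pts[0].slow_eigenvalue)) < 1e-2

    def test_exclusion_threshold_in_reference_bracket(self, exclusion_a):
        assert 0.23 < exclusion_a < 0.9

    def test_interior_y_vanishes_continuously_at_exclusion(
        self, default_params, exclusion_a
    ):
        below = [
            q
            for q in find_equilibria(default_params.replace(a=exclusion_a - 1e-6))
            if q.kind == "interior" and q.stable
        ]
        assert below and below[0].state.Y < 1e-3
        above = [
            q
            for q in find_equilibria(default_params.replace(a=exclusion_a + 1e-6))
            if q.kind == "interior" and q.stable
        ]
        assert not above

    def test_thresholds_invariant_under_grid_refinement(self, default_params,
                                                        saddle_node_a):
        coarse = saddle_node_point(default_params, n_grid=3000)
        assert coarse == pytest.approx(saddle_node_a, abs=1e-6)

    def test_no_fold_without_death(self, default_params):
        with pytest.raises(BracketingError):
            saddle_node_point(default_params.replace(delta=0.0), bracket=(0.01, 1.0))

    def test_symmetric_strains_never_exclude(self, default_params):
        sym = default_params.replace(r_y=1.0, beta=1.0)
        with pytest.raises(BracketingError):
            exclusion_threshold(sym, bracket=(0.23, 0.9))


@pytest.fixture(scope="module")
def diagram(default_params):
    return bifurcation_scan(
        default_params, np.arange(0.02, 1.0001, 0.02), n_grid=4000, tol=1e-7
    )


class TestBifurcationScan:

    def test_boundaries_present_and_ordered(self, diagram):
        b = diagram.boundaries
        assert set(b) == {"saddle_node", "x_viability", "y_viability", "exclusion"}
        assert b["saddle_node"] < b["x_viability"] < b["y_viability"] < b["exclusion"]

    def test_viability_boundaries_match_closed_form(self, diagram, default_params):
        assert diagram.boundaries["x_viability"] == pytest.approx(
            monoculture_viability_threshold(default_params, "x"), abs=1e-6
        )
        assert diagram.boundaries["y_viability"] == pytest.approx(
            monoculture_viability_threshold(default_params, "y"), abs=1e-6
        )

    def test_tidy_export(self, diagram, tmp_path):
        path = tmp_path / "diagram.csv"
        diagram.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["a", "kind", "X", "Y", "stable",
                                    "eig_slow", "eig_fast"]
        assert len(df) == sum(len(p) for p in diagram.points)

    def test_grid_below_fold_has_no_interior(self, default_params):
        d = bifurcation_scan(default_params, np.linspace(0.01, 0.07, 5), n_grid=2000)
        assert all(p.kind != "interior" for pts in d.points for p in pts)
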