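"""Trajectories, the daily-dilution map, fate grids and relaxation geometry."""

import math

import numpy as np
import pytest

from crossfeed.dynamics import (
    DEFAULT_T_DAY,
    batch_dilution_map,
    batch_equilibrium,
    fate_grid,
    integrate_continuous,
    relaxation_diagnostics,
    run_batch_protocol,
)
from crossfeed.equilibria import find_equilibria
from crossfeed.errors import CrossfeedError
from crossfeed.model import ModelParams, PopulationState


def stable_interior(params):
    return [
        p for p in find_equilibria(params) if p.kind == "interior" and p.stable
    ][0]


class TestContinuous:
    def test_zero_initial_stays_zero(self, default_params):
        traj = integrate_continuous(
            default_params.replace(a=0.2), PopulationState(0, 0), t_end=10
        )
        assert np.all(traj.X == 0) and np.all(traj.Y == 0)

    def test_below_fold_everything_dies(self, default_params):
        traj = integrate_continuous(
            default_params.replace(a=0.08), PopulationState(0.3, 0.3), t_end=500
        )
        assert traj.terminal_fate == "extinction"

    def test_coexistence_fate_and_simplex_invariance(self, default_params):
        traj = integrate_continuous(
            default_params.replace(a=0.23), PopulationState(0.45, 0.45), t_end=300
        )
        assert traj.terminal_fate == "coexistence"
        assert np.all(traj.n <= 1 + 1e-9)
        assert np.all(traj.X >= 0) and np.all(traj.Y >= 0)

    def test_high_supplementation_excludes_slower_strain(self, default_params):
        traj = integrate_continuous(
            default_params.replace(a=1.5), PopulationState(0.3, 0.3), t_end=800
        )
        assert traj.terminal_fate == "exclusion_y"

    def test_relaxation_rate_matches_slow_eigenvalue(self, default_params):
        """Log-distance decay toward a stable point follows its slow mode."""
        p = default_params.replace(a=0.2)
        eq = stable_interior(p)
        v = np.real(eq.slow_eigenvector)
        x0 = PopulationState(eq.state.X + 0.01 * v[0], eq.state.Y + 0.01 * v[1])
        traj = integrate_continuous(p, x0, t_end=60, dt_out=0.5)
        d = np.hypot(traj.X - eq.state.X, traj.Y - eq.state.Y)
        mask = (traj.t > 20) & (d > 1e-12)
        slope = np.polyfit(traj.t[mask], np.log(d[mask]), 1)[0]
        assert slope == pytest.approx(np.real(eq.slow_eigenvalue), rel=0.05)

    def test_trajectory_frame_schema(self, default_params, tmp_path):
        import pandas as pd

        traj = integrate_continuous(
            default_params.replace(a=0.2), PopulationState(0.1, 0.1), t_end=5
        )
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["t", "X", "Y", "n", "f"]


class TestBatchMap:
    def test_zero_state_is_fixed(self, default_params):
        st = batch_dilution_map(default_params.replace(a=0.2),
                                PopulationState(0, 0))
        assert (st.X, st.Y) == (0.0, 0.0)

    def test_no_growth_shrinks_by_dilution_exactly(self, default_params):
        st = batch_dilution_map(default_params.replace(a=0.0),
                                PopulationState(0.05, 0.0), dilution_factor=10)
        assert st.X == pytest.approx(0.005, rel=1e-9)

    def test_saturated_monoculture_persists_across_days(self, default_params):
        # ample nutrient allows more than the log2(10) ~ 3.3 doublings per
        # day needed to beat the dilution
        p = default_params.replace(a=5.0)
        track = run_batch_protocol(p, PopulationState(0.02, 0.0), days=8)
        assert track[-1].X > 0.5

    def test_day_length_supports_required_doublings(self, default_params):
        # capacity at saturation: t_day * r_x / ln 2 doublings
        capacity = DEFAULT_T_DAY * default_params.r_x / math.log(2)
        assert capacity > math.log2(10)

    def test_batch_equilibrium_matches_continuous_regime(self, default_params):
        """The daily map with matched effective death rate reproduces the
        continuous model's qualitative outcome."""
        # coexistence window
        eq = batch_equilibrium(default_params.replace(a=0.2),
                               PopulationState(0.1, 0.1))
        assert eq.X > 0.05 and eq.Y > 0.05
        # below the fold
        eq = batch_equilibrium(default_params.replace(a=0.05),
                               PopulationState(0.1, 0.1))
        assert eq.n < 1e-6


class TestFateGrid:
    def test_all_extinct_below_fold(self, default_params):
        fg = fate_grid(default_params.replace(a=0.08), [0.05, 0.2], [0.5, 1.0],
                       t_end=600)
        assert set(fg["fate"]) == {"extinction"}

    def test_all_coexist_in_competition_window(self, default_params):
        fg = fate_grid(default_params.replace(a=0.23), [0.05, 0.2], [0.5, 2.0],
                       t_end=600)
        assert set(fg["fate"]) == {"coexistence"}

    def test_balanced_cultures_survive_at_lower_density_near_fold(
        self, default_params
    ):
        """Just above the fold, survival demands both size and balance."""
        fg = fate_grid(default_params.replace(a=0.084),
                       [0.02, 0.05, 0.1, 0.2, 0.4], [1.0, 100.0], t_end=600)
        surv = fg[fg["fate"] == "coexistence"]
        min_n_balanced = surv[surv["f0"] == 1.0]["n0"].min()
        imb = surv[surv["f0"] == 100.0]["n0"]
        min_n_imbalanced = imb.min() if len(imb) else np.inf
        assert min_n_balanced < min_n_imbalanced


class TestRelaxationDiagnostics:
    def test_near_fold_total_density_is_slow(self, default_params, saddle_node_a):
        d = relaxation_diagnostics(default_params.replace(a=saddle_node_a + 0.002))
        assert d["align_constant_f"] > 0.95
        assert d["timescale_ratio"] > 1.0

    def test_near_exclusion_ratio_is_slow(self, default_params, exclusion_a):
        d = relaxation_diagnostics(default_params.replace(a=exclusion_a - 0.002))
        assert d["align_constant_n"] > 0.95

    def test_midrange_has_no_dominant_direction(self, default_params):
        d = relaxation_diagnostics(default_params.replace(a=0.12))
        assert d["timescale_ratio"] < 3.0

    def test_requires_stable_interior(self, default_params):
        with pytest.raises(CrossfeedError):
            relaxation_diagnostics(default_params.replace(a=0.05))
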