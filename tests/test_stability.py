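import numpy as np
import pytest

from rmdyn.params import ExternalParams, InternalParams
from rmdyn.pcr_model import c_dynamics_rhs, c_dynamics_rhs_derivative
from rmdyn.stability import (
    bifurcation_diagram,
    bistable_region_area,
    cusp_surface,
    fold_interval,
    is_bistable,
    stability_boundary,
    steady_states,
)


def count_roots_dense(external, internal, n=100_000):
    """Independent root count: sign changes of the rhs on a dense grid."""
    upper = external.r * (external.s + 1)
    grid = np.linspace(upper * 1e-9, upper, n)
    vals = c_dynamics_rhs(grid, external, internal)
    return int(np.sum(np.sign(vals[:-1]) != np.sign(vals[1:])))


class TestSteadyStates:
    def test_origin_root_without_leakage(self, esp):
        sset = steady_states(ExternalParams(s=0.0, r=5.0), esp.internal)
        assert sset.roots[0].c_total == 0.0

    def test_three_roots_with_alternating_stability(self, esp, boundaries):
        lo, hi = fold_interval(0.02, boundaries["esp1396i"])
        ext = ExternalParams(s=0.02, r=float(np.sqrt(lo * hi)))
        sset = steady_states(ext, esp.internal)
        assert len(sset) == 3 and not sset.degenerate
        assert [r.stable for r in sset.roots] == [True, False, True]
        assert np.all(np.diff(sset.c_values) > 0)
        # dense-grid sign-change oracle agrees
        assert count_roots_dense(ext, esp.internal) == 3

    def test_monostable_at_high_leakage(self, esp):
        for r in np.geomspace(0.05, 500, 40):
            sset = steady_states(ExternalParams(s=0.08, r=float(r)), esp.internal)
            assert len(sset) == 1 and sset.roots[0].stable

    def test_roots_satisfy_rhs_zero(self, ahdi, boundaries):
        lo, hi = fold_interval(0.0043, boundaries["ahdi"])
        ext = ExternalParams(s=0.0043, r=float(np.sqrt(lo * hi)))
        for root in steady_states(ext, ahdi.internal).roots:
            assert abs(c_dynamics_rhs(root.c_total, ext, ahdi.internal)) < 1e-10


class TestStabilityBoundary:
    def test_fold_conditions_hold_along_curve(self, esp, boundaries):
        b = boundaries["esp1396i"]
        for i in range(0, len(b.c_total), 97):
            ext = ExternalParams(s=max(b.s_curve[i], 0.0), r=b.r_curve[i])
            if b.s_curve[i] < 0:  # unphysical tail of the parametric curve
                continue
            assert abs(c_dynamics_rhs(b.c_total[i], ext, esp.internal)) < 1e-10
            assert abs(c_dynamics_rhs_derivative(b.c_total[i], ext, esp.internal)) < 1e-8

    def test_cusp_is_interior_maximum(self, boundaries):
        for b in boundaries.values():
            assert 0 < b.cusp_index < len(b.s_curve) - 1
            assert b.s_max == np.max(b.s_curve)
            assert np.all(b.r_curve > 0)

    def test_esp_bistability_bound_near_five_percent(self, boundaries):
        assert boundaries["esp1396i"].s_max == pytest.approx(0.05, rel=0.2)

    def test_fold_interval_none_above_cusp(self, boundaries):
        b = boundaries["esp1396i"]
        assert fold_interval(b.s_max * 1.01, b) is None
        assert fold_interval(0.0, b) is None
        lo, hi = fold_interval(b.s_max * 0.5, b)
        assert 0 < lo < hi

    def test_grid_size_validated(self, esp):
        with pytest.raises(ValueError):
            stability_boundary(esp.internal, grid_size=10)

    @pytest.mark.parametrize(
        "internal",
        [
            InternalParams(p=25, omega=130, alpha=16.9),
            InternalParams(p=8.0, omega=40.0, alpha=3.0),
            InternalParams(p=60.0, omega=500.0, alpha=30.0),
        ],
        ids=["esp1396i", "random-a", "random-b"],
    )
    def test_boundary_matches_brute_force_root_counts(self, internal):
        """Parametric wedge classification equals exhaustive root counting.

        One-cell tolerance at the curve: a mismatching grid point must have
        a neighbour with the opposite classification (i.e. sit on the
        boundary at grid resolution).
        """
        b = stability_boundary(internal)
        r_grid = np.geomspace(0.5, 30, 40)
        s_grid = np.geomspace(1e-3, 0.2, 40)
        inside = np.zeros((len(s_grid), len(r_grid)), dtype=bool)
        multi = np.zeros_like(inside)
        for j, s in enumerate(s_grid):
            for k, r in enumerate(r_grid):
                inside[j, k] = is_bistable(float(r), float(s), b)
                multi[j, k] = (
                    len(steady_states(ExternalParams(s=float(s), r=float(r)), internal, n_grid=600))
                    == 3
                )
        mismatch = inside != multi
        if np.any(mismatch):
            for j, k in zip(*np.nonzero(mismatch)):
                neighbours = [
                    inside[jj, kk]
                    for jj, kk in (
                        (j - 1, k), (j + 1, k), (j, k - 1), (j, k + 1)
                    )
                    if 0 <= jj < inside.shape[0] and 0 <= kk < inside.shape[1]
                ]
                assert len(set(neighbours)) > 1, (
                    f"classification mismatch away from the boundary at "
                    f"s={s_grid[j]:.4g}, r={r_grid[k]:.4g}"
                )


class TestBifurcationDiagram:
    def test_bistable_band_structure(self, esp, boundaries):
        diagram = bifurcation_diagram(
            0.02, esp.internal, np.geomspace(0.5, 20, 80), boundary=boundaries["esp1396i"]
        )
        assert diagram.fold_interval is not None
        lo, hi = diagram.fold_interval
        counts = diagram.table.groupby("r").size()
        for r, count in counts.items():
            if lo * 1.02 < r < hi * 0.98:
                assert count == 3
            elif r < lo * 0.98 or r > hi * 1.02:
                assert count == 1

    def test_monostable_leakage_has_no_fold(self, esp, boundaries):
        diagram = bifurcation_diagram(
            0.08, esp.internal, np.geomspace(0.5, 20, 30), boundary=boundaries["esp1396i"]
        )
        assert diagram.fold_interval is None
        assert diagram.table.groupby("r").size().max() == 1

    def test_hysteresis_state_following(self, esp, boundaries):
        """Sweeping r up and down jumps at the two fold radii."""
        b = boundaries["esp1396i"]
        lo, hi = fold_interval(0.02, b)
        r_grid = np.geomspace(lo * 0.5, hi * 2.0, 400)
        state = None
        jump_up = None
        for r in r_grid:  # upward sweep follows the low branch
            stable = sorted(
                steady_states(ExternalParams(s=0.02, r=float(r)), esp.internal).stable_values
            )
            if state is None:
                state = stable[0]
            nearest = min(stable, key=lambda x: abs(x - state))
            if nearest > state * 3:
                jump_up = r
            state = nearest
        assert jump_up == pytest.approx(hi, rel=0.05)
        state, jump_down = None, None
        for r in r_grid[::-1]:  # downward sweep follows the high branch
            stable = sorted(
                steady_states(ExternalParams(s=0.02, r=float(r)), esp.internal).stable_values
            )
            if state is None:
                state = stable[-1]
            nearest = min(stable, key=lambda x: abs(x - state))
            if nearest < state / 3:
                jump_down = r
            state = nearest
        assert jump_down == pytest.approx(lo, rel=0.05)


class TestCuspSurface:
    def test_sheet_counts_match_regions(self, ahdi, boundaries):
        b = boundaries["ahdi"]
        r_grid = np.geomspace(2, 15, 12)
        s_grid = np.geomspace(1e-3, 0.05, 12)
        surf = cusp_surface(ahdi.internal, r_grid, s_grid, boundary=b)
        for j, s in enumerate(s_grid):
            for k, r in enumerate(r_grid):
                n_sheets = int(np.sum(np.isfinite(surf.sheets[:, j, k])))
                if is_bistable(float(r), float(s), b):
                    assert n_sheets == 3
        # monostable cells have exactly one sheet
        mono = [
            int(np.sum(np.isfinite(surf.sheets[:, j, k])))
            for j, s in enumerate(s_grid)
            for k, r in enumerate(r_grid)
            if not is_bistable(float(r), float(s), b)
            and fold_interval(float(s), b) is None
        ]
        assert mono and all(c == 1 for c in mono)

    def test_surface_consistent_with_bifurcation_slice(self, esp, boundaries):
        b = boundaries["esp1396i"]
        r_grid = np.geomspace(1, 10, 15)
        surf = cusp_surface(esp.internal, r_grid, np.array([0.02]), boundary=b)
        diagram = bifurcation_diagram(0.02, esp.internal, r_grid, boundary=b)
        for k, r in enumerate(r_grid):
            roots = np.sort(diagram.table.loc[diagram.table.r == r, "c_total"].values)
            sheet_vals = surf.sheets[:, 0, k]
            finite = np.sort(sheet_vals[np.isfinite(sheet_vals)])
            np.testing.assert_allclose(finite, roots, atol=1e-8)


class TestBistableArea:
    def test_monotone_in_window(self, esp, boundaries):
        b = boundaries["esp1396i"]
        a1 = bistable_region_area(esp.internal, 10, boundary=b)
        a2 = bistable_region_area(esp.internal, 50, boundary=b)
        assert 0 < a1 <= a2

    def test_zero_below_cusp_with_warning(self, esp, boundaries):
        b = boundaries["esp1396i"]
        with pytest.warns(UserWarning):
            assert bistable_region_area(esp.internal, b.cusp[0] * 0.5, boundary=b) == 0.0

    def test_system_ordering(self, esp, ahdi, ecorv, boundaries):
        areas = {
            name: bistable_region_area(preset.internal, 50, boundary=boundaries[name])
            for name, preset in (("ecorv", ecorv), ("esp1396i", esp), ("ahdi", ahdi))
        }
        assert areas["ecorv"] > areas["esp1396i"] > areas["ahdi"]

    def test_cooperativity_shrinks_and_dbs_strength_grows_area(self, esp, boundaries):
        base = bistable_region_area(esp.internal, 50, boundary=boundaries["esp1396i"])
        half_omega = bistable_region_area(InternalParams(p=25, omega=65, alpha=16.9), 50)
        double_p = bistable_region_area(InternalParams(p=50, omega=130, alpha=16.9), 50)
        double_omega = bistable_region_area(InternalParams(p=25, omega=260, alpha=16.9), 50)
        assert half_omega > base
        assert double_p > base
        assert double_omega < base
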