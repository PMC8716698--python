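"""Grid pore-area algorithm: occupancy counting and rupture detection."""

import numpy as np
import pandas as pd
import pytest

from sapfilm import (
    Frame,
    GridSpec,
    PoreSeries,
    SyntheticTrajectory,
    build_grid,
    detect_rupture,
    pore_area_series,
    pore_fraction,
    select_headgroup_positions,
)


def brute_force_pore_fraction(positions, M, spacing):
    """Independent oracle: nearest grid node by explicit distance argmin."""
    nodes = np.arange(M) * spacing
    occupied = set()
    for x, y in positions:
        i = int(np.argmin(np.abs(nodes - x)))
        j = int(np.argmin(np.abs(nodes - y)))
        occupied.add((i, j))
    return 1.0 - len(occupied) / M**2


class TestHeadgroupSelection:
    def test_synthetic_frame_is_identity(self):
        frame = Frame(time=0.0, positions=[[1.0, 2.0], [3.0, 4.0]], h_xy=18.0, h_z=60.0)
        np.testing.assert_array_equal(select_headgroup_positions(frame, "glycolipid"), frame.positions)

    def test_phospholipid_selects_p_and_n(self):
        atoms = pd.DataFrame(
            {
                "name": ["P8", "N4", "C1", "O2"] * 280,
                "x": np.arange(1120, dtype=float),
                "y": np.arange(1120, dtype=float),
            }
        )
        out = select_headgroup_positions(atoms, "phospholipid")
        assert len(out) == 560  # one P and one N per lipid

    def test_glycolipid_selects_oxygens(self):
        atoms = pd.DataFrame({"name": ["OA1", "OB2", "C3"], "x": [0.0, 1.0, 2.0], "y": [0.0] * 3})
        assert len(select_headgroup_positions(atoms, "glycolipid")) == 2

    def test_empty_selection_names_lipid_type(self):
        atoms = pd.DataFrame({"name": ["C1", "C2"], "x": [0.0, 1.0], "y": [0.0, 1.0]})
        with pytest.raises(ValueError, match="phospholipid"):
            select_headgroup_positions(atoms, "phospholipid")


class TestBuildGrid:
    @pytest.mark.parametrize(
        "n_atoms, box, offset_fraction, M, spacing",
        [
            (576, 18.0, 0.0, 24, 0.75),
            (1, 7.0, 0.0, 1, 7.0),
            (560, 18.0, 0.01, 24, (18.0 - 2 * 0.18) / 24),
        ],
    )
    def test_rounding_rule(self, n_atoms, box, offset_fraction, M, spacing):
        grid = build_grid(n_atoms, box, offset_fraction)
        assert grid.M == M
        assert grid.spacing == pytest.approx(spacing)

    def test_rejects_large_offset(self):
        with pytest.raises(ValueError):
            build_grid(100, 10.0, 0.5)


class TestPoreFraction:
    def test_single_occupied_cell(self):
        grid = GridSpec(M=4, spacing=1.0, offset=0.0)
        positions = np.tile([[1.2, 2.1]], (16, 1))
        assert pore_fraction(positions, grid, 4.0) == pytest.approx(15 / 16)

    def test_full_coverage_gives_zero(self):
        M, spacing = 5, 1.0
        grid = GridSpec(M=M, spacing=spacing, offset=0.0)
        xx, yy = np.meshgrid(np.arange(M) * spacing, np.arange(M) * spacing)
        positions = np.column_stack([xx.ravel(), yy.ravel()])
        assert pore_fraction(positions, grid, M * spacing) == 0.0

    def test_empty_positions_warn_all_water(self):
        grid = GridSpec(M=4, spacing=1.0, offset=0.0)
        with pytest.warns(UserWarning):
            assert pore_fraction(np.empty((0, 2)), grid, 4.0) == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(50, 600))
            box = float(rng.uniform(10, 25))
            grid = build_grid(n, box, offset_fraction=0.0)
            positions = rng.uniform(0, box, size=(n, 2))
            expected = brute_force_pore_fraction(positions, grid.M, grid.spacing)
            assert pore_fraction(positions, grid, box) == expected

    def test_translation_by_grid_period_is_invariant(self):
        rng = np.random.default_rng(5)
        box, n = 14.0, 196
        grid = build_grid(n, box, offset_fraction=0.0)
        # put every atom in the lower half of its cell so no wrapped image
        # ever lands in the clip zone past the last node
        cells = rng.integers(0, grid.M, size=(n, 2))
        positions = (cells + rng.uniform(0, 0.45, size=(n, 2))) * grid.spacing
        base = pore_fraction(positions, grid, box)
        shifted = np.mod(positions + 3 * grid.spacing, box)
        assert pore_fraction(shifted, grid, box) == base

    def test_adding_an_atom_never_opens_a_pore(self):
        rng = np.random.default_rng(8)
        box = 10.0
        grid = build_grid(100, box, offset_fraction=0.0)
        positions = rng.uniform(0, box, size=(100, 2))
        f0 = pore_fraction(positions, grid, box)
        for _ in range(20):
            extra = np.vstack([positions, rng.uniform(0, box, size=(1, 2))])
            assert pore_fraction(extra, grid, box) <= f0

    def test_truncation_mode_differs_from_rounding(self):
        grid = GridSpec(M=4, spacing=1.0, offset=0.0)
        positions = np.array([[2.7, 0.0]])  # rounds to 3, truncates to 2
        r = pore_fraction(positions, grid, 4.0, mode="round")
        t = pore_fraction(positions, grid, 4.0, mode="truncate")
        assert r == t  # same *count*, different cell
        scaled = np.array([[2.7, 0.0], [3.0, 0.0]])
        assert pore_fraction(scaled, grid, 4.0, mode="round") == pytest.approx(15 / 16)
        assert pore_fraction(scaled, grid, 4.0, mode="truncate") == pytest.approx(14 / 16)


class TestPoreAreaSeries:
    def test_static_trajectory_gives_constant_series(self):
        rng = np.random.default_rng(0)
        positions = rng.uniform(0, 18, size=(276, 2))
        frames = [Frame(time=10.0 * k, positions=positions, h_xy=18.0, h_z=60.0) for k in range(5)]
        traj = SyntheticTrajectory(
            frames=frames, external_pressure=-1.0, lipid_mode="glycolipid",
            n_lipids_per_monolayer=276, seed=0,
        )
        series = pore_area_series(traj)
        assert np.ptp(series.pore_fraction) == 0.0

    def test_inconsistent_atom_counts_rejected(self):
        frames = [
            Frame(time=0.0, positions=np.zeros((4, 2)), h_xy=5.0, h_z=10.0),
            Frame(time=1.0, positions=np.zeros((5, 2)), h_xy=5.0, h_z=10.0),
        ]
        traj = SyntheticTrajectory(
            frames=frames, external_pressure=-1.0, lipid_mode="glycolipid",
            n_lipids_per_monolayer=4, seed=0,
        )
        with pytest.raises(ValueError, match="inconsistent"):
            pore_area_series(traj)

    def test_pore_area_grows_before_rupture(self, glycolipid_runs):
        traj = glycolipid_runs[-3.5]
        series = pore_area_series(traj)
        cut = np.searchsorted(series.times, traj.rupture_time)
        pre = series.pore_fraction[:cut]
        q = len(pre) // 4
        assert pre[-q:].mean() > pre[:q].mean()

    def test_phospholipid_equilibrium_coverage(self, phospholipid_run):
        series = pore_area_series(phospholipid_run)
        assert series.pore_fraction.mean() == pytest.approx(0.23, abs=0.05)

    def test_fixed_grid_policy_sees_expansion_as_exposure(self, glycolipid_runs):
        traj = glycolipid_runs[-3.5]
        fixed = pore_area_series(traj, grid_policy="fixed_first_frame")
        per_frame = pore_area_series(traj, grid_policy="per_frame")
        # under a frozen grid the affine expansion itself vacates cells
        assert fixed.pore_fraction[-1] >= per_frame.pore_fraction[-1]


class TestDetectRupture:
    def _series(self, fractions, dt=100.0):
        n = len(fractions)
        return PoreSeries(
            times=np.arange(n) * dt,
            pore_fraction=np.asarray(fractions),
            grid=GridSpec(M=17, spacing=1.0, offset=0.0),
        )

    def test_first_crossing_is_reported(self):
        fractions = np.concatenate([np.linspace(0, 0.09, 120), np.linspace(0.11, 0.5, 20)])
        series = self._series(fractions)
        event = detect_rupture(series, threshold=0.10, min_consecutive=1)
        assert event.time == pytest.approx(12_000.0)
        assert event.pore_fraction_at_event >= 0.10

    def test_bounded_series_has_no_event(self):
        assert detect_rupture(self._series(np.full(50, 0.05))) is None

    def test_single_spike_is_debounced(self):
        fractions = np.full(60, 0.04)
        fractions[30] = 0.2
        assert detect_rupture(self._series(fractions), min_consecutive=3) is None
        spike = detect_rupture(self._series(fractions), min_consecutive=1)
        assert spike.time == pytest.approx(3000.0)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            detect_rupture(self._series([]))
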