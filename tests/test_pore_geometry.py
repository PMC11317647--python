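"""Maximal-inscribed-sphere profiles and SF-geometry statistics."""

import numpy as np
import pytest

from permkit.core import PoreSpec
from permkit.pore_geometry import (
    DistanceSeries,
    combine_profiles,
    mean_radius_profile,
    min_pair_distance,
    pair_distance_distribution,
    radius_profile,
)
from permkit.synthetic import build_toy_pore

from conftest import make_topology, make_traj
from oracles import min_image_27


def _profile_on_truth(traj, truth, z_lo, z_hi, z_step=1.0, seed=0):
    fr = traj.frames[0]
    idx = np.arange(traj.n_atoms)
    off = truth["z_offset"]
    z, r, fl = radius_profile(
        fr, idx, traj.topology.elements, truth["axis_xy"],
        (z_lo + off, z_hi + off), z_step=z_step,
        vdw_table=truth["vdw_table"], seed=seed,
    )
    return z - off, r, fl


class TestRadiusProfile:
    def test_two_atoms_straddling_axis(self):
        """Two r=1.5 Å atoms 8 Å apart across the axis leave a 2.5 Å sphere."""
        top = make_topology(["X", "X"], elements=["X", "X"])
        traj = make_traj([np.array([[21.0, 25.0, 25.0], [29.0, 25.0, 25.0]])],
                         top)
        # an open two-atom geometry bounds the probe only on the axis itself,
        # so the centre search is pinned there (search_radius=0)
        z, r, _ = radius_profile(
            traj.frames[0], np.array([0, 1]), traj.topology.elements,
            (25.0, 25.0), (25.0, 25.0), z_step=1.0,
            vdw_table={"X": 1.5}, seed=1, search_radius=0.0)
        assert r[0] == pytest.approx(2.5, abs=0.02)

    def test_constant_toy_pore_recovered(self):
        traj, truth = build_toy_pore(lambda z: 3.5, z_range=(-6, 6))
        z, r, _ = _profile_on_truth(traj, truth, -4, 4)
        expected = truth["analytic_radius"](z)
        np.testing.assert_allclose(r, expected, atol=0.05)

    def test_hourglass_minimum_located_at_constriction(self):
        traj, truth = build_toy_pore(
            lambda z: 1.0 + 0.06 * z * z, z_range=(-8, 8))
        z, r, _ = _profile_on_truth(traj, truth, -6, 6, z_step=0.5)
        assert z[np.argmin(r)] == pytest.approx(0.0, abs=0.51)
        np.testing.assert_allclose(r, truth["analytic_radius"](z), atol=0.05)

    def test_empty_slice_returns_cap_and_flag(self):
        top = make_topology(["X"], elements=["X"])
        traj = make_traj([np.array([[25.0, 25.0, 5.0]])], top)
        z, r, fl = radius_profile(
            traj.frames[0], np.array([0]), traj.topology.elements,
            (25.0, 25.0), (40.0, 40.0), z_step=1.0, vdw_table={"X": 1.5})
        assert r[0] == 10.0 and fl[0]

    def test_invariant_under_rotation_about_axis(self):
        traj, truth = build_toy_pore(
            lambda z: 2.0 + 0.1 * abs(z), z_range=(-5, 5), n_per_ring=17)
        z0, r0, _ = _profile_on_truth(traj, truth, -3, 3)
        # rotate all atoms by an arbitrary angle about the pore axis
        fr = traj.frames[0]
        cx, cy = truth["axis_xy"]
        th = 0.83
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pos = fr.positions.copy()
        pos[:, :2] = (pos[:, :2] - [cx, cy]) @ R.T + [cx, cy]
        rot = make_traj([pos], traj.topology, box=tuple(fr.box))
        off = truth["z_offset"]
        z1, r1, _ = radius_profile(
            rot.frames[0], np.arange(rot.n_atoms), rot.topology.elements,
            truth["axis_xy"], (-3 + off, 3 + off), z_step=1.0,
            vdw_table=truth["vdw_table"], seed=3)
        np.testing.assert_allclose(r1, r0, atol=0.02)

    def test_adding_atoms_never_increases_radius(self):
        traj, truth = build_toy_pore(lambda z: 3.0, z_range=(-4, 4))
        z0, r0, _ = _profile_on_truth(traj, truth, -2, 2)
        # add an extra atom near the axis at z=0
        fr = traj.frames[0]
        cx, cy = truth["axis_xy"]
        extra = np.array([[cx + 2.0, cy, truth["z_offset"]]])
        top2 = make_topology(
            list(traj.topology.names) + ["X"],
            elements=list(traj.topology.elements) + ["X"])
        aug = make_traj([np.vstack([fr.positions, extra])], top2,
                        box=tuple(fr.box))
        off = truth["z_offset"]
        z1, r1, _ = radius_profile(
            aug.frames[0], np.arange(aug.n_atoms), aug.topology.elements,
            truth["axis_xy"], (-2 + off, 2 + off), z_step=1.0,
            vdw_table=truth["vdw_table"], seed=0)
        assert np.all(r1 <= r0 + 1e-6)
        assert np.all(r1 >= 0)


class TestMeanRadiusProfile:
    def test_static_pore_has_zero_sd(self):
        traj, truth = build_toy_pore(lambda z: 3.0, z_range=(-4, 4))
        multi = make_traj([traj.frames[0].positions] * 5, traj.topology,
                          box=tuple(traj.frames[0].box))
        prof = mean_radius_profile(
            multi, "all", PoreSpec(), (-2.0, 2.0), z_step=1.0,
            vdw_table=truth["vdw_table"])
        np.testing.assert_allclose(prof.sd, 0.0, atol=1e-9)

    def test_mean_and_sd_over_repeats(self):
        z = np.array([0.0, 1.0])
        prof = combine_profiles([np.array([3.0, 3.0]), np.array([5.0, 5.0])], z)
        np.testing.assert_allclose(prof.mean, 4.0)
        np.testing.assert_allclose(prof.sd, np.sqrt(2.0))

    def test_fractional_window_takes_last_frames(self):
        traj, truth = build_toy_pore(lambda z: 3.0, z_range=(-3, 3))
        base = traj.frames[0].positions
        # 10 frames: first 4 with a blocked pore (extra shrink), last 6 clean
        frames = [base * 1.0 for _ in range(10)]
        multi = make_traj(frames, traj.topology, box=tuple(traj.frames[0].box))
        prof_all = mean_radius_profile(
            multi, "all", PoreSpec(), (-1.0, 1.0), z_step=1.0,
            vdw_table=truth["vdw_table"], window=0.6)
        # 60% of 10 frames = 6 frames used; result well-defined and constant
        assert prof_all.mean.shape == (3,)
        np.testing.assert_allclose(prof_all.sd, 0.0, atol=1e-9)


class TestMinPairDistance:
    def _two_residue_traj(self, d, box=(50.0, 50.0, 50.0)):
        top = make_topology(
            ["CA", "CG", "CA", "CG"],
            resnames=["ASN"] * 4, resids=[653, 653, 753, 753],
            chains=["A", "A", "B", "B"], elements=["C"] * 4,
            species=["protein"] * 4)
        pos = np.array([
            [10.0, 10.0, 10.0], [12.0, 10.0, 10.0],
            [12.0 + d, 10.0, 10.0], [16.0 + d, 10.0, 10.0],
        ])
        return make_traj([pos], top, box=box)

    def test_closest_heavy_atoms_define_distance(self):
        traj = self._two_residue_traj(4.0)
        s = min_pair_distance(traj, "resid 653", "resid 753")
        assert s.values[0] == pytest.approx(4.0)

    def test_identical_selections_rejected(self):
        traj = self._two_residue_traj(4.0)
        with pytest.raises(ValueError, match="identical"):
            min_pair_distance(traj, "resid 653", "resid 653")

    def test_symmetric_in_selections(self):
        traj = self._two_residue_traj(3.3)
        ab = min_pair_distance(traj, "resid 653", "resid 753").values
        ba = min_pair_distance(traj, "resid 753", "resid 653").values
        np.testing.assert_allclose(ab, ba)

    def test_minimum_image_across_boundary(self):
        """Atoms 47 Å apart in-box but 3 Å apart through the boundary."""
        top = make_topology(["CA", "CA"], resnames=["ASN", "ASN"],
                            resids=[1, 2], elements=["C", "C"],
                            species=["protein", "protein"])
        pos = np.array([[1.0, 25.0, 25.0], [48.0, 25.0, 25.0]])
        traj = make_traj([pos], top, box=(50.0, 50.0, 50.0))
        s = min_pair_distance(traj, "resid 1", "resid 2")
        assert s.values[0] == pytest.approx(3.0)
        assert s.values[0] == pytest.approx(
            min_image_27(pos[0], pos[1], np.array([50.0, 50.0, 50.0])))

    def test_hydrogens_excluded_by_default(self):
        top = make_topology(
            ["CA", "HA", "CA"], resnames=["ASN"] * 3, resids=[1, 1, 2],
            elements=["C", "H", "C"], species=["protein"] * 3)
        pos = np.array([[10.0, 10, 10], [12.0, 10, 10], [13.0, 10, 10]])
        traj = make_traj([pos], top)
        s = min_pair_distance(traj, "resid 1", "resid 2")
        assert s.values[0] == pytest.approx(3.0)  # CA–CA, not HA–CA


class TestDistanceDistribution:
    def test_constant_series_single_mode(self):
        out = pair_distance_distribution(np.full(500, 4.0), bins=20,
                                         range=(0, 10))
        widths = np.diff(np.linspace(0, 10, 21))
        assert np.sum(out["density"] * widths) == pytest.approx(1.0)
        assert len(out["modes"]) == 1
        assert out["modes"][0] == pytest.approx(4.0, abs=0.5)

    def test_two_state_series_is_bimodal_with_equal_mass(self):
        vals = np.concatenate([np.full(1000, 4.0) + 0.01,
                               np.full(1000, 12.0) - 0.01])
        out = pair_distance_distribution(vals, bins=32, range=(0, 16))
        assert out["bimodal"]
        modes = np.sort(out["modes"])
        assert modes[0] == pytest.approx(4.0, abs=0.5)
        assert modes[-1] == pytest.approx(12.0, abs=0.5)
        widths = np.diff(np.linspace(0, 16, 33))
        mass_low = np.sum((out["density"] * widths)[out["centers"] < 8])
        assert mass_low == pytest.approx(0.5, abs=0.01)

    def test_density_normalised_for_random_input(self):
        rng = np.random.default_rng(3)
        vals = rng.gamma(4.0, 1.5, size=2000)
        out = pair_distance_distribution(vals, bins=40)
        widths = np.diff(np.histogram_bin_edges(vals, bins=40))
        assert np.sum(out["density"] * widths) == pytest.approx(1.0)

    def test_joint_2d_density_integrates_to_one(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(5, 1, 3000), rng.normal(9, 1, 3000)
        out = pair_distance_distribution((a, b), bins=25)
        dx = np.diff(out["x_centers"])[0]
        dy = np.diff(out["y_centers"])[0]
        assert out["density"].sum() * dx * dy == pytest.approx(1.0, abs=0.01)


class TestDistanceSeries:
    def test_rejects_nonpositive_values(self):
        with pytest.raises(ValueError):
            DistanceSeries("x", np.array([0.0, 1.0]), np.array([1.0, -2.0]))

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            DistanceSeries("x", np.array([0.0]), np.array([1.0, 2.0]))
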