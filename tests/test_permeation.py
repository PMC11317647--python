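"""Event detection, conductance arithmetic, and permeability ratios."""

import numpy as np
import pytest

from permkit.core import PoreSpec
from permkit.permeation import (
    PermeationEvent,
    conductance,
    conductance_summary,
    cumulative_counts,
    detect_events,
    format_ratio,
    permeability_ratio,
)
from permkit.synthetic import DriftSpec, generate_drift_trajectory

from conftest import make_topology, make_traj
from oracles import brute_force_crossings


def _ion_path_traj(z_path, x=30.0, y=30.0, box=(60.0, 60.0, 80.0), r_path=None):
    """Single cation following a prescribed absolute z path (box centre 40)."""
    top = make_topology(["NA"], resnames=["SOD"], elements=["NA"],
                        species=["cation"])
    frames = []
    for i, z in enumerate(z_path):
        xi = x if r_path is None else x + r_path[i]
        frames.append(np.array([[xi, y, z]]))
    return make_traj(frames, top, box=box)


PORE = PoreSpec(z_sf=10.0, z_gate=-10.0)  # box centre at z=40 -> planes 50/30


class TestDetectEvents:
    def test_planted_crossings_detected_exactly(self):
        spec = DriftSpec(n_ions=6, n_waters=6, planted_crossings=4,
                         diffusion_coefficient=0.0, drift_velocity=0.0, seed=2)
        traj, truth = generate_drift_trajectory(spec)
        events = detect_events(traj, spec.pore)
        assert len(events) == truth.n_crossings
        assert all(e.direction == 1 for e in events)
        assert sorted(e.atom for e in events) == truth.crosser_indices

    def test_enter_and_retreat_emits_nothing(self):
        # down into the pore, then back up to the lumen
        z = [55, 48, 42, 38, 42, 48, 55]
        events = detect_events(_ion_path_traj(z), PORE)
        assert events == []

    def test_reverse_crossing_has_direction_minus_one(self):
        z = [25, 30, 36, 44, 48, 55]
        events = detect_events(_ion_path_traj(z), PORE)
        assert len(events) == 1
        assert events[0].direction == -1
        assert cumulative_counts(events, np.array([100.0]))[-1] == 0

    def test_radial_excursion_invalidates_strict_mode(self):
        z = [55, 45, 40, 35, 25]
        r = [0, 0, 8.0, 0, 0]  # leaves the 6 Å cylinder mid-pore
        traj = _ion_path_traj(z, r_path=r)
        assert detect_events(traj, PORE, strict_cylinder=True) == []
        # permissive mode only checks the last in-pore frame
        assert len(detect_events(traj, PORE, strict_cylinder=False)) == 1

    def test_reentrant_ion_emits_multiple_events(self):
        z = [55, 40, 25, 25, 55, 55, 40, 25]
        events = detect_events(_ion_path_traj(z), PORE)
        assert [e.direction for e in events] == [1, 1]
        assert events[0].t_cross < events[1].t_cross

    def test_event_times_entry_before_cross(self):
        z = [55, 55, 45, 40, 35, 25]
        (e,) = detect_events(_ion_path_traj(z), PORE)
        assert e.t_entry == 1.0  # last luminal-bulk frame
        assert e.t_cross == 5.0  # first cytosolic-bulk frame

    def test_zero_matching_atoms_warns_and_returns_empty(self, tiny_traj):
        with pytest.warns(UserWarning, match="no atoms"):
            assert detect_events(tiny_traj, PORE, species="anion") == []

    def test_bad_stride_rejected(self, tiny_traj):
        with pytest.raises(ValueError):
            detect_events(tiny_traj, PORE, stride=0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle_on_diffusive_trajectories(self, seed):
        spec = DriftSpec(n_ions=10, n_waters=0, n_frames=150, seed=seed,
                         box=(40.0, 40.0, 80.0),
                         drift_velocity=30.0, diffusion_coefficient=10.0)
        traj, _ = generate_drift_trajectory(spec)
        events = detect_events(traj, spec.pore)
        n_fwd = sum(1 for e in events if e.direction == 1)
        n_rev = sum(1 for e in events if e.direction == -1)
        oracle_fwd, oracle_rev = brute_force_crossings(traj, spec.pore)
        assert (n_fwd, n_rev) == (oracle_fwd, oracle_rev)

    def test_invariant_to_rigid_translation_and_rewrapping(self):
        """With the pore centred on its anchor atoms, translating the whole
        wrapped system anywhere in the box changes no event."""
        spec = DriftSpec(n_ions=10, n_waters=0, n_frames=150, seed=1,
                         box=(40.0, 40.0, 80.0),
                         drift_velocity=30.0, diffusion_coefficient=10.0)
        traj, _ = generate_drift_trajectory(spec)
        pore = PoreSpec(z_sf=spec.pore.z_sf, z_gate=spec.pore.z_gate,
                        center_selection="species protein")
        ev0 = detect_events(traj, pore)
        assert ev0  # non-trivial baseline
        shift = np.array([7.3, -14.1, 23.7])
        shifted = make_traj(
            [np.mod(fr.positions + shift, fr.box) for fr in traj.frames],
            traj.topology, box=tuple(traj.frames[0].box), dt=traj.dt)
        ev1 = detect_events(shifted, pore)
        assert [(e.atom, e.direction) for e in ev1] == [
            (e.atom, e.direction) for e in ev0]


class TestCumulativeCounts:
    def test_step_function(self):
        events = [
            PermeationEvent(atom=0, species="cation", charge=1,
                            t_entry=t - 1, t_cross=t, direction=1)
            for t in (10.0, 20.0, 30.0)
        ]
        grid = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
        np.testing.assert_array_equal(
            cumulative_counts(events, grid), [0, 1, 2, 3, 3])

    def test_no_events_all_zero(self):
        np.testing.assert_array_equal(
            cumulative_counts([], np.linspace(0, 10, 5)), np.zeros(5))

    def test_nondecreasing_for_any_event_set(self):
        rng = np.random.default_rng(0)
        events = [
            PermeationEvent(atom=i, species="cation", charge=1,
                            t_entry=0.0, t_cross=float(t), direction=1)
            for i, t in enumerate(rng.uniform(0, 100, 25))
        ]
        counts = cumulative_counts(events, np.linspace(0, 100, 300))
        assert np.all(np.diff(counts) >= 0)
        assert counts[-1] == 25


class TestConductance:
    def test_sodium_worked_example(self):
        """44.1 events / 500 ns at 750 mV, z=1 -> 18.8 pS (prints as 19)."""
        c = conductance(44.1, 1, 500.0, 750.0)
        assert c == pytest.approx(18.8, abs=0.05)

    def test_calcium_worked_example(self):
        """5.7 events / 500 ns at 750 mV, z=2 -> 4.9 pS."""
        c = conductance(5.7, 2, 500.0, 750.0)
        assert c == pytest.approx(4.9, abs=0.05)

    def test_zero_events_zero_conductance(self):
        assert conductance(0, 2, 100.0, 500.0) == 0.0

    def test_linearity_properties(self):
        base = conductance(10, 1, 200.0, 500.0)
        assert conductance(20, 1, 200.0, 500.0) == pytest.approx(2 * base)
        assert conductance(10, 2, 200.0, 500.0) == pytest.approx(2 * base)
        assert conductance(10, 1, 100.0, 500.0) == pytest.approx(2 * base)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            conductance(1, 1, 0.0, 750.0)
        with pytest.raises(ValueError):
            conductance(1, 1, 500.0, 0.0)

    def test_summary_mean_and_sample_sd(self):
        est = conductance_summary([10.0, 14.0, 18.0])
        assert est.mean == pytest.approx(14.0)
        assert est.sd == pytest.approx(4.0)
        assert conductance_summary([5.0]).sd == 0.0


class TestPermeabilityRatio:
    def test_study_rates_give_ratio(self):
        r = permeability_ratio(44.1 / 500.0, 5.7 / 500.0)
        assert format_ratio(r) == "7.7:1"

    def test_equal_rates(self):
        assert format_ratio(permeability_ratio(3.0, 3.0)) == "1.0:1"

    def test_simple_arithmetic(self):
        assert permeability_ratio(10, 4) == pytest.approx(2.5)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            permeability_ratio(1.0, 0.0)
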