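"""Single-follicle dynamics: conservation, kinetics, growth, checkpoints."""

import dataclasses
import math

import numpy as np
import pytest

from pelage import (
    GrowthLaw,
    GrowthSignal,
    HFGeometry,
    HFState,
    PathwayParams,
    Phase,
    PhaseThresholds,
    StabilityError,
    checkpoint_update,
    default_params,
    geometry_step,
    growth_signal,
    phase_durations,
    reaction_diffusion_step,
    simulate_hf,
)
from pelage.hf_core import Trajectory
import pandas as pd


def inert_pathway(**kw):
    base = dict(
        diffusion_coeff=0.3, production_region1=0.0,
        production_region2={Phase.TELOGEN: 0.0, Phase.ANAGEN: 0.0},
        bind_on=0.0, bind_off=0.0, degradation=0.0, receptor_total=1.0,
    )
    base.update(kw)
    return PathwayParams(**base)


def trapz_mass(field, dx):
    return dx * (field.sum() - 0.5 * (field[0] + field[-1]))


class TestReactionDiffusion:
    def test_closed_system_conserves_ligand_mass(self):
        """No sources, no binding, no decay, reflecting ends: the trapezoidal
        ligand mass stays constant to 1e-10 relative over 1000 steps."""
        geom = HFGeometry()
        state = HFState.resting(geom)
        x = geom.axis_grid()
        state.ligand_act[:] = np.exp(-((x - 0.5) ** 2) / 0.02)
        state.ligand_inh[:] = 0.3 + 0.1 * np.sin(4 * x)
        p = inert_pathway()
        m0a = trapz_mass(state.ligand_act, geom.grid_spacing)
        m0i = trapz_mass(state.ligand_inh, geom.grid_spacing)
        for _ in range(1000):
            state = reaction_diffusion_step(state, p, p, dt=0.0125)
        assert abs(trapz_mass(state.ligand_act, geom.grid_spacing) - m0a) <= 1e-10 * m0a
        assert abs(trapz_mass(state.ligand_inh, geom.grid_spacing) - m0i) <= 1e-10 * m0i

    def test_uniform_field_is_diffusion_invariant(self):
        geom = HFGeometry()
        state = HFState.resting(geom)
        state.ligand_act[:] = 0.7
        p = inert_pathway()
        out = reaction_diffusion_step(state, p, p, dt=0.0125)
        np.testing.assert_array_equal(out.ligand_act, state.ligand_act)

    def test_single_step_matches_fine_step_reference(self):
        """One explicit step on a 5-node grid agrees with a reference
        integration at dt/1000 to within the scheme's O(dt) local error."""
        geom = HFGeometry(grid_spacing=0.3, region1_interval=(0.2, 0.6),
                          length_min=1.2, length_max=3.0)
        assert geom.n_nodes() == 5
        act = PathwayParams(0.25, 0.05,
                            {Phase.TELOGEN: 0.3, Phase.ANAGEN: 0.3},
                            bind_on=0.5, bind_off=0.1, degradation=0.2,
                            receptor_total=2.0)
        inh = act.replace(diffusion_coeff=0.15)
        state = HFState.resting(geom)
        x = geom.axis_grid()
        state.ligand_act[:] = 0.5 + 0.5 * x
        state.ligand_inh[:] = 1.0 - 0.3 * x
        in_region1 = (x >= 0.2) & (x <= 0.6)
        state.bound_act[in_region1] = 0.1
        dt = 0.02
        coarse = reaction_diffusion_step(state, act, inh, dt)
        fine = state
        for _ in range(1000):
            fine = reaction_diffusion_step(fine, act, inh, dt / 1000)
        for f in ("ligand_act", "ligand_inh", "bound_act", "bound_inh"):
            err = np.max(np.abs(getattr(coarse, f) - getattr(fine, f)))
            assert err < 5e-3, f"{f}: {err}"

    def test_stability_bound_violation_names_the_limit(self):
        geom = HFGeometry()
        state = HFState.resting(geom)
        p = inert_pathway(diffusion_coeff=0.3)
        limit = geom.grid_spacing**2 / (2 * 0.3)
        with pytest.raises(StabilityError, match="maximum admissible dt"):
            reaction_diffusion_step(state, p, p, dt=2 * limit)


class TestGrowthSignal:
    def test_balanced_fields_give_zero(self):
        state = HFState.resting(HFGeometry())
        state.bound_act[:] = 0.8
        state.bound_inh[:] = 0.8
        assert growth_signal(state).value == 0.0

    def test_constant_fields(self):
        state = HFState.resting(HFGeometry())
        state.bound_act[:] = 2.0
        state.bound_inh[:] = 0.5
        assert growth_signal(state).value == pytest.approx(1.5, abs=1e-12)

    def test_piecewise_linear_fields_match_direct_mean(self):
        """Region I aligned to whole cells: the signal equals the plain node
        mean of (bound_act - bound_inh) over the 7 Region-I nodes."""
        geom = HFGeometry(grid_spacing=0.1, region1_interval=(0.15, 0.85),
                          length_min=1.3, length_max=3.0, region2_width=0.4)
        state = HFState.resting(geom)
        x = geom.axis_grid()
        state.bound_act[:] = np.where(x < 0.5, 2 * x, 1.0)
        state.bound_inh[:] = 0.1 + 0.2 * x
        nodes = (x >= 0.2 - 1e-9) & (x <= 0.8 + 1e-9)
        assert nodes.sum() == 7
        expected = np.mean(state.bound_act[nodes] - state.bound_inh[nodes])
        assert growth_signal(state).value == pytest.approx(expected, abs=1e-12)


class TestGeometryStep:
    def test_zero_velocity_leaves_state_unchanged(self):
        geom = HFGeometry(length_current=2.0)
        state = HFState.resting(HFGeometry())
        state = dataclasses.replace(state, geometry=geom,
                                    ligand_act=np.linspace(1, 2, geom.n_nodes()),
                                    ligand_inh=np.zeros(geom.n_nodes()),
                                    bound_act=np.zeros(geom.n_nodes()),
                                    bound_inh=np.zeros(geom.n_nodes()))
        out = geometry_step(state, GrowthSignal(0.0), lambda C, ana: 0.0, dt=1.0)
        assert out.geometry.length_current == 2.0
        np.testing.assert_array_equal(out.ligand_act, state.ligand_act)

    def test_length_clamps_at_maximum(self):
        geom = HFGeometry()
        state = HFState.resting(geom)
        state = dataclasses.replace(
            state, geometry=geom.with_length(geom.length_max),
            ligand_act=np.ones(geom.max_nodes), ligand_inh=np.zeros(geom.max_nodes),
            bound_act=np.zeros(geom.max_nodes), bound_inh=np.zeros(geom.max_nodes))
        out = geometry_step(state, GrowthSignal(1.0), lambda C, ana: +5.0, dt=1.0)
        assert out.geometry.length_current == geom.length_max

    def test_elongation_by_one_cell_adds_exactly_the_new_cell_content(self):
        """Interpolation is conservative: after growing one grid cell the
        trapezoidal ligand mass equals the pre-step mass plus dx times the
        extrapolated distal value (the new cell's content)."""
        geom = HFGeometry()
        dx = geom.grid_spacing
        state = HFState.resting(geom)
        n = geom.n_nodes()
        state.ligand_act[:] = np.linspace(0.5, 1.5, n)
        m0 = trapz_mass(state.ligand_act, dx)
        edge = state.ligand_act[-1]
        out = geometry_step(state, GrowthSignal(1.0),
                            lambda C, ana: dx / 1.0, dt=1.0)
        assert out.geometry.n_nodes() == n + 1
        m1 = trapz_mass(out.ligand_act, dx)
        assert m1 == pytest.approx(m0 + dx * edge, rel=1e-12)

    def test_retraction_discards_the_removed_cell(self):
        geom = HFGeometry(length_current=2.0)
        n = geom.n_nodes()
        state = dataclasses.replace(
            HFState.resting(geom), geometry=geom,
            ligand_act=np.linspace(1.0, 2.0, n), ligand_inh=np.zeros(n),
            bound_act=np.zeros(n), bound_inh=np.zeros(n))
        out = geometry_step(state, GrowthSignal(0.0),
                            lambda C, ana: -geom.grid_spacing, dt=1.0)
        assert out.geometry.n_nodes() == n - 1
        np.testing.assert_allclose(out.ligand_act, state.ligand_act[:-1])


class TestCheckpoints:
    thresholds = PhaseThresholds(activation_threshold=0.45,
                                 termination_threshold=0.15,
                                 refractory_min_duration=1.0)

    def make_state(self, phase, elapsed=10.0):
        s = HFState.resting(HFGeometry())
        s.phase = phase
        s.phase_elapsed = elapsed
        return s

    def test_subthreshold_signal_gives_no_transition(self):
        s = self.make_state(Phase.TELOGEN)
        out = checkpoint_update(s, GrowthSignal(0.1), self.thresholds)
        assert out.phase == Phase.TELOGEN

    def test_dwell_guard_blocks_early_transition(self):
        s = self.make_state(Phase.TELOGEN, elapsed=0.2)
        out = checkpoint_update(s, GrowthSignal(0.9), self.thresholds)
        assert out.phase == Phase.TELOGEN

    def test_sinusoidal_signal_gives_two_transitions_per_period(self):
        """A sinusoid crossing both thresholds once per period must produce
        exactly one entry and one exit per period (crossing-count oracle)."""
        period, dt, n_periods = 20.0, 0.1, 3
        t = np.arange(0, n_periods * period, dt)
        c = 0.3 + 0.3 * np.sin(2 * np.pi * t / period)
        # independent oracle: sign-change counting on the sampled series
        ups = np.sum((c[:-1] < 0.45) & (c[1:] >= 0.45))
        downs = np.sum((c[:-1] >= 0.15) & (c[1:] < 0.15))
        state = self.make_state(Phase.TELOGEN)
        n_trans = 0
        for k in range(1, len(t)):
            new = checkpoint_update(state, GrowthSignal(c[k]), self.thresholds,
                                    t=t[k])
            if new.phase != state.phase:
                n_trans += 1
            new.phase_elapsed = state.phase_elapsed + dt \
                if new.phase == state.phase else 0.0
            state = new
        assert ups == downs == n_periods
        assert n_trans == 2 * n_periods


class TestSimulateHF:
    def test_identical_seeds_give_bit_identical_trajectories(self, defaults):
        act, inh, geom, thr, law = defaults
        act = act.replace(noise_amplitude=0.01)
        inh = inh.replace(noise_amplitude=0.01)
        runs = [simulate_hf(act, inh, geom, thr, horizon=20.0, dt=0.0125,
                            seed=42, growth_law=law) for _ in range(2)]
        for f in ("times", "phase", "length", "signal",
                  "mean_bound_act", "mean_bound_inh"):
            np.testing.assert_array_equal(getattr(runs[0], f), getattr(runs[1], f))
        assert runs[0].transitions.equals(runs[1].transitions)

    def test_zero_horizon_returns_initial_state_only(self, defaults):
        act, inh, geom, thr, law = defaults
        traj = simulate_hf(act, inh, geom, thr, horizon=0.0, dt=0.0125,
                           growth_law=law)
        assert len(traj.times) == 1
        assert traj.times[0] == 0.0

    def test_excitable_regime_cycles_with_stable_period(self, baseline_durations):
        """After the first (transient) cycle, successive periods agree to
        well under 1% — autonomous, clock-free cycling."""
        post = baseline_durations[baseline_durations["cycle"] > 1]
        assert len(post) >= 3
        cv = post["period"].std() / post["period"].mean()
        assert cv < 0.01

    def test_strong_inhibition_equilibrates_in_extended_telogen(self, defaults):
        act, inh, geom, thr, law = defaults
        traj = simulate_hf(act, inh.scale_production(4.0), geom, thr,
                           horizon=300.0, dt=0.0125, growth_law=law)
        entries = (traj.transitions["to_phase"] == 1).sum()
        assert entries <= 1
        assert traj.phase[-1] == Phase.TELOGEN
        assert traj.length[-1] == pytest.approx(geom.length_min)


class TestPhaseDurations:
    def _traj(self, transitions):
        tr = pd.DataFrame(transitions,
                          columns=["time", "from_phase", "to_phase", "cycle_index"])
        z = np.zeros(1)
        return Trajectory(times=z, phase=z.astype(np.int8), length=z, signal=z,
                          mean_bound_act=z, mean_bound_inh=z, transitions=tr)

    def test_scripted_transitions_give_expected_row(self):
        traj = self._traj([(0.0, 0, 1, 1), (10.0, 1, 0, 1), (25.0, 0, 1, 2)])
        table = phase_durations(traj)
        assert len(table) == 1
        row = table.iloc[0]
        assert (row["anagen_duration"], row["telogen_duration"], row["period"]) \
            == (10.0, 15.0, 25.0)

    def test_periodic_trajectory_gives_identical_rows(self, baseline_durations):
        post = baseline_durations[baseline_durations["cycle"] > 1]
        assert np.ptp(post["anagen_duration"]) < 0.2
        assert np.ptp(post["telogen_duration"]) < 0.6

    def test_no_complete_cycle_warns_and_returns_empty(self):
        traj = self._traj([(5.0, 0, 1, 1)])
        with pytest.warns(UserWarning, match="no complete cycle"):
            table = phase_durations(traj)
        assert table.empty


class TestInvariants:
    def test_positivity_and_receptor_cap_under_noise(self, defaults):
        """Fields stay nonnegative and bound receptor below the local
        capacity; undershoot clips are far rarer than 0.1% of nodes."""
        from pelage._engine import SimEngine

        act, inh, geom, thr, law = defaults
        eng = SimEngine(geom, [act.replace(noise_amplitude=0.005)],
                        [inh.replace(noise_amplitude=0.005)], [thr], [law],
                        dt=0.0125, seed=3)
        cap = eng.R_tot * eng.w1[None, None, :]
        for k in range(4000):
            eng.step()
            if k % 200 == 0:
                assert (eng.L >= 0).all()
                assert (eng.B >= 0).all()
                assert (eng.B <= cap + 1e-12).all()
        frac = eng.counters.clip_events / (eng.counters.steps
                                           * eng.counters.nodes_per_step)
        assert frac < 1e-3

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            PathwayParams(-0.1, 0, {Phase.TELOGEN: 0, Phase.ANAGEN: 0},
                          0, 0, 0, 1.0)
        with pytest.raises(ValueError, match="receptor_total"):
            inert_pathway(receptor_total=0.0)
        with pytest.raises(ValueError, match="missing phase"):
            PathwayParams(0.1, 0, {Phase.TELOGEN: 0.1}, 0, 0, 0, 1.0)
        with pytest.raises(ValueError):
            PhaseThresholds(activation_threshold=0.1, termination_threshold=0.2)
        with pytest.raises(ValueError, match="disjoint"):
            HFGeometry(region1_interval=(0.2, 1.0))
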