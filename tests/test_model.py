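"""Coiling simulator: rules, decision tree, physics invariants."""

from dataclasses import replace

import numpy as np
import pytest

from tendrilcoil import (
    CoilSimulation,
    ModelParams,
    PhaseRecord,
    Support,
    TendrilState,
    Trajectory,
    ValidationError,
    classify_phases,
    detect_contact,
    phase_diagram,
    simulate,
    simulate_free,
)


def straight_state(n=21, ds=2.5):
    nodes = np.zeros((n, 3))
    nodes[:, 0] = np.arange(n) * ds
    return TendrilState(nodes=nodes, ds=ds, joint_bend=np.zeros(n))


class TestParams:
    def test_defaults_place_bifurcation_in_printed_band(self):
        p = ModelParams()
        assert 10.0 <= p.phi_crit <= 15.0

    @pytest.mark.parametrize(
        "field,value",
        [
            ("theta_min", -1.0),
            ("free_coil_diameter", 0.0),
            ("max_time", 0.0),
            ("root_contact_fraction", 1.5),
        ],
    )
    def test_invalid_params(self, field, value):
        with pytest.raises(ValidationError):
            ModelParams(**{field: value})


class TestDetectContact:
    def test_tangent_node_detected(self):
        state = straight_state()
        support = Support(center=np.array([7 * 2.5, -5.0, 0.0]), diameter=10)
        assert detect_contact(state, support, contact_tol=0.25) == 7

    def test_no_contact_returns_none(self):
        state = straight_state()
        support = Support(center=np.array([20.0, -30.0, 0.0]), diameter=10)
        assert detect_contact(state, support, contact_tol=0.25) is None

    def test_tie_break_is_root_most(self):
        state = straight_state()
        support = Support(center=np.array([7 * 2.5, -5.0, 0.0]), diameter=10)
        # generous tolerance: several nodes qualify; compare with an
        # exhaustive distance scan
        tol = 3.0
        got = detect_contact(state, support, contact_tol=tol)
        dist = np.linalg.norm(
            state.nodes[:, :2] - support.center[:2], axis=1
        )
        qualifying = np.nonzero(dist - 5.0 <= tol)[0]
        assert len(qualifying) > 1
        assert got == qualifying[0]

    def test_penetrating_node_counts_as_touching(self):
        state = straight_state()
        state.nodes[7, 1] = -1.0  # pushed inside the support
        support = Support(center=np.array([7 * 2.5, -5.0, 0.0]), diameter=10)
        assert detect_contact(state, support, contact_tol=0.25) == 7


class TestStep:
    def test_dt_must_be_positive(self, params_nojitter):
        sim = CoilSimulation(100, 10, params=params_nojitter)
        with pytest.raises(ValidationError):
            sim.step(dt=0.0)

    def test_small_support_contact_never_moves(self, params_nojitter):
        sim = CoilSimulation(100, 10, params=params_nojitter)
        k0 = sim.k_contact
        for _ in range(50):
            sim.step()
        contacts = [c for _, c in sim.traj.contact_history if c is not None]
        assert all(c == k0 for c in contacts)

    def test_large_support_contact_migrates_tipward(self, params_nojitter):
        sim = CoilSimulation(60, 40, params=params_nojitter)
        for _ in range(50):
            if sim.terminal:
                break
            sim.step()
        assert sim.traj.has_event("liftoff")
        contacts = [c for _, c in sim.traj.contact_history if c is not None]
        assert all(b >= a for a, b in zip(contacts, contacts[1:]))
        assert contacts[-1] > contacts[0]

    def test_no_stimulus_no_coiling(self, params_nojitter):
        sim = CoilSimulation(
            100, 10, params=params_nojitter, support_gap=20.0
        )
        assert not sim.contact_started
        for _ in range(20):
            sim.step()
        assert np.all(sim.b == 0.0)


class TestSimulateExamples:
    def test_small_support_continuous_coiling(self, params_nojitter):
        rec = classify_phases(simulate(100, 10, params=params_nojitter))
        assert rec.step1 == "continuous_coiling"
        assert rec.step2 == "not_applicable"
        assert rec.step3 == "success"

    def test_short_tendril_large_support_tip_contact(self, params_nojitter):
        rec = classify_phases(simulate(60, 35, params=params_nojitter))
        assert rec.step1 == "moving_contact_point"
        assert rec.step2 == "tip_contact"
        assert rec.step3 == "detach"
        assert 0 < rec.time_to_detach < 60

    def test_long_tendril_clip_majority_of_20_seeds(self):
        """With seeded circumnutation, the 160 mm / 20 mm cell resolves
        into clip-shape coiling for the majority of seeds."""
        p = ModelParams()
        outcomes = []
        for seed in range(20):
            traj = simulate(
                160, 20, params=replace(p, seed=seed), record_frames=False
            )
            outcomes.append(classify_phases(traj).step2)
        clip = sum(o == "clip_shape_coiling" for o in outcomes)
        assert clip > 10

    def test_invalid_inputs(self, params_nojitter):
        with pytest.raises(ValidationError):
            simulate(100, -5, params=params_nojitter)
        with pytest.raises(ValidationError):
            simulate(2.0, 10, params=params_nojitter)


class TestClassifyPhases:
    def _traj(self, events, contacts=None, wraps=None):
        p = ModelParams(jitter_sd=0.0)
        return Trajectory(
            times=[], frames=[],
            contact_history=contacts or [(0.0, 10), (5.0, 10), (10.0, 10)],
            wrap_history=wraps or [(0.0, 0.0), (10.0, 30.0)],
            events=events, params=p, support=None, length=100.0,
        )

    def test_constant_contact_is_continuous_success(self):
        rec = classify_phases(self._traj([(0.0, "initial_contact")]))
        assert (rec.step1, rec.step2, rec.step3) == (
            "continuous_coiling", "not_applicable", "success",
        )

    def test_liftoff_then_tip_is_tip_contact_detach(self):
        rec = classify_phases(
            self._traj(
                [
                    (0.0, "initial_contact"),
                    (1.5, "liftoff"),
                    (8.0, "tip_reached"),
                    (12.0, "detach"),
                ]
            )
        )
        assert (rec.step1, rec.step2, rec.step3) == (
            "moving_contact_point", "tip_contact", "detach",
        )
        assert rec.time_to_detach == pytest.approx(12.0)

    def test_secondary_root_contact_is_clip_success(self):
        rec = classify_phases(
            self._traj(
                [
                    (0.0, "initial_contact"),
                    (1.5, "liftoff"),
                    (9.0, "secondary_contact_root"),
                    (40.0, "wrap_closed"),
                ],
                wraps=[(0.0, 0.0), (40.0, 380.0)],
            )
        )
        assert (rec.step1, rec.step2, rec.step3) == (
            "moving_contact_point", "clip_shape_coiling", "success",
        )
        assert rec.total_wrap == pytest.approx(380.0)

    def test_no_contact_raises(self):
        with pytest.raises(ValidationError, match="no coiling"):
            classify_phases(self._traj([]))

    def test_phase_record_invariants_enforced(self):
        with pytest.raises(ValidationError):
            PhaseRecord(
                step1="continuous_coiling", step2="tip_contact",
                step3="success", time_to_detach=None, total_wrap=0.0,
            )
        with pytest.raises(ValidationError):
            PhaseRecord(
                step1="moving_contact_point", step2="tip_contact",
                step3="detach", time_to_detach=None, total_wrap=0.0,
            )


class TestPhysicsInvariants:
    @pytest.mark.parametrize(
        "length,diameter,seed",
        [(100, 10, 0), (60, 35, 0), (160, 20, 0), (160, 20, 3)],
    )
    def test_non_penetration_and_inextensibility(self, length, diameter, seed):
        traj = simulate(
            length, diameter, params=ModelParams(seed=seed)
        )
        center = traj.support.center[:2]
        radius = traj.support.radius
        for nodes in traj.frames:
            xy = nodes[:, :2]
            clearance = np.linalg.norm(xy - center, axis=1) - radius
            assert clearance.min() > -1e-6
            spacing = np.linalg.norm(np.diff(xy, axis=0), axis=1)
            np.testing.assert_allclose(spacing, traj.params.ds, atol=1e-6)

    def test_free_coil_converges_to_configured_diameter(self, params_nojitter):
        """Without a support every joint's curvature converges to
        2 / free_coil_diameter (within 1%)."""
        sim = CoilSimulation(100, None, params=params_nojitter)
        sim.run()
        kappa = np.radians(sim.b[1 : sim.n - 1]) / params_nojitter.ds
        target = 2.0 / params_nojitter.free_coil_diameter
        np.testing.assert_allclose(kappa, target, rtol=0.01)

    def test_bitwise_determinism(self):
        p = ModelParams(seed=11)
        a = simulate(160, 20, params=p)
        b = simulate(160, 20, params=p)
        assert len(a.frames) == len(b.frames)
        for fa, fb in zip(a.frames, b.frames):
            assert np.array_equal(fa, fb)
        assert a.events == b.events
        assert a.contact_history == b.contact_history

    def test_joint_bend_capped_at_free_curvature(self, params_nojitter):
        sim = CoilSimulation(100, 10, params=params_nojitter)
        sim.run()
        assert np.all(sim.b <= params_nojitter.joint_cap + 1e-9)
        assert np.all(sim.b >= 0)


class TestPhaseDiagram:
    def test_single_cell(self, params_nojitter):
        df = phase_diagram([100], [10], params=params_nojitter, seeds=[0])
        assert len(df) == 1
        assert df.iloc[0].step1 == "continuous_coiling"

    def test_step1_boundary_within_printed_band(self, params_nojitter):
        diams = [10, 12, 15, 18, 20, 24, 30, 32, 35]
        df = phase_diagram(
            [60, 160], diams, params=params_nojitter, seeds=[0]
        )
        for length in (60, 160):
            sub = df[df.length_mm == length].sort_values("diameter_mm")
            cont = sub[sub.step1 == "continuous_coiling"].diameter_mm
            mov = sub[sub.step1 == "moving_contact_point"].diameter_mm
            assert cont.max() >= 10.0
            assert mov.min() <= 15.0
            assert cont.max() < mov.min()

    def test_success_non_increasing_in_diameter(self, params_nojitter):
        diams = [10, 12, 15, 18, 20, 24, 30, 32, 35]
        df = phase_diagram([100], diams, params=params_nojitter, seeds=[0])
        s = (
            df.sort_values("diameter_mm").step3.eq("success").astype(int)
        ).to_numpy()
        assert all(a >= b for a, b in zip(s, s[1:]))

    def test_cell_errors_recorded_not_raised(self, params_nojitter):
        df = phase_diagram([4.0, 100.0], [10], params=params_nojitter,
                           seeds=[0])
        assert len(df) == 2
        bad = df[df.length_mm == 4.0].iloc[0]
        assert bad.error is not None
        good = df[df.length_mm == 100.0].iloc[0]
        assert good.error is None

    def test_empty_grid_raises(self, params_nojitter):
        with pytest.raises(ValidationError):
            phase_diagram([], [10], params=params_nojitter)
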