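"""Spring-mass model: construction, dynamics, equilibrium, impact."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import musclenet as mn
from musclenet import springs as sp
from musclenet.hypergraph import Hypergraph


def one_spring_oracle(t_eval, clamped=(0.0, 0.0, 0.0, 1.0),
                      start=(1.0, 0.0, 0.0, 0.0), strength=1.0,
                      rest=1.0, beta=1.0):
    """High-accuracy adaptive integration of the single-spring ODE."""
    a = np.asarray(clamped)

    def rhs(t, y):
        r, v = y[:4], y[4:]
        l = r - a
        dist = np.linalg.norm(l)
        f = strength * (rest - dist) / dist * l
        return np.concatenate([v, f - beta * v])

    y0 = np.concatenate([np.asarray(start), np.zeros(4)])
    sol = solve_ivp(rhs, (0, t_eval[-1]), y0, t_eval=t_eval,
                    rtol=1e-11, atol=1e-12, method="DOP853")
    return sol.y[:4].T


class TestBuild:
    def test_degree_two_muscle_one_unit_spring(self, fixtures):
        s = sp.build_spring_system(fixtures["dumbbell"]["hypergraph"],
                                   fixtures["dumbbell"]["embedding"])
        assert s.n_springs == 1
        assert s.strength[0] == 1.0

    def test_degree_k_gives_k_choose_2_springs(self):
        k = 25
        h = Hypergraph([f"b{i}" for i in range(k)], ["big"],
                       np.ones((k, 1), dtype=int))
        emb = sp.PhysicalEmbedding(
            {f"b{i}": np.array([float(i), 0, 0]) for i in range(k)},
            {f"b{i}": i == 0 for i in range(k)})
        s = sp.build_spring_system(h, emb)
        assert s.n_springs == k * (k - 1) // 2
        assert np.allclose(s.strength, 1 / (k - 1))

    def test_shared_pair_strengths_accumulate(self):
        h = Hypergraph(["b1", "b2"], ["m1", "m2"], [[1, 1], [1, 1]])
        emb = sp.PhysicalEmbedding({"b1": np.zeros(3), "b2": np.r_[1., 0, 0]},
                                   {"b1": True, "b2": False})
        s = sp.build_spring_system(h, emb)
        assert s.n_springs == 1
        assert s.strength[0] == pytest.approx(2.0)

    def test_missing_coordinates_listed(self):
        h = Hypergraph(["b1", "b2"], ["m1"], [[1], [1]])
        emb = sp.PhysicalEmbedding({"b1": np.zeros(3)}, {"b1": True})
        with pytest.raises(sp.BuildError, match="b2"):
            sp.build_spring_system(h, emb)

    def test_no_fixed_bone_rejected(self):
        with pytest.raises(sp.ConstraintError):
            sp.PhysicalEmbedding({"b1": np.zeros(3)}, {"b1": False})

    def test_rest_lengths_put_system_at_equilibrium(self, fixtures):
        s = sp.build_spring_system(fixtures["chain"]["hypergraph"],
                                   fixtures["chain"]["embedding"])
        assert np.allclose(s.forces(s.positions0), 0.0)


class TestPerturb:
    def test_members_clamped_at_displacement(self, fixtures):
        s = sp.build_spring_system(fixtures["dumbbell"]["hypergraph"],
                                   fixtures["dumbbell"]["embedding"])
        state = sp.perturb_muscle(s, "m1", 1.0)
        assert state.clamped.sum() == 2
        assert np.allclose(state.positions[:, 3], 1.0)

    def test_membership_clamp_overrides_fixed_flag(self, fixtures):
        s = sp.build_spring_system(fixtures["dumbbell"]["hypergraph"],
                                   fixtures["dumbbell"]["embedding"])
        state = sp.perturb_muscle(s, "m1", 0.5)
        assert state.positions[0, 3] == 0.5  # b1 is globally fixed
        assert any("overrides fixed" in line for line in state.log)

    def test_zero_displacement_stays_at_equilibrium(self, fixtures):
        h, emb = (fixtures["chain"]["hypergraph"],
                  fixtures["chain"]["embedding"])
        s = sp.build_spring_system(h, emb)
        traj = sp.integrate_dynamics(sp.perturb_muscle(s, "mb", 0.0),
                                     t_max=5.0)
        assert traj.free_displacement_integral == 0.0
        assert np.allclose(traj.final_positions, s.positions0)

    def test_unknown_muscle(self, fixtures):
        s = sp.build_spring_system(fixtures["dumbbell"]["hypergraph"],
                                   fixtures["dumbbell"]["embedding"])
        with pytest.raises(KeyError):
            sp.perturb_muscle(s, "nope", 1.0)


class TestDynamics:
    def test_matches_adaptive_ode_oracle_on_one_spring(self):
        # free unit mass on one unit spring to a clamped node displaced
        # by d=1 in the fourth dimension
        h = Hypergraph(["anchor", "free"], ["m1"], [[1], [1]])
        emb = sp.PhysicalEmbedding(
            {"anchor": np.zeros(3), "free": np.r_[1.0, 0, 0]},
            {"anchor": True, "free": False})
        s = sp.build_spring_system(h, emb)
        state = sp.perturb_muscle(s, "m1", 1.0)
        # only the anchor is a member? no: both are members -> both clamp.
        # Clamp manually: displace anchor only.
        state = sp.PerturbationState(
            s, np.array([[0, 0, 0, 1.0], [1, 0, 0, 0]]),
            np.array([True, False]), "m1", 1.0)
        dt = 1e-4
        traj = sp.integrate_dynamics(state, dt=dt, t_max=5.0, speed_tol=0.0,
                                     record=True)
        oracle = one_spring_oracle(traj.times)
        err = np.abs(traj.positions[:, 1, :] - oracle).max()
        scale = np.abs(oracle - np.r_[1.0, 0, 0, 0]).max()
        assert err / scale < 1e-3  # first-order integrator at dt=1e-4

    def test_mirror_symmetric_perturbation_stays_symmetric(self, fixtures):
        s = sp.build_spring_system(fixtures["star"]["hypergraph"],
                                   fixtures["star"]["embedding"])
        # perturb the hub muscle: clamps everything symmetric by design;
        # instead clamp only the center and watch the 4 leaves mirror
        pos = s.positions0.copy()
        pos[0, 3] = 1.0
        clamped = np.array([True, False, False, False, False])
        traj = sp.integrate_dynamics(
            sp.PerturbationState(s, pos, clamped, "hub", 1.0),
            dt=0.01, t_max=20.0, record=True)
        # leaves at +x/-x and +y/-y are mirror pairs: identical w motion
        assert np.allclose(traj.positions[:, 1, 3], traj.positions[:, 2, 3])
        assert np.allclose(traj.positions[:, 3, 3], traj.positions[:, 4, 3])

    def test_divergence_raises_instability(self, fixtures):
        s = sp.build_spring_system(fixtures["chain"]["hypergraph"],
                                   fixtures["chain"]["embedding"])
        with pytest.raises(sp.InstabilityError):
            sp.integrate_dynamics(sp.perturb_muscle(s, "ma", 1.0), dt=5.0,
                                  t_max=200.0)


class TestSteadyState:
    def test_no_perturbation_zero_displacement(self, fixtures):
        s = sp.build_spring_system(fixtures["chain"]["hypergraph"],
                                   fixtures["chain"]["embedding"])
        eq = sp.steady_state_solve(sp.perturb_muscle(s, "mb", 0.0))
        assert np.allclose(eq.displacements, 0.0, atol=1e-10)

    def test_one_spring_closed_form(self):
        # anchor clamped at (0,0,0,1); the free node relaxes onto the
        # sphere of radius rest=1 around it, along the line to its start
        h = Hypergraph(["anchor", "free"], ["m1"], [[1], [1]])
        emb = sp.PhysicalEmbedding(
            {"anchor": np.zeros(3), "free": np.r_[1.0, 0, 0]},
            {"anchor": True, "free": False})
        s = sp.build_spring_system(h, emb)
        state = sp.PerturbationState(
            s, np.array([[0, 0, 0, 1.0], [1, 0, 0, 0]]),
            np.array([True, False]), "m1", 1.0)
        eq = sp.steady_state_solve(state, force_tol=1e-10)
        a = np.r_[0, 0, 0, 1.0]
        p0 = np.r_[1.0, 0, 0, 0]
        expect = a + (p0 - a) / np.linalg.norm(p0 - a)
        assert np.abs(eq.final_positions[1] - expect).max() < 1e-8

    def test_agrees_with_long_time_dynamics(self):
        # taut 6-bone ladder: every spring is stretched in the perturbed
        # equilibrium, so all modes are exponentially stable and the
        # dynamic relaxation reaches the static solution (springs at
        # their rest length have zero transverse stiffness and relax
        # only algebraically; such mechanisms are excluded by design)
        nb = 6
        inc = np.zeros((nb, nb - 1), dtype=int)
        for j in range(nb - 1):
            inc[[j, j + 1], j] = 1
        h = Hypergraph([f"b{i}" for i in range(nb)],
                       [f"m{j}" for j in range(nb - 1)], inc)
        emb = sp.PhysicalEmbedding(
            {f"b{i}": np.r_[float(i), 0, 0] for i in range(nb)},
            {f"b{i}": i in (0, nb - 1) for i in range(nb)})
        s = sp.build_spring_system(h, emb)
        eq = sp.steady_state_solve(sp.perturb_muscle(s, "m1", 0.7),
                                   force_tol=1e-10)
        traj = sp.integrate_dynamics(sp.perturb_muscle(s, "m1", 0.7),
                                     dt=0.005, t_max=400.0, speed_tol=1e-10,
                                     dwell=20)
        assert np.abs(eq.final_positions - traj.final_positions).max() < 1e-4

    def test_doubling_strengths_leaves_equilibrium_unchanged(self, fixtures):
        h, emb = (fixtures["chain"]["hypergraph"],
                  fixtures["chain"]["embedding"])
        s1 = sp.build_spring_system(h, emb)
        s2 = sp.build_spring_system(h, emb)
        s2.strength = 2 * s2.strength
        e1 = sp.steady_state_solve(sp.perturb_muscle(s1, "ma", 1.0),
                                   force_tol=1e-9)
        e2 = sp.steady_state_solve(sp.perturb_muscle(s2, "ma", 1.0),
                                   force_tol=1e-9)
        assert np.abs(e1.final_positions - e2.final_positions).max() < 1e-6

    def test_damping_changes_dynamic_not_static_impact(self, fixtures):
        h, emb = (fixtures["chain"]["hypergraph"],
                  fixtures["chain"]["embedding"])
        st_a = mn.impact_score(h, emb, "ma", "steady_state_4d",
                               sp.ImpactSettings(beta=1.0))
        st_b = mn.impact_score(h, emb, "ma", "steady_state_4d",
                               sp.ImpactSettings(beta=3.0))
        dy_a = mn.impact_score(h, emb, "ma", "dynamic_4d",
                               sp.ImpactSettings(beta=1.0, t_max=30.0))
        dy_b = mn.impact_score(h, emb, "ma", "dynamic_4d",
                               sp.ImpactSettings(beta=3.0, t_max=30.0))
        assert st_a == pytest.approx(st_b, rel=1e-6)
        assert dy_a != pytest.approx(dy_b, rel=1e-3)


class TestImpact:
    def test_zero_perturbation_zero_impact_every_mode(self, fixtures):
        h, emb = (fixtures["chain"]["hypergraph"],
                  fixtures["chain"]["embedding"])
        for mode in ("dynamic_4d", "steady_state_4d", "orthogonal_3d_sum"):
            s = mn.impact_score(h, emb, "mb", mode,
                                sp.ImpactSettings(d=0.0, t_max=5.0))
            assert s == pytest.approx(0.0, abs=1e-8)

    def test_dynamic_impact_matches_oracle_quadrature(self):
        h = Hypergraph(["anchor", "free"], ["m1"], [[1], [1]])
        emb = sp.PhysicalEmbedding(
            {"anchor": np.zeros(3), "free": np.r_[1.0, 0, 0]},
            {"anchor": True, "free": False})
        s = sp.build_spring_system(h, emb)
        state = sp.PerturbationState(
            s, np.array([[0, 0, 0, 1.0], [1, 0, 0, 0]]),
            np.array([True, False]), "m1", 1.0)
        dt = 1e-4
        t_max = 5.0
        traj = sp.integrate_dynamics(state, dt=dt, t_max=t_max, speed_tol=0.0)
        oracle = one_spring_oracle(traj.times)
        disp = np.linalg.norm(oracle - np.r_[1.0, 0, 0, 0], axis=1)
        oracle_quadrature = float(np.sum(disp) * dt)
        assert traj.free_displacement_integral == pytest.approx(
            oracle_quadrature, rel=1e-3)

    def test_higher_degree_muscle_has_larger_static_impact(self, fixtures):
        h, emb = (fixtures["chain"]["hypergraph"],
                  fixtures["chain"]["embedding"])
        table = mn.impact_all(h, emb, "steady_state_4d")
        scores = dict(zip(table.muscle, table.impact))
        assert scores["ma"] > scores["mb"]
        assert scores["ma"] > scores["mc"]

    def test_impact_all_rows_finite_and_order_invariant(self, small_body,
                                                        small_impacts):
        h, emb, _ = small_body
        assert len(small_impacts) == h.n_muscles
        assert np.isfinite(small_impacts["impact"]).all()
        one = mn.impact_score(h, emb, h.muscle_labels[13], "steady_state_4d")
        row = small_impacts.set_index("muscle").loc[h.muscle_labels[13]]
        assert one == pytest.approx(row["impact"], rel=1e-9)

    def test_clamped_term_grows_with_membership(self):
        # star muscles of increasing degree: the clamped contribution
        # to the impact is k*d and never decreases with added members
        prev = -np.inf
        for k in (2, 3, 5):
            bones = [f"b{i}" for i in range(k + 1)]
            inc = np.zeros((k + 1, 2), dtype=int)
            inc[:k, 0] = 1                       # perturbed muscle m
            inc[[k - 1, k], 1] = 1               # tie to the fixed anchor
            emb = sp.PhysicalEmbedding(
                {f"b{i}": np.r_[float(i), 0, 0] for i in range(k + 1)},
                {f"b{i}": i == k for i in range(k + 1)})
            h2 = Hypergraph(bones, ["m", "tie"], inc)
            s = sp.build_spring_system(h2, emb)
            eq = sp.steady_state_solve(sp.perturb_muscle(s, "m", 1.0))
            clamped_term = eq.displacements[:k].sum()
            assert clamped_term >= prev
            prev = clamped_term

    def test_dt_refinement_changes_impact_under_one_percent(self, fixtures):
        h, emb = (fixtures["chain"]["hypergraph"],
                  fixtures["chain"]["embedding"])
        coarse = mn.impact_score(h, emb, "ma", "dynamic_4d",
                                 sp.ImpactSettings(dt=0.01, t_max=40.0,
                                                   speed_tol=0.0))
        fine = mn.impact_score(h, emb, "ma", "dynamic_4d",
                               sp.ImpactSettings(dt=0.005, t_max=40.0,
                                                 speed_tol=0.0))
        assert abs(coarse - fine) / fine < 0.01

    def test_orthogonal_sum_mode_positive(self, fixtures):
        h, emb = (fixtures["chain"]["hypergraph"],
                  fixtures["chain"]["embedding"])
        s = mn.impact_score(h, emb, "mb", "orthogonal_3d_sum")
        assert s > 0


class TestMostImpacted:
    def test_chain_ranks_adjacent_above_distant(self, fixtures):
        h, emb = (fixtures["chain"]["hypergraph"],
                  fixtures["chain"]["embedding"])
        ranked = mn.most_impacted(h, emb, ["ma"])
        assert list(ranked["muscle"]) == ["mb", "mc"]
        assert ranked["displacement"].iloc[0] > ranked["displacement"].iloc[1]

    def test_empty_target_set_rejected(self, fixtures):
        h, emb = (fixtures["chain"]["hypergraph"],
                  fixtures["chain"]["embedding"])
        with pytest.raises(ValueError):
            mn.most_impacted(h, emb, ["ma"], exclude=["mb", "mc"])
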