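"""Network dynamics: derivative structure, equilibria and solver agreement."""

import numpy as np
import pytest

from immunet import dynamics as dy
from immunet import genome as gn

PHI = 0.3


def _host_with_uniform_edges(value_bits: int) -> gn.HostGenome:
    """Host whose every input domain is at Hamming distance `value_bits`
    from every output domain."""
    block = np.zeros((4, 3, 10), dtype=np.uint8)
    block[:, gn.S_O, :value_bits] = 1
    return gn.HostGenome.from_array(block)


class TestBuildInteractions:
    def test_all_matching_domains_give_mu_one(self):
        m = dy.build_interactions(_host_with_uniform_edges(0))
        assert np.allclose(m.mu, 1.0)
        assert m.mu_rp is None

    def test_maximal_mismatch_gives_mu_minus_one(self):
        m = dy.build_interactions(_host_with_uniform_edges(10))
        assert np.allclose(m.mu, -1.0)

    def test_parasite_only_adds_receptor_edge(self, rng):
        host = gn.random_genome("host", 10, rng)
        par = gn.random_genome("parasite", 10, rng)
        alone = dy.build_interactions(host)
        with_par = dy.build_interactions(host, par, "specific")
        assert np.array_equal(alone.mu, with_par.mu)
        assert with_par.mu_rp in (0.0, 1.0)

    def test_population_coefficients_match_single_genome_path(self, rng):
        pop = gn.random_host_population(20, 10, rng)
        batch = dy.host_edge_coefficients(pop)
        for i in range(20):
            single = dy.build_interactions(gn.HostGenome.from_array(pop[i])).mu
            assert np.allclose(batch[i], single)


class TestDerivative:
    def test_receptor_without_parasite_has_no_inputs(self, rng):
        host = gn.random_genome("host", 10, rng)
        m = dy.build_interactions(host)
        d = dy.derivative(dy.ActivityState(0.0, 0.0, 0.0), m, PHI, parasite_present=False)
        assert d[0] == 0.0

    def test_receptor_rate_at_rest_equals_driving_input(self):
        m = dy.InteractionMatrix(np.zeros(6), mu_rp=0.2)
        d = dy.derivative(dy.ActivityState(0.0, 0.0, 0.0), m, PHI, parasite_present=True)
        assert d[0] == pytest.approx(0.2)

    def test_saturated_node_can_only_decay(self):
        """At y_i = 1 activation vanishes, so dy/dt = -phi."""
        m = dy.build_interactions(_host_with_uniform_edges(0))
        d = dy.derivative(dy.ActivityState(0.0, 1.0, 1.0), m, PHI)
        assert d[1] == pytest.approx(-PHI)
        assert d[2] == pytest.approx(-PHI)

    def test_boundary_derivatives_preserve_unit_interval(self, rng):
        """dy >= 0 at y=0 and dy <= 0 at y=1 for random genomes."""
        for _ in range(100):
            host = gn.random_genome("host", 10, rng)
            par = gn.random_genome("parasite", 10, rng)
            m = dy.build_interactions(host, par, "nonspecific")
            low = dy.derivative(dy.ActivityState(0, 0, 0), m, PHI, True)
            high = dy.derivative(dy.ActivityState(1, 1, 1), m, PHI, True)
            assert np.all(low >= 0)
            assert np.all(high <= 0)


class TestClosedForms:
    def test_receptor_specific_detection(self):
        """Single-input node: y = mu/(phi+mu) -> 1/1.3 for a detected parasite."""
        assert dy.receptor_equilibrium(1.0, PHI) == pytest.approx(1 / 1.3)

    def test_receptor_nonspecific(self):
        assert dy.receptor_equilibrium(0.2, PHI) == pytest.approx(0.4)

    def test_receptor_undriven_or_inhibited_is_zero(self):
        assert dy.receptor_equilibrium(0.0, PHI) == 0.0
        assert dy.receptor_equilibrium(-0.5, PHI) == 0.0

    def test_effectors_driven_only_by_C(self):
        """With both C edges +1 and zero cross-regulation, each effector is a
        single-input node: y = 1/(phi+1)."""
        m = dy.InteractionMatrix(np.array([0.0, 0.0, 1.0, 1.0, 0.0, 0.0]))
        s = dy.solve_equilibrium(m, PHI)
        assert s.y_es == pytest.approx(1 / 1.3, abs=1e-7)
        assert s.y_en == pytest.approx(1 / 1.3, abs=1e-7)

    def test_rk4_reproduces_closed_form(self):
        m = dy.InteractionMatrix(np.array([0.0, 0.0, 0.5, -0.3, 0.0, 0.0]))
        s = dy.solve_equilibrium(m, PHI, method="rk4")
        assert s.y_es == pytest.approx(0.5 / (PHI + 0.5), abs=1e-7)
        assert s.y_en == pytest.approx(0.0, abs=1e-7)


class TestSolverAgreement:
    def test_fixed_point_matches_rk4_on_random_genomes(self, rng):
        """Constitutive and induced equilibria from the damped accelerator
        agree with forward RK4 integration from the same initial state."""
        n = 200
        hosts = gn.random_host_population(n, 10, rng)
        mu6 = dy.host_edge_coefficients(hosts)
        y0, _ = dy.effector_equilibria(mu6, np.zeros(n), PHI, None, 1e-8)
        rk_const = dy._rk4_batch(mu6, 0.0, PHI, np.zeros((n, 3)), False, 1e-8, 1e3)
        assert np.max(np.abs(rk_const[:, 1:] - y0)) < 1e-6

        mu_rp = rng.choice([0.0, 0.2, 1.0], size=n)
        y_r = dy.receptor_equilibrium(mu_rp, PHI)
        ystar, _ = dy.effector_equilibria(mu6, y_r, PHI, y0, 1e-8)
        init = np.concatenate([np.zeros((n, 1)), y0], axis=1)
        rk_ind = dy._rk4_batch(mu6, mu_rp, PHI, init, True, 1e-8, 1e3)
        assert np.max(np.abs(rk_ind[:, 0] - y_r)) < 1e-6
        assert np.max(np.abs(rk_ind[:, 1:] - ystar)) < 1e-6

    def test_fixed_point_residual_is_reported(self, rng):
        host = gn.random_genome("host", 10, rng)
        m = dy.build_interactions(host)
        state, info = dy.solve_equilibrium(m, PHI, full_output=True)
        assert info["residual"] < 1e-7
        assert info["iterations"] >= 1
        assert 0.0 <= state.y_es <= 1.0

    def test_activities_stay_in_unit_interval(self, rng):
        pop = gn.random_host_population(2000, 10, rng)
        mu6 = dy.host_edge_coefficients(pop)
        y0, _ = dy.effector_equilibria(mu6, np.zeros(2000), PHI, None, 1e-8)
        ystar, _ = dy.effector_equilibria(mu6, np.full(2000, 1 / 1.3), PHI, y0, 1e-8)
        for y in (y0, ystar):
            assert np.all(y >= 0.0) and np.all(y <= 1.0)


class TestConstitutiveAndInducedStates:
    def test_receptor_rests_at_zero_without_parasite(self, rng):
        host = gn.random_genome("host", 10, rng)
        assert dy.constitutive_state(host).y_r == 0.0

    def test_undetected_parasite_changes_nothing(self, rng):
        """Specific receptor below the match threshold: mu_RxP = 0 makes the
        infected system identical to the resting one."""
        from immunet.io import make_fixture

        host, par = make_fixture("escaped_parasite")
        rest = dy.constitutive_state(host)
        induced = dy.induced_state(host, par, "specific")
        assert induced.y_r == 0.0
        assert induced.y_es == pytest.approx(rest.y_es, abs=1e-7)
        assert induced.y_en == pytest.approx(rest.y_en, abs=1e-7)

    def test_mismatched_receptor_cannot_induce(self):
        """Both receptor->effector edges inhibitory: induced component <= 0."""
        block = np.zeros((4, 3, 10), dtype=np.uint8)
        block[gn.R, gn.S_O] = 1  # receptor output mismatches both effector inputs
        host = gn.HostGenome.from_array(block)
        par = gn.ParasiteGenome.from_array(np.zeros((3, 10), dtype=np.uint8))
        rest = dy.constitutive_state(host)
        induced = dy.induced_state(host, par, "nonspecific")
        assert induced.y_es <= rest.y_es + 1e-9
        assert induced.y_en <= rest.y_en + 1e-9

    def test_induced_state_insensitive_to_init_on_random_genomes(self, rng):
        """Uniqueness probe: solving the infected system from rest vs from
        zero reaches the same equilibrium for sampled genomes."""
        for _ in range(50):
            host = gn.random_genome("host", 10, rng)
            par = gn.random_genome("parasite", 10, rng)
            m = dy.build_interactions(host, par, "nonspecific")
            rest = dy.constitutive_state(host)
            from_rest = dy.solve_equilibrium(m, PHI, True, init=rest, tol=1e-9)
            from_zero = dy.solve_equilibrium(m, PHI, True, tol=1e-9)
            assert np.allclose(from_rest.as_array(), from_zero.as_array(), atol=1e-7)

    def test_nonconvergence_raises(self):
        m = dy.InteractionMatrix(np.zeros(6), mu_rp=0.2)
        with pytest.raises(dy.EquilibriumError):
            dy.integrate_rk4(m, PHI, parasite_present=True, t_max=0.1, tol=1e-12)
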