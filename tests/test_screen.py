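"""Screening pipeline: topology enumeration, existence decisions,
classification, phases, robustness and the minimum diffusion ratio."""

import numpy as np
import pytest

from rdscreen import (
    ConstraintSet,
    DiffusionRegime,
    NetworkGraph,
    RDSystem,
    RobustnessOptions,
    ScreenOptions,
    Topology,
    enumerate_topologies,
    fixture,
    make_nodes,
    min_diffusion_ratio,
    phase_pattern,
    robustness,
    run_pipeline,
    topology_is_stable,
    topology_turing_capable,
)
from rdscreen.lsa import is_turing_unstable

D_CRIT = 4 + 2 * np.sqrt(3)

FAST = ScreenOptions(budget=6000, chunk=3000, robustness_samples=0, classify=False)


class TestEnumerateTopologies:
    def test_unconstrained_two_node_has_sixteen(self, two_node_net):
        tops = list(enumerate_topologies(two_node_net))
        assert len(tops) == 16
        assert len({t.sign_bits() for t in tops}) == 16

    def test_sign_constraints_halve_the_count(self, two_node_net):
        cons = ConstraintSet(sign_constraints={(0, 0): +1, (1, 1): -1})
        assert len(list(enumerate_topologies(two_node_net, cons))) == 4

    def test_fully_constrained_single_topology(self, two_node_net):
        cons = ConstraintSet(
            sign_constraints={(0, 0): +1, (0, 1): -1, (1, 0): +1, (1, 1): -1}
        )
        tops = list(enumerate_topologies(two_node_net, cons))
        assert len(tops) == 1
        assert tops[0].signs[(0, 1)] == -1


class TestStability:
    def test_pure_mutual_activation_never_stable(self, two_node_net):
        top = Topology(two_node_net, {e: +1 for e in two_node_net.edges})
        found, witness = topology_is_stable(top, FAST, seed=3)
        assert not found and witness is None

    def test_activator_inhibitor_has_stable_witness(self, activator_inhibitor):
        found, J = topology_is_stable(activator_inhibitor, FAST, seed=3)
        assert found
        assert np.linalg.eigvals(J).real.max() < 0


class TestTuringCapability:
    def test_activator_inhibitor_free_regime(self, activator_inhibitor):
        found, w = topology_turing_capable(activator_inhibitor, DiffusionRegime("free"), FAST, seed=3)
        assert found
        rep = is_turing_unstable(RDSystem(w.J, w.D))
        assert rep.turing_unstable

    def test_activator_inhibitor_cannot_pattern_with_equal_diffusivities(self, activator_inhibitor):
        found, _ = topology_turing_capable(activator_inhibitor, DiffusionRegime("equal"), FAST, seed=3)
        assert not found

    def test_capacitor_topology_universal_under_permissive_criterion(self, three_nodes):
        # sign structure of the capacitor fixture: stable Jacobian with an
        # unstable immobile sub-block certifies every diffusion choice
        net = NetworkGraph(
            three_nodes, frozenset({(0, 0), (1, 1), (0, 2), (1, 2), (2, 0), (2, 1), (2, 2)})
        )
        top = Topology(net, {(0, 0): -1, (1, 1): -1, (0, 2): +1, (1, 2): +1,
                             (2, 0): -1, (2, 1): -1, (2, 2): +1})
        opts = ScreenOptions(budget=6000, chunk=3000, wavelength_selection=False,
                             classify=False, robustness_samples=0)
        found, w = topology_turing_capable(top, DiffusionRegime("universal"), opts, seed=3)
        assert found
        assert np.linalg.eigvals(w.J).real.max() < 0
        assert w.J[2, 2] > 0

    def test_budget_monotonicity(self, activator_inhibitor):
        """A witness found at a small budget is still found at any larger
        budget with the same seed (prefix property of the draw streams)."""
        small = ScreenOptions(budget=2000, chunk=1000, classify=False, robustness_samples=0)
        large = ScreenOptions(budget=8000, chunk=1000, classify=False, robustness_samples=0)
        f_small, w_small = topology_turing_capable(activator_inhibitor, None, small, seed=11)
        f_large, w_large = topology_turing_capable(activator_inhibitor, None, large, seed=11)
        assert f_small and f_large
        assert np.array_equal(w_small.J, w_large.J)


class TestPhasePattern:
    def test_activator_inhibitor_is_in_phase(self, activator_inhibitor):
        _, w = topology_turing_capable(activator_inhibitor, None, FAST, seed=3)
        assert phase_pattern(RDSystem(w.J, w.D)) == (1, 1)

    def test_substrate_depleted_is_out_of_phase(self, substrate_depleted):
        _, w = topology_turing_capable(substrate_depleted, None, FAST, seed=3)
        assert phase_pattern(RDSystem(w.J, w.D)) == (1, -1)

    def test_eigenvector_signs_for_reference_jacobian(self, ai_jacobian):
        sys = RDSystem(ai_jacobian, np.array([1.0, 10.0]))
        assert phase_pattern(sys) == (1, 1)


class TestPipeline:
    def test_two_node_control(self):
        cfg = fixture("two_node")
        res = run_pipeline(cfg.nodes, cfg.k, options=ScreenOptions(
            budget=6000, chunk=3000, robustness_samples=0, seed=5))
        assert res.n_networks == 1
        entry = res.entries[0]
        assert entry.n_phase_classes == 2
        assert set(entry.phase_classes) == {(1, 1), (1, -1)}
        assert entry.network_type == "I"
        counts = res.step_table.to_frame()[["n_networks", "n_topologies"]].to_numpy()
        assert (np.diff(counts, axis=0) <= 0).all()  # steps only remove

    def test_rejects_fewer_than_two_diffusible_nodes(self):
        nodes = make_nodes([True, False])
        with pytest.raises(ValueError, match="two diffusible"):
            run_pipeline(nodes, 4)

    def test_nodal_lefty_screen(self):
        cfg = fixture("nodal_lefty")
        res = cfg.run(cfg.options(budget=8000, robustness_samples=0, seed=2))
        assert res.n_networks == 2
        types = {}
        for e in res.entries:
            mechanism = "receptor" if (2, 1) in e.network.edges else "direct"
            types[mechanism] = e.network_type
        assert types == {"receptor": "II", "direct": "III"}
        # the phase constraint held: Nodal and Lefty in phase everywhere
        for e in res.entries:
            for s in e.surviving:
                assert s.phase[0] == s.phase[1]

    def test_witnesses_replay(self):
        cfg = fixture("two_node")
        res = cfg.run(cfg.options(budget=6000, robustness_samples=0, seed=5))
        for entry in res.entries:
            for surv in entry.surviving:
                rep = is_turing_unstable(surv.system(), require_wavelength_selection=True)
                assert rep.turing_unstable

    def test_type_hierarchy_on_classified_entries(self):
        cfg = fixture("nodal_lefty")
        res = cfg.run(cfg.options(budget=8000, robustness_samples=0, seed=2))
        for e in res.entries:
            if e.network_type == "III":
                capable_equal = any(
                    topology_turing_capable(
                        s.topology, DiffusionRegime("equal"), FAST, seed=7,
                        constraints=cfg.constraints)[0]
                    for s in e.surviving
                )
                assert capable_equal  # III implies equal-diffusivity capable


class TestRobustness:
    def test_all_negative_cycle_topology_has_zero_volume(self, two_node_net):
        top = Topology(two_node_net, {(0, 0): -1, (0, 1): -1, (1, 0): +1, (1, 1): -1})
        est = robustness(top, opts=RobustnessOptions(n_samples=4000, seed=1))
        assert est.value == 0.0

    def test_activator_inhibitor_equal_regime_is_impossible(self, activator_inhibitor):
        est = robustness(activator_inhibitor, DiffusionRegime("equal"),
                         RobustnessOptions(n_samples=4000, seed=1))
        assert est.value == 0.0

    def test_free_regime_matches_closed_form_oracle(self, activator_inhibitor):
        """MC estimate within 3 SE of a dense low-discrepancy evaluation of
        the closed-form two-node conditions."""
        from scipy.stats import qmc

        est = robustness(activator_inhibitor, DiffusionRegime("free"),
                         RobustnessOptions(n_samples=60000, seed=9))
        sob = qmc.Sobol(d=6, scramble=False, seed=0)
        pts = sob.random_base2(m=20)
        a, b, c, e = (0.5 * pts[:, i] for i in range(4))
        d1, d2 = pts[:, 4], pts[:, 5]
        det = -a * e + b * c
        stable = (a - e < 0) & (det > 0)
        s = d2 * a - d1 * e
        turing = stable & (s > 0) & (s * s > 4 * d1 * d2 * det)
        oracle = turing.mean()
        assert abs(est.value - oracle) < 3 * est.stderr

    def test_convergence_rate(self, activator_inhibitor):
        small = robustness(activator_inhibitor, opts=RobustnessOptions(n_samples=5000, seed=4))
        large = robustness(activator_inhibitor, opts=RobustnessOptions(n_samples=20000, seed=5))
        assert small.stderr == pytest.approx(2 * large.stderr, rel=0.35)
        assert abs(small.value - large.value) < 3 * (small.stderr + large.stderr)


class TestMinDiffusionRatio:
    def test_reference_jacobian_threshold(self, two_node_net):
        top = Topology(two_node_net, {(0, 0): +1, (0, 1): -1, (1, 0): +1, (1, 1): -1})
        cons = ConstraintSet(value_constraints={(0, 0): 1.0, (0, 1): -1.0,
                                                (1, 0): 3.0, (1, 1): -2.0})
        r = min_diffusion_ratio(top, cons)
        assert r == pytest.approx(D_CRIT, abs=1e-3)

    def test_unconstrained_diffusivity_network_has_zero_infimum(self):
        cfg = fixture("nodal_lefty")
        res = cfg.run(cfg.options(budget=6000, robustness_samples=0, classify=False, seed=2))
        direct = next(e for e in res.entries if (0, 1) in e.network.edges)
        top = direct.surviving[0].topology
        opts = ScreenOptions(budget=3000, chunk=1500)
        r = min_diffusion_ratio(top, cfg.constraints, opts, n_scan=33)
        assert r == 0.0

    def test_infeasible_topology_returns_none(self, two_node_net):
        top = Topology(two_node_net, {(0, 0): -1, (0, 1): -1, (1, 0): +1, (1, 1): -1})
        opts = ScreenOptions(budget=2000, chunk=1000)
        assert min_diffusion_ratio(top, None, opts, n_scan=17) is None
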