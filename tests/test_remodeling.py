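"""Biochemical rule semantics: geometry of polymerization, nucleotide
dynamics, branching, capping, cofilin, bundling, breaking, severing,
and mass balance."""

import math

import numpy as np
import pytest

from spinedgg.engine import enumerate_instances, fire, run, step
from spinedgg.fixtures import (branched_y, bundled_pair,
                               cofilactin_boundary_filament, seed_spine,
                               straight_filament)
from spinedgg.remodeling import (Aip1Bind, Aip1Sever, BarbedElongation,
                                 BarbedRetraction, BranchNucleation,
                                 BreakFilament, CamkiiBind, CamkiiUnbind,
                                 Cap, CofilinBindAccel1, CofilinBindAccel2,
                                 CofilinBindBare, CofilinUnbind, Debranch,
                                 NucleotideHydrolysis, PiRelease,
                                 PointedElongation, PointedRetraction,
                                 Uncap, remodeling_rules)


def _one(state, rule):
    insts = enumerate_instances(state, rule)
    assert len(insts) == 1
    return insts[0]


class TestElongationGeometry:
    def test_zero_angle_continues_colinearly(self, params, scripted_rng):
        state = straight_filament(2, params)
        state.rng = scripted_rng(normals=[0.0])
        fire(state, _one(state, BarbedElongation()))
        new = state.graph.nodes[2]
        assert np.allclose(new.x, [2.0, 0.0], atol=1e-12)

    def test_right_angle_rotation(self, params, scripted_rng):
        state = straight_filament(2, params)
        state.rng = scripted_rng(normals=[math.pi / 2])
        fire(state, _one(state, BarbedElongation()))
        assert np.allclose(state.graph.nodes[2].x, [1.0, 1.0], atol=1e-12)
        # the old end stores the drawn angle
        assert state.graph.nodes[1].theta == pytest.approx(math.pi / 2)

    def test_pointed_elongation_opposite_direction(self, params, scripted_rng):
        state = straight_filament(2, params)
        state.rng = scripted_rng(normals=[0.0])
        fire(state, _one(state, PointedElongation()))
        new_id = max(state.graph.nodes)
        assert np.allclose(state.graph.nodes[new_id].x, [-1.0, 0.0],
                           atol=1e-12)
        assert state.graph.kind(new_id) == "pointed_end"

    def test_mirror_symmetry_of_signed_angle(self, params, scripted_rng):
        theta = 0.4
        bstate = straight_filament(2, params)
        bstate.rng = scripted_rng(normals=[theta])
        fire(bstate, _one(bstate, BarbedElongation()))
        pstate = straight_filament(2, params)
        pstate.rng = scripted_rng(normals=[theta])
        fire(pstate, _one(pstate, PointedElongation()))
        xb = bstate.graph.nodes[2].x          # barbed growth from (1, 0)
        xp = pstate.graph.nodes[2].x          # pointed growth from (0, 0)
        # same magnitude of deflection, mirrored across the filament axis
        assert xb[1] == pytest.approx(xp[1])

    def test_elongation_angle_distribution(self, params, rng):
        state = straight_filament(2, params)
        state.rng = rng
        state.pools.counts["actin"] = 1e9
        rule = BarbedElongation()
        draws = []
        for _ in range(10_000):
            fire(state, _one(state, rule))
            draws.append(state.graph.nodes[1].theta)
            new_id = max(state.graph.nodes)
            state.graph.set_next(1, None)
            state.graph.remove_node(new_id)
            state.graph.nodes[1].theta = 0.0
        sd = float(np.std(draws))
        assert abs(float(np.mean(draws))) < 3 * sd / math.sqrt(len(draws))
        assert sd == pytest.approx(params.sigma_theta, rel=0.03)


class TestRetraction:
    def test_retraction_restores_two_node_filament(self, params):
        state = straight_filament(3, params)
        fire(state, _one(state, BarbedRetraction()))
        assert sorted(state.graph.nodes) == [0, 1]
        assert state.graph.kind(1) == "barbed_end"
        assert state.graph.nodes[1].theta == 0.0

    def test_seed_dimer_persists(self, params):
        state = straight_filament(2, params)
        assert enumerate_instances(state, BarbedRetraction()) == []
        assert enumerate_instances(state, PointedRetraction()) == []

    def test_all_adp_off_rate_is_7p2_per_s(self, params):
        state = straight_filament(3, params, all_adp=True)
        inst = _one(state, BarbedRetraction())
        assert inst.propensity == pytest.approx(7.2)

    def test_monomer_conservation_elongate_retract_cycle(self, params):
        state = straight_filament(2, params)
        total = (state.pools.counts["actin"]
                 + state.graph.total_monomers())
        state.rng = np.random.default_rng(0)
        fire(state, _one(state, BarbedElongation()))
        fire(state, _one(state, BarbedRetraction()))
        assert (state.pools.counts["actin"] + state.graph.total_monomers()
                == pytest.approx(total))

    def test_treadmilling_net_barbed_drift(self, params):
        from spinedgg.membrane import make_circle
        from spinedgg.pools import init_steady_state
        state = straight_filament(8, params, with_rules=False)
        # roomy membrane and a correspondingly large replenished pool so
        # neither end is wall-limited over the run
        state.membrane = make_circle(300.0, 64, center=(3.5, 0.0))
        state.pools = init_steady_state(params, state.membrane.signed_area())
        state.rng = np.random.default_rng(3)
        state.register(BarbedElongation(), BarbedRetraction(),
                       PointedElongation(), PointedRetraction())
        x0 = np.mean([n.x[0] for n in state.graph.nodes.values()])
        run(state, 1e9, max_events=600)
        x1 = np.mean([n.x[0] for n in state.graph.nodes.values()])
        assert x1 > x0


class TestNucleotideDynamics:
    def test_hydrolysis_propensity_is_per_monomer(self, params):
        state = straight_filament(2, params)
        insts = enumerate_instances(state, NucleotideHydrolysis())
        assert all(i.propensity == pytest.approx(12 * 0.35) for i in insts)

    def test_sequential_states(self, params):
        state = straight_filament(2, params)
        fire(state, enumerate_instances(state, NucleotideHydrolysis())[0])
        node = state.graph.nodes[0]
        assert (node.n_atp, node.n_adp_pi, node.n_adp) == (11, 1, 0)
        fire(state, enumerate_instances(state, PiRelease())[0])
        assert (node.n_atp, node.n_adp_pi, node.n_adp) == (11, 0, 1)

    def test_cofilin_accelerates_pi_release(self, params):
        state = cofilactin_boundary_filament(params, n=6)
        for node in state.graph.nodes.values():
            node.n_adp_pi, node.n_adp = node.n_adp, node.n_adp_pi
        insts = {i.key[0]: i.propensity
                 for i in enumerate_instances(state, PiRelease())}
        # node 0 is far from cofilin; node 2 is adjacent to cofilin at 3
        assert insts[2] / insts[0] == pytest.approx(0.035 / 0.006)

    def test_no_substrate_no_instances(self, params):
        state = straight_filament(2, params, all_adp=True)
        assert enumerate_instances(state, NucleotideHydrolysis()) == []
        assert enumerate_instances(state, PiRelease()) == []


class TestBranching:
    def test_branch_angle_magnitude_and_sides(self, params, rng):
        state = straight_filament(3, params)
        state.rng = rng
        state.pools.counts["arp23"] = 1e9
        state.pools.counts["actin"] = 1e9
        rule = BranchNucleation()
        angles = []
        for _ in range(10_000):
            inst = next(i for i in enumerate_instances(state, rule)
                        if i.key[0] == 1)
            fire(state, inst)
            angles.append(state.graph.nodes[1].theta_branch)
            did = state.graph.nodes[1].daughter_id
            state.graph.set_daughter(1, None)
            state.graph.remove_node(did)
        angles = np.array(angles)
        mean_abs = math.degrees(float(np.mean(np.abs(angles))))
        se = math.degrees(float(np.std(np.abs(angles))
                                / math.sqrt(len(angles))))
        assert abs(mean_abs - 70.0) < 3 * se
        frac_pos = float(np.mean(angles > 0))
        assert abs(frac_pos - 0.5) < 3 * math.sqrt(0.25 / len(angles))

    def test_cofilin_blocks_branching(self, params):
        state = straight_filament(3, params)
        node = state.graph.nodes[1]
        node.n_adp = node.n_mono
        node.n_atp = 0
        node.n_cof = node.n_mono
        keys = [i.key[0]
                for i in enumerate_instances(state, BranchNucleation())]
        assert 1 not in keys

    def test_branch_makes_junction_with_two_outgoing(self, params):
        state = branched_y(params)
        assert state.graph.kind(1) == "junction"
        assert abs(math.degrees(state.graph.nodes[1].theta_branch)
                   - 70.0) < 1e-6

    def test_debranch_node_count_conserved_and_rates(self, params):
        state = branched_y(params)
        n0 = len(state.graph.nodes)
        inst = _one(state, Debranch())
        assert inst.propensity == pytest.approx(2e-3)
        # full cofilin occupancy on junction and neighbors: x50
        for nid in (0, 1, 2, 3):
            node = state.graph.nodes[nid]
            node.n_cof = node.n_mono
        inst50 = _one(state, Debranch())
        assert inst50.propensity / 2e-3 == pytest.approx(50.0)
        fire(state, inst50)
        assert len(state.graph.nodes) == n0
        assert len(state.graph.filaments()) == 2


class TestCapping:
    def test_cap_blocks_elongation_and_retraction(self, params):
        state = straight_filament(3, params)
        fire(state, _one(state, Cap()))
        assert state.graph.kind(2) == "capped_end"
        assert enumerate_instances(state, BarbedElongation()) == []
        assert enumerate_instances(state, BarbedRetraction()) == []

    def test_cap_uncap_round_trip(self, params):
        state = straight_filament(3, params)
        cap_count = state.pools.counts["cap"]
        fire(state, _one(state, Cap()))
        fire(state, _one(state, Uncap()))
        assert state.graph.kind(2) == "barbed_end"
        assert state.pools.counts["cap"] == pytest.approx(cap_count)

    def test_cap_propensity_mass_action(self, params):
        state = straight_filament(3, params)
        a1 = _one(state, Cap()).propensity
        state.pools.counts["cap"] *= 2
        assert _one(state, Cap()).propensity == pytest.approx(2 * a1)


class TestCofilin:
    def test_bare_binding_requires_hydrolyzed_object(self, params):
        atp_state = straight_filament(3, params)
        assert enumerate_instances(atp_state, CofilinBindBare()) == []
        adp_state = straight_filament(3, params, all_adp=True)
        assert len(enumerate_instances(adp_state, CofilinBindBare())) == 3

    def test_rate_hierarchy_accelerated_vs_bare(self, params):
        state = straight_filament(3, params, all_adp=True)
        bare = enumerate_instances(state, CofilinBindBare())[0].propensity
        fire(state, enumerate_instances(state, CofilinBindBare())[0])
        state.pools.counts["cof"] += 1   # compare at equal concentration
        accel = _one(state, CofilinBindAccel1()).propensity
        # 2 x 17e6 vs 1e4 per molar: the cooperative pathway dominates
        assert accel / bare == pytest.approx(2 * 17e6 / 1e4, rel=1e-9)

    def test_flanked_node_doubled(self, params):
        state = cofilactin_boundary_filament(params, n=6)
        node2 = state.graph.nodes[2]        # bare, next to cofilactin at 3
        insts = {i.key[0]: i.propensity
                 for i in enumerate_instances(state, CofilinBindAccel2())}
        single = insts[2]
        # decorate node 1 as well: node 2 is now flanked on both sides
        node1 = state.graph.nodes[1]
        node1.n_cof = node1.n_mono
        insts2 = {i.key[0]: i.propensity
                  for i in enumerate_instances(state, CofilinBindAccel2())}
        assert insts2[2] == pytest.approx(2 * single)

    def test_unbind_returns_pool_and_clears_aip1(self, params):
        state = cofilactin_boundary_filament(params, n=4)
        node = state.graph.nodes[3]
        node.n_cof = 1
        node.aip1 = True
        pool_cof = state.pools.counts["cof"]
        pool_aip = state.pools.counts["aip1"]
        inst = next(i for i in enumerate_instances(state, CofilinUnbind())
                    if i.key[0] == 3)
        fire(state, inst)
        assert node.n_cof == 0 and not node.aip1
        assert state.pools.counts["cof"] == pytest.approx(pool_cof + 1)
        assert state.pools.counts["aip1"] == pytest.approx(pool_aip + 1)


class TestCamkii:
    def test_eligible_pair_within_distance_and_angle(self, params):
        # 0.01 um apart (< 0.0175 um) at 5 degrees (< 15): eligible
        sep = 0.01e-6 / params.l0
        state = bundled_pair(params, separation=sep)
        state.graph.remove_link(0)
        for nid in (3, 4, 5):
            node = state.graph.nodes[nid]
            c, s = math.cos(math.radians(5)), math.sin(math.radians(5))
            node.x = np.array([nid - 3, sep]) @ np.array([[c, s], [-s, c]]).T \
                + np.array([0.0, sep])
        assert enumerate_instances(state, CamkiiBind())

    def test_20_degrees_ineligible(self, params):
        sep = 0.3
        state = bundled_pair(params, separation=sep)
        state.graph.remove_link(0)
        c, s = math.cos(math.radians(20)), math.sin(math.radians(20))
        rot = np.array([[c, -s], [s, c]])
        for nid in (3, 4, 5):
            node = state.graph.nodes[nid]
            node.x = rot @ np.array([float(nid - 3), 0.0]) + [0, sep]
        assert enumerate_instances(state, CamkiiBind()) == []

    def test_bound_lifetime_reciprocal_off_rate(self, params):
        state = bundled_pair(params, with_rules=False)
        state.register(CamkiiUnbind())
        dts = []
        for _ in range(2000):
            _, dt = step(state)
            dts.append(dt)
            state.graph.add_link(1, 4, 0.5)
        mean = float(np.mean(dts))
        se = float(np.std(dts) / math.sqrt(len(dts)))
        assert abs(mean - 1 / 0.23) < 3 * se

    def test_cofilin_and_camkii_mutually_exclusive(self, params):
        state = bundled_pair(params)
        node = state.graph.nodes[1]         # carries the bundle link
        node.n_adp, node.n_atp = node.n_mono, 0
        keys = [i.key[0]
                for i in enumerate_instances(state, CofilinBindBare())]
        assert 1 not in keys


class TestBreakingGates:
    @pytest.mark.parametrize("angle_deg,cof_pattern,eligible", [
        (60, "bare", True),      # 60 > 57 bare threshold
        (50, "bare", False),
        (40, "boundary", True),  # 40 > 31 boundary threshold
        (40, "bare", False),     # same geometry, no boundary: 40 < 57
        (75, "cofilactin", True),
        (60, "cofilactin", False),   # 60 < 73 for cofilactin
        (0, "boundary", False),  # never at zero angle
    ])
    def test_threshold_selection(self, params, angle_deg, cof_pattern,
                                 eligible):
        state = straight_filament(4, params, all_adp=True)
        g = state.graph
        if cof_pattern == "boundary":
            g.nodes[2].n_cof = g.nodes[2].n_mono
        elif cof_pattern == "cofilactin":
            for nid in (1, 2):
                g.nodes[nid].n_cof = g.nodes[nid].n_mono
        g.nodes[1].theta = math.radians(angle_deg)
        keys = [i.key for i in enumerate_instances(state, BreakFilament())]
        assert ((1, 2) in keys) == eligible

    def test_break_resets_angles_and_makes_ends(self, params):
        state = straight_filament(4, params)
        state.graph.nodes[1].theta = 1.2
        inst = next(i for i in enumerate_instances(state, BreakFilament())
                    if i.key == (1, 2))
        fire(state, inst)
        assert state.graph.kind(1) == "barbed_end"
        assert state.graph.kind(2) == "pointed_end"
        assert state.graph.nodes[1].theta == 0.0


class TestAip1:
    def test_bind_requires_cofilactin(self, params):
        state = straight_filament(3, params)
        assert enumerate_instances(state, Aip1Bind()) == []
        state2 = cofilactin_boundary_filament(params, n=4)
        assert len(enumerate_instances(state2, Aip1Bind())) == 2

    def test_sever_caps_upstream_and_frees_downstream(self, params):
        state = cofilactin_boundary_filament(params, n=5)
        node = state.graph.nodes[3]
        node.aip1 = True
        n_before = state.graph.total_monomers()
        inst = _one(state, Aip1Sever())
        fire(state, inst)
        assert state.graph.nodes[2].capped == "aip1"
        assert state.graph.kind(2) == "capped_end"
        assert state.graph.kind(3) == "pointed_end"
        assert not node.aip1
        assert state.graph.total_monomers() == n_before
        assert len(state.graph.filaments()) == 2


class TestMassBalance:
    def test_conservation_over_random_firings(self, params):
        zeroed = {k: 0.0 for k in params.raw
                  if k.startswith(("k_synth", "k_influx", "k_deg"))}
        state = seed_spine(params, seed=11)
        # freeze synthesis/degradation after the steady-state init so the
        # only mass flux is bind/unbind bookkeeping
        state.pools.params = params.with_updates(**zeroed)
        g = state.graph

        def inventory():
            pools = state.pools.counts
            return {
                "actin": pools["actin"] + g.total_monomers(),
                "cof": pools["cof"] + sum(n.n_cof for n in g.nodes.values()),
                "arp23": pools["arp23"] + sum(
                    1 for n in g.nodes.values() if n.daughter_id is not None),
                "camkii": pools["camkii"] + len(g.links),
                "aip1": pools["aip1"] + sum(
                    1 for n in g.nodes.values() if n.aip1)
                + sum(1 for n in g.nodes.values() if n.capped == "aip1"),
                "cap": pools["cap"] + sum(
                    1 for n in g.nodes.values() if n.capped == "cap"),
            }

        before = inventory()
        run(state, 1e9, max_events=800)
        after = inventory()
        for species in before:
            assert after[species] == pytest.approx(before[species]), species
        # occupancy exclusivity holds in the final snapshot
        for node in g.nodes.values():
            assert not (node.camkii_link is not None and node.n_cof > 0)
        g.check_invariants()
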