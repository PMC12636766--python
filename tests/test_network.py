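"""Network specs, reaction engine semantics, sign-product predictions."""

import numpy as np
import pytest

import raftnet as rn
from raftnet.network import NetworkValidationError

from conftest import make_component


def two_point_network(prefs_a, prefs_t, rate=1.0):
    """Minimal actor/target network with point components."""
    comps = [
        make_component("A", states=("active",), prefs=(prefs_a,), count=1),
        make_component(
            "T", states=("inactive", "active"), prefs=prefs_t, count=1
        ),
    ]
    rules = [
        rn.ReactionRule(
            actor=("A", "active"),
            substrate=("T", "inactive"),
            product_state="active",
            rate=rate,
            activity_sign=+1,
        )
    ]
    return rn.NetworkSpec(components=comps, rules=rules, target="T")


class TestSerialization:
    def test_bundled_fig1(self, fig1_network):
        names = [c.name for c in fig1_network.components]
        assert names == ["A", "I", "T"]
        assert fig1_network.target == "T"
        assert fig1_network.component("A").boundary_pref == {"active": -1}
        assert fig1_network.component("T").boundary_pref == {
            "inactive": 1,
            "active": 1,
        }

    def test_bundled_fig5_switches_partitioning(self, fig5_network):
        t = fig5_network.component("T")
        assert t.boundary_pref["inactive"] == -1
        assert t.boundary_pref["active"] == 1
        assert fig5_network.component("A").boundary_pref["active"] == 1

    def test_round_trip(self, tmp_path, fig5_network):
        path = tmp_path / "net.yaml"
        rn.save_network(fig5_network, path)
        loaded = rn.load_network(path)
        assert loaded.to_dict() == fig5_network.to_dict()

    def test_empty_components_rejected(self):
        with pytest.raises(NetworkValidationError, match="components"):
            rn.NetworkSpec(components=[], rules=[], target="")

    def test_bad_rule_reference_reports_path(self):
        comps = [make_component("A", states=("active",), prefs=(1,))]
        with pytest.raises(NetworkValidationError, match=r"rules\[0\]"):
            rn.NetworkSpec(
                components=comps,
                rules=[
                    rn.ReactionRule(
                        actor=("A", "active"),
                        substrate=("NOPE", "x"),
                        product_state="x",
                    )
                ],
                target="A",
                target_active_state="active",
            )

    def test_rate_bounds_enforced(self):
        with pytest.raises(NetworkValidationError, match="rate"):
            rn.ReactionRule(
                actor=("A", "a"), substrate=("T", "i"),
                product_state="a", rate=1.5,
            )


class TestSignPredict:
    def test_static_partitioning_cascade_is_positive(self, fig1_network):
        assert rn.sign_predict(fig1_network) == +1

    def test_partition_switching_cascade_is_positive(self, fig5_network):
        assert rn.sign_predict(fig5_network) == +1

    def test_disagreeing_pathways_indeterminate(self):
        comps = [
            make_component("A", states=("active",), prefs=(-1,)),
            make_component("I", states=("active",), prefs=(-1,)),
            make_component(
                "T", states=("inactive", "active"), prefs=(1, 1), count=2
            ),
        ]
        rules = [
            rn.ReactionRule(("A", "active"), ("T", "inactive"), "active",
                            activity_sign=+1),
            rn.ReactionRule(("I", "active"), ("T", "active"), "inactive",
                            activity_sign=-1),
        ]
        net = rn.NetworkSpec(components=comps, rules=rules, target="T")
        # both actors partition opposite to the target: products {+1, -1}
        assert rn.sign_predict(net) == rn.INDETERMINATE

    def test_invariant_under_phase_relabeling(self, fig1_network, fig5_network):
        # exchanging the ordered/disordered labels flips every preference
        # but leaves same-vs-different domains, hence the prediction, alone
        for net in (fig1_network, fig5_network):
            flipped = rn.NetworkSpec.from_dict(net.to_dict())
            for comp in flipped.components:
                comp.boundary_pref = {
                    k: -v for k, v in comp.boundary_pref.items()
                }
            assert rn.sign_predict(flipped) == rn.sign_predict(net)


class TestApplyReactions:
    def _contact_state(self, net, L=6):
        state = rn.init_lattice(L, 0.0, net, seed=0)
        a, t = state.inclusions
        state.occ[:] = -1
        a.center, t.center = (2, 2), (2, 3)
        state.occ[2, 2] = a.id
        state.occ[2, 3] = t.id
        state.sval[2, 2] = a.boundary_pref
        state.sval[2, 3] = t.boundary_pref
        return state

    def test_contact_fires_at_unit_rate(self, rng):
        net = two_point_network(-1, (1, 1))
        state = self._contact_state(net)
        events = rn.apply_reactions(state, net, rng)
        assert len(events) == 1
        assert state.inclusions[1].state == "active"

    def test_no_contact_no_change(self, rng):
        net = two_point_network(-1, (1, 1))
        state = self._contact_state(net)
        t = state.inclusions[1]
        state.occ[2, 3] = -1
        state.sval[2, 3] = 1
        t.center = (5, 5)
        state.occ[5, 5] = t.id
        state.sval[5, 5] = t.boundary_pref
        assert rn.apply_reactions(state, net, rng) == []
        assert t.state == "inactive"

    def test_partition_switch_rewrites_boundary_spins(self, rng):
        net = two_point_network(1, (-1, 1))  # activation flips -1 -> +1
        state = self._contact_state(net)
        assert state.sval[2, 3] == -1
        rn.apply_reactions(state, net, rng)
        assert state.inclusions[1].state == "active"
        assert state.sval[2, 3] == 1

    def test_zero_rate_never_fires(self, rng):
        net = two_point_network(-1, (1, 1), rate=0.0)
        state = self._contact_state(net)
        for _ in range(20):
            assert rn.apply_reactions(state, net, rng) == []

    def test_one_modification_per_substrate_per_pass(self, rng):
        # a target touching both an activator and an inactivator changes
        # state exactly once per pass
        comps = [
            make_component("A", states=("active",), prefs=(-1,)),
            make_component("I", states=("active",), prefs=(1,)),
            make_component("T", states=("inactive", "active"), prefs=(1, 1)),
        ]
        rules = [
            rn.ReactionRule(("A", "active"), ("T", "inactive"), "active",
                            activity_sign=+1),
            rn.ReactionRule(("I", "active"), ("T", "active"), "inactive",
                            activity_sign=-1),
        ]
        net = rn.NetworkSpec(components=comps, rules=rules, target="T")
        state = rn.init_lattice(7, 0.0, net, seed=0)
        a, i, t = state.inclusions
        state.occ[:] = -1
        for inc, c in ((a, (3, 2)), (i, (3, 4)), (t, (3, 3))):
            inc.center = c
            state.occ[c] = inc.id
            state.sval[c] = inc.boundary_pref
        for trial in range(20):
            # starting inactive: only the activation rule can fire, and the
            # freshly modified substrate is shielded from the second rule
            t.state = "inactive"
            state.sval[3, 3] = t.type.boundary_pref["inactive"]
            events = rn.apply_reactions(state, net, np.random.default_rng(trial))
            assert len(events) == 1
            assert t.state == "active"
            # starting active: exactly one deactivation per pass, never a
            # re-activation of the just-modified substrate
            events = rn.apply_reactions(state, net, np.random.default_rng(trial))
            assert len(events) == 1
            assert t.state == "inactive"

    def test_reactions_touch_only_states_not_geometry(self, rng, fig5_network):
        state = rn.init_lattice(24, 0.0, fig5_network, seed=3)
        occ_before = state.occ.copy()
        centers = [inc.center for inc in state.inclusions]
        counts = state.spin_counts()
        rn.apply_reactions(state, fig5_network, rng)
        assert np.array_equal(state.occ, occ_before)
        assert [inc.center for inc in state.inclusions] == centers
        assert state.spin_counts() == counts
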