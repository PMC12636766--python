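"""Analysis layer: activity, logistic fits, correlations, pockets."""

import numpy as np
import pytest

import raftnet as rn
from raftnet.analysis import (
    bin_activities,
    flag_activity_outliers,
    label_ordered_clusters,
    pocket_events,
)
from raftnet.simulation import ActivityTrace, SnapshotSet

from conftest import make_component


def make_trace(activity_per_record, n_targets=10):
    n = len(activity_per_record)
    counts = np.zeros((n, 1, 2), dtype=np.int64)
    for i, f in enumerate(activity_per_record):
        counts[i, 0, 1] = round(f * n_targets)
        counts[i, 0, 0] = n_targets - counts[i, 0, 1]
    return ActivityTrace(
        sweeps=(np.arange(n) + 1) * 10,
        counts=counts,
        component_names=["T"],
        state_names=[("inactive", "active")],
        target="T",
        target_active_state="active",
        energy=np.zeros(n),
        magnetization=np.zeros(n),
        acc_lipid=np.zeros(n),
        acc_inclusion=np.zeros(n),
        seed=0,
        config_digest="",
    )


class TestSteadyStateActivity:
    def test_all_active(self):
        trace = make_trace([1.0] * 8)
        assert rn.steady_state_activity(trace, burn_in=0) == 1.0

    def test_alternating_records_average_to_half(self):
        trace = make_trace([0.0, 1.0] * 10)
        assert rn.steady_state_activity(trace, burn_in=0) == pytest.approx(0.5)

    def test_matches_recount_from_exported_table(self):
        rng = np.random.default_rng(0)
        fa = rng.random(40).round(1)
        trace = make_trace(fa)
        burn = 150
        df = trace.to_dataframe()
        df = df[df["sweep"] > burn]
        expected = (df["T:active"] / (df["T:active"] + df["T:inactive"])).mean()
        assert rn.steady_state_activity(trace, burn_in=burn) == pytest.approx(expected)

    def test_empty_window_is_error(self):
        trace = make_trace([0.5] * 3)
        with pytest.raises(ValueError, match="burn_in"):
            rn.steady_state_activity(trace, burn_in=1000)


class TestFitLogistic:
    def test_exact_recovery_on_noiseless_data(self):
        tau = np.linspace(0.8, 1.4, 25)
        fa = rn.logistic_curve(tau, 0.1, 0.9, 0.05, 1.02)
        fit = rn.fit_logistic(tau, fa)
        assert fit.converged and fit.identifiable
        assert fit.left == pytest.approx(0.1, abs=1e-6)
        assert fit.right == pytest.approx(0.9, abs=1e-6)
        assert fit.delta_tau == pytest.approx(0.05, abs=1e-6)
        assert fit.tau0 == pytest.approx(1.02, abs=1e-6)

    def test_flat_data_flagged_unidentifiable(self):
        tau = np.linspace(0.9, 1.3, 8)
        fit = rn.fit_logistic(tau, np.full(8, 0.3))
        assert fit.left == pytest.approx(0.3)
        assert fit.right == pytest.approx(0.3)
        assert not fit.identifiable

    def test_asymptote_bounds_respected(self):
        rng = np.random.default_rng(1)
        tau = np.repeat(np.linspace(0.85, 1.4, 8), 4)
        fa = np.clip(
            rn.logistic_curve(tau, 0.02, 0.97, 0.06, 1.05)
            + rng.normal(0, 0.05, tau.size),
            0,
            1,
        )
        fit = rn.fit_logistic(tau, fa)
        assert 0 <= fit.left <= 1 and 0 <= fit.right <= 1
        assert fit.delta_tau > 0
        lo, hi = fit.ci["tau0"]
        assert lo < fit.tau0 < hi

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            rn.fit_logistic([1.0, 1.1, 1.1], [0, 1, 1])


class TestCrossCorrelation:
    def _snapshots(self, L, centers_by_type, n_types=2):
        comps = [
            make_component(n, states=("s",), prefs=(1,), count=max(len(c), 1))
            for n, c in centers_by_type.items()
        ]
        net = rn.NetworkSpec(components=comps, rules=[], target="")
        occ = np.full((1, L, L), -1, np.int32)
        sval = np.ones((1, L, L), np.int8)
        inc_type, k = [], 0
        for t, (name, centers) in enumerate(centers_by_type.items()):
            for (x, y) in centers:
                occ[0, x, y] = k
                inc_type.append(t)
                k += 1
        return SnapshotSet(
            sweeps=np.array([0]),
            sval=sval,
            occ=occ,
            inc_state=np.zeros((1, k), np.int64),
            inc_type=np.array(inc_type),
            network=net,
        )

    def test_self_correlation_peaks_at_zero(self):
        snaps = self._snapshots(16, {"A": [(3, 3)]})
        prof = rn.cross_correlation(snaps, "A", "A")
        assert prof.value[0] == prof.value.max()
        assert prof.value[0] > 1

    def test_independent_uniform_types_are_uncorrelated(self):
        rng = np.random.default_rng(7)
        L = 40
        acc = []
        for _ in range(30):
            sites = rng.choice(L * L, size=30, replace=False)
            a = [(s // L, s % L) for s in sites[:15]]
            b = [(s // L, s % L) for s in sites[15:]]
            snaps = self._snapshots(L, {"A": a, "B": b})
            prof = rn.cross_correlation(snaps, "A", "B", max_radius=12)
            acc.append(prof.value)
        mean_prof = np.nanmean(acc, axis=0)
        # beyond the excluded-volume bin everything should sit near 1
        assert np.all(np.abs(mean_prof[1:] - 1.0) < 0.15)

    def test_absent_type_is_error(self):
        snaps = self._snapshots(16, {"A": [(3, 3)], "B": []})
        with pytest.raises(ValueError, match="absent"):
            rn.cross_correlation(snaps, "A", "B")


class TestPockets:
    def _pocket_snapshots(self, with_inactivator_inside, n_snap=4):
        """Hand-built ordered cluster holding activators and active targets."""
        L = 16
        comps = [
            make_component("A", states=("active",), prefs=(1,), count=1),
            make_component("I", states=("active",), prefs=(1,), count=1),
            make_component(
                "T", states=("inactive", "active"), prefs=(-1, 1), count=3
            ),
        ]
        rules = [
            rn.ReactionRule(("A", "active"), ("T", "inactive"), "active",
                            activity_sign=+1),
            rn.ReactionRule(("I", "active"), ("T", "active"), "inactive",
                            activity_sign=-1),
        ]
        net = rn.NetworkSpec(components=comps, rules=rules, target="T")
        sval = -np.ones((n_snap, L, L), np.int8)
        occ = np.full((n_snap, L, L), -1, np.int32)
        # one dark 6x6 block containing 1 activator and 3 active targets
        sval[:, 4:10, 4:10] = 1
        positions = {0: (5, 5), 2: (6, 6), 3: (7, 7), 4: (8, 8)}  # A + 3 T
        i_pos = (5, 8) if with_inactivator_inside else (0, 0)
        positions[1] = i_pos
        for k, (x, y) in positions.items():
            occ[:, x, y] = k
            sval[:, x, y] = 1
        if not with_inactivator_inside:
            sval[:, 0, 0] = 1  # its own tiny cluster, no targets there
        inc_state = np.ones((n_snap, 5), np.int64)
        inc_state[:, 0] = 0  # single-state components use index 0
        inc_state[:, 1] = 0
        return SnapshotSet(
            sweeps=np.arange(1, n_snap + 1) * 100,
            sval=sval,
            occ=occ,
            inc_state=inc_state,
            inc_type=np.array([0, 1, 2, 2, 2]),
            network=net,
        )

    def test_persistent_recruiting_cluster_is_one_pocket(self):
        snaps = self._pocket_snapshots(with_inactivator_inside=False)
        events = pocket_events(snaps, t_persist=3)
        assert len(events) == 1
        assert events[0].length == 4
        assert events[0].max_size >= 36

    def test_cluster_containing_excluder_is_not_a_pocket(self):
        snaps = self._pocket_snapshots(with_inactivator_inside=True)
        assert pocket_events(snaps, t_persist=3) == []

    def test_short_lived_cluster_below_persistence_is_ignored(self):
        snaps = self._pocket_snapshots(with_inactivator_inside=False, n_snap=2)
        assert pocket_events(snaps, t_persist=3) == []

    def test_outlier_flagging_uses_median_and_mad(self):
        fa = np.array([0.1, 0.12, 0.11, 0.09, 0.1, 0.9])
        flags = flag_activity_outliers(fa, k=5.0)
        assert flags.tolist() == [False] * 5 + [True]
        assert flag_activity_outliers(np.full(6, 0.2), k=5.0).sum() == 0


class TestClusterLabeling:
    def test_periodic_wraparound_merged(self):
        sval = -np.ones((8, 8), np.int8)
        occ = np.full((8, 8), -1, np.int32)
        sval[0, :] = 1
        sval[7, :] = 1  # touches row 0 through the periodic seam
        labels = label_ordered_clusters(sval, occ, np.zeros((8, 8), bool))
        assert labels[0, 0] == labels[7, 0] != 0
        assert labels[3, 3] == 0

    def test_diagonal_not_connected(self):
        sval = -np.ones((6, 6), np.int8)
        occ = np.full((6, 6), -1, np.int32)
        sval[1, 1] = 1
        sval[2, 2] = 1
        labels = label_ordered_clusters(sval, occ, np.zeros((6, 6), bool))
        assert labels[1, 1] != labels[2, 2]


def test_bin_activities_freedman_diaconis():
    rng = np.random.default_rng(0)
    fa = rng.beta(2, 5, 200)
    hist, edges = bin_activities(fa)
    assert hist.sum() == 200
    assert np.all(np.diff(edges) > 0)
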