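"""Steady-state activity, logistic response fits, cross-correlations,
activity binning, and pocket detection.

The central summary statistic is the steady-state active-target fraction
``f_A``.  Its dependence on the rescaled temperature is quantified by a
generalized logistic (tanh) fit

    f_A(tau) = (R - L)/2 * tanh((tau - tau0) / (2 dtau)) + (R + L)/2

whose growth width ``dtau`` measures how sharply the network responds to
the distance from criticality, and whose inflection point ``tau0`` marks
the temperature of steepest response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, stats

__all__ = [
    "LogisticFitResult",
    "CorrelationProfile",
    "PocketEvent",
    "PocketReport",
    "steady_state_activity",
    "logistic_curve",
    "fit_logistic",
    "cross_correlation",
    "bin_activities",
    "label_ordered_clusters",
    "pocket_events",
    "flag_activity_outliers",
    "detect_pockets",
]


def steady_state_activity(trace, burn_in: int | None = None) -> float:
    """Mean active-target fraction over post-burn-in records.

    ``burn_in`` is a sweep index; records strictly after it enter the
    average.  Defaults to the first half of the trace.
    """
    fa = trace.activity()
    sweeps = np.asarray(trace.sweeps)
    if burn_in is None:
        burn_in = int(sweeps[-1]) // 2 if len(sweeps) else 0
    keep = sweeps > burn_in
    if len(sweeps) == 1 and sweeps[0] == 0 and burn_in == 0:
        keep = sweeps >= 0  # a sweeps=0 run: only the initial record exists
    if not np.any(keep):
        raise ValueError(
            f"no records after burn_in={burn_in}; trace ends at sweep "
            f"{sweeps[-1] if len(sweeps) else 'n/a'}"
        )
    return float(np.nanmean(fa[keep]))


def logistic_curve(tau, left, right, delta_tau, tau0):
    """The tanh-form generalized logistic used for activity-vs-tau fits."""
    tau = np.asarray(tau, dtype=float)
    return (right - left) / 2.0 * np.tanh((tau - tau0) / (2.0 * delta_tau)) + (
        right + left
    ) / 2.0


@dataclass
class LogisticFitResult:
    left: float
    right: float
    delta_tau: float
    tau0: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    converged: bool = True
    identifiable: bool = True
    residual_norm: float = np.nan
    n_points: int = 0

    def predict(self, tau):
        return logistic_curve(tau, self.left, self.right, self.delta_tau, self.tau0)


def fit_logistic(
    tau_values, fa_values, confidence: float = 0.95, bounded: bool = True
) -> LogisticFitResult:
    """Nonlinear least squares of the tanh logistic to activity data.

    Replicates are passed as repeated ``tau`` entries.  Asymptotes are
    bounded to [0, 1] when ``bounded`` (activity fractions), the growth
    width to positive values.  Initial values come from the data: edge
    means for the asymptotes, the steepest finite-difference slope for
    ``tau0``.  Confidence intervals are Wald intervals from the fit
    covariance with a t quantile on ``n - 4`` degrees of freedom.

    Non-convergence yields a flagged result (``converged=False``) rather
    than an exception; flat data yield ``left == right`` with the width
    marked unidentifiable.
    """
    tau = np.asarray(tau_values, dtype=float)
    fa = np.asarray(fa_values, dtype=float)
    ok = np.isfinite(tau) & np.isfinite(fa)
    tau, fa = tau[ok], fa[ok]
    if len(np.unique(tau)) < 4:
        raise ValueError("need at least 4 distinct tau values to fit")
    order = np.argsort(tau)
    tau, fa = tau[order], fa[order]
    span = tau[-1] - tau[0]

    uniq, inv = np.unique(tau, return_inverse=True)
    means = np.array([fa[inv == i].mean() for i in range(len(uniq))])
    if np.ptp(fa) < 1e-9:
        m = float(fa.mean())
        return LogisticFitResult(
            left=m, right=m, delta_tau=np.nan, tau0=float(uniq.mean()),
            converged=True, identifiable=False, residual_norm=0.0,
            n_points=len(fa),
        )

    slopes = np.diff(means) / np.diff(uniq)
    steepest = int(np.argmax(np.abs(slopes)))
    p0 = [
        float(means[0]),
        float(means[-1]),
        max(span / 10.0, 1e-3),
        float(0.5 * (uniq[steepest] + uniq[steepest + 1])),
    ]
    if bounded:
        lo = [0.0, 0.0, 1e-6, tau[0] - span]
        hi = [1.0, 1.0, 10.0 * span, tau[-1] + span]
        p0 = [min(max(p, a), b) for p, a, b in zip(p0, lo, hi)]
        bounds = (lo, hi)
    else:
        bounds = (-np.inf, np.inf)
    try:
        popt, pcov = optimize.curve_fit(
            logistic_curve, tau, fa, p0=p0, bounds=bounds, maxfev=20_000
        )
        converged = np.all(np.isfinite(popt)) and np.all(np.isfinite(np.diag(pcov)))
    except RuntimeError:
        popt, pcov = np.array(p0), np.full((4, 4), np.nan)
        converged = False

    resid = fa - logistic_curve(tau, *popt)
    dof = max(len(fa) - 4, 1)
    tq = stats.t.ppf(0.5 + confidence / 2.0, dof)
    se = np.sqrt(np.diag(pcov))
    names = ("left", "right", "delta_tau", "tau0")
    ci = {
        n: (float(popt[i] - tq * se[i]), float(popt[i] + tq * se[i]))
        for i, n in enumerate(names)
    }
    return LogisticFitResult(
        left=float(popt[0]),
        right=float(popt[1]),
        delta_tau=float(popt[2]),
        tau0=float(popt[3]),
        ci=ci,
        converged=bool(converged),
        identifiable=True,
        residual_norm=float(np.sqrt(np.sum(resid**2))),
        n_points=len(fa),
    )


# ---------------------------------------------------------------------------
# spatial statistics


@dataclass
class CorrelationProfile:
    r: np.ndarray
    value: np.ndarray
    pair: tuple[str, str]
    n_snapshots: int


def _type_field(snapshots, snap_idx: int, type_name: str, state: str | None):
    """Indicator field: 1 on footprint sites of matching inclusions."""
    comp_names = [c.name for c in snapshots.network.components]
    t = comp_names.index(type_name)
    occ = snapshots.occ[snap_idx]
    field_ = np.zeros(occ.shape, dtype=float)
    match_ids = np.flatnonzero(snapshots.inc_type == t)
    if state is not None:
        s = snapshots.network.components[t].state_index(state)
        match_ids = match_ids[snapshots.inc_state[snap_idx, match_ids] == s]
    if match_ids.size:
        field_[np.isin(occ, match_ids)] = 1.0
    return field_


def cross_correlation(
    snapshots,
    type_a: str,
    type_b: str,
    state_a: str | None = None,
    state_b: str | None = None,
    max_radius: float | None = None,
    bin_width: float = 1.0,
) -> CorrelationProfile:
    """Radially averaged density cross-correlation between two components.

    For indicator occupancy fields ``rho_A``, ``rho_B`` this is
    ``<rho_A(x) rho_B(x + r)> / (<rho_A><rho_B>)`` computed with periodic
    FFTs, averaged over displacement directions into radial bins of
    minimum-image distance, then averaged over snapshots.  A value of 1
    means no association at that distance.
    """
    n_snap = len(snapshots)
    if n_snap < 1:
        raise ValueError("need at least one snapshot")
    L = snapshots.sval.shape[1]
    if max_radius is None:
        max_radius = L / 2.0
    ii = np.arange(L)
    dist = np.minimum(ii, L - ii)
    rgrid = np.sqrt(dist[:, None] ** 2 + dist[None, :] ** 2)
    bins = np.arange(0.0, max_radius + bin_width, bin_width)
    which = np.digitize(rgrid.ravel(), bins) - 1
    n_bins = len(bins) - 1

    acc = np.zeros(n_bins)
    cnt = np.zeros(n_bins)
    used = 0
    for s in range(n_snap):
        fa = _type_field(snapshots, s, type_a, state_a)
        fb = _type_field(snapshots, s, type_b, state_b)
        ma, mb = fa.mean(), fb.mean()
        if ma == 0 or mb == 0:
            continue
        corr = np.fft.ifft2(np.conj(np.fft.fft2(fa)) * np.fft.fft2(fb)).real
        corr /= L * L * ma * mb
        used += 1
        flat = corr.ravel()
        for b in range(n_bins):
            sel = which == b
            acc[b] += flat[sel].sum()
            cnt[b] += sel.sum()
    if used == 0:
        raise ValueError(
            f"components {type_a!r}/{type_b!r} absent from every snapshot"
        )
    value = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    centers = 0.5 * (bins[:-1] + bins[1:])
    return CorrelationProfile(
        r=centers, value=value, pair=(type_a, type_b), n_snapshots=used
    )


def bin_activities(fa_values, bin_width: float | None = None):
    """Histogram of per-replicate activities (Freedman-Diaconis default)."""
    fa = np.asarray(fa_values, dtype=float)
    if bin_width is None:
        iqr = np.subtract(*np.percentile(fa, [75, 25]))
        bin_width = 2.0 * iqr / np.cbrt(len(fa)) if iqr > 0 else 0.05
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    hist, edges = np.histogram(fa, bins=edges)
    return hist, edges


# ---------------------------------------------------------------------------
# pockets


def label_ordered_clusters(sval, occ, ordered_pref_sites) -> np.ndarray:
    """Four-connected clusters of the ordered phase, periodic boundaries.

    A site belongs to the ordered phase if it is a lipid with spin +1 or
    an inclusion site flagged in ``ordered_pref_sites`` (a boolean grid
    marking sites of ordered-preferring inclusions).  Returns an integer
    label grid (0 = not ordered).
    """
    mask = ((occ < 0) & (sval == 1)) | ordered_pref_sites
    labels, n = ndimage.label(mask)
    if n == 0:
        return labels
    # merge labels across the periodic seams
    parent = np.arange(n + 1)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for a, b in zip(labels[0, :], labels[-1, :]):
        if a and b:
            union(a, b)
    for a, b in zip(labels[:, 0], labels[:, -1]):
        if a and b:
            union(a, b)
    flat = np.array([find(i) for i in range(n + 1)])
    return flat[labels]


@dataclass
class PocketEvent:
    first_snapshot: int
    last_snapshot: int
    first_sweep: int
    last_sweep: int
    max_size: int

    @property
    def length(self) -> int:
        return self.last_snapshot - self.first_snapshot + 1


def _cluster_candidates(snapshots, snap_idx):
    """Ordered clusters containing >=1 active target and >=1 activator
    but no inactivator, as sets of flat site indices."""
    net = snapshots.network
    occ = snapshots.occ[snap_idx]
    sval = snapshots.sval[snap_idx]
    L = occ.shape[0]
    inc_type = snapshots.inc_type
    inc_state = snapshots.inc_state[snap_idx]

    # per-inclusion boundary preference in its current state
    prefs = np.array(
        [
            net.components[t].boundary_pref[net.components[t].states[s]]
            for t, s in zip(inc_type, inc_state)
        ]
    ) if len(inc_type) else np.zeros(0, int)
    ordered_sites = np.zeros_like(occ, dtype=bool)
    if len(prefs):
        ordered_ids = np.flatnonzero(prefs == 1)
        ordered_sites = np.isin(occ, ordered_ids) & (occ >= 0)
    labels = label_ordered_clusters(sval, occ, ordered_sites)

    comp_names = [c.name for c in net.components]
    t_target = comp_names.index(net.target)
    s_active = net.components[t_target].state_index(net.target_active_state)

    # activators push the target toward active, inactivators away
    activator_types = set()
    inactivator_types = set()
    for rule in net.rules:
        at = comp_names.index(rule.actor[0])
        if at == t_target:
            continue
        if rule.activity_sign > 0:
            activator_types.add(at)
        else:
            inactivator_types.add(at)

    # cluster label under each inclusion (majority over footprint sites)
    candidates = {}
    n_inc = len(inc_type)
    per_cluster = {}
    for k in range(n_inc):
        sites = np.flatnonzero(occ.ravel() == k)
        if sites.size == 0:
            continue
        labs = labels.ravel()[sites]
        labs = labs[labs > 0]
        if labs.size == 0:
            continue
        lab = int(np.bincount(labs).argmax())
        info = per_cluster.setdefault(lab, [0, 0, 0])  # targets, activators, inactivators
        t = inc_type[k]
        if t == t_target:
            if inc_state[k] == s_active:
                info[0] += 1
        elif t in activator_types:
            info[1] += 1
        elif t in inactivator_types:
            info[2] += 1
    for lab, (n_t, n_a, n_i) in per_cluster.items():
        if n_t >= 1 and n_a >= 1 and n_i == 0:
            candidates[lab] = frozenset(np.flatnonzero(labels.ravel() == lab))
    return candidates


def pocket_events(
    snapshots, t_persist: int = 3, min_overlap: float = 0.5
) -> list[PocketEvent]:
    """Structural pocket detector.

    A pocket is an ordered-phase cluster (dark lipids plus embedded
    ordered-preferring inclusions) containing at least one active target
    and one activator but no inactivator, persisting for at least
    ``t_persist`` consecutive snapshots with at least ``min_overlap``
    site overlap (relative to the smaller cluster) between consecutive
    occurrences.
    """
    n_snap = len(snapshots)
    chains: list[dict] = []  # {"sites", "start", "last", "max_size"}
    events: list[PocketEvent] = []

    def close(chain):
        if chain["last"] - chain["start"] + 1 >= t_persist:
            events.append(
                PocketEvent(
                    first_snapshot=chain["start"],
                    last_snapshot=chain["last"],
                    first_sweep=int(snapshots.sweeps[chain["start"]]),
                    last_sweep=int(snapshots.sweeps[chain["last"]]),
                    max_size=chain["max_size"],
                )
            )

    for s in range(n_snap):
        cands = list(_cluster_candidates(snapshots, s).values())
        matched = [False] * len(cands)
        surviving = []
        for chain in chains:
            best, best_ov = None, 0.0
            for ci, sites in enumerate(cands):
                if matched[ci]:
                    continue
                ov = len(chain["sites"] & sites) / max(
                    min(len(chain["sites"]), len(sites)), 1
                )
                if ov > best_ov:
                    best, best_ov = ci, ov
            if best is not None and best_ov >= min_overlap:
                matched[best] = True
                chain["sites"] = cands[best]
                chain["last"] = s
                chain["max_size"] = max(chain["max_size"], len(cands[best]))
                surviving.append(chain)
            else:
                close(chain)
        for ci, sites in enumerate(cands):
            if not matched[ci]:
                surviving.append(
                    {"sites": sites, "start": s, "last": s, "max_size": len(sites)}
                )
        chains = surviving
    for chain in chains:
        close(chain)
    return events


def flag_activity_outliers(
    fa_values, k: float = 5.0, mad_floor: float = 0.005
) -> np.ndarray:
    """Distributional pocketing detector across replicates.

    Flags runs whose steady-state activity exceeds the replicate median
    by more than ``k`` times the median absolute deviation.  ``mad_floor``
    keeps the threshold meaningful when most replicates coincide.
    """
    fa = np.asarray(fa_values, dtype=float)
    med = np.median(fa)
    mad = np.median(np.abs(fa - med))
    return fa > med + k * max(mad, mad_floor)


@dataclass
class PocketReport:
    events_per_run: list[list[PocketEvent]]
    outlier_flags: np.ndarray
    activities: np.ndarray
    warnings: list[str] = field(default_factory=list)

    @property
    def n_structural(self) -> int:
        return sum(len(ev) for ev in self.events_per_run)

    @property
    def n_outliers(self) -> int:
        return int(self.outlier_flags.sum())


def detect_pockets(
    results,
    t_persist: int = 3,
    min_overlap: float = 0.5,
    k: float = 5.0,
) -> PocketReport:
    """Run both pocket detectors over a battery of replicate runs.

    ``results`` is a sequence of :class:`~raftnet.simulation.SimulationResult`.
    The structural detector needs snapshots; runs without them are skipped
    with a warning and only the distributional detector applies.
    """
    msgs = []
    events = []
    activities = []
    for i, res in enumerate(results):
        activities.append(res.steady_state_activity)
        if res.snapshots is None or len(res.snapshots) == 0:
            msgs.append(f"run {i}: no snapshots; structural detector skipped")
            events.append([])
        else:
            events.append(
                pocket_events(res.snapshots, t_persist=t_persist, min_overlap=min_overlap)
            )
    if msgs:
        warnings.warn("; ".join(msgs), stacklevel=2)
    fa = np.asarray(activities)
    return PocketReport(
        events_per_run=events,
        outlier_flags=flag_activity_outliers(fa, k=k),
        activities=fa,
        warnings=msgs,
    )
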