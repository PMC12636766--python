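"""Scheduler and configuration: sweeps, recording, replicates, parameter scans.

One sweep = one Kawasaki swap attempt per lipid site (random site order),
with ``C`` translation attempts per inclusion interleaved at random points
of the sweep, followed by one contact-reaction pass over the post-movement
configuration.  Runs are bit-reproducible from ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _pack
from ._kernels import kernel_run
from .lattice import LatticeState, ThermoParams, init_lattice
from .network import NetworkSpec, bundled_network, load_network

__all__ = [
    "SimulationConfig",
    "ActivityTrace",
    "SnapshotSet",
    "SimulationResult",
    "run_simulation",
    "run_scan",
    "replicate_seed",
    "load_config",
]

SCAN_AXES = ("tau", "m_target", "radius")


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one run."""

    L: int
    thermo: ThermoParams
    network: NetworkSpec
    sweeps: int
    burn_in: int | None = None   # None -> first half of the sweeps discarded
    record_every: int = 10
    snapshots_every: int = 0
    seed: int = 0
    replicates: int = 1
    max_logged_events: int = 200_000

    def __post_init__(self) -> None:
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if self.sweeps < 0:
            raise ValueError("sweeps must be >= 0")
        if self.burn_in is not None and self.sweeps > 0 and not (
            0 <= self.burn_in < self.sweeps
        ):
            raise ValueError("burn_in must satisfy 0 <= burn_in < sweeps")

    @property
    def effective_burn_in(self) -> int:
        return self.sweeps // 2 if self.burn_in is None else self.burn_in

    def digest(self) -> str:
        doc = {
            "L": self.L,
            "thermo": dataclasses.asdict(self.thermo),
            "network": self.network.to_dict(),
            "sweeps": self.sweeps,
            "burn_in": self.burn_in,
            "record_every": self.record_every,
            "snapshots_every": self.snapshots_every,
            "seed": self.seed,
        }
        blob = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ActivityTrace:
    """Per-sweep recorded counts and diagnostics of a single run."""

    sweeps: np.ndarray                  # recorded sweep indices
    counts: np.ndarray                  # (n_rec, n_types, n_states)
    component_names: list[str]
    state_names: list[tuple[str, ...]]
    target: str
    target_active_state: str
    energy: np.ndarray
    magnetization: np.ndarray
    acc_lipid: np.ndarray
    acc_inclusion: np.ndarray
    seed: int
    config_digest: str

    def activity(self) -> np.ndarray:
        """Fraction of target inclusions in the active state, per record."""
        t = self.component_names.index(self.target)
        s = self.state_names[t].index(self.target_active_state)
        total = self.counts[:, t, :].sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(total > 0, self.counts[:, t, s] / total, np.nan)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"sweep": self.sweeps}
        for t, name in enumerate(self.component_names):
            for s, label in enumerate(self.state_names[t]):
                cols[f"{name}:{label}"] = self.counts[:, t, s]
        cols["energy"] = self.energy
        cols["magnetization"] = self.magnetization
        cols["acc_lipid"] = self.acc_lipid
        cols["acc_inclusion"] = self.acc_inclusion
        return pd.DataFrame(cols)


@dataclass
class SnapshotSet:
    """Configuration snapshots on a fixed cadence.

    ``sval``/``occ`` follow the lattice conventions; ``inc_state`` holds the
    per-snapshot state index of each inclusion and ``inc_type`` its (static)
    type index into ``network.components``.
    """

    sweeps: np.ndarray
    sval: np.ndarray       # (n_snap, L, L) int8
    occ: np.ndarray        # (n_snap, L, L) int32
    inc_state: np.ndarray  # (n_snap, n_inc)
    inc_type: np.ndarray   # (n_inc,)
    network: NetworkSpec

    def __len__(self) -> int:
        return len(self.sweeps)


@dataclass
class SimulationResult:
    config: SimulationConfig
    trace: ActivityTrace
    snapshots: SnapshotSet | None
    state: LatticeState
    events: pd.DataFrame
    events_truncated: bool

    @property
    def steady_state_activity(self) -> float:
        from .analysis import steady_state_activity

        return steady_state_activity(self.trace, self.config.effective_burn_in)


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Execute one seeded run and return traces (and snapshots, if on)."""
    ss = np.random.SeedSequence(config.seed)
    init_seed, kernel_seed = (
        int(s) & 0x7FFFFFFF for s in ss.generate_state(2, np.uint64)
    )
    state = init_lattice(
        config.L, config.thermo.m_target, config.network, seed=init_seed
    )
    pn = _pack.pack_network(config.network)
    args = _pack.kernel_args(state, pn)
    out = kernel_run(
        *args,
        np.float64(config.thermo.beta),
        np.float64(config.thermo.J),
        np.float64(config.thermo.J_int),
        np.int64(config.sweeps),
        np.int64(config.record_every),
        np.int64(config.snapshots_every),
        np.int64(kernel_seed),
        np.int64(config.max_logged_events),
    )
    (
        rec_sweep, rec_counts, rec_energy, rec_mag, rec_acc_lip, rec_acc_inc,
        snap_sweep, snap_sval, snap_occ, snap_state,
        log_sweep, log_rule, log_actor, log_sub, counters,
    ) = out
    _pack.writeback(state, pn, args)
    state.validate()

    trace = ActivityTrace(
        sweeps=np.asarray(rec_sweep),
        counts=np.asarray(rec_counts),
        component_names=[c.name for c in config.network.components],
        state_names=[tuple(c.states) for c in config.network.components],
        target=config.network.target,
        target_active_state=config.network.target_active_state,
        energy=np.asarray(rec_energy),
        magnetization=np.asarray(rec_mag),
        acc_lipid=np.asarray(rec_acc_lip),
        acc_inclusion=np.asarray(rec_acc_inc),
        seed=config.seed,
        config_digest=config.digest(),
    )
    snapshots = None
    if config.snapshots_every > 0:
        snapshots = SnapshotSet(
            sweeps=np.asarray(snap_sweep),
            sval=np.asarray(snap_sval),
            occ=np.asarray(snap_occ),
            inc_state=np.asarray(snap_state),
            inc_type=np.asarray(args[4]),
            network=config.network,
        )
    events = pd.DataFrame(
        {
            "sweep": np.asarray(log_sweep),
            "rule": np.asarray(log_rule),
            "actor": np.asarray(log_actor),
            "substrate": np.asarray(log_sub),
        }
    )
    return SimulationResult(
        config=config,
        trace=trace,
        snapshots=snapshots,
        state=state,
        events=events,
        events_truncated=bool(counters[5]),
    )


def replicate_seed(master_seed: int, *indices: int) -> int:
    """Derive an independent child seed from a master seed and counters."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, indices)])
    return int(ss.generate_state(1, np.uint64)[0]) & 0x7FFFFFFF


def _config_for(base: SimulationConfig, axis: str, value) -> SimulationConfig:
    if axis == "tau":
        return replace(base, thermo=replace(base.thermo, tau=float(value)))
    if axis == "m_target":
        return replace(
            base, thermo=replace(base.thermo, m_target=float(value))
        )
    if axis == "radius":
        return replace(base, network=base.network.with_radius(int(value)))
    raise ValueError(f"unknown scan axis {axis!r}; one of {SCAN_AXES}")


def run_scan(
    base_config: SimulationConfig,
    axis: str,
    values,
    replicates: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Steady-state activity over a parameter grid with seeded replicates.

    Returns a tidy frame with one row per (value, replicate):
    ``axis, value, replicate, seed, f_A``.
    """
    from .analysis import steady_state_activity

    if axis not in SCAN_AXES:
        raise ValueError(f"unknown scan axis {axis!r}; one of {SCAN_AXES}")
    if seed is None:
        seed = base_config.seed
    rows = []
    for vi, value in enumerate(values):
        cfg = _config_for(base_config, axis, value)
        for rep in range(replicates):
            rs = replicate_seed(seed, vi, rep)
            result = run_simulation(replace(cfg, seed=rs))
            fa = steady_state_activity(result.trace, cfg.effective_burn_in)
            rows.append(
                {
                    "axis": axis,
                    "value": value,
                    "replicate": rep,
                    "seed": rs,
                    "f_A": fa,
                }
            )
    return pd.DataFrame(rows)


def load_config(path: str | Path) -> SimulationConfig:
    """Read a YAML run configuration.

    The ``network`` entry is either the name of a bundled network
    (``fig1``/``fig5``), a path to a network YAML relative to the config
    file, or an inline mapping.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    net = doc.get("network", "fig1")
    if isinstance(net, dict):
        network = NetworkSpec.from_dict(net)
    elif isinstance(net, str) and net.endswith((".yaml", ".yml")):
        network = load_network((path.parent / net) if not Path(net).is_absolute() else net)
    else:
        network = bundled_network(str(net))
    th = doc.get("thermo", {})
    thermo = ThermoParams(
        tau=float(th.get("tau", 1.0)),
        J=float(th.get("J", 1.0)),
        J_int=float(th.get("J_int", 1.0)),
        m_target=float(th.get("m_target", 0.0)),
        Tc_bare=th.get("Tc_bare"),
    )
    run = doc.get("run", {})
    return SimulationConfig(
        L=int(doc.get("lattice", {}).get("L", 64)),
        thermo=thermo,
        network=network,
        sweeps=int(run.get("sweeps", 10_000)),
        burn_in=run.get("burn_in"),
        record_every=int(run.get("record_every", 10)),
        snapshots_every=int(run.get("snapshots_every", 0)),
        seed=int(run.get("seed", 0)),
        replicates=int(run.get("replicates", 1)),
    )
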