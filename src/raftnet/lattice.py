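"""The Ising membrane: spin grid, Hamiltonian, conserved-order-parameter dynamics.

Membrane lipids sit on an ``L x L`` periodic square lattice as Ising spins
``s = +-1`` standing for components that preferentially partition into the
liquid-ordered (+1) / liquid-disordered (-1) phase.  Composition is set by
the magnetization ``m = <s>`` and is conserved exactly: lipids diffuse by
Kawasaki spin exchange, so the dynamics are in the model B universality
class.  Temperature enters as the rescaled temperature ``tau = T / Tc``
measured against the bare-membrane critical temperature, taken to be the
exact Onsager value ``2 J / ln(1 + sqrt 2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .inclusions import ComponentType, Inclusion, rasterize_disk

__all__ = [
    "TC_ONSAGER",
    "ThermoParams",
    "LatticeState",
    "SweepStats",
    "init_lattice",
    "hamiltonian_mem",
    "kawasaki_sweep",
    "magnetization",
]

#: Critical temperature of the square-lattice Ising model at J=1 (Onsager).
TC_ONSAGER = 2.0 / math.log(1.0 + math.sqrt(2.0))


@dataclass
class ThermoParams:
    """Thermodynamic parameters of the membrane.

    Attributes
    ----------
    tau : rescaled temperature ``T / Tc`` of the bare membrane.
    J : lipid-lipid coupling (energy units; k_B = 1).
    J_int : inclusion-boundary/lipid coupling.
    m_target : magnetization, i.e. the ordered/disordered area-fraction
        imbalance, in ``[-1, 1]``.
    Tc_bare : critical temperature used to convert ``tau`` to an inverse
        temperature; defaults to the Onsager value ``2 J / ln(1+sqrt 2)``.
    """

    tau: float
    J: float = 1.0
    J_int: float = 1.0
    m_target: float = 0.0
    Tc_bare: float | None = None

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if abs(self.m_target) > 1:
            raise ValueError(f"|m_target| must be <= 1, got {self.m_target}")

    @property
    def tc(self) -> float:
        return self.Tc_bare if self.Tc_bare is not None else TC_ONSAGER * self.J

    @property
    def beta(self) -> float:
        """Inverse temperature ``1 / (tau * Tc_bare)``."""
        return 1.0 / (self.tau * self.tc)


@dataclass
class SweepStats:
    lipid_attempted: int = 0
    lipid_accepted: int = 0
    inclusion_attempted: int = 0
    inclusion_accepted: int = 0


@dataclass
class LatticeState:
    """Full mutable simulation state.

    ``sval`` holds the per-site spin value: the lipid spin on lipid sites,
    the boundary preference of the covering inclusion on inclusion-boundary
    sites, and 0 on inert disk-interior sites.  ``occ`` maps each site to
    -1 (lipid) or the id of the covering inclusion.  The inclusion registry
    is kept consistent with ``occ``: inclusion ids equal their index in the
    registry and their rasterized footprints equal their occupancy entries.
    """

    L: int
    sval: np.ndarray
    occ: np.ndarray
    inclusions: list[Inclusion] = field(default_factory=list)

    @property
    def lipid_mask(self) -> np.ndarray:
        return self.occ < 0

    @property
    def n_lipids(self) -> int:
        return int(np.sum(self.lipid_mask))

    def spin_counts(self) -> tuple[int, int]:
        """(number of +1 lipid spins, number of -1 lipid spins)."""
        lip = self.lipid_mask
        up = int(np.sum(self.sval[lip] == 1))
        return up, int(np.sum(lip)) - up

    def copy(self) -> "LatticeState":
        incs = [
            Inclusion(type=i.type, center=tuple(i.center), state=i.state, id=i.id)
            for i in self.inclusions
        ]
        return LatticeState(self.L, self.sval.copy(), self.occ.copy(), incs)

    def validate(self) -> None:
        if self.sval.shape != (self.L, self.L) or self.occ.shape != (self.L, self.L):
            raise ValueError("sval/occ shape does not match lattice size")
        lip = self.lipid_mask
        if not np.all(np.isin(self.sval[lip], (-1, 1))):
            raise ValueError("lipid sites must carry spin +1 or -1")
        seen = np.full((self.L, self.L), False)
        for idx, inc in enumerate(self.inclusions):
            if inc.id != idx:
                raise ValueError(f"inclusion id {inc.id} != registry index {idx}")
            sites = inc.footprint_sites(self.L)
            if not np.all(self.occ[sites[:, 0], sites[:, 1]] == inc.id):
                raise ValueError(
                    f"occupancy inconsistent with footprint of inclusion {inc.id}"
                )
            if np.any(seen[sites[:, 0], sites[:, 1]]):
                raise ValueError(f"inclusion {inc.id} overlaps another inclusion")
            seen[sites[:, 0], sites[:, 1]] = True
        if int(np.sum(seen)) != int(np.sum(~lip)):
            raise ValueError("occupancy map and inclusion registry disagree")


class PlacementError(RuntimeError):
    """Raised when an inclusion cannot be placed without overlap."""


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def init_lattice(
    L: int,
    m_target: float,
    network=None,
    seed: int | None = 0,
    max_tries: int = 10_000,
) -> LatticeState:
    """Build a fresh lattice: place inclusions, then shuffle lipid spins.

    Inclusions are placed uniformly at random without overlap (bounded
    rejection sampling; a :class:`PlacementError` names the component that
    could not be placed).  The remaining sites are lipids, of which exactly
    ``round((1 + m_target)/2 * n_lipids)`` are set to +1 (ties rounded half
    away from zero) at uniformly shuffled positions.  Reproducible from
    ``seed``.

    ``network`` may be ``None`` (bare membrane) or anything with a
    ``components`` list of :class:`~raftnet.inclusions.ComponentType`.
    """
    if abs(m_target) > 1:
        raise ValueError(f"|m_target| must be <= 1, got {m_target}")
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng(seed)
    occ = np.full((L, L), -1, dtype=np.int32)
    sval = np.zeros((L, L), dtype=np.int8)
    inclusions: list[Inclusion] = []

    components: list[ComponentType] = list(network.components) if network else []
    next_id = 0
    for comp in components:
        off, bnd = rasterize_disk(comp.radius)
        if off.shape[0] * comp.count > L * L:
            raise PlacementError(
                f"component {comp.name!r}: footprint area exceeds the lattice"
            )
        state0 = comp.states[0]
        b = comp.boundary_pref[state0]
        for _ in range(comp.count):
            for attempt in range(max_tries):
                cx, cy = (int(v) for v in rng.integers(0, L, size=2))
                sx = (cx + off[:, 0]) % L
                sy = (cy + off[:, 1]) % L
                if np.all(occ[sx, sy] < 0):
                    occ[sx, sy] = next_id
                    sval[sx, sy] = np.where(bnd, b, 0).astype(np.int8)
                    inclusions.append(
                        Inclusion(type=comp, center=(cx, cy), state=state0, id=next_id)
                    )
                    next_id += 1
                    break
            else:
                raise PlacementError(
                    f"could not place component {comp.name!r} after "
                    f"{max_tries} tries (lattice too crowded)"
                )

    lip_idx = np.flatnonzero(occ.ravel() < 0)
    n_lip = lip_idx.size
    if n_lip:
        n_up = _round_half_away((1.0 + m_target) / 2.0 * n_lip)
        spins = np.full(n_lip, -1, dtype=np.int8)
        spins[:n_up] = 1
        rng.shuffle(spins)
        sval.ravel()[lip_idx] = spins

    state = LatticeState(L=L, sval=sval, occ=occ, inclusions=inclusions)
    state.validate()
    return state


def hamiltonian_mem(state: LatticeState, params: ThermoParams) -> float:
    """Membrane self-energy ``-J sum_<ij> s_i s_j`` over lipid-lipid bonds.

    Nearest-neighbor pairs with periodic boundaries; any bond touching an
    inclusion site is excluded (those belong to the inclusion coupling
    term)."""
    lip = state.lipid_mask
    s = np.where(lip, state.sval, 0).astype(np.int64)
    e = 0
    for axis in (0, 1):
        both = lip & np.roll(lip, -1, axis=axis)
        e += int(np.sum(s * np.roll(s, -1, axis=axis) * both))
    return -params.J * e


def magnetization(state: LatticeState) -> float:
    """Mean spin over lipid sites (inclusion sites excluded)."""
    lip = state.lipid_mask
    n = int(np.sum(lip))
    if n == 0:
        raise ValueError("magnetization undefined: no lipid sites")
    return float(np.sum(state.sval[lip])) / n


def kawasaki_sweep(
    state: LatticeState,
    params: ThermoParams,
    rng: np.random.Generator,
    n_sweeps: int = 1,
) -> SweepStats:
    """Run ``n_sweeps`` Kawasaki exchange sweeps over the lipids, in place.

    Each sweep visits every site in a fresh random order; at each lipid
    site a random four-neighbor is drawn and, if both sites are lipids
    with unequal spins, the pair is swapped with the Metropolis
    probability ``min(1, exp(-beta dE))``.  ``dE`` includes lipid-lipid
    and lipid-inclusion-boundary bonds.  Spin counts are conserved
    exactly.  Inclusions do not move here; they are obstacles.
    """
    from . import _pack
    from ._kernels import kernel_run

    pn = _pack.pack_state_network(state)
    seed = int(rng.integers(2**31))
    args = _pack.kernel_args(state, pn, mobility_override=0.0)
    out = kernel_run(
        *args,
        np.float64(params.beta),
        np.float64(params.J),
        np.float64(params.J_int),
        np.int64(max(n_sweeps, 0)),
        np.int64(max(n_sweeps, 1)),
        np.int64(0),
        np.int64(seed),
        np.int64(0),
    )
    _pack.writeback(state, pn, args)
    counters = out[-1]
    return SweepStats(
        lipid_attempted=int(counters[0]),
        lipid_accepted=int(counters[1]),
        inclusion_attempted=int(counters[2]),
        inclusion_accepted=int(counters[3]),
    )
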