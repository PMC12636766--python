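"""Disk-shaped protein inclusions embedded in the membrane lattice.

Membrane proteins are modelled as rigid disks of lattice sites.  Only the
*boundary* sites of a disk carry a spin value (the boundary preference
``b`` of the inclusion's current state, +1 for liquid-ordered and -1 for
liquid-disordered); interior sites are inert.  Boundary spins couple to
four-adjacent lipid spins with strength ``J_int``, which is what makes an
inclusion partition into one phase or the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import TYPE_CHECKING, Iterable

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .lattice import LatticeState, ThermoParams

__all__ = [
    "ComponentType",
    "Inclusion",
    "rasterize_disk",
    "hamiltonian_int",
    "inclusion_move",
    "detect_contacts",
]


@lru_cache(maxsize=64)
def _rasterize_cached(r: int) -> tuple[np.ndarray, np.ndarray]:
    if r < 0:
        raise ValueError(f"disk radius must be >= 0, got {r}")
    span = np.arange(-r, r + 1)
    dx, dy = np.meshgrid(span, span, indexing="ij")
    inside = dx * dx + dy * dy <= r * r
    offsets = np.stack([dx[inside], dy[inside]], axis=1).astype(np.int64)
    member = {(int(a), int(b)) for a, b in offsets}
    boundary = np.array(
        [
            any(
                (int(a) + sx, int(b) + sy) not in member
                for sx, sy in ((1, 0), (-1, 0), (0, 1), (0, -1))
            )
            for a, b in offsets
        ],
        dtype=bool,
    )
    offsets.setflags(write=False)
    boundary.setflags(write=False)
    return offsets, boundary


def rasterize_disk(r: int) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a disk of radius ``r`` onto the square lattice.

    The footprint is every integer offset ``(dx, dy)`` with
    ``dx**2 + dy**2 <= r**2``; the boundary is the subset of footprint
    sites with at least one four-neighbor outside the footprint.  At
    ``r=0`` the disk is a single site, so a network of radius-zero
    components reduces spatially to the plain 2D Ising model.

    Returns
    -------
    offsets : (n, 2) int array of footprint offsets relative to the center.
    boundary : (n,) bool array marking boundary sites.
    """
    return _rasterize_cached(int(r))


@dataclass
class ComponentType:
    """A species of the interaction network.

    Parameters
    ----------
    name : identifier used in reaction rules and analysis output.
    radius : disk radius in lattice units.
    states : ordered state labels; the first is the initial state.
    boundary_pref : state label -> +1 (ordered) or -1 (disordered).
    count : number of copies placed in the membrane.
    mobility : translation attempts per copy per sweep (the ``C`` of the
        sweep protocol); may be fractional, realized stochastically.
    """

    name: str
    radius: int = 0
    states: tuple[str, ...] = ("active",)
    boundary_pref: dict[str, int] = field(default_factory=dict)
    count: int = 1
    mobility: float = 0.1

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        if not self.name:
            raise ValueError("component name must be non-empty")
        if self.radius < 0:
            raise ValueError(f"component {self.name!r}: radius must be >= 0")
        if self.count < 1:
            raise ValueError(f"component {self.name!r}: count must be >= 1")
        if self.mobility < 0:
            raise ValueError(f"component {self.name!r}: mobility must be >= 0")
        if not self.states:
            raise ValueError(f"component {self.name!r}: needs at least one state")
        for s in self.states:
            b = self.boundary_pref.get(s)
            if b not in (+1, -1):
                raise ValueError(
                    f"component {self.name!r}: state {s!r} needs a boundary "
                    f"preference of +1 or -1, got {b!r}"
                )

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ValueError(
                f"component {self.name!r} has no state {state!r}; "
                f"known states: {list(self.states)}"
            ) from None

    @property
    def footprint(self) -> tuple[np.ndarray, np.ndarray]:
        return rasterize_disk(self.radius)


@dataclass
class Inclusion:
    """A placed instance of a :class:`ComponentType`."""

    type: ComponentType
    center: tuple[int, int]
    state: str
    id: int

    def footprint_sites(self, L: int) -> np.ndarray:
        """Absolute (wrapped) lattice sites covered by this inclusion."""
        off, _ = self.type.footprint
        return (np.asarray(self.center) + off) % L

    @property
    def boundary_pref(self) -> int:
        return self.type.boundary_pref[self.state]


def hamiltonian_int(
    state: "LatticeState", params: "ThermoParams", J_int: float | None = None
) -> float:
    """Inclusion-membrane coupling energy.

    Sums ``-J_int * b_i * s`` over every (inclusion boundary site,
    four-adjacent lipid site) pair.  Interior disk sites carry no spin
    and contribute nothing.  Two inclusions in direct contact exchange
    no energy: inclusions interact with each other only through the
    membrane they deform (excluded volume aside), mirroring the
    boundary-spins-to-membrane-spins form of the coupling.
    """
    if J_int is None:
        J_int = params.J_int
    sval = state.sval.astype(np.int64)
    occ = state.occ
    lip = occ < 0
    e = 0
    for axis in (0, 1):
        v2 = np.roll(sval, -1, axis=axis)
        l2 = np.roll(lip, -1, axis=axis)
        mask = lip ^ l2  # exactly one endpoint is a lipid
        e += int(np.sum(sval * v2 * mask))
    return -J_int * e


def inclusion_move(
    state: "LatticeState",
    inc: Inclusion,
    params: "ThermoParams",
    rng: np.random.Generator,
    direction: tuple[int, int] | None = None,
) -> bool:
    """Attempt one diffusive translation of ``inc`` by one lattice site.

    The move is rejected outright if the translated footprint would
    overlap another inclusion.  Lipid spins on the leading edge (sites
    newly covered) are relocated to the vacated trailing edge through
    the mirror map ``offset o -> -o`` about the old center; because the
    disk footprint is symmetric under negation this map is an involution,
    so the reverse move undoes it exactly and detailed balance holds.
    The move is accepted with the Metropolis probability
    ``min(1, exp(-beta dE))`` where ``dE`` covers all affected bonds.

    This is the reference (unoptimized) implementation; the simulation
    scheduler uses a compiled equivalent validated against exhaustive
    enumeration.
    """
    from .lattice import hamiltonian_mem

    L = state.L
    if direction is None:
        direction = [(1, 0), (-1, 0), (0, 1), (0, -1)][int(rng.integers(4))]
    dx, dy = direction
    off, bnd = inc.type.footprint
    cx, cy = inc.center
    nx, ny = (cx + dx) % L, (cy + dy) % L

    new_sites = (np.array([nx, ny]) + off) % L
    occ_new = state.occ[new_sites[:, 0], new_sites[:, 1]]
    if np.any((occ_new >= 0) & (occ_new != inc.id)):
        return False

    e_before = hamiltonian_mem(state, params) + hamiltonian_int(state, params)
    member = {(int(a), int(b)) for a, b in off}

    sval, occ = state.sval, state.occ
    sval_saved, occ_saved = sval.copy(), occ.copy()
    # collect leading-edge lipid spins and their mirror destinations
    moved: list[tuple[int, int, int]] = []
    for (ox, oy) in off:
        if (int(ox) + dx, int(oy) + dy) not in member:
            sx, sy = (nx + ox) % L, (ny + oy) % L
            moved.append(((cx - ox) % L, (cy - oy) % L, int(sval[sx, sy])))
    old_sites = (np.array([cx, cy]) + off) % L
    occ[old_sites[:, 0], old_sites[:, 1]] = -1
    sval[old_sites[:, 0], old_sites[:, 1]] = 0
    b = inc.boundary_pref
    occ[new_sites[:, 0], new_sites[:, 1]] = inc.id
    sval[new_sites[:, 0], new_sites[:, 1]] = np.where(bnd, b, 0).astype(np.int8)
    for tx, ty, s in moved:
        sval[tx, ty] = s
    e_after = hamiltonian_mem(state, params) + hamiltonian_int(state, params)

    dE = e_after - e_before
    if dE <= 0 or rng.random() < np.exp(-params.beta * dE):
        inc.center = (nx, ny)
        return True
    sval[...] = sval_saved
    occ[...] = occ_saved
    return False


def detect_contacts(
    state: "LatticeState", connectivity: int = 4
) -> list[tuple[int, int]]:
    """Unordered inclusion pairs whose footprints are adjacent.

    Contact means some footprint site of one inclusion is a four-neighbor
    (or eight-neighbor with ``connectivity=8``) of a footprint site of
    the other.  Each pair is reported once as ``(i, j)`` with ``i < j``.
    """
    if connectivity == 4:
        shifts = ((1, 0), (-1, 0), (0, 1), (0, -1))
    elif connectivity == 8:
        shifts = (
            (1, 0), (-1, 0), (0, 1), (0, -1),
            (1, 1), (1, -1), (-1, 1), (-1, -1),
        )
    else:
        raise ValueError("connectivity must be 4 or 8")
    L = state.L
    occ = state.occ
    pairs: set[tuple[int, int]] = set()
    for inc in state.inclusions:
        sites = inc.footprint_sites(L)
        for sx, sy in shifts:
            other = occ[(sites[:, 0] + sx) % L, (sites[:, 1] + sy) % L]
            for o in np.unique(other):
                if o >= 0 and o != inc.id:
                    pairs.add((min(inc.id, int(o)), max(inc.id, int(o))))
    return sorted(pairs)
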