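"""Exhaustive Boltzmann enumeration of tiny systems.

Validates the Monte Carlo samplers: for lattices small enough to
enumerate, the long-run Kawasaki (+ inclusion translation) configuration
frequencies must converge to ``exp(-beta E)/Z`` at fixed composition.
Energies here are computed by a deliberately naive site-by-site double
loop, written independently of both the vectorized Hamiltonian functions
and the compiled kernels, so that agreement between the three is a real
cross-check rather than a tautology.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from numba import njit
from scipy.special import logsumexp

from . import _pack
from ._kernels import kernel_sample
from .inclusions import ComponentType, rasterize_disk
from .lattice import LatticeState, ThermoParams

__all__ = [
    "EnumeratedEnsemble",
    "enumerate_boltzmann",
    "sample_frequencies",
    "compare_to_sampler",
    "naive_total_energy",
]

MAX_CONFIGS = 10_000_000


@njit(cache=True)
def _naive_energy(sval, occ, J, Jint):
    # independent of _kernels: every ordered neighbor pair, halved
    L = sval.shape[0]
    e = 0.0
    for i in range(L):
        for j in range(L):
            for (di, dj) in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni = (i + di) % L
                nj = (j + dj) % L
                o1 = occ[i, j]
                o2 = occ[ni, nj]
                if o1 >= 0 and o2 >= 0:
                    # inclusion-inclusion: no direct energy, membrane-mediated only
                    continue
                if o1 < 0 and o2 < 0:
                    e += -J * sval[i, j] * sval[ni, nj]
                else:
                    e += -Jint * sval[i, j] * sval[ni, nj]
    return e / 2.0


def naive_total_energy(state: LatticeState, params: ThermoParams) -> float:
    """Brute-force total energy of a state (oracle code path)."""
    return float(
        _naive_energy(state.sval, state.occ, params.J, params.J_int)
    )


@dataclass
class EnumeratedEnsemble:
    """All configurations of a tiny system with Boltzmann probabilities."""

    keys: np.ndarray
    energies: np.ndarray
    probs: np.ndarray
    L: int
    n_up: int
    n_lip: int
    component: ComponentType | None
    params: ThermoParams

    @property
    def n_configs(self) -> int:
        return len(self.keys)

    @property
    def key_space(self) -> int:
        pos = self.L * self.L if self.component is not None else 1
        return pos * (1 << self.n_lip)


def _count_configs(L: int, n_up: int, component: ComponentType | None) -> int:
    from math import comb

    off, _ = rasterize_disk(component.radius) if component else (np.zeros((0, 2)), None)
    n_lip = L * L - (off.shape[0] if component else 0)
    n_pos = L * L if component else 1
    return n_pos * comb(n_lip, n_up)


def enumerate_boltzmann(
    L: int,
    n_up: int,
    params: ThermoParams,
    component: ComponentType | None = None,
    state_label: str | None = None,
) -> EnumeratedEnsemble:
    """Enumerate every configuration at fixed composition.

    ``n_up`` is the conserved number of +1 lipid spins.  If ``component``
    is given, a single inclusion of that type is enumerated over all
    ``L*L`` center positions (distinct positions give distinct
    configurations; no symmetry reduction).  Raises if the configuration
    count exceeds the enumeration bound.
    """
    n_total = _count_configs(L, n_up, component)
    if n_total > MAX_CONFIGS:
        raise ValueError(
            f"state space has {n_total} configurations, above the "
            f"enumeration bound {MAX_CONFIGS}"
        )
    if component is not None:
        off, bnd = rasterize_disk(component.radius)
        label = state_label or component.states[0]
        b = component.boundary_pref[label]
        positions = [(i, j) for i in range(L) for j in range(L)]
    else:
        off = np.zeros((0, 2), np.int64)
        bnd = np.zeros(0, bool)
        b = 0
        positions = [None]
    n_fp = off.shape[0]
    n_lip = L * L - n_fp

    keys, energies = [], []
    sval = np.zeros((L, L), np.int8)
    occ = np.full((L, L), -1, np.int32)
    for pos in positions:
        occ[:] = -1
        sval[:] = 0
        if pos is not None:
            sx = (pos[0] + off[:, 0]) % L
            sy = (pos[1] + off[:, 1]) % L
            occ[sx, sy] = 0
            sval[sx, sy] = np.where(bnd, b, 0).astype(np.int8)
            pos_key = pos[0] * L + pos[1]
        else:
            pos_key = 0
        lip_flat = np.flatnonzero(occ.ravel() < 0)  # flat order = key bit order
        base = pos_key * (1 << n_lip)
        for combo in combinations(range(n_lip), n_up):
            sval.ravel()[lip_flat] = -1
            idx = np.array(combo, dtype=np.int64)
            sval.ravel()[lip_flat[idx]] = 1
            bits = 0
            for c in combo:
                bits |= 1 << (n_lip - 1 - c)
            keys.append(base + bits)
            energies.append(_naive_energy(sval, occ, params.J, params.J_int))

    energies = np.asarray(energies, dtype=float)
    logw = -params.beta * energies
    probs = np.exp(logw - logsumexp(logw))
    return EnumeratedEnsemble(
        keys=np.asarray(keys, dtype=np.int64),
        energies=energies,
        probs=probs,
        L=L,
        n_up=n_up,
        n_lip=n_lip,
        component=component,
        params=params,
    )


def sample_frequencies(
    ensemble: EnumeratedEnsemble,
    n_sweeps: int,
    seed: int = 0,
    mobility: float | None = None,
) -> np.ndarray:
    """Long-run per-key visit counts of the actual Monte Carlo sampler.

    Initializes a random configuration of the same composition, runs the
    compiled movement kernel for ``n_sweeps`` sweeps recording the
    configuration key after every sweep, and returns the count vector
    over the ensemble's key space.
    """
    from .lattice import init_lattice
    from .network import NetworkSpec

    comp = ensemble.component
    if comp is not None:
        if mobility is not None:
            comp = ComponentType(
                name=comp.name,
                radius=comp.radius,
                states=comp.states,
                boundary_pref=dict(comp.boundary_pref),
                count=1,
                mobility=mobility,
            )
        net = NetworkSpec(components=[comp], rules=[], target="")
    else:
        net = None
    L, n_up = ensemble.L, ensemble.n_up
    state = init_lattice(L, 0.0, net, seed=seed)
    # enforce the exact composition regardless of rounding
    lip = np.flatnonzero(state.occ.ravel() < 0)
    rng = np.random.default_rng(seed + 1)
    spins = np.full(lip.size, -1, np.int8)
    spins[:n_up] = 1
    rng.shuffle(spins)
    state.sval.ravel()[lip] = spins

    pn = _pack.pack_state_network(state)
    args = _pack.kernel_args(state, pn)
    counts = np.zeros(ensemble.key_space, dtype=np.int64)
    kernel_sample(
        *args[:13],
        np.float64(ensemble.params.beta),
        np.float64(ensemble.params.J),
        np.float64(ensemble.params.J_int),
        np.int64(n_sweeps),
        np.int64(seed + 2),
        counts,
    )
    return counts


@dataclass
class SamplerComparison:
    tv: float
    n_samples: int
    worst: list[tuple[int, float, float]]  # (key, p_exact, p_sampled)
    unexpected_mass: float


def compare_to_sampler(
    ensemble: EnumeratedEnsemble, counts, n_worst: int = 5
) -> SamplerComparison:
    """Total-variation distance between enumeration and sampled counts.

    ``counts`` is either a vector over the ensemble key space or a
    mapping ``key -> count``.  Mass observed on keys outside the
    enumerated set (which would indicate a conservation bug) is counted
    fully against the distance and reported separately.
    """
    if isinstance(counts, dict):
        vec = np.zeros(ensemble.key_space, dtype=np.int64)
        for k, v in counts.items():
            if not 0 <= int(k) < ensemble.key_space:
                raise ValueError(f"key {k} outside the ensemble key space")
            vec[int(k)] = v
        counts = vec
    counts = np.asarray(counts)
    if counts.shape[0] != ensemble.key_space:
        raise ValueError(
            f"count vector has length {counts.shape[0]}, expected "
            f"key space {ensemble.key_space}"
        )
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no samples")
    p_samp = counts[ensemble.keys] / total
    extra = 1.0 - p_samp.sum()
    diff = np.abs(ensemble.probs - p_samp)
    tv = 0.5 * (diff.sum() + extra)
    order = np.argsort(diff)[::-1][:n_worst]
    worst = [
        (int(ensemble.keys[i]), float(ensemble.probs[i]), float(p_samp[i]))
        for i in order
    ]
    return SamplerComparison(
        tv=float(tv), n_samples=total, worst=worst, unexpected_mass=float(extra)
    )
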