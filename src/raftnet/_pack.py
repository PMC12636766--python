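"""Packing of lattice state and network specs into flat arrays for the kernels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inclusions import ComponentType, rasterize_disk


@dataclass
class Packed:
    """Component types, geometry and reaction rules as kernel-ready arrays."""

    types: list[ComponentType]
    type_index: dict[str, int]
    rad: np.ndarray
    mob: np.ndarray
    bpref: np.ndarray       # (n_types, max_states) int8; 0 where state absent
    n_states: np.ndarray    # states per type
    fp_off: np.ndarray      # (sum footprints, 2)
    fp_bnd: np.ndarray
    fp_start: np.ndarray    # (n_types + 1,)
    fp_mask: np.ndarray     # (n_types, maxw, maxw) centered membership masks
    ru_actor_t: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    ru_actor_s: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    ru_sub_t: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    ru_sub_s: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    ru_prod: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    ru_rate: np.ndarray = field(default_factory=lambda: np.empty(0, np.float64))

    def state_label(self, type_idx: int, state_idx: int) -> str:
        return self.types[type_idx].states[state_idx]


def pack_types(components: list[ComponentType]) -> Packed:
    n = len(components)
    max_states = max((len(c.states) for c in components), default=1)
    max_r = max((c.radius for c in components), default=0)
    maxw = 2 * max_r + 1
    rad = np.zeros(n, np.int64)
    mob = np.zeros(n, np.float64)
    bpref = np.zeros((n, max(max_states, 1)), np.int8)
    n_states = np.zeros(n, np.int64)
    offs, bnds, starts = [], [], [0]
    fp_mask = np.zeros((n, maxw, maxw), np.bool_)
    for t, c in enumerate(components):
        rad[t] = c.radius
        mob[t] = c.mobility
        n_states[t] = len(c.states)
        for s, label in enumerate(c.states):
            bpref[t, s] = c.boundary_pref[label]
        off, bnd = rasterize_disk(c.radius)
        offs.append(off)
        bnds.append(bnd)
        starts.append(starts[-1] + off.shape[0])
        fp_mask[t, off[:, 0] + max_r, off[:, 1] + max_r] = True
    fp_off = (
        np.concatenate(offs, axis=0).astype(np.int64)
        if offs
        else np.empty((0, 2), np.int64)
    )
    fp_bnd = (
        np.concatenate(bnds, axis=0).astype(np.bool_)
        if bnds
        else np.empty(0, np.bool_)
    )
    return Packed(
        types=list(components),
        type_index={c.name: t for t, c in enumerate(components)},
        rad=rad,
        mob=mob,
        bpref=bpref,
        n_states=n_states,
        fp_off=fp_off,
        fp_bnd=fp_bnd,
        fp_start=np.asarray(starts, np.int64),
        fp_mask=fp_mask,
    )


def pack_network(network) -> Packed:
    """Pack a NetworkSpec: component types plus reaction rules."""
    pn = pack_types(list(network.components))
    rules = list(network.rules)
    m = len(rules)
    pn.ru_actor_t = np.zeros(m, np.int64)
    pn.ru_actor_s = np.zeros(m, np.int64)
    pn.ru_sub_t = np.zeros(m, np.int64)
    pn.ru_sub_s = np.zeros(m, np.int64)
    pn.ru_prod = np.zeros(m, np.int64)
    pn.ru_rate = np.zeros(m, np.float64)
    for r, rule in enumerate(rules):
        at = pn.type_index[rule.actor[0]]
        st = pn.type_index[rule.substrate[0]]
        pn.ru_actor_t[r] = at
        pn.ru_actor_s[r] = pn.types[at].state_index(rule.actor[1])
        pn.ru_sub_t[r] = st
        pn.ru_sub_s[r] = pn.types[st].state_index(rule.substrate[1])
        pn.ru_prod[r] = pn.types[st].state_index(rule.product_state)
        pn.ru_rate[r] = rule.rate
    return pn


def pack_state_network(state) -> Packed:
    """Pack the component types present in a bare state (no rules)."""
    seen: list[ComponentType] = []
    for inc in state.inclusions:
        if all(t is not inc.type for t in seen):
            seen.append(inc.type)
    return pack_types(seen)


def kernel_args(state, pn: Packed, mobility_override: float | None = None):
    """Kernel argument tuple; arrays are fresh copies mutated by the kernel."""
    n_inc = len(state.inclusions)
    inc_x = np.zeros(n_inc, np.int64)
    inc_y = np.zeros(n_inc, np.int64)
    inc_type = np.zeros(n_inc, np.int64)
    inc_state = np.zeros(n_inc, np.int64)
    for k, inc in enumerate(state.inclusions):
        inc_x[k], inc_y[k] = inc.center
        inc_type[k] = pn.type_index[inc.type.name]
        inc_state[k] = inc.type.state_index(inc.state)
    mob = pn.mob.copy()
    if mobility_override is not None:
        mob[:] = mobility_override
    return (
        state.sval.copy(),
        state.occ.copy(),
        inc_x,
        inc_y,
        inc_type,
        inc_state,
        pn.rad,
        mob,
        pn.bpref,
        pn.fp_off,
        pn.fp_bnd,
        pn.fp_start,
        pn.fp_mask,
        pn.ru_actor_t,
        pn.ru_actor_s,
        pn.ru_sub_t,
        pn.ru_sub_s,
        pn.ru_prod,
        pn.ru_rate,
    )


def writeback(state, pn: Packed, args) -> None:
    """Copy kernel-mutated arrays back into the LatticeState."""
    sval, occ, inc_x, inc_y, _, inc_state = args[:6]
    state.sval[...] = sval
    state.occ[...] = occ
    for k, inc in enumerate(state.inclusions):
        inc.center = (int(inc_x[k]), int(inc_y[k]))
        inc.state = inc.type.states[int(inc_state[k])]
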