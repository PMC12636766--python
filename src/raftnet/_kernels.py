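"""Compiled Monte Carlo engine (numba).

All sampling-critical loops live here: Kawasaki lipid exchange, inclusion
translation with mirror-mapped lipid displacement, the per-sweep contact
reaction pass, and the per-sweep configuration-key recorder used by the
exhaustive-enumeration cross-checks.  The Python modules wrap these
kernels; their semantics are validated against reference implementations
and against exact Boltzmann enumeration in the test suite.

Conventions: ``occ[i, j] == -1`` marks a lipid site, otherwise the id of
the covering inclusion.  ``sval[i, j]`` is the lipid spin on lipid sites,
the boundary preference on inclusion-boundary sites, and 0 on inert
interior sites.  Bond energy between adjacent sites a, b is
``-c * sval_a * sval_b`` with ``c = J`` for lipid-lipid bonds, ``J_int``
for lipid-inclusion bonds, and 0 between any two inclusion sites
(inclusions interact only through the membrane; excluded volume aside).

Randomness comes from a single xorshift64* stream per kernel invocation
(numba's library generators are several times slower in these loops);
the stream is seeded through splitmix64 from the caller-provided seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_DX = np.array([1, -1, 0, 0], dtype=np.int64)
_DY = np.array([0, 0, 1, -1], dtype=np.int64)

_U64 = np.uint64
_INV_2_53 = 1.0 / 9007199254740992.0


@njit(cache=True, inline="always")
def _rng_next(state):
    x = state[0]
    x ^= x >> _U64(12)
    x ^= x << _U64(25)
    x ^= x >> _U64(27)
    state[0] = x
    return x * _U64(0x2545F4914F6CDD1D)


@njit(cache=True, inline="always")
def _rng_uniform(state):
    return float(_rng_next(state) >> _U64(11)) * _INV_2_53


@njit(cache=True, inline="always")
def _rng_below(state, n):
    # floor(u * n); bias is O(n / 2^53), negligible for lattice-sized n
    return int(_rng_uniform(state) * n)


@njit(cache=True)
def _rng_init(seed):
    state = np.empty(1, np.uint64)
    z = _U64(seed) + _U64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    z = z ^ (z >> _U64(31))
    if z == _U64(0):
        z = _U64(0x9E3779B97F4A7C15)
    state[0] = z
    return state


@njit(cache=True, inline="always")
def _bond(sval, occ, J, Jint, i1, j1, i2, j2):
    o1 = occ[i1, j1]
    o2 = occ[i2, j2]
    if o1 >= 0:
        if o2 >= 0:
            return 0.0  # inclusions interact only through the membrane
        return -Jint * sval[i1, j1] * sval[i2, j2]
    if o2 >= 0:
        return -Jint * sval[i1, j1] * sval[i2, j2]
    return -J * sval[i1, j1] * sval[i2, j2]


@njit(cache=True)
def total_energy(sval, occ, J, Jint):
    """Full Hamiltonian: every right/down bond counted once."""
    L = sval.shape[0]
    e = 0.0
    for i in range(L):
        for j in range(L):
            e += _bond(sval, occ, J, Jint, i, j, (i + 1) % L, j)
            e += _bond(sval, occ, J, Jint, i, j, i, (j + 1) % L)
    return e


@njit(cache=True)
def _window_energy(sval, occ, J, Jint, x0, y0, w, h):
    # right/down bonds for all sites in the (wrapped) window; callers pick a
    # window that covers every changed site plus a 1-site margin so that the
    # before/after difference over the window equals the full-energy change.
    L = sval.shape[0]
    e = 0.0
    for a in range(w):
        i = (x0 + a) % L
        for b in range(h):
            j = (y0 + b) % L
            e += _bond(sval, occ, J, Jint, i, j, (i + 1) % L, j)
            e += _bond(sval, occ, J, Jint, i, j, i, (j + 1) % L)
    return e


@njit(cache=True)
def _try_inclusion_move(
    sval, occ, inc_x, inc_y, inc_type, inc_state,
    rad, bpref, fp_off, fp_bnd, fp_start, fp_mask,
    beta, J, Jint, k, rng,
    buf_s, buf_o, lead_s, dest_x, dest_y,
):
    L = sval.shape[0]
    t = inc_type[k]
    r = rad[t]
    d = _rng_below(rng, 4)
    dx = _DX[d]
    dy = _DY[d]
    cx = inc_x[k]
    cy = inc_y[k]
    nx = (cx + dx) % L
    ny = (cy + dy) % L
    f0 = fp_start[t]
    f1 = fp_start[t + 1]

    # excluded volume
    for f in range(f0, f1):
        si = (nx + fp_off[f, 0]) % L
        sj = (ny + fp_off[f, 1]) % L
        o = occ[si, sj]
        if o >= 0 and o != k:
            return 0

    # affected window: union of old and new bounding boxes, 1-site margin
    x0 = cx - r - 1 + min(dx, 0)
    y0 = cy - r - 1 + min(dy, 0)
    w = 2 * r + 3 + abs(dx)
    h = 2 * r + 3 + abs(dy)
    if w > L:
        x0 = 0
        w = L
    if h > L:
        y0 = 0
        h = L
    x0 = x0 % L
    y0 = y0 % L

    e_before = _window_energy(sval, occ, J, Jint, x0, y0, w, h)
    for a in range(w):
        i = (x0 + a) % L
        for b in range(h):
            j = (y0 + b) % L
            buf_s[a, b] = sval[i, j]
            buf_o[a, b] = occ[i, j]

    # leading-edge lipids (offsets o with o+d outside the footprint) are
    # relocated to the mirrored trailing sites center - o
    mw = fp_mask.shape[1]
    mr = (mw - 1) // 2
    nrel = 0
    for f in range(f0, f1):
        ox = fp_off[f, 0]
        oy = fp_off[f, 1]
        ax = ox + dx + mr
        ay = oy + dy + mr
        inside = 0 <= ax < mw and 0 <= ay < mw and fp_mask[t, ax, ay]
        if not inside:
            lead_s[nrel] = sval[(nx + ox) % L, (ny + oy) % L]
            dest_x[nrel] = (cx - ox) % L
            dest_y[nrel] = (cy - oy) % L
            nrel += 1
    # clear old footprint, stamp new footprint, deposit relocated spins
    for f in range(f0, f1):
        occ[(cx + fp_off[f, 0]) % L, (cy + fp_off[f, 1]) % L] = -1
        sval[(cx + fp_off[f, 0]) % L, (cy + fp_off[f, 1]) % L] = 0
    b_cur = bpref[t, inc_state[k]]
    for f in range(f0, f1):
        si = (nx + fp_off[f, 0]) % L
        sj = (ny + fp_off[f, 1]) % L
        occ[si, sj] = k
        sval[si, sj] = b_cur if fp_bnd[f] else 0
    for q in range(nrel):
        sval[dest_x[q], dest_y[q]] = lead_s[q]

    e_after = _window_energy(sval, occ, J, Jint, x0, y0, w, h)
    dE = e_after - e_before
    if dE <= 0.0 or _rng_uniform(rng) < np.exp(-beta * dE):
        inc_x[k] = nx
        inc_y[k] = ny
        return 1
    for a in range(w):
        i = (x0 + a) % L
        for b in range(h):
            j = (y0 + b) % L
            sval[i, j] = buf_s[a, b]
            occ[i, j] = buf_o[a, b]
    return 0


@njit(cache=True)
def _one_sweep(
    sval, occ, inc_x, inc_y, inc_type, inc_state,
    rad, mob, bpref, fp_off, fp_bnd, fp_start, fp_mask,
    beta, J, Jint, rng,
    n_lip, acc_tab, xp, xm, si_, sj_, att_inc, att_t,
    buf_s, buf_o, lead_s, dest_x, dest_y,
    counters,
):
    """One sweep: as many random-site swap attempts as there are lipid
    sites, with stochastically scheduled inclusion translation attempts
    interleaved at uniformly random points of the sweep.

    ``n_lip`` (invariant under all dynamics) and the quantized-acceptance
    table ``acc_tab`` are precomputed by the caller."""
    L = sval.shape[0]
    n_site = L * L
    n_inc = inc_x.shape[0]
    uniform_c = J == Jint and J > 0.0

    n_att = 0
    for k in range(n_inc):
        c = mob[inc_type[k]]
        nk = int(c)
        if _rng_uniform(rng) < c - nk:
            nk += 1
        for _ in range(nk):
            att_inc[n_att] = k
            att_t[n_att] = _rng_below(rng, max(n_lip, 1))
            n_att += 1
    # insertion sort of the (few) scheduled attempt times
    for a in range(1, n_att):
        ta = att_t[a]
        ka = att_inc[a]
        b = a - 1
        while b >= 0 and att_t[b] > ta:
            att_t[b + 1] = att_t[b]
            att_inc[b + 1] = att_inc[b]
            b -= 1
        att_t[b + 1] = ta
        att_inc[b + 1] = ka

    lip_att = 0
    lip_acc = 0
    inc_att = 0
    inc_acc = 0
    four_n = 4.0 * n_site
    done = 0
    # swap attempts run in tight segments between scheduled inclusion moves
    for a in range(n_att + 1):
        seg_end = att_t[a] if a < n_att else n_lip
        while done < seg_end:
            # one uniform draw yields both the site and the direction
            k = int(_rng_uniform(rng) * four_n)
            site = k >> 2
            i = si_[site]
            j = sj_[site]
            if occ[i, j] >= 0:
                continue
            done += 1
            d = k & 3
            ni = xp[i] if d == 0 else (xm[i] if d == 1 else i)
            nj = xp[j] if d == 2 else (xm[j] if d == 3 else j)
            lip_att += 1
            if occ[ni, nj] >= 0:
                continue
            s1 = sval[i, j]
            s2 = sval[ni, nj]
            if s1 == s2:
                continue
            # partner-inclusive fields give dE = (s1-s2)(S1-S2) + J (s1-s2)^2
            if uniform_c:
                q = (s1 - s2) * (
                    sval[xp[i], j] + sval[xm[i], j]
                    + sval[i, xp[j]] + sval[i, xm[j]]
                    - sval[xp[ni], nj] - sval[xm[ni], nj]
                    - sval[ni, xp[nj]] - sval[ni, xm[nj]]
                ) + 4
                if q <= 0 or _rng_uniform(rng) < acc_tab[(q + 12) >> 1]:
                    sval[i, j] = s2
                    sval[ni, nj] = s1
                    lip_acc += 1
            else:
                S1 = 0.0
                S2 = 0.0
                for d2 in range(4):
                    ai = xp[i] if d2 == 0 else (xm[i] if d2 == 1 else i)
                    aj = xp[j] if d2 == 2 else (xm[j] if d2 == 3 else j)
                    S1 += (J if occ[ai, aj] < 0 else Jint) * sval[ai, aj]
                    bi = xp[ni] if d2 == 0 else (xm[ni] if d2 == 1 else ni)
                    bj = xp[nj] if d2 == 2 else (xm[nj] if d2 == 3 else nj)
                    S2 += (J if occ[bi, bj] < 0 else Jint) * sval[bi, bj]
                dE = (s1 - s2) * (S1 - S2) + 4.0 * J
                if dE <= 0.0 or _rng_uniform(rng) < np.exp(-beta * dE):
                    sval[i, j] = s2
                    sval[ni, nj] = s1
                    lip_acc += 1
        if a < n_att:
            inc_att += 1
            inc_acc += _try_inclusion_move(
                sval, occ, inc_x, inc_y, inc_type, inc_state,
                rad, bpref, fp_off, fp_bnd, fp_start, fp_mask,
                beta, J, Jint, att_inc[a], rng,
                buf_s, buf_o, lead_s, dest_x, dest_y,
            )
    counters[0] += lip_att
    counters[1] += lip_acc
    counters[2] += inc_att
    counters[3] += inc_acc


@njit(cache=True)
def _sweep_consts(occ, beta, J):
    """Lipid-site count and the quantized Metropolis acceptance table.

    With uniform coupling the swap energy change is J*q, q an even integer
    in [-12, 20]; tabulating min(1, exp(-beta*J*q)) avoids exp() calls in
    the hot loop."""
    L = occ.shape[0]
    n_lip = 0
    for i in range(L):
        for j in range(L):
            if occ[i, j] < 0:
                n_lip += 1
    acc_tab = np.empty(17, np.float64)
    for qi in range(17):
        q = 2 * qi - 12
        acc_tab[qi] = np.exp(-beta * J * q) if q > 0 else 1.0
    return n_lip, acc_tab


@njit(cache=True)
def _reaction_pass(
    sval, occ, inc_x, inc_y, inc_type, inc_state,
    rad, bpref, fp_off, fp_bnd, fp_start, fp_mask,
    ru_actor_t, ru_actor_s, ru_sub_t, ru_sub_s, ru_prod, ru_rate,
    sweep, rng, pair_stamp, mod_stamp,
    pa, pb, ev_a, ev_s, ev_r,
    log_sweep, log_rule, log_actor, log_sub, counters, ev_cap,
):
    L = sval.shape[0]
    n_inc = inc_x.shape[0]
    n_rules = ru_rate.shape[0]

    # contacting pairs via four-adjacency of boundary sites
    n_pairs = 0
    for k in range(n_inc):
        t = inc_type[k]
        marker = sweep * n_inc + k + 1
        for f in range(fp_start[t], fp_start[t + 1]):
            if not fp_bnd[f]:
                continue
            bx = (inc_x[k] + fp_off[f, 0]) % L
            by = (inc_y[k] + fp_off[f, 1]) % L
            for d in range(4):
                o = occ[(bx + _DX[d]) % L, (by + _DY[d]) % L]
                if o > k and pair_stamp[o] != marker:
                    pair_stamp[o] = marker
                    if n_pairs < pa.shape[0]:
                        pa[n_pairs] = k
                        pb[n_pairs] = o
                        n_pairs += 1

    n_ev = 0
    cap = ev_a.shape[0]
    for p in range(n_pairs):
        i = pa[p]
        j = pb[p]
        for r in range(n_rules):
            if (
                inc_type[i] == ru_actor_t[r]
                and inc_type[j] == ru_sub_t[r]
                and n_ev < cap
            ):
                ev_a[n_ev] = i
                ev_s[n_ev] = j
                ev_r[n_ev] = r
                n_ev += 1
            if (
                inc_type[j] == ru_actor_t[r]
                and inc_type[i] == ru_sub_t[r]
                and n_ev < cap
            ):
                ev_a[n_ev] = j
                ev_s[n_ev] = i
                ev_r[n_ev] = r
                n_ev += 1

    for idx in range(n_ev - 1, 0, -1):
        jdx = _rng_below(rng, idx + 1)
        for arr in (ev_a, ev_s, ev_r):
            tmp = arr[idx]
            arr[idx] = arr[jdx]
            arr[jdx] = tmp

    for e in range(n_ev):
        a = ev_a[e]
        s = ev_s[e]
        r = ev_r[e]
        if mod_stamp[s] == sweep + 1:
            continue
        if inc_state[a] != ru_actor_s[r] or inc_state[s] != ru_sub_s[r]:
            continue
        if _rng_uniform(rng) >= ru_rate[r]:
            continue
        inc_state[s] = ru_prod[r]
        mod_stamp[s] = sweep + 1
        t = inc_type[s]
        newb = bpref[t, ru_prod[r]]
        for f in range(fp_start[t], fp_start[t + 1]):
            if fp_bnd[f]:
                sval[(inc_x[s] + fp_off[f, 0]) % L,
                     (inc_y[s] + fp_off[f, 1]) % L] = newb
        nlog = counters[4]
        if nlog < ev_cap:
            log_sweep[nlog] = sweep
            log_rule[nlog] = r
            log_actor[nlog] = a
            log_sub[nlog] = s
            counters[4] = nlog + 1
        else:
            counters[5] = 1


@njit(cache=True)
def _make_scratch(sval, occ, rad, mob, fp_start, n_inc):
    L = sval.shape[0]
    n_types = rad.shape[0]
    max_fp = 0
    max_r = 0
    for t in range(n_types):
        if fp_start[t + 1] - fp_start[t] > max_fp:
            max_fp = fp_start[t + 1] - fp_start[t]
        if rad[t] > max_r:
            max_r = rad[t]
    maxw = min(2 * max_r + 4, L)
    buf_s = np.zeros((maxw, maxw), np.int8)
    buf_o = np.zeros((maxw, maxw), np.int32)
    lead_s = np.zeros(max(max_fp, 1), np.int8)
    dest_x = np.zeros(max(max_fp, 1), np.int64)
    dest_y = np.zeros(max(max_fp, 1), np.int64)
    max_att = 0
    for t in range(n_types):
        if int(mob[t]) + 1 > max_att:
            max_att = int(mob[t]) + 1
    att_inc = np.zeros(max(n_inc * max_att, 1), np.int64)
    att_t = np.zeros(max(n_inc * max_att, 1), np.int64)
    xp = np.zeros(L, np.int64)
    xm = np.zeros(L, np.int64)
    si_ = np.zeros(L * L, np.int32)
    sj_ = np.zeros(L * L, np.int32)
    for i in range(L):
        xp[i] = (i + 1) % L
        xm[i] = (i - 1) % L
        for j in range(L):
            si_[i * L + j] = i
            sj_[i * L + j] = j
    return buf_s, buf_o, lead_s, dest_x, dest_y, att_inc, att_t, xp, xm, si_, sj_


@njit(cache=True)
def kernel_run(
    sval, occ, inc_x, inc_y, inc_type, inc_state,
    rad, mob, bpref, fp_off, fp_bnd, fp_start, fp_mask,
    ru_actor_t, ru_actor_s, ru_sub_t, ru_sub_s, ru_prod, ru_rate,
    beta, J, Jint,
    n_sweeps, record_every, snap_every, seed, ev_cap,
):
    """Run the full sweep schedule; mutates sval/occ/inc_* in place.

    Returns recorded traces (sweep index, per-type-state counts, energy,
    lipid magnetization, acceptance fractions), snapshots on cadence,
    the reaction event log, and cumulative attempt/accept counters.
    """
    rng = _rng_init(seed)
    L = sval.shape[0]
    n_inc = inc_x.shape[0]
    n_types = rad.shape[0]
    n_states = bpref.shape[1]
    n_rules = ru_rate.shape[0]

    (buf_s, buf_o, lead_s, dest_x, dest_y, att_inc, att_t,
     xp, xm, si_, sj_) = _make_scratch(sval, occ, rad, mob, fp_start, n_inc)

    pair_cap = max(8 * n_inc, 1)
    pa = np.zeros(pair_cap, np.int64)
    pb = np.zeros(pair_cap, np.int64)
    ev_buf_cap = max(2 * pair_cap * max(n_rules, 1), 1)
    ev_a = np.zeros(ev_buf_cap, np.int64)
    ev_s = np.zeros(ev_buf_cap, np.int64)
    ev_r = np.zeros(ev_buf_cap, np.int64)
    pair_stamp = np.full(max(n_inc, 1), -1, np.int64)
    mod_stamp = np.full(max(n_inc, 1), -1, np.int64)

    n_rec = n_sweeps // record_every + 1
    rec_sweep = np.zeros(n_rec, np.int64)
    rec_counts = np.zeros((n_rec, n_types, n_states), np.int64)
    rec_energy = np.zeros(n_rec, np.float64)
    rec_mag = np.zeros(n_rec, np.float64)
    rec_acc_lip = np.zeros(n_rec, np.float64)
    rec_acc_inc = np.zeros(n_rec, np.float64)

    n_snap = n_sweeps // snap_every if snap_every > 0 else 0
    snap_sweep = np.zeros(max(n_snap, 1), np.int64)[:n_snap]
    snap_sval = np.zeros((n_snap, L, L), np.int8)
    snap_occ = np.zeros((n_snap, L, L), np.int32)
    snap_state = np.zeros((n_snap, n_inc), np.int64)

    cap = max(ev_cap, 0)
    log_sweep = np.zeros(max(cap, 1), np.int64)[:cap]
    log_rule = np.zeros(max(cap, 1), np.int64)[:cap]
    log_actor = np.zeros(max(cap, 1), np.int64)[:cap]
    log_sub = np.zeros(max(cap, 1), np.int64)[:cap]

    # counters: lip_att, lip_acc, inc_att, inc_acc, n_events, ev_overflow
    counters = np.zeros(6, np.int64)

    n_lip, acc_tab = _sweep_consts(occ, beta, J)

    # record index 0 = initial configuration
    rec_sweep[0] = 0
    for k in range(n_inc):
        rec_counts[0, inc_type[k], inc_state[k]] += 1
    rec_energy[0] = total_energy(sval, occ, J, Jint)
    msum = 0.0
    for i in range(L):
        for j in range(L):
            if occ[i, j] < 0:
                msum += sval[i, j]
    rec_mag[0] = msum / n_lip if n_lip > 0 else 0.0
    nrec = 1

    prev = np.zeros(4, np.int64)
    for sweep in range(1, n_sweeps + 1):
        _one_sweep(
            sval, occ, inc_x, inc_y, inc_type, inc_state,
            rad, mob, bpref, fp_off, fp_bnd, fp_start, fp_mask,
            beta, J, Jint, rng,
            n_lip, acc_tab, xp, xm, si_, sj_, att_inc, att_t,
            buf_s, buf_o, lead_s, dest_x, dest_y,
            counters,
        )
        if n_rules > 0:
            _reaction_pass(
                sval, occ, inc_x, inc_y, inc_type, inc_state,
                rad, bpref, fp_off, fp_bnd, fp_start, fp_mask,
                ru_actor_t, ru_actor_s, ru_sub_t, ru_sub_s, ru_prod, ru_rate,
                sweep, rng, pair_stamp, mod_stamp,
                pa, pb, ev_a, ev_s, ev_r,
                log_sweep, log_rule, log_actor, log_sub, counters, ev_cap,
            )
        if sweep % record_every == 0:
            rec_sweep[nrec] = sweep
            for k in range(n_inc):
                rec_counts[nrec, inc_type[k], inc_state[k]] += 1
            rec_energy[nrec] = total_energy(sval, occ, J, Jint)
            msum = 0.0
            for i in range(L):
                for j in range(L):
                    if occ[i, j] < 0:
                        msum += sval[i, j]
            rec_mag[nrec] = msum / n_lip if n_lip > 0 else 0.0
            d_att = counters[0] - prev[0]
            d_acc = counters[1] - prev[1]
            rec_acc_lip[nrec] = d_acc / d_att if d_att > 0 else 0.0
            d_att = counters[2] - prev[2]
            d_acc = counters[3] - prev[3]
            rec_acc_inc[nrec] = d_acc / d_att if d_att > 0 else 0.0
            for q in range(4):
                prev[q] = counters[q]
            nrec += 1
        if snap_every > 0 and sweep % snap_every == 0:
            sidx = sweep // snap_every - 1
            snap_sweep[sidx] = sweep
            for i in range(L):
                for j in range(L):
                    snap_sval[sidx, i, j] = sval[i, j]
                    snap_occ[sidx, i, j] = occ[i, j]
            for k in range(n_inc):
                snap_state[sidx, k] = inc_state[k]

    return (
        rec_sweep[:nrec], rec_counts[:nrec], rec_energy[:nrec],
        rec_mag[:nrec], rec_acc_lip[:nrec], rec_acc_inc[:nrec],
        snap_sweep, snap_sval, snap_occ, snap_state,
        log_sweep[:counters[4]], log_rule[:counters[4]],
        log_actor[:counters[4]], log_sub[:counters[4]],
        counters,
    )


@njit(cache=True)
def config_key(sval, occ, inc_x, inc_y, n_lip):
    """Canonical integer key: inclusion position index, then lipid spin
    bits in flat site order (first lipid site = most significant bit)."""
    L = sval.shape[0]
    pos = 0
    if inc_x.shape[0] == 1:
        pos = inc_x[0] * L + inc_y[0]
    bits = 0
    for i in range(L):
        for j in range(L):
            if occ[i, j] < 0:
                bits = (bits << 1) | (1 if sval[i, j] > 0 else 0)
    return pos * (1 << n_lip) + bits


@njit(cache=True)
def kernel_sample(
    sval, occ, inc_x, inc_y, inc_type, inc_state,
    rad, mob, bpref, fp_off, fp_bnd, fp_start, fp_mask,
    beta, J, Jint,
    n_sweeps, seed, counts,
):
    """Movement-only sampler recording a configuration key every sweep.

    ``counts`` must be sized ``n_position_keys * 2**n_lip``; used by the
    detailed-balance validation against exhaustive enumeration.
    """
    rng = _rng_init(seed)
    L = sval.shape[0]
    n_inc = inc_x.shape[0]
    n_lip, acc_tab = _sweep_consts(occ, beta, J)

    (buf_s, buf_o, lead_s, dest_x, dest_y, att_inc, att_t,
     xp, xm, si_, sj_) = _make_scratch(sval, occ, rad, mob, fp_start, n_inc)
    counters = np.zeros(6, np.int64)

    for _ in range(n_sweeps):
        _one_sweep(
            sval, occ, inc_x, inc_y, inc_type, inc_state,
            rad, mob, bpref, fp_off, fp_bnd, fp_start, fp_mask,
            beta, J, Jint, rng,
            n_lip, acc_tab, xp, xm, si_, sj_, att_inc, att_t,
            buf_s, buf_o, lead_s, dest_x, dest_y,
            counters,
        )
        counts[config_key(sval, occ, inc_x, inc_y, n_lip)] += 1
    return counters
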