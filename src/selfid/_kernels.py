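"""Numba kernels behind the simulation engine.

These functions implement the per-gamete and per-generation inner loops on a
flat array representation of the population:

* ``trait``   -- ``int8[N, 2, n_z]`` trait alleles (+1 = allele a, -1 = A),
* ``pos``     -- one flat, per-haplotype-sorted ``float64`` array of all
  deleterious-mutation positions,
* ``off``     -- ``int64[2N + 1]`` offsets; haplotype ``g`` of individual
  ``i`` is ``pos[off[2i + g] : off[2i + g + 1]]``.

All randomness uses numba's internal ``np.random`` state; every entry point
called from Python takes an explicit ``seed`` and seeds that state first, so
a run is fully reproducible from its seed sequence. The same compiled
meiosis/mutation primitives serve both the per-individual Python API and the
batched generation step.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# meiosis primitives
# ---------------------------------------------------------------------------


@njit(cache=True)
def _draw_breakpoints(L):
    """Poisson(L) crossover breakpoints, sorted, each ~ U(0,1)."""
    n = np.random.poisson(L)
    b = np.empty(n, dtype=np.float64)
    for i in range(n):
        b[i] = np.random.random()
    return np.sort(b)


@njit(cache=True)
def _recombine(pos_a, pos_b, tr_a, tr_b, breaks, start, n_z):
    """Build one gamete by alternating parental segments at ``breaks``.

    Segments are half-open ``[prev, b)``; the haplotype active at position
    ``p`` is ``(start + #breaks <= p) % 2`` with 0 = ``a`` and 1 = ``b``.
    Returns sorted positions and the n_z trait alleles of the gamete.
    """
    out_pos = np.empty(pos_a.size + pos_b.size, dtype=np.float64)
    m = 0
    prev = 0.0
    cur = start
    nb = breaks.size
    for seg in range(nb + 1):
        hi = breaks[seg] if seg < nb else 1.0
        src = pos_a if cur == 0 else pos_b
        lo_i = np.searchsorted(src, prev, side="left")
        hi_i = np.searchsorted(src, hi, side="left")
        for t in range(lo_i, hi_i):
            out_pos[m] = src[t]
            m += 1
        prev = hi
        cur = 1 - cur
    out_tr = np.empty(n_z, dtype=np.int8)
    for l in range(n_z):
        p = l / n_z
        j = np.searchsorted(breaks, p, side="right")
        if (start + j) % 2 == 0:
            out_tr[l] = tr_a[l]
        else:
            out_tr[l] = tr_b[l]
    return out_pos[:m].copy(), out_tr


@njit(cache=True)
def _is_trait_position(p, n_z):
    sc = p * n_z
    return sc == np.floor(sc)


@njit(cache=True)
def _add_mutations(pos, tr, U, U_z, n_z):
    """Add Poisson(U/2) deleterious and Poisson(U_z/2) trait mutations.

    Deleterious positions are uniform on (0,1); draws that hit a trait-locus
    position or an existing position (probability-zero ties) are redrawn.
    Trait mutation events each flip the allele at one uniform locus.
    Mutates ``tr`` in place; returns the new sorted position array.
    """
    nmut = np.random.poisson(U * 0.5)
    if nmut > 0:
        newp = np.empty(nmut, dtype=np.float64)
        for i in range(nmut):
            while True:
                p = np.random.random()
                if p <= 0.0 or _is_trait_position(p, n_z):
                    continue
                idx = np.searchsorted(pos, p, side="left")
                if idx < pos.size and pos[idx] == p:
                    continue
                dup = False
                for j in range(i):
                    if newp[j] == p:
                        dup = True
                        break
                if dup:
                    continue
                newp[i] = p
                break
        pos = np.sort(np.concatenate((pos, newp)))
    ntm = np.random.poisson(U_z * 0.5)
    for _ in range(ntm):
        l = np.random.randint(0, n_z)
        tr[l] = -tr[l]
    return pos


@njit(cache=True)
def _gamete(pos_a, pos_b, tr_a, tr_b, L, U, U_z, n_z):
    """One full meiosis: crossovers + segregation + mutation."""
    breaks = _draw_breakpoints(L)
    start = 0 if np.random.random() < 0.5 else 1
    pos, tr = _recombine(pos_a, pos_b, tr_a, tr_b, breaks, start, n_z)
    pos = _add_mutations(pos, tr, U, U_z, n_z)
    return pos, tr


@njit(cache=True)
def _zygosity(p1, p2):
    """(n_het, n_hom) of two sorted unique position arrays."""
    i = 0
    j = 0
    n_hom = 0
    while i < p1.size and j < p2.size:
        if p1[i] == p2[j]:
            n_hom += 1
            i += 1
            j += 1
        elif p1[i] < p2[j]:
            i += 1
        else:
            j += 1
    n_het = p1.size + p2.size - 2 * n_hom
    return n_het, n_hom


# ---------------------------------------------------------------------------
# seeded entry points for the per-individual Python API
# ---------------------------------------------------------------------------


@njit(cache=True)
def gamete_seeded(pos_a, pos_b, tr_a, tr_b, L, U, U_z, n_z, seed):
    np.random.seed(seed)
    return _gamete(pos_a, pos_b, tr_a, tr_b, L, U, U_z, n_z)


@njit(cache=True)
def recombine_given(pos_a, pos_b, tr_a, tr_b, breaks, start, n_z):
    return _recombine(pos_a, pos_b, tr_a, tr_b, breaks, start, n_z)


@njit(cache=True)
def breakpoints_seeded(n, L, seed):
    """Crossover counts and a pooled position sample over n meioses."""
    np.random.seed(seed)
    counts = np.empty(n, dtype=np.int64)
    total = 0
    for i in range(n):
        b = _draw_breakpoints(L)
        counts[i] = b.size
        total += b.size
    positions = np.empty(total, dtype=np.float64)
    np.random.seed(seed)
    m = 0
    for i in range(n):
        b = _draw_breakpoints(L)
        for j in range(b.size):
            positions[m] = b[j]
            m += 1
    return counts, positions


@njit(cache=True)
def offspring_new_mutation_counts(n, L, U, U_z, n_z, seed):
    """New deleterious mutations per diploid offspring of mutation-free parents.

    Each offspring is built from two full meioses of mutation-free parents,
    so every position it carries is a new mutation. Returns per-offspring
    counts and the pooled positions.
    """
    np.random.seed(seed)
    empty = np.empty(0, dtype=np.float64)
    tr = np.ones(n_z, dtype=np.int8)
    counts = np.empty(n, dtype=np.int64)
    pool = np.empty(int(n * U) + 8 * int(np.sqrt(n * U) + 10), dtype=np.float64)
    m = 0
    for i in range(n):
        c = 0
        for _ in range(2):
            g_pos, _g_tr = _gamete(empty, empty, tr, tr, L, U, 0.0, n_z)
            c += g_pos.size
            for j in range(g_pos.size):
                if m < pool.size:
                    pool[m] = g_pos[j]
                    m += 1
        counts[i] = c
    return counts, pool[:m].copy()


@njit(cache=True)
def zygosity_batch(pos, off):
    n = (off.size - 1) // 2
    n_het = np.empty(n, dtype=np.int64)
    n_hom = np.empty(n, dtype=np.int64)
    for i in range(n):
        het, hom = _zygosity(
            pos[off[2 * i] : off[2 * i + 1]], pos[off[2 * i + 1] : off[2 * i + 2]]
        )
        n_het[i] = het
        n_hom[i] = hom
    return n_het, n_hom


# ---------------------------------------------------------------------------
# batched generation step
# ---------------------------------------------------------------------------


@njit(cache=True)
def advance_generation(trait, pos, off, alpha, s, h, L, U, U_z, n_z, lam):
    """One full life cycle: reproduction + mutation + viability selection.

    Adults (arrays ``trait``/``pos``/``off`` with selfing rates ``alpha``)
    produce N juveniles: for each, a uniformly drawn mother selfs with
    probability ``alpha[mother]`` (two independent meioses of the same
    parent) or outcrosses with a uniformly drawn father != mother. Juveniles
    are then resampled to N adults with replacement, with probability
    proportional to ``w = w1 * w2``.

    Returns ``(ok, trait', pos', off')`` for the new adult generation;
    ``ok = 0`` signals extinction (all juveniles at fitness zero).
    """
    N = trait.shape[0]
    cap = pos.size + int(2.0 * N * U) + 256
    jpos = np.empty(cap, dtype=np.float64)
    joff = np.empty(2 * N + 1, dtype=np.int64)
    joff[0] = 0
    jtrait = np.empty((N, 2, n_z), dtype=np.int8)
    used = 0
    for o in range(N):
        mother = np.random.randint(0, N)
        if np.random.random() < alpha[mother]:
            father = mother
        else:
            father = np.random.randint(0, N - 1)
            if father >= mother:
                father += 1
        for slot in range(2):
            par = mother if slot == 0 else father
            a0 = off[2 * par]
            a1 = off[2 * par + 1]
            a2 = off[2 * par + 2]
            g_pos, g_tr = _gamete(
                pos[a0:a1], pos[a1:a2], trait[par, 0], trait[par, 1], L, U, U_z, n_z
            )
            ng = g_pos.size
            while used + ng > cap:
                cap *= 2
                tmp = np.empty(cap, dtype=np.float64)
                tmp[:used] = jpos[:used]
                jpos = tmp
            jpos[used : used + ng] = g_pos
            used += ng
            joff[2 * o + slot + 1] = used
            jtrait[o, slot, :] = g_tr
    # juvenile fitness
    w = np.empty(N, dtype=np.float64)
    for o in range(N):
        tsum = 0
        for g in range(2):
            for l in range(n_z):
                tsum += jtrait[o, g, l]
        z = tsum / n_z
        het, hom = _zygosity(
            jpos[joff[2 * o] : joff[2 * o + 1]],
            jpos[joff[2 * o + 1] : joff[2 * o + 2]],
        )
        w1 = np.exp(-lam * z * z)
        w2 = (1.0 - h * s) ** het * (1.0 - s) ** hom
        w[o] = w1 * w2
    cum = np.cumsum(w)
    tot = cum[N - 1]
    empty_tr = np.empty((0, 2, n_z), dtype=np.int8)
    empty_pos = np.empty(0, dtype=np.float64)
    empty_off = np.empty(0, dtype=np.int64)
    if tot <= 0.0:
        return 0, empty_tr, empty_pos, empty_off
    sel = np.empty(N, dtype=np.int64)
    total_sel = 0
    for o in range(N):
        r = np.random.random() * tot
        idx = np.searchsorted(cum, r, side="right")
        if idx >= N:  # guard against r == tot edge
            idx = N - 1
        sel[o] = idx
        total_sel += joff[2 * idx + 2] - joff[2 * idx]
    atrait = np.empty((N, 2, n_z), dtype=np.int8)
    apos = np.empty(total_sel, dtype=np.float64)
    aoff = np.empty(2 * N + 1, dtype=np.int64)
    aoff[0] = 0
    u2 = 0
    for o in range(N):
        sj = sel[o]
        for g in range(2):
            b0 = joff[2 * sj + g]
            b1 = joff[2 * sj + g + 1]
            for t in range(b0, b1):
                apos[u2] = jpos[t]
                u2 += 1
            aoff[2 * o + g + 1] = u2
            atrait[o, g, :] = jtrait[sj, g, :]
    return 1, atrait, apos, aoff


@njit(cache=True)
def advance_generation_seeded(trait, pos, off, alpha, s, h, L, U, U_z, n_z, lam, seed):
    np.random.seed(seed)
    return advance_generation(trait, pos, off, alpha, s, h, L, U, U_z, n_z, lam)


@njit(cache=True)
def family_assay_kernel(trait, pos, off, s, h, L, U, U_z, n_z, seed):
    """Per-adult selfed/outcrossed assay-offspring deleterious fitness.

    For each adult: one selfed offspring (two independent meioses of that
    adult) and one outcrossed offspring (one meiosis of that adult, one of a
    uniformly drawn other adult). Only the deleterious component ``w2`` is
    recorded; assay offspring never join the population.
    """
    np.random.seed(seed)
    N = trait.shape[0]
    w_self = np.empty(N, dtype=np.float64)
    w_out = np.empty(N, dtype=np.float64)
    for i in range(N):
        a0 = off[2 * i]
        a1 = off[2 * i + 1]
        a2 = off[2 * i + 2]
        g1p, _t1 = _gamete(
            pos[a0:a1], pos[a1:a2], trait[i, 0], trait[i, 1], L, U, U_z, n_z
        )
        g2p, _t2 = _gamete(
            pos[a0:a1], pos[a1:a2], trait[i, 0], trait[i, 1], L, U, U_z, n_z
        )
        het, hom = _zygosity(g1p, g2p)
        w_self[i] = (1.0 - h * s) ** het * (1.0 - s) ** hom
        j = np.random.randint(0, N - 1)
        if j >= i:
            j += 1
        b0 = off[2 * j]
        b1 = off[2 * j + 1]
        b2 = off[2 * j + 2]
        g3p, _t3 = _gamete(
            pos[a0:a1], pos[a1:a2], trait[i, 0], trait[i, 1], L, U, U_z, n_z
        )
        g4p, _t4 = _gamete(
            pos[b0:b1], pos[b1:b2], trait[j, 0], trait[j, 1], L, U, U_z, n_z
        )
        het, hom = _zygosity(g3p, g4p)
        w_out[i] = (1.0 - h * s) ** het * (1.0 - s) ** hom
    return w_self, w_out
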