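"""Numba kernels for the cubic-lattice sticker-spacer Monte Carlo engine.

Geometry: simple cubic lattice with periodic boundaries.  Two sites are
"adjacent" when their minimum-image Chebyshev distance is 1 (the 26-site
Moore neighborhood); chain connectivity and bond eligibility both use this
adjacency.  Each site holds at most one bead; each sticker bead holds at
most one anisotropic bond, and bonds are only allowed between sticker
kinds with a nonzero energy-matrix entry.

Sampling scheme
---------------
All configurational energy comes from bonds (isotropic terms are zero), so
pure spatial rearrangements have dE = 0.  Bonds change ONLY inside the
single-bead moves (rotational / local / shake): the move proposes a new
position and simultaneously redraws the bead's bond uniformly from the set
S = {unbonded} + {eligible neighboring partners} at the proposed position.
Because the proposal probability is 1/|S|, acceptance carries the Hastings
factor |S_fwd| / |S_rev| in addition to exp(-beta dE).  Every multi-bead
move (colocal, translations, cluster translations, pivots) preserves the
bond list exactly and is rejected outright if it would separate a bonded
pair; this keeps every move reversible and the chain in detailed balance
with the Boltzmann distribution over placements x bond pairings.
"""

from __future__ import annotations

import math
from itertools import permutations, product

import numpy as np
from numba import njit


def _build_neighbor_offsets() -> np.ndarray:
    offs = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    return np.array(offs, dtype=np.int64)


def _build_proper_rotations() -> np.ndarray:
    """The 24 proper rotations of the cube as integer matrices."""
    mats = []
    for perm in permutations(range(3)):
        for signs in product((1, -1), repeat=3):
            m = np.zeros((3, 3), dtype=np.int64)
            for row, (col, s) in enumerate(zip(perm, signs)):
                m[row, col] = s
            if round(np.linalg.det(m)) == 1:
                mats.append(m)
    assert len(mats) == 24
    return np.stack(mats)


NEIGHBOR_OFFSETS = _build_neighbor_offsets()
PROPER_ROTATIONS = _build_proper_rotations()

# move kind codes, in the order the study lists their attempt frequencies
MOVE_NAMES = (
    "rotational",
    "local",
    "colocal",
    "shake",
    "translation",
    "small_cluster_translation",
    "cluster_translation",
    "pivot",
    "double_pivot",
)
DEFAULT_MOVE_WEIGHTS = np.array(
    [0.25, 0.13, 0.25, 0.04, 0.04, 0.04, 0.04, 0.13, 0.10]
)  # printed per-step frequencies; sum 1.02, renormalized before use


@njit(cache=True)
def _site(x, y, z, L):
    return (x * L + y) * L + z


@njit(cache=True)
def _mind(d, L):
    d = d % L
    if d > L - d:
        d = L - d
    return d


@njit(cache=True)
def _adj(ax, ay, az, bx, by, bz, L):
    dx = _mind(ax - bx, L)
    if dx > 1:
        return False
    dy = _mind(ay - by, L)
    if dy > 1:
        return False
    dz = _mind(az - bz, L)
    if dz > 1:
        return False
    return dx + dy + dz > 0


@njit(cache=True)
def _wrapstep(d, L):
    # minimum-image representative of a single chain step (in {-1, 0, 1})
    d = d % L
    if d > L - d:
        d -= L
    return d


@njit(cache=True)
def _conn_ok(i, nx, ny, nz, pos, mol_of, L):
    """Would bead i at (nx,ny,nz) stay adjacent to its chain neighbors?"""
    N = pos.shape[0]
    m = mol_of[i]
    if i > 0 and mol_of[i - 1] == m:
        j = i - 1
        if not _adj(nx, ny, nz, pos[j, 0], pos[j, 1], pos[j, 2], L):
            return False
    if i + 1 < N and mol_of[i + 1] == m:
        j = i + 1
        if not _adj(nx, ny, nz, pos[j, 0], pos[j, 1], pos[j, 2], L):
            return False
    return True


@njit(cache=True)
def _bond_options(i, ki, px, py, pz, pos, grid, kind, partner, E, L, nb, out):
    """Distinct eligible bond partners for sticker i sitting at (px,py,pz):
    stickers within the 26-neighborhood, nonzero pair energy, unbonded or
    already bonded to i.  Returns the count; indices land in ``out``."""
    n = 0
    for t in range(26):
        x = (px + nb[t, 0]) % L
        y = (py + nb[t, 1]) % L
        z = (pz + nb[t, 2]) % L
        j = grid[_site(x, y, z, L)] - 1
        if j < 0 or j == i:
            continue
        kj = kind[j]
        if kj < 0:
            continue
        if E[ki, kj] == 0.0:
            continue
        p = partner[j]
        if p != -1 and p != i:
            continue
        dup = False
        for q in range(n):
            if out[q] == j:
                dup = True
                break
        if dup:
            continue
        out[n] = j
        n += 1
    return n


@njit(cache=True)
def _try_single_bead(i, nx, ny, nz, pos, grid, kind, mol_of, partner, E, beta, L, nb, opts):
    """Metropolis-Hastings step for one bead: spatial displacement plus,
    for stickers, a uniform redraw of its bond state.  Returns (dE, acc)."""
    ox, oy, oz = pos[i, 0], pos[i, 1], pos[i, 2]
    ki = kind[i]
    s_new = _site(nx, ny, nz, L)
    occ = grid[s_new] - 1
    blocked = (occ != -1 and occ != i) or not _conn_ok(i, nx, ny, nz, pos, mol_of, L)
    if blocked:
        if ki < 0:
            return 0.0, 0
        # geometrically blocked: fall back to a pure bond resample in place
        # (the position kernel stays symmetric; blocked proposals map to
        # "stay", identically in both directions)
        nx, ny, nz = ox, oy, oz
        s_new = _site(nx, ny, nz, L)
    if ki < 0:
        grid[_site(ox, oy, oz, L)] = 0
        grid[s_new] = i + 1
        pos[i, 0] = nx
        pos[i, 1] = ny
        pos[i, 2] = nz
        return 0.0, 1
    nf = _bond_options(i, ki, nx, ny, nz, pos, grid, kind, partner, E, L, nb, opts)
    r = int(np.random.random() * (nf + 1))
    if r > nf:
        r = nf
    newp = -1 if r == 0 else opts[r - 1]
    nr = _bond_options(i, ki, ox, oy, oz, pos, grid, kind, partner, E, L, nb, opts)
    oldp = partner[i]
    dE = 0.0
    if newp >= 0:
        dE += E[ki, kind[newp]]
    if oldp >= 0:
        dE -= E[ki, kind[oldp]]
    a = math.exp(-beta * dE) * (nf + 1.0) / (nr + 1.0)
    if a < 1.0 and np.random.random() >= a:
        return 0.0, 0
    grid[_site(ox, oy, oz, L)] = 0
    grid[s_new] = i + 1
    pos[i, 0] = nx
    pos[i, 1] = ny
    pos[i, 2] = nz
    if oldp != newp:
        if oldp >= 0:
            partner[oldp] = -1
        if newp >= 0:
            partner[newp] = i
        partner[i] = newp
    return dE, 1


@njit(cache=True)
def _move_rotational(pos, grid, kind, mol_of, mol_start, mol_len, partner, E, beta, L, nb, opts):
    M = mol_start.shape[0]
    m = int(np.random.random() * M)
    if m >= M:
        m = M - 1
    st = mol_start[m]
    le = mol_len[m]
    if le == 1:
        i = st
        ax, ay, az = pos[i, 0], pos[i, 1], pos[i, 2]
    elif np.random.random() < 0.5:
        i = st
        ax, ay, az = pos[st + 1, 0], pos[st + 1, 1], pos[st + 1, 2]
    else:
        i = st + le - 1
        ax, ay, az = pos[i - 1, 0], pos[i - 1, 1], pos[i - 1, 2]
    t = int(np.random.random() * 26)
    if t > 25:
        t = 25
    nx = (ax + nb[t, 0]) % L
    ny = (ay + nb[t, 1]) % L
    nz = (az + nb[t, 2]) % L
    return _try_single_bead(i, nx, ny, nz, pos, grid, kind, mol_of, partner, E, beta, L, nb, opts)


@njit(cache=True)
def _move_local(pos, grid, kind, mol_of, partner, E, beta, L, nb, opts):
    N = pos.shape[0]
    i = int(np.random.random() * N)
    if i >= N:
        i = N - 1
    t = int(np.random.random() * 26)
    if t > 25:
        t = 25
    nx = (pos[i, 0] + nb[t, 0]) % L
    ny = (pos[i, 1] + nb[t, 1]) % L
    nz = (pos[i, 2] + nb[t, 2]) % L
    return _try_single_bead(i, nx, ny, nz, pos, grid, kind, mol_of, partner, E, beta, L, nb, opts)


@njit(cache=True)
def _move_shake(pos, grid, kind, mol_of, partner, E, beta, L, nb, opts, tbuf):
    """Redraw a bead anywhere inside its connectivity corridor: the sites
    adjacent to both chain neighbors (interior bead), the neighborhood of
    the single neighbor (terminal bead), or the whole box (free bead)."""
    N = pos.shape[0]
    i = int(np.random.random() * N)
    if i >= N:
        i = N - 1
    m = mol_of[i]
    has_prev = i > 0 and mol_of[i - 1] == m
    has_next = i + 1 < N and mol_of[i + 1] == m
    if has_prev and has_next:
        px, py, pz = pos[i - 1, 0], pos[i - 1, 1], pos[i - 1, 2]
        qx, qy, qz = pos[i + 1, 0], pos[i + 1, 1], pos[i + 1, 2]
        cnt = 0
        for t in range(26):
            cx = (px + nb[t, 0]) % L
            cy = (py + nb[t, 1]) % L
            cz = (pz + nb[t, 2]) % L
            if _adj(cx, cy, cz, qx, qy, qz, L):
                tbuf[cnt] = t
                cnt += 1
        if cnt == 0:
            return 0.0, 0
        t = tbuf[int(np.random.random() * cnt) % cnt]
        nx = (px + nb[t, 0]) % L
        ny = (py + nb[t, 1]) % L
        nz = (pz + nb[t, 2]) % L
    elif has_prev or has_next:
        j = i - 1 if has_prev else i + 1
        t = int(np.random.random() * 26)
        if t > 25:
            t = 25
        nx = (pos[j, 0] + nb[t, 0]) % L
        ny = (pos[j, 1] + nb[t, 1]) % L
        nz = (pos[j, 2] + nb[t, 2]) % L
    else:
        nx = int(np.random.random() * L) % L
        ny = int(np.random.random() * L) % L
        nz = int(np.random.random() * L) % L
    return _try_single_bead(i, nx, ny, nz, pos, grid, kind, mol_of, partner, E, beta, L, nb, opts)


@njit(cache=True)
def _move_colocal(pos, grid, kind, mol_of, partner, sticker_idx, L, nb):
    """Rigid displacement of one bonded sticker pair; the bond (hence the
    energy) is untouched, so this is plain Metropolis at dE = 0."""
    S = sticker_idx.shape[0]
    if S == 0:
        return 0.0, 0
    i = sticker_idx[int(np.random.random() * S) % S]
    j = partner[i]
    if j < 0:
        return 0.0, 0
    t = int(np.random.random() * 26)
    if t > 25:
        t = 25
    dx, dy, dz = nb[t, 0], nb[t, 1], nb[t, 2]
    nix = (pos[i, 0] + dx) % L
    niy = (pos[i, 1] + dy) % L
    niz = (pos[i, 2] + dz) % L
    njx = (pos[j, 0] + dx) % L
    njy = (pos[j, 1] + dy) % L
    njz = (pos[j, 2] + dz) % L
    oi = grid[_site(nix, niy, niz, L)] - 1
    if oi != -1 and oi != i and oi != j:
        return 0.0, 0
    oj = grid[_site(njx, njy, njz, L)] - 1
    if oj != -1 and oj != i and oj != j:
        return 0.0, 0
    # connectivity of both beads; a chain neighbor that is the moving
    # partner keeps its relative offset, so skip it
    N = pos.shape[0]
    for pair in range(2):
        b = i if pair == 0 else j
        bx = nix if pair == 0 else njx
        by = niy if pair == 0 else njy
        bz = niz if pair == 0 else njz
        mb = mol_of[b]
        for d in range(-1, 2, 2):
            c = b + d
            if c < 0 or c >= N or mol_of[c] != mb:
                continue
            if c == i or c == j:
                continue
            if not _adj(bx, by, bz, pos[c, 0], pos[c, 1], pos[c, 2], L):
                return 0.0, 0
    grid[_site(pos[i, 0], pos[i, 1], pos[i, 2], L)] = 0
    grid[_site(pos[j, 0], pos[j, 1], pos[j, 2], L)] = 0
    pos[i, 0], pos[i, 1], pos[i, 2] = nix, niy, niz
    pos[j, 0], pos[j, 1], pos[j, 2] = njx, njy, njz
    grid[_site(nix, niy, niz, L)] = i + 1
    grid[_site(njx, njy, njz, L)] = j + 1
    return 0.0, 1


@njit(cache=True)
def _rigid_translate(bead_list, nb_beads, dx, dy, dz, pos, grid, set_flag, L):
    """Translate a bead set rigidly; occupancy may only clash with beads
    inside the set.  Returns 1 on success (positions/grid updated)."""
    for b in range(nb_beads):
        i = bead_list[b]
        nx = (pos[i, 0] + dx) % L
        ny = (pos[i, 1] + dy) % L
        nz = (pos[i, 2] + dz) % L
        occ = grid[_site(nx, ny, nz, L)] - 1
        if occ != -1 and set_flag[occ] == 0:
            return 0
    for b in range(nb_beads):
        i = bead_list[b]
        grid[_site(pos[i, 0], pos[i, 1], pos[i, 2], L)] = 0
    for b in range(nb_beads):
        i = bead_list[b]
        pos[i, 0] = (pos[i, 0] + dx) % L
        pos[i, 1] = (pos[i, 1] + dy) % L
        pos[i, 2] = (pos[i, 2] + dz) % L
        grid[_site(pos[i, 0], pos[i, 1], pos[i, 2], L)] = i + 1
    return 1


@njit(cache=True)
def _move_translation(pos, grid, mol_of, mol_start, mol_len, partner, L, set_flag, bead_list):
    """Random rigid displacement of one molecule.  Rejected when the
    molecule is bonded to another molecule (those are moved by the cluster
    moves), so the bond list never changes."""
    M = mol_start.shape[0]
    m = int(np.random.random() * M) % M
    st = mol_start[m]
    le = mol_len[m]
    for i in range(st, st + le):
        p = partner[i]
        if p >= 0 and mol_of[p] != m:
            return 0.0, 0
    dx = int(np.random.random() * L) % L
    dy = int(np.random.random() * L) % L
    dz = int(np.random.random() * L) % L
    n = 0
    for i in range(st, st + le):
        bead_list[n] = i
        set_flag[i] = 1
        n += 1
    ok = _rigid_translate(bead_list, n, dx, dy, dz, pos, grid, set_flag, L)
    for i in range(st, st + le):
        set_flag[i] = 0
    return 0.0, ok


@njit(cache=True)
def _cluster_of(m, partner, mol_of, mol_start, mol_len, visited, queue, max_n):
    """Bond-connected molecule cluster containing molecule m (BFS).

    Stops as soon as the cluster exceeds ``max_n`` molecules (the caller
    rejects those moves anyway), returning max_n + 1."""
    queue[0] = m
    visited[m] = 1
    n = 1
    head = 0
    while head < n:
        c = queue[head]
        head += 1
        for i in range(mol_start[c], mol_start[c] + mol_len[c]):
            p = partner[i]
            if p >= 0:
                pm = mol_of[p]
                if visited[pm] == 0:
                    visited[pm] = 1
                    queue[n] = pm
                    n += 1
                    if n > max_n:
                        return n
    return n


@njit(cache=True)
def _move_cluster_translation(
    pos, grid, mol_of, mol_start, mol_len, partner, L,
    set_flag, bead_list, visited, queue, max_molecules,
):
    """Rigid displacement of a whole bond-connected cluster (internal bonds
    ride along).  Clusters above ``max_molecules`` are rejected; the cut is
    on cluster size alone, which is unchanged by the move, so reversibility
    is preserved."""
    M = mol_start.shape[0]
    m = int(np.random.random() * M) % M
    nmol = _cluster_of(m, partner, mol_of, mol_start, mol_len, visited, queue, max_molecules)
    if nmol > max_molecules:
        for q in range(nmol):
            visited[queue[q]] = 0
        return 0.0, 0
    n = 0
    for q in range(nmol):
        c = queue[q]
        for i in range(mol_start[c], mol_start[c] + mol_len[c]):
            bead_list[n] = i
            set_flag[i] = 1
            n += 1
    dx = int(np.random.random() * L) % L
    dy = int(np.random.random() * L) % L
    dz = int(np.random.random() * L) % L
    ok = _rigid_translate(bead_list, n, dx, dy, dz, pos, grid, set_flag, L)
    for b in range(n):
        set_flag[bead_list[b]] = 0
    for q in range(nmol):
        visited[queue[q]] = 0
    return 0.0, ok


@njit(cache=True)
def _segment_new_positions(st_idx, end_idx, anchor, rot, pos, newpos, L, ascending):
    """Positions of a chain segment after a point-group rotation about the
    anchor bead, accumulated step by step so connectivity is exact."""
    px, py, pz = pos[anchor, 0], pos[anchor, 1], pos[anchor, 2]
    if ascending:
        rng_start, rng_stop, stepdir = st_idx, end_idx + 1, 1
    else:
        rng_start, rng_stop, stepdir = st_idx, end_idx - 1, -1
    prev = anchor
    k = rng_start
    while k != rng_stop:
        sx = _wrapstep(pos[k, 0] - pos[prev, 0], L)
        sy = _wrapstep(pos[k, 1] - pos[prev, 1], L)
        sz = _wrapstep(pos[k, 2] - pos[prev, 2], L)
        rx = rot[0, 0] * sx + rot[0, 1] * sy + rot[0, 2] * sz
        ry = rot[1, 0] * sx + rot[1, 1] * sy + rot[1, 2] * sz
        rz = rot[2, 0] * sx + rot[2, 1] * sy + rot[2, 2] * sz
        px = (px + rx) % L
        py = (py + ry) % L
        pz = (pz + rz) % L
        newpos[k, 0] = px
        newpos[k, 1] = py
        newpos[k, 2] = pz
        prev = k
        k += stepdir
    return 0


@njit(cache=True)
def _apply_segment(lo, hi, pos, newpos, grid, L):
    for i in range(lo, hi + 1):
        grid[_site(pos[i, 0], pos[i, 1], pos[i, 2], L)] = 0
    for i in range(lo, hi + 1):
        pos[i, 0] = newpos[i, 0]
        pos[i, 1] = newpos[i, 1]
        pos[i, 2] = newpos[i, 2]
        grid[_site(pos[i, 0], pos[i, 1], pos[i, 2], L)] = i + 1
    return 0


@njit(cache=True)
def _move_pivot(pos, grid, mol_of, mol_start, mol_len, partner, L, rots, newpos):
    """Rotate one chain tail around an anchor bead by a random proper
    lattice rotation.  Moved beads carrying bonds to unmoved beads reject
    the move (rotation is rigid, so intra-segment bonds survive)."""
    M = mol_start.shape[0]
    m = int(np.random.random() * M) % M
    st = mol_start[m]
    le = mol_len[m]
    if le < 2:
        return 0.0, 0
    a_local = int(np.random.random() * le) % le
    a = st + a_local
    tail = np.random.random() < 0.5
    if tail:
        lo = a + 1
        hi = st + le - 1
    else:
        lo = st
        hi = a - 1
    if lo > hi:
        return 0.0, 0
    for i in range(lo, hi + 1):
        p = partner[i]
        if p >= 0 and (p < lo or p > hi):
            return 0.0, 0
    r = int(np.random.random() * 24) % 24
    rot = rots[r]
    if tail:
        _segment_new_positions(lo, hi, a, rot, pos, newpos, L, True)
    else:
        _segment_new_positions(hi, lo, a, rot, pos, newpos, L, False)
    for i in range(lo, hi + 1):
        occ = grid[_site(newpos[i, 0], newpos[i, 1], newpos[i, 2], L)] - 1
        if occ != -1 and (occ < lo or occ > hi):
            return 0.0, 0
    _apply_segment(lo, hi, pos, newpos, grid, L)
    return 0.0, 1


@njit(cache=True)
def _move_double_pivot(pos, grid, mol_of, mol_start, mol_len, partner, L, rots, newpos):
    """Rotate the head before anchor a and the tail after anchor b by two
    independent lattice rotations (two rigid pieces, one compound move)."""
    M = mol_start.shape[0]
    m = int(np.random.random() * M) % M
    st = mol_start[m]
    le = mol_len[m]
    if le < 3:
        return 0.0, 0
    a_local = int(np.random.random() * (le - 1)) % (le - 1)
    span = le - 1 - a_local
    b_local = a_local + 1 + int(np.random.random() * span) % span
    a = st + a_local
    b = st + b_local
    lo1, hi1 = st, a - 1
    lo2, hi2 = b + 1, st + le - 1
    if lo1 > hi1 and lo2 > hi2:
        return 0.0, 0
    for i in range(lo1, hi1 + 1):
        p = partner[i]
        if p >= 0 and (p < lo1 or p > hi1):
            return 0.0, 0
    for i in range(lo2, hi2 + 1):
        p = partner[i]
        if p >= 0 and (p < lo2 or p > hi2):
            return 0.0, 0
    r1 = int(np.random.random() * 24) % 24
    r2 = int(np.random.random() * 24) % 24
    if lo1 <= hi1:
        _segment_new_positions(hi1, lo1, a, rots[r1], pos, newpos, L, False)
    if lo2 <= hi2:
        _segment_new_positions(lo2, hi2, b, rots[r2], pos, newpos, L, True)
    for i in range(lo1, hi1 + 1):
        occ = grid[_site(newpos[i, 0], newpos[i, 1], newpos[i, 2], L)] - 1
        if occ != -1 and not (lo1 <= occ <= hi1) and not (lo2 <= occ <= hi2):
            return 0.0, 0
    for i in range(lo2, hi2 + 1):
        occ = grid[_site(newpos[i, 0], newpos[i, 1], newpos[i, 2], L)] - 1
        if occ != -1 and not (lo1 <= occ <= hi1) and not (lo2 <= occ <= hi2):
            return 0.0, 0
    # the two pieces move independently: check they do not land on each other
    for i in range(lo1, hi1 + 1):
        for j in range(lo2, hi2 + 1):
            if (
                newpos[i, 0] == newpos[j, 0]
                and newpos[i, 1] == newpos[j, 1]
                and newpos[i, 2] == newpos[j, 2]
            ):
                return 0.0, 0
    # clear every old cell of both pieces before writing any new cell (a
    # piece may move into a site the other piece is vacating)
    for i in range(lo1, hi1 + 1):
        grid[_site(pos[i, 0], pos[i, 1], pos[i, 2], L)] = 0
    for i in range(lo2, hi2 + 1):
        grid[_site(pos[i, 0], pos[i, 1], pos[i, 2], L)] = 0
    for i in range(lo1, hi1 + 1):
        pos[i, 0] = newpos[i, 0]
        pos[i, 1] = newpos[i, 1]
        pos[i, 2] = newpos[i, 2]
        grid[_site(pos[i, 0], pos[i, 1], pos[i, 2], L)] = i + 1
    for i in range(lo2, hi2 + 1):
        pos[i, 0] = newpos[i, 0]
        pos[i, 1] = newpos[i, 1]
        pos[i, 2] = newpos[i, 2]
        grid[_site(pos[i, 0], pos[i, 1], pos[i, 2], L)] = i + 1
    return 0.0, 1


@njit(cache=True)
def total_energy_kernel(kind, partner, E):
    tot = 0.0
    for i in range(partner.shape[0]):
        p = partner[i]
        if p > i:
            tot += E[kind[i], kind[p]]
    return tot


@njit(cache=True)
def run_kernel(
    pos, grid, kind, mol_of, mol_start, mol_len, partner, sticker_idx,
    E, beta, L, n_steps, cumw, rots, nb, seed, record_interval,
    out_pos, out_partner, out_energy, out_step, attempts, accepts,
    max_cluster_molecules,
):
    """Run ``n_steps`` attempted moves; snapshots every ``record_interval``
    steps.  Returns (final incremental energy, number of records)."""
    np.random.seed(seed)
    N = pos.shape[0]
    M = mol_start.shape[0]
    opts = np.empty(26, np.int32)
    tbuf = np.empty(26, np.int64)
    newpos = np.empty((N, 3), np.int64)
    visited = np.zeros(M, np.uint8)
    queue = np.empty(M, np.int64)
    set_flag = np.zeros(N, np.uint8)
    bead_list = np.empty(N, np.int64)
    totE = total_energy_kernel(kind, partner, E)
    rec = 0
    max_rec = out_energy.shape[0]
    for step in range(1, n_steps + 1):
        u = np.random.random()
        mk = 0
        while mk < 8 and u >= cumw[mk]:
            mk += 1
        attempts[mk] += 1
        if mk == 0:
            dE, acc = _move_rotational(
                pos, grid, kind, mol_of, mol_start, mol_len, partner, E, beta, L, nb, opts
            )
        elif mk == 1:
            dE, acc = _move_local(pos, grid, kind, mol_of, partner, E, beta, L, nb, opts)
        elif mk == 2:
            dE, acc = _move_colocal(pos, grid, kind, mol_of, partner, sticker_idx, L, nb)
        elif mk == 3:
            dE, acc = _move_shake(pos, grid, kind, mol_of, partner, E, beta, L, nb, opts, tbuf)
        elif mk == 4:
            dE, acc = _move_translation(
                pos, grid, mol_of, mol_start, mol_len, partner, L, set_flag, bead_list
            )
        elif mk == 5:
            dE, acc = _move_cluster_translation(
                pos, grid, mol_of, mol_start, mol_len, partner, L,
                set_flag, bead_list, visited, queue, 5,
            )
        elif mk == 6:
            dE, acc = _move_cluster_translation(
                pos, grid, mol_of, mol_start, mol_len, partner, L,
                set_flag, bead_list, visited, queue, max_cluster_molecules,
            )
        elif mk == 7:
            dE, acc = _move_pivot(pos, grid, mol_of, mol_start, mol_len, partner, L, rots, newpos)
        else:
            dE, acc = _move_double_pivot(
                pos, grid, mol_of, mol_start, mol_len, partner, L, rots, newpos
            )
        if acc == 1:
            accepts[mk] += 1
            totE += dE
        if record_interval > 0 and step % record_interval == 0 and rec < max_rec:
            for i in range(N):
                out_pos[rec, i, 0] = pos[i, 0]
                out_pos[rec, i, 1] = pos[i, 1]
                out_pos[rec, i, 2] = pos[i, 2]
                out_partner[rec, i] = partner[i]
            out_energy[rec] = totE
            out_step[rec] = step
            rec += 1
    return totE, rec
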