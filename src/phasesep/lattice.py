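"""Cubic-lattice Monte Carlo engine for two-species sticker-spacer mixtures.

A :class:`LatticeState` holds bead positions of all chains on a periodic
simple-cubic lattice together with the anisotropic bond pairing between
sticker beads.  :func:`run_mc` advances the state with the nine-move
repertoire (rotational, local, colocal, shake, translation, small-cluster
translation, cluster translation, pivot, double pivot) at the configured
per-attempt frequencies and records snapshots.

The simulated concentration is reported in micromolecules per
lattice-unit^3: (n_molecules / L^3) * 1e6.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _mc
from ._mc import DEFAULT_MOVE_WEIGHTS, MOVE_NAMES, NEIGHBOR_OFFSETS, PROPER_ROTATIONS
from .stickers import ALL_KINDS, R_KCAL, T_DEFAULT, EnergyMatrix, MoleculeTopology

DEFAULT_BETA = 1.0 / (R_KCAL * T_DEFAULT)


class PackingError(RuntimeError):
    """Raised when chains cannot be placed self-avoidingly; use a larger box."""


class InvariantViolation(RuntimeError):
    """A lattice-state invariant does not hold."""


def concentration_of(n_molecules: int, box_length: int) -> float:
    """Concentration in micromolecules per lattice-unit^3 (1e-6 molecules
    per site volume)."""
    if n_molecules < 1 or box_length < 1:
        raise ValueError("need n_molecules >= 1 and box_length >= 1")
    return n_molecules / float(box_length) ** 3 * 1e6


def metropolis_accept(dE: float, beta: float, u: float) -> bool:
    """Standard Metropolis criterion: accept iff u < min(1, exp(-beta dE))."""
    if dE <= 0:
        return True
    return u < math.exp(-beta * dE)


@dataclass
class SimParams:
    """Monte Carlo run parameters.

    ``move_weights`` are the per-attempt frequencies of the nine moves in
    the order of :data:`MOVE_NAMES`; the printed set sums to 1.02 and is
    renormalized to exactly 1 before use.  One "step" is one attempted
    move.  ``beta`` defaults to 1/(RT) at 310 K so sampling and energy
    parameterization share the same temperature.
    """

    n_steps: int
    seed: int = 0
    move_weights: Sequence[float] = tuple(DEFAULT_MOVE_WEIGHTS)
    record_interval: int | None = None
    beta: float = DEFAULT_BETA
    max_cluster_molecules: int = 64

    def __post_init__(self):
        w = np.asarray(self.move_weights, dtype=float)
        if w.shape != (9,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("move_weights must be 9 nonnegative weights")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.record_interval is None:
            self.record_interval = max(1, self.n_steps // 50)

    @property
    def normalized_weights(self) -> np.ndarray:
        w = np.asarray(self.move_weights, dtype=float)
        s = w.sum()
        if abs(s - 1.0) > 1e-12:
            warnings.warn(
                f"move weights sum to {s:g}; renormalizing to 1", stacklevel=2
            )
        return w / s

    @property
    def cumulative_weights(self) -> np.ndarray:
        return np.cumsum(self.normalized_weights)


@dataclass
class SystemInfo:
    """Immutable description of the simulated system (shared by state and
    snapshots): box, chain layout, sticker kinds and the energy matrix."""

    L: int
    kind: np.ndarray  # (N,) int8; sticker-kind code or -1 for spacer
    mol_of: np.ndarray  # (N,) int32
    mol_start: np.ndarray  # (M,) int32
    mol_len: np.ndarray  # (M,) int32
    kinds: tuple[str, ...]
    energy: np.ndarray  # (K, K) float64
    species_names: tuple[str, ...] = ()

    @property
    def n_beads(self) -> int:
        return int(self.kind.shape[0])

    @property
    def n_molecules(self) -> int:
        return int(self.mol_start.shape[0])

    @property
    def sticker_idx(self) -> np.ndarray:
        return np.flatnonzero(self.kind >= 0).astype(np.int32)


@dataclass
class LatticeState:
    """Bead positions plus bond pairing; mutable during a run."""

    info: SystemInfo
    pos: np.ndarray  # (N, 3) int64
    partner: np.ndarray  # (N,) int32; bead index or -1

    @property
    def L(self) -> int:
        return self.info.L

    @property
    def n_beads(self) -> int:
        return self.info.n_beads

    @property
    def n_molecules(self) -> int:
        return self.info.n_molecules

    def concentration(self) -> float:
        return concentration_of(self.n_molecules, self.L)

    def copy(self) -> "LatticeState":
        return LatticeState(self.info, self.pos.copy(), self.partner.copy())

    def occupancy_grid(self) -> np.ndarray:
        L = self.L
        grid = np.zeros(L * L * L, dtype=np.int32)
        sites = (self.pos[:, 0] * L + self.pos[:, 1]) * L + self.pos[:, 2]
        if np.unique(sites).size != sites.size:
            raise InvariantViolation("two beads occupy the same lattice site")
        grid[sites] = np.arange(1, self.n_beads + 1, dtype=np.int32)
        return grid

    def validate(self) -> None:
        """Check every state invariant; raises InvariantViolation."""
        info, L = self.info, self.L
        if self.pos.min() < 0 or self.pos.max() >= L:
            raise InvariantViolation("bead position outside the box")
        self.occupancy_grid()  # site-exclusion check
        # chain connectivity within the 26-neighborhood
        same_mol = info.mol_of[1:] == info.mol_of[:-1]
        d = np.abs(self.pos[1:] - self.pos[:-1])
        d = np.minimum(d, L - d)
        ok = (d.max(axis=1) <= 1) & (d.sum(axis=1) > 0)
        if not ok[same_mol].all():
            raise InvariantViolation("chain connectivity broken")
        # bond pairing
        p = self.partner
        bonded = np.flatnonzero(p >= 0)
        if bonded.size:
            if not (p[p[bonded]] == bonded).all():
                raise InvariantViolation("bond pairing not symmetric")
            i = bonded[p[bonded] > bonded]
            j = p[i]
            if (info.kind[i] < 0).any() or (info.kind[j] < 0).any():
                raise InvariantViolation("bond involves a spacer bead")
            d = np.abs(self.pos[i] - self.pos[j])
            d = np.minimum(d, L - d)
            if not ((d.max(axis=1) <= 1) & (d.sum(axis=1) > 0)).all():
                raise InvariantViolation("bonded stickers are not neighbors")
            if (info.energy[info.kind[i], info.kind[j]] == 0).any():
                raise InvariantViolation("bond between a zero-energy pair")


@dataclass
class Snapshot:
    """One recorded configuration: positions, bond list, running energy."""

    info: SystemInfo
    step: int
    pos: np.ndarray
    partner: np.ndarray
    energy: float

    @property
    def L(self) -> int:
        return self.info.L

    def as_state(self) -> LatticeState:
        return LatticeState(self.info, self.pos.astype(np.int64), self.partner.copy())

    def bonds(self) -> tuple[tuple[int, int], ...]:
        i = np.flatnonzero(self.partner >= 0)
        i = i[self.partner[i] > i]
        return tuple((int(a), int(b)) for a, b in zip(i, self.partner[i]))


def total_energy(state) -> float:
    """Sum of bond energies (kcal/mol); always <= 0 for an attractive
    energy matrix.  A bond between a zero-energy pair is an invariant
    violation and raises."""
    info = state.info
    p = np.asarray(state.partner)
    i = np.flatnonzero(p >= 0)
    i = i[p[i] > i]
    if i.size == 0:
        return 0.0
    e = info.energy[info.kind[i], info.kind[p[i]]]
    if (e == 0).any():
        raise InvariantViolation("bond between a zero-energy pair")
    return float(e.sum())


def init_lattice(
    topologies: Sequence[MoleculeTopology],
    counts: Sequence[int],
    L: int,
    seed: int = 0,
    energy: EnergyMatrix | None = None,
    max_retries: int = 2000,
    enforce_min_box: bool = True,
) -> LatticeState:
    """Place ``counts[s]`` copies of each topology self-avoidingly on an
    L^3 periodic lattice as random walks with no initial bonds.
    Deterministic for a given seed; raises :class:`PackingError` (with a
    suggestion to enlarge the box) when placement keeps failing.

    By default the box edge must be at least the longest chain's bead
    count; ``enforce_min_box=False`` lifts this (used to seed compact
    droplet configurations, where chains may wrap the torus)."""
    if len(topologies) != len(counts):
        raise ValueError("topologies and counts length mismatch")
    longest = max((t.n_beads for t in topologies), default=0)
    if enforce_min_box and L < max(1, longest):
        raise ValueError(
            f"box_length {L} smaller than the longest chain ({longest} beads)"
        )
    n_beads_total = sum(t.n_beads * c for t, c in zip(topologies, counts))
    if n_beads_total > L**3:
        raise PackingError(
            f"{n_beads_total} beads cannot fit in a box of {L}^3 sites; "
            "use a larger box"
        )

    kinds = ALL_KINDS
    if energy is None:
        emat = np.zeros((len(kinds), len(kinds)))
    else:
        if tuple(energy.kinds) != tuple(kinds):
            raise ValueError("energy matrix kinds must equal the global kind set")
        emat = np.asarray(energy.matrix, dtype=float)

    kind_list, mol_of, mol_start, mol_len, names = [], [], [], [], []
    b = 0
    m = 0
    for topo, count in zip(topologies, counts):
        codes = topo.kind_codes
        for _ in range(count):
            mol_start.append(b)
            mol_len.append(topo.n_beads)
            kind_list.append(codes)
            mol_of.extend([m] * topo.n_beads)
            b += topo.n_beads
            m += 1
        names.extend([topo.name] * count)

    info = SystemInfo(
        L=int(L),
        kind=np.concatenate(kind_list) if kind_list else np.zeros(0, np.int8),
        mol_of=np.asarray(mol_of, dtype=np.int32),
        mol_start=np.asarray(mol_start, dtype=np.int32),
        mol_len=np.asarray(mol_len, dtype=np.int32),
        kinds=tuple(kinds),
        energy=emat,
        species_names=tuple(names),
    )

    rng = np.random.default_rng(seed)
    grid = np.zeros(L * L * L, dtype=np.int32)
    pos = np.zeros((info.n_beads, 3), dtype=np.int64)
    offs = NEIGHBOR_OFFSETS

    def site(p):
        return (p[0] * L + p[1]) * L + p[2]

    for mi in range(info.n_molecules):
        st = int(info.mol_start[mi])
        le = int(info.mol_len[mi])
        placed = 0
        for _attempt in range(max_retries):
            # head
            head = rng.integers(0, L, size=3)
            if grid[site(head)] != 0:
                continue
            pos[st] = head
            grid[site(head)] = st + 1
            placed = 1
            ok = True
            for k in range(st + 1, st + le):
                order = rng.permutation(26)
                found = False
                for t in order:
                    cand = (pos[k - 1] + offs[t]) % L
                    if grid[site(cand)] == 0:
                        pos[k] = cand
                        grid[site(cand)] = k + 1
                        placed += 1
                        found = True
                        break
                if not found:
                    ok = False
                    break
            if ok:
                break
            for k in range(st, st + placed):  # unwind and retry
                grid[site(pos[k])] = 0
            placed = 0
        else:
            raise PackingError(
                f"could not place molecule {mi} after {max_retries} attempts; "
                f"try a larger box than L={L}"
            )

    state = LatticeState(info, pos, np.full(info.n_beads, -1, dtype=np.int32))
    return state


@dataclass
class RunResult:
    """Snapshot stream plus move statistics from one MC run."""

    snapshots: list[Snapshot]
    final_state: LatticeState
    final_energy: float
    attempts: np.ndarray
    accepts: np.ndarray
    params: SimParams

    def __iter__(self):
        return iter(self.snapshots)

    def __len__(self):
        return len(self.snapshots)

    def __getitem__(self, i):
        return self.snapshots[i]

    def acceptance_table(self):
        import pandas as pd

        with np.errstate(invalid="ignore", divide="ignore"):
            rate = self.accepts / np.maximum(self.attempts, 1)
        return pd.DataFrame(
            {"move": MOVE_NAMES, "attempts": self.attempts, "accepts": self.accepts,
             "rate": rate}
        )


def run_mc(state: LatticeState, params: SimParams) -> RunResult:
    """Advance a copy of ``state`` by ``params.n_steps`` attempted moves.

    Byte-identical output for identical (state, params): the kernel RNG is
    seeded from ``params.seed`` alone.
    """
    work = state.copy()
    info = work.info
    grid = work.occupancy_grid()
    cumw = params.cumulative_weights
    n_rec = params.n_steps // params.record_interval
    N = info.n_beads
    out_pos = np.zeros((n_rec, N, 3), dtype=np.int32)
    out_partner = np.zeros((n_rec, N), dtype=np.int32)
    out_energy = np.zeros(n_rec, dtype=np.float64)
    out_step = np.zeros(n_rec, dtype=np.int64)
    attempts = np.zeros(9, dtype=np.int64)
    accepts = np.zeros(9, dtype=np.int64)
    final_E, rec = _mc.run_kernel(
        work.pos, grid, info.kind, info.mol_of, info.mol_start, info.mol_len,
        work.partner, info.sticker_idx, info.energy, float(params.beta),
        int(info.L), int(params.n_steps), cumw, PROPER_ROTATIONS,
        NEIGHBOR_OFFSETS, int(params.seed) % (2**31), int(params.record_interval),
        out_pos, out_partner, out_energy, out_step, attempts, accepts,
        int(params.max_cluster_molecules),
    )
    snaps = [
        Snapshot(info, int(out_step[r]), out_pos[r], out_partner[r], float(out_energy[r]))
        for r in range(rec)
    ]
    return RunResult(snaps, work, float(final_E), attempts, accepts, params)


def apply_move(state: LatticeState, kind: str, seed: int = 0):
    """Apply a single attempted move of the named kind (testing hook).

    Returns ``(new_state, accepted)``; a rejected proposal returns an
    unchanged copy of the input state.
    """
    if kind not in MOVE_NAMES:
        raise ValueError(f"unknown move kind {kind!r}; one of {MOVE_NAMES}")
    k = MOVE_NAMES.index(kind)
    weights = np.zeros(9)
    weights[k] = 1.0
    params = SimParams(
        n_steps=1, seed=seed, move_weights=weights, record_interval=1,
        beta=DEFAULT_BETA,
    )
    res = run_mc(state, params)
    accepted = bool(res.accepts.sum() == 1)
    return res.final_state, accepted
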