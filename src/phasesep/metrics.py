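"""Phase diagnostics computed from snapshots.

Two scalar order parameters summarize a configuration:

* GDIP (global density inhomogeneity parameter) — the shell-volume-weighted
  mean squared deviation of the normalized radial density profile from
  uniformity, measured about the center of the densest region.  A value
  above 0.025 flags phase separation; a homogeneous box gives a value near
  zero (binomial counting noise only).
* Percolation value — the fraction of all polymers belonging to the single
  largest bond-connected cluster; 1/N with no bonds, 1 when the molecule
  graph is connected.

Radial profiles use minimum-image distances about a lattice reference
point.  Bin "volumes" are exact lattice site counts per shell, so mass
conservation (sum density * volume = bead count) holds to machine
precision, and the a-priori reference for normalization defaults to the
analytic uniform profile (a zero-energy control simulation can be passed
instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

GDIP_THRESHOLD = 0.025
DEFAULT_N_BINS = 30

_shell_cache: dict = {}


@njit(cache=True)
def _site_count_histogram(L, edges):
    nb = edges.shape[0] - 1
    counts = np.zeros(nb, dtype=np.int64)
    half = L / 2.0
    for x in range(L):
        mx = x if x <= L - x else L - x
        for y in range(L):
            my = y if y <= L - y else L - y
            for z in range(L):
                mz = z if z <= L - z else L - z
                r = np.sqrt(mx * mx + my * my + mz * mz)
                b = np.searchsorted(edges, r, side="right") - 1
                if b == nb:
                    b = nb - 1
                if 0 <= b < nb:
                    counts[b] += 1
    return counts


def radial_bin_edges(L: int, n_bins: int) -> np.ndarray:
    rmax = np.sqrt(3.0) * L / 2.0 * (1 + 1e-9)
    return np.linspace(0.0, rmax, n_bins + 1)


def shell_site_counts(L: int, n_bins: int) -> np.ndarray:
    """Exact number of lattice sites per radial bin (minimum-image distance
    from a lattice point); cached per (L, n_bins)."""
    key = (int(L), int(n_bins))
    if key not in _shell_cache:
        edges = radial_bin_edges(L, n_bins)
        _shell_cache[key] = _site_count_histogram(int(L), edges)
    return _shell_cache[key]


@dataclass
class RadialDensity:
    """Radial bead density about a reference point, in beads per
    lattice-unit^3 (bin volume = lattice sites per shell)."""

    edges: np.ndarray
    counts: np.ndarray
    volumes: np.ndarray
    reference_point: tuple[int, int, int]
    n_total: int

    @property
    def density(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.volumes > 0, self.counts / self.volumes, 0.0)

    def mass(self) -> float:
        return float((self.density * self.volumes).sum())


@dataclass
class NormalizedRadialDensity:
    """Bin-wise ratio of an observed to a reference radial density."""

    edges: np.ndarray
    ratio: np.ndarray
    valid: np.ndarray  # bins with nonzero reference density
    volumes: np.ndarray


@dataclass
class GDIPResult:
    value: float
    threshold: float = GDIP_THRESHOLD

    @property
    def phase_separated(self) -> bool:
        return self.value > self.threshold


@dataclass
class PercolationResult:
    value: float
    largest_cluster: int
    n_molecules: int


def _molecule_clusters(snapshot) -> np.ndarray:
    """Union-find labels of the molecule-level bond graph."""
    info = snapshot.info
    M = info.n_molecules
    parent = np.arange(M)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    p = np.asarray(snapshot.partner)
    i = np.flatnonzero(p >= 0)
    i = i[p[i] > i]
    for a, b in zip(info.mol_of[i], info.mol_of[p[i]]):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    return np.array([find(a) for a in range(M)])


def _circular_com(points: np.ndarray, L: int) -> np.ndarray:
    """Center of mass on the torus (circular mean per axis)."""
    theta = points * (2 * np.pi / L)
    c = np.cos(theta).mean(axis=0)
    s = np.sin(theta).mean(axis=0)
    ang = np.mod(np.arctan2(s, c), 2 * np.pi)
    return ang * L / (2 * np.pi)


def _densest_bead(pos: np.ndarray, L: int, max_candidates: int = 512) -> np.ndarray:
    """Bead with the most neighbors within L/6 (minimum-image), ties to the
    lowest index.  Exactly equivariant under global translation, unlike a
    box-anchored voxel grid."""
    n = pos.shape[0]
    stride = max(1, n // max_candidates)
    cand = pos[::stride]
    r2 = max(2.0, L / 6.0) ** 2
    best_count, best_idx = -1, 0
    # chunk candidates to bound the (candidates x beads) distance matrix
    for start in range(0, cand.shape[0], 64):
        c = cand[start : start + 64]
        d = np.abs(c[:, None, :] - pos[None, :, :])
        d = np.minimum(d, L - d).astype(float)
        counts = ((d**2).sum(axis=2) <= r2).sum(axis=1)
        i = int(np.argmax(counts))
        if counts[i] > best_count:
            best_count, best_idx = int(counts[i]), start + i
    return cand[best_idx].astype(float)


def reference_point_of(snapshot) -> tuple[int, int, int]:
    """Center of the densest region: minimum-image center of mass of the
    largest bonded cluster, or the locally densest bead when no bonds
    exist; snapped to the nearest lattice site."""
    info = snapshot.info
    pos = np.asarray(snapshot.pos)
    if (np.asarray(snapshot.partner) >= 0).any():
        labels = _molecule_clusters(snapshot)
        _, counts = np.unique(labels, return_counts=True)
        best = np.unique(labels)[np.argmax(counts)]
        sel = np.isin(info.mol_of, np.flatnonzero(labels == best))
        com = _circular_com(pos[sel], info.L)
    else:
        com = _densest_bead(pos, info.L)
    ref = np.round(com).astype(int) % info.L
    return (int(ref[0]), int(ref[1]), int(ref[2]))


def radial_density(
    snapshot, n_bins: int = DEFAULT_N_BINS, reference_point=None
) -> RadialDensity:
    """Bead density per radial shell about the reference point, with
    periodic minimum-image distances."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    info = snapshot.info
    L = info.L
    pos = np.asarray(snapshot.pos)
    if reference_point is None:
        reference_point = reference_point_of(snapshot)
    ref = np.asarray(reference_point, dtype=np.int64) % L
    d = np.abs(pos - ref)
    d = np.minimum(d, L - d)
    r = np.sqrt((d.astype(float) ** 2).sum(axis=1))
    edges = radial_bin_edges(L, n_bins)
    counts, _ = np.histogram(r, bins=edges)
    volumes = shell_site_counts(L, n_bins).astype(float)
    return RadialDensity(
        edges=edges,
        counts=counts.astype(np.int64),
        volumes=volumes,
        reference_point=(int(ref[0]), int(ref[1]), int(ref[2])),
        n_total=pos.shape[0],
    )


def uniform_reference(observed: RadialDensity, L: int) -> RadialDensity:
    """Analytic a-priori profile: the same binning filled at the bulk
    density n_total / L^3 (what a zero-energy control converges to)."""
    rho = observed.n_total / float(L) ** 3
    counts = observed.volumes * rho
    return RadialDensity(
        edges=observed.edges,
        counts=counts,
        volumes=observed.volumes,
        reference_point=observed.reference_point,
        n_total=observed.n_total,
    )


def normalize_density(
    observed: RadialDensity, reference: RadialDensity
) -> NormalizedRadialDensity:
    """Bin-wise observed/reference density ratio; zero-reference bins are
    flagged invalid and excluded downstream."""
    if observed.edges.shape != reference.edges.shape or not np.allclose(
        observed.edges, reference.edges
    ):
        raise ValueError("observed and reference binning differ")
    obs = observed.density
    ref = reference.density
    valid = ref > 0
    if (~valid & (observed.counts > 0)).any():
        warnings.warn("bins with zero reference density excluded from profile")
    ratio = np.zeros_like(obs)
    ratio[valid] = obs[valid] / ref[valid]
    return NormalizedRadialDensity(
        edges=observed.edges, ratio=ratio, valid=valid, volumes=observed.volumes
    )


def gdip(profile: NormalizedRadialDensity) -> GDIPResult:
    """Squared deviation of the radial mass distribution from uniformity.

    With q_b the reference (volume) fraction of each shell and
    rho_hat_b the normalized density, the observed bead fraction is
    p_b = q_b rho_hat_b and

        GDIP = sum_b (p_b - q_b)^2 = sum_b q_b^2 (rho_hat_b - 1)^2,

    i.e. the L2 divergence between the observed and a-priori radial mass
    profiles.  It is exactly 0 for a uniform profile, rises through the
    phase transition as the largest cluster gathers an increasing fraction
    of all beads (above ~0.025 once roughly a sixth of the material is
    co-located), approaches (1 - q_inner)^2 ~ 1 for a compact condensate,
    and decays again at very high concentration where the whole box turns
    dense — which is why percolation takes over as the order parameter
    there."""
    v = profile.valid & (profile.volumes > 0)
    if v.sum() < 2:
        raise ValueError("need at least 2 valid bins")
    q = profile.volumes[v] / profile.volumes[v].sum()
    dev = q * (profile.ratio[v] - 1.0)
    return GDIPResult(value=float((dev**2).sum()))


def gdip_of_snapshot(
    snapshot, n_bins: int = DEFAULT_N_BINS, reference: RadialDensity | None = None
) -> GDIPResult:
    """Radial profile -> normalization -> GDIP in one call."""
    obs = radial_density(snapshot, n_bins=n_bins)
    ref = uniform_reference(obs, snapshot.info.L) if reference is None else reference
    return gdip(normalize_density(obs, ref))


def percolation_value(snapshot) -> PercolationResult:
    """Fraction of polymers in the single largest bond-connected cluster."""
    labels = _molecule_clusters(snapshot)
    M = labels.shape[0]
    _, counts = np.unique(labels, return_counts=True)
    largest = int(counts.max())
    return PercolationResult(value=largest / M, largest_cluster=largest, n_molecules=M)
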