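"""Generators for every input the pipeline consumes, plus an exact
enumeration oracle for tiny lattice systems.

Everything here is synthetic and fully reproducible from (parameters,
seed): a packaged K_D fixture for the SLP65 x CIN85 sticker pairs, settled
-droplet fluorescence images whose dispersion index rises sigmoidally in
concentration around a known ground-truth saturation concentration,
noisy logistic series for fit-recovery experiments, and a brute-force
partition-function enumeration used to validate the Monte Carlo sampler.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from ._mc import NEIGHBOR_OFFSETS
from .imaging import ImageRecord
from .saturation import PHI_OFFSET, logistic
from .stickers import (
    EnergyMatrix,
    KdTable,
    MoleculeTopology,
    load_kd_table,
)

try:
    from importlib.resources import files as _pkg_files
except ImportError:  # pragma: no cover
    from importlib_resources import files as _pkg_files


def make_kd_fixture() -> KdTable:
    """The packaged 21-pair K_D table (18 SLP65 x CIN85 pairs + 3 pairs of
    CIN85's own PRM1*).

    Pairs whose values are not individually published are ranking-
    consistent placeholders flagged ``approx=True``; the anchors (the 6 uM
    SH3B-PRM4 interaction, the ~4 mM weakest PRM2 interaction, and the
    PRM1* triplet 720/1140/210 uM) are exact.
    """
    return load_kd_table(str(_pkg_files("phasesep") / "data" / "kd_slp65_cin85.csv"))


# ---------------------------------------------------------------------------
# droplet images


@dataclass
class DropletFieldParams:
    """Settled-droplet image generator.

    The expected droplet count follows a logistic in concentration whose
    rise is placed so that the ONSET (the second-derivative maximum of the
    resulting DI curve) sits at ``phi_true``:  x0 = phi_true + ln(2+sqrt3)/k.
    Below phi_true droplets are exponentially rare and the image is a
    Poisson-noise background (DI ~ 1); far above, bright blurred discs
    dominate the variance (DI >> 1).
    """

    phi_true: float = 6.7  # uM
    k: float = 0.6  # transition steepness, 1/uM
    n_droplets_max: float = 16.0
    droplet_intensity: float = 3000.0  # counts added inside a droplet
    background: float = 600.0  # mean background counts
    radius_median: float = 2.0  # px, log-normal droplet radii
    radius_sigma: float = 0.3
    psf_sigma: float = 1.0  # px, Gaussian optical blur
    read_noise_sd: float = 0.0  # optional Gaussian read noise, counts
    shape: tuple[int, int] = (128, 128)

    @property
    def x0(self) -> float:
        return self.phi_true + PHI_OFFSET / self.k

    def expected_droplets(self, conc: float) -> float:
        return float(self.n_droplets_max / (1.0 + math.exp(-self.k * (conc - self.x0))))


def generate_droplet_image(
    conc: float,
    params: DropletFieldParams | None = None,
    seed=None,
    z_um: float = 0.0,
    replicate: int = 0,
) -> ImageRecord:
    """One synthetic 16-bit fluorescence image at total concentration
    ``conc`` (uM); deterministic for a given seed."""
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    p = params or DropletFieldParams()
    rng = np.random.default_rng(seed)
    h, w = p.shape
    scene = np.full((h, w), p.background, dtype=float)
    n = rng.poisson(p.expected_droplets(conc))
    # defocused planes: droplets dimmer and wider away from the surface
    defocus = 1.0 + 1.5 * abs(z_um)
    for _ in range(n):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.lognormal(math.log(p.radius_median), p.radius_sigma) * defocus
        yy, xx = np.ogrid[:h, :w]
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        scene[mask] += p.droplet_intensity / defocus**2
    scene = ndimage.gaussian_filter(scene, sigma=p.psf_sigma * defocus)
    img = rng.poisson(scene).astype(float)
    if p.read_noise_sd > 0:
        img += rng.normal(0.0, p.read_noise_sd, size=img.shape)
    img = np.rint(img)
    if (img > 65535).any():
        warnings.warn("intensity overflow clipped at 65535")
    img = np.clip(img, 0, 65535).astype(np.uint16)
    return ImageRecord(
        pixels=img, concentration_uM=float(conc), z_um=float(z_um),
        replicate=int(replicate),
    )


DEFAULT_CONCENTRATIONS_UM = (0.5, 1.0, 2.0, 4.0, 7.0, 12.0, 20.0, 40.0)


def generate_di_dataset(
    phi_true: float = 6.7,
    concentrations=DEFAULT_CONCENTRATIONS_UM,
    n_per_point: int = 15,
    params: DropletFieldParams | None = None,
    seed: int = 0,
    outdir=None,
    n_z: int = 1,
):
    """A full synthetic imaging dataset: ``n_per_point`` surface images per
    concentration (plus ``n_z - 1`` defocused planes per stack, which the
    analysis must discard).  Returns (records, manifest DataFrame); when
    ``outdir`` is given, TIFFs and a manifest.csv are also written."""
    p = replace(params or DropletFieldParams(), phi_true=float(phi_true))
    records: list[ImageRecord] = []
    rows = []
    for ci, conc in enumerate(concentrations):
        for rep in range(n_per_point):
            child = np.random.SeedSequence(entropy=seed, spawn_key=(ci, rep))
            zseeds = child.generate_state(n_z)
            for zi in range(n_z):
                rec = generate_droplet_image(
                    conc, p, seed=int(zseeds[zi] % 2**31), z_um=float(zi),
                    replicate=rep,
                )
                records.append(rec)
                rows.append(
                    {"path": f"img_c{ci:02d}_r{rep:02d}_z{zi}.tif",
                     "concentration_uM": conc, "z_um": float(zi), "replicate": rep}
                )
    manifest = pd.DataFrame(rows)
    if outdir is not None:
        import tifffile

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for rec, row in zip(records, manifest.itertuples()):
            tifffile.imwrite(outdir / row.path, rec.pixels)
            rec.path = str(outdir / row.path)
        manifest.to_csv(outdir / "manifest.csv", index=False)
    return records, manifest


# ---------------------------------------------------------------------------
# logistic fit-recovery fixtures


def generate_logistic_samples(
    H: float, C: float, k: float, x0: float, noise_sd: float,
    x_grid, n_per_point: int = 15, seed: int = 0,
) -> pd.DataFrame:
    """Noisy samples of the logistic H/(1+exp(-k(x-x0)))+C on a grid:
    columns (concentration, replicate, value)."""
    if k <= 0:
        raise ValueError("k must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for x in x_grid:
        mu = float(logistic(np.array([x]), H, C, k, x0)[0])
        for rep in range(n_per_point):
            y = mu + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"concentration": float(x), "replicate": rep, "value": y})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle


@dataclass
class TinySystemSpec:
    """A lattice system small enough to enumerate exactly: at most two
    chains of at most two beads each."""

    topologies: list[MoleculeTopology]
    L: int
    energy: EnergyMatrix
    beta: float
    max_configs: int = 10_000_000


@dataclass
class TinyEnumeration:
    """Exact Boltzmann statistics over placements x bond pairings."""

    n_placements: int
    partition_function: float
    p_bonded: float
    mean_energy: float
    bond_class_probs: dict[tuple, float]
    n_pairs: int


def _chain_placements(n_beads: int, L: int) -> np.ndarray:
    """All distinct self-avoiding placements of a 1- or 2-bead chain as
    site-index rows."""
    n_sites = L**3
    sites = np.arange(n_sites, dtype=np.int64)
    if n_beads == 1:
        return sites[:, None]
    if n_beads != 2:
        raise ValueError("oracle supports chains of at most 2 beads")
    x, y, z = sites // (L * L), (sites // L) % L, sites % L
    placements = set()
    for dx, dy, dz in NEIGHBOR_OFFSETS:
        s2 = ((x + dx) % L) * L * L + ((y + dy) % L) * L + ((z + dz) % L)
        for a, b in zip(sites, s2):
            if a != b:
                placements.add((int(a), int(b)))
    return np.array(sorted(placements), dtype=np.int64)


def _site_adjacency(L: int) -> np.ndarray:
    n = L**3
    s = np.arange(n)
    x, y, z = s // (L * L), (s // L) % L, s % L

    def mind(d):
        d = np.abs(d)
        return np.minimum(d, L - d)

    dx = mind(x[:, None] - x[None, :])
    dy = mind(y[:, None] - y[None, :])
    dz = mind(z[:, None] - z[None, :])
    cheb = np.maximum(np.maximum(dx, dy), dz)
    return (cheb == 1) | ((cheb == 0) & (dx + dy + dz > 0))


def _matchings(pairs: list[tuple[int, int]]):
    """All partial matchings (bond sets with no shared sticker) over the
    eligible-pair list, as (pair-index-mask, pair indices) tuples."""
    out = []

    def rec(i, used, mask, chosen):
        if i == len(pairs):
            out.append((mask, tuple(chosen)))
            return
        rec(i + 1, used, mask, chosen)
        a, b = pairs[i]
        if a not in used and b not in used:
            rec(i + 1, used | {a, b}, mask | (1 << i), chosen + [i])

    rec(0, frozenset(), 0, [])
    return out


def enumerate_tiny_system(spec: TinySystemSpec) -> TinyEnumeration:
    """Exact enumeration of all placements and bond pairings of a tiny
    system, with Boltzmann weights exp(-beta E).

    Placements carry no energy (isotropic terms are zero), so the joint
    distribution factorizes per bond-eligibility pattern; the oracle
    histograms eligibility bitmasks over all non-overlapping placements
    and sums matchings analytically.  Returns the partition function, the
    probability that at least one bond exists, the mean energy, and the
    exact probability of every bond set (keyed by global-bead-index
    pairs, matching the engine's bead numbering).
    """
    topos = spec.topologies
    if not 1 <= len(topos) <= 2 or any(t.n_beads > 2 for t in topos):
        raise ValueError("oracle bounds: at most 2 chains of at most 2 beads")
    L = spec.L
    E = np.asarray(spec.energy.matrix)
    kind_codes = [t.kind_codes for t in topos]
    offsets = [0]
    for t in topos[:-1]:
        offsets.append(offsets[-1] + t.n_beads)

    placements = [_chain_placements(t.n_beads, L) for t in topos]
    n_joint = int(np.prod([p.shape[0] for p in placements]))
    if n_joint > spec.max_configs:
        raise ValueError(f"state space too large to enumerate ({n_joint:g} placements)")
    adj = _site_adjacency(L)

    # candidate sticker pairs with nonzero energy (global bead indices)
    pairs: list[tuple[int, int]] = []
    pair_energy: list[float] = []
    beads = [
        (ci, bi, kind_codes[ci][bi])
        for ci in range(len(topos))
        for bi in range(topos[ci].n_beads)
        if kind_codes[ci][bi] >= 0
    ]
    for ii in range(len(beads)):
        for jj in range(ii + 1, len(beads)):
            ci, bi, ki = beads[ii]
            cj, bj, kj = beads[jj]
            e = E[ki, kj]
            if e != 0.0:
                pairs.append((offsets[ci] + bi, offsets[cj] + bj))
                pair_energy.append(float(e))
    P = len(pairs)
    if P > 16:
        raise ValueError("too many candidate bond pairs to enumerate")

    # eligibility bitmask per joint placement
    if len(topos) == 1:
        A = placements[0]
        overlap = np.zeros(A.shape[0], dtype=bool)
        mask = np.zeros(A.shape[0], dtype=np.int64)
        site_of = {0: A}
        for pi, (ga, gb) in enumerate(pairs):
            el = adj[A[:, ga], A[:, gb]]
            mask |= el.astype(np.int64) << pi
        valid = ~overlap
        masks = mask[valid]
    else:
        A, B = placements
        na, nb = topos[0].n_beads, topos[1].n_beads
        overlap = np.zeros((A.shape[0], B.shape[0]), dtype=bool)
        for i in range(na):
            for j in range(nb):
                overlap |= A[:, i][:, None] == B[:, j][None, :]
        mask = np.zeros((A.shape[0], B.shape[0]), dtype=np.int64)
        for pi, (ga, gb) in enumerate(pairs):
            if ga < offsets[1] and gb < offsets[1]:  # intra chain A
                el = adj[A[:, ga], A[:, gb]][:, None] & np.ones(B.shape[0], bool)[None, :]
            elif ga >= offsets[1] and gb >= offsets[1]:  # intra chain B
                el = adj[B[:, ga - offsets[1]], B[:, gb - offsets[1]]][None, :] & np.ones(
                    A.shape[0], bool
                )[:, None]
            else:
                el = adj[A[:, ga][:, None], B[:, gb - offsets[1]][None, :]]
            mask |= el.astype(np.int64) << pi
        valid = ~overlap
        masks = mask[valid]

    n_placed = int(masks.size)
    hist = np.bincount(masks, minlength=2**P).astype(float)
    all_masks = np.arange(2**P)

    Z = 0.0
    Esum = 0.0
    class_probs: dict[tuple, float] = {}
    empty_weight = 0.0
    for pm, chosen in _matchings(pairs):
        count = hist[(all_masks & pm) == pm].sum()
        if count == 0:
            continue
        e = sum(pair_energy[i] for i in chosen)
        w = count * math.exp(-spec.beta * e)
        Z += w
        Esum += w * e
        key = tuple(sorted(pairs[i] for i in chosen))
        class_probs[key] = class_probs.get(key, 0.0) + w
        if not chosen:
            empty_weight += w
    for key in class_probs:
        class_probs[key] /= Z
    return TinyEnumeration(
        n_placements=n_placed,
        partition_function=Z,
        p_bonded=1.0 - empty_weight / Z,
        mean_energy=Esum / Z,
        bond_class_probs=class_probs,
        n_pairs=P,
    )
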