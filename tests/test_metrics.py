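"""Phase diagnostics: radial densities, GDIP, percolation."""

import numpy as np
import pytest

from phasesep.lattice import LatticeState, SystemInfo, init_lattice
from phasesep.metrics import (
    GDIP_THRESHOLD,
    NormalizedRadialDensity,
    RadialDensity,
    gdip,
    gdip_of_snapshot,
    normalize_density,
    percolation_value,
    radial_bin_edges,
    radial_density,
    shell_site_counts,
    uniform_reference,
)

from conftest import single_sticker


def _point_system(positions, L, n_per_mol=1, partners=None):
    """Snapshot-like state of single-bead molecules at given positions."""
    pos = np.asarray(positions, dtype=np.int64)
    n = pos.shape[0]
    assert n % n_per_mol == 0
    m = n // n_per_mol
    info = SystemInfo(
        L=L,
        kind=np.zeros(n, np.int8),  # all SH3A stickers
        mol_of=np.repeat(np.arange(m, dtype=np.int32), n_per_mol),
        mol_start=(np.arange(m, dtype=np.int32) * n_per_mol),
        mol_len=np.full(m, n_per_mol, np.int32),
        kinds=("SH3A", "PRM1"),
        energy=np.array([[0.0, -1.0], [-1.0, 0.0]]),
    )
    p = np.full(n, -1, np.int32) if partners is None else np.asarray(partners, np.int32)
    state = LatticeState(info, pos, p)

    class Snap:
        pass

    s = Snap()
    s.info = info
    s.pos = pos
    s.partner = p
    s.L = L
    return s


class TestRadialDensity:
    def test_all_mass_at_reference_lands_in_first_bin(self):
        snap = _point_system([(5, 5, 5)] * 1, L=16)
        rd = radial_density(snap, n_bins=8, reference_point=(5, 5, 5))
        assert rd.counts[0] == 1
        assert rd.counts[1:].sum() == 0

    def test_mass_conservation_exact(self, construct_library):
        state = init_lattice([construct_library["CIN85-ABC"]], [25], 60, seed=2)
        rd = radial_density(state, n_bins=20, reference_point=(0, 0, 0))
        assert rd.mass() == pytest.approx(state.n_beads, abs=1e-9)
        # shell site counts partition the box exactly
        assert shell_site_counts(60, 20).sum() == 60**3

    def test_uniform_configuration_close_to_bulk_density(self):
        rng = np.random.default_rng(0)
        L, n = 24, 4000
        sites = rng.choice(L**3, size=n, replace=False)
        pos = np.stack([sites // (L * L), (sites // L) % L, sites % L], axis=1)
        snap = _point_system(pos, L=L)
        rd = radial_density(snap, n_bins=6, reference_point=(3, 17, 9))
        rho = n / L**3
        for c, v in zip(rd.counts, rd.volumes):
            se = np.sqrt(n * (v / L**3) * (1 - v / L**3))
            assert abs(c - rho * v) <= 4 * se + 1

    def test_too_few_bins_rejected(self):
        snap = _point_system([(0, 0, 0)], L=8)
        with pytest.raises(ValueError):
            radial_density(snap, n_bins=1)


class TestNormalize:
    def _rd(self, counts, volumes, L=10):
        edges = radial_bin_edges(L, len(counts))
        return RadialDensity(
            edges=edges, counts=np.asarray(counts, float),
            volumes=np.asarray(volumes, float), reference_point=(0, 0, 0),
            n_total=int(np.sum(counts)),
        )

    def test_observed_equals_reference_gives_ones(self):
        obs = self._rd([4, 4, 4], [2, 2, 2])
        out = normalize_density(obs, obs)
        assert np.allclose(out.ratio[out.valid], 1.0)

    def test_three_bin_worked_case(self):
        obs = self._rd([2, 1, 1], [1, 1, 1])
        ref = self._rd([1, 1, 1], [1, 1, 1])
        out = normalize_density(obs, ref)
        assert np.allclose(out.ratio, [2.0, 1.0, 1.0])

    def test_zero_reference_bin_excluded_with_warning(self):
        obs = self._rd([2, 1, 1], [1, 1, 1])
        ref = self._rd([1, 0, 1], [1, 1, 1])
        with pytest.warns(UserWarning, match="zero reference"):
            out = normalize_density(obs, ref)
        assert not out.valid[1]
        assert out.valid[[0, 2]].all()

    def test_binning_mismatch_rejected(self):
        obs = self._rd([2, 1, 1], [1, 1, 1], L=10)
        ref = self._rd([2, 1], [1, 1], L=10)
        with pytest.raises(ValueError, match="binning"):
            normalize_density(obs, ref)


class TestGDIP:
    def test_uniform_profile_gives_zero(self):
        prof = NormalizedRadialDensity(
            edges=np.arange(5.0), ratio=np.ones(4), valid=np.ones(4, bool),
            volumes=np.array([1.0, 7.0, 19.0, 37.0]),
        )
        assert gdip(prof).value == 0.0

    def test_four_bin_hand_case(self):
        # ratios (2, 1.5, 0.5, 0.2) on shells of 10/40/90/160 sites:
        # q = (1/30, 2/15, 3/10, 8/15); GDIP = sum (q*(r-1))^2
        prof = NormalizedRadialDensity(
            edges=np.arange(5.0),
            ratio=np.array([2.0, 1.5, 0.5, 0.2]),
            valid=np.ones(4, bool),
            volumes=np.array([10.0, 40.0, 90.0, 160.0]),
        )
        hand = (
            (10 / 300 * 1.0) ** 2
            + (40 / 300 * 0.5) ** 2
            + (90 / 300 * -0.5) ** 2
            + (160 / 300 * -0.8) ** 2
        )
        assert gdip(prof).value == pytest.approx(hand, rel=1e-12)

    def test_condensed_fixture_exceeds_threshold(self):
        # all molecules inside a small central ball of an otherwise empty box
        L = 40
        rng = np.random.default_rng(1)
        center = np.array([20, 20, 20])
        offs = rng.integers(-4, 5, size=(600, 3))
        pos = np.unique(center + offs, axis=0)
        snap = _point_system(pos, L=L)
        res = gdip_of_snapshot(snap, n_bins=12)
        assert res.value > GDIP_THRESHOLD
        assert res.phase_separated

    def test_invariant_under_global_translation(self):
        L = 32
        rng = np.random.default_rng(2)
        ball = np.unique(rng.integers(-3, 4, size=(300, 3)), axis=0)
        v1 = gdip_of_snapshot(_point_system((ball + 8) % L, L=L), n_bins=10).value
        v2 = gdip_of_snapshot(_point_system((ball + 25) % L, L=L), n_bins=10).value
        assert v1 == pytest.approx(v2, rel=1e-9)


class TestPercolation:
    def test_no_bonds_gives_one_over_n(self):
        snap = _point_system([(i, 0, 0) for i in range(0, 10, 2)], L=12)
        res = percolation_value(snap)
        assert res.value == pytest.approx(1 / 5)

    def test_fully_connected_gives_one(self):
        # three 2-bead molecules daisy-chained by inter-molecular bonds
        pos = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0), (2, 2, 0), (3, 2, 0)]
        partners = [-1, 2, 1, 4, 3, -1]
        snap = _point_system(pos, L=12, n_per_mol=2, partners=partners)
        assert percolation_value(snap).value == 1.0

    def test_cluster_sizes_3_2_1(self):
        # six 1-bead molecules; bonds 0-1, 1? invalid: each bead one bond.
        # molecules of 2 beads: m0-m1, m1-m2 (cluster of 3); m3-m4 (2); m5 (1)
        pos = [(i, j, 0) for i in range(6) for j in range(2)]
        partners = np.full(12, -1)
        partners[[1, 2]] = [2, 1]   # m0 bead1 - m1 bead0
        partners[[3, 4]] = [4, 3]   # m1 bead1 - m2 bead0
        partners[[7, 8]] = [8, 7]   # m3 bead1 - m4 bead0
        snap = _point_system(pos, L=12, n_per_mol=2, partners=partners)
        res = percolation_value(snap)
        assert res.value == pytest.approx(0.5)
        assert res.largest_cluster == 3
        assert res.n_molecules == 6

    def test_invariant_under_bond_relabeling(self):
        pos = [(i, j, 0) for i in range(4) for j in range(2)]
        partners = np.full(8, -1)
        partners[[1, 2]] = [2, 1]
        snap1 = _point_system(pos, L=12, n_per_mol=2, partners=partners)
        partners2 = np.full(8, -1)
        partners2[[3, 4]] = [4, 3]  # different beads, same molecule pair
        snap2 = _point_system(pos, L=12, n_per_mol=2, partners=partners2)
        assert percolation_value(snap1).value == percolation_value(snap2).value
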