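"""Generators and the exhaustive enumeration oracle."""

import numpy as np
import pytest

from phasesep.imaging import dispersion_index
from phasesep.saturation import fit_phi
from phasesep.stickers import KdRecord, KdTable, build_energy_matrix, load_kd_table
from phasesep.synthetic import (
    DropletFieldParams,
    TinySystemSpec,
    enumerate_tiny_system,
    generate_di_dataset,
    generate_droplet_image,
    generate_logistic_samples,
    make_kd_fixture,
)

from conftest import single_sticker


class TestKdFixture:
    def test_printed_anchor_values(self, kd_table):
        assert len(kd_table) == 21
        assert kd_table.get("SH3C", "PRM1star").kd == pytest.approx(210e-6)
        assert kd_table.get("SH3A", "PRM1star").kd == pytest.approx(720e-6)
        assert kd_table.get("SH3B", "PRM1star").kd == pytest.approx(1140e-6)
        assert kd_table.get("SH3B", "PRM4").kd == pytest.approx(6e-6)

    def test_range_and_prm4_ranking(self, kd_table):
        kds = np.array([r.kd for r in kd_table])
        assert kds.min() == pytest.approx(6e-6)
        assert (kds >= 6e-6).all() and (kds <= 4e-3).all()
        for sh3 in ("SH3A", "SH3B", "SH3C"):
            col = {r.prm: r.kd for r in kd_table if r.sh3 == sh3 and r.prm != "PRM1star"}
            assert min(col, key=col.get) == "PRM4"

    def test_roundtrip_through_csv(self, tmp_path, kd_table):
        p = tmp_path / "kd.csv"
        kd_table.write_csv(p)
        back = load_kd_table(p)
        assert [(r.sh3, r.prm, r.kd) for r in back] == [
            (r.sh3, r.prm, r.kd) for r in kd_table
        ]


class TestDropletImages:
    def test_seed_determinism(self):
        p = DropletFieldParams(shape=(64, 64))
        a = generate_droplet_image(10.0, p, seed=4)
        b = generate_droplet_image(10.0, p, seed=4)
        assert np.array_equal(a.pixels, b.pixels)
        c = generate_droplet_image(10.0, p, seed=5)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_subsaturated_image_is_poisson_like(self):
        p = DropletFieldParams(shape=(128, 128))
        rec = generate_droplet_image(0.1 * p.phi_true, p, seed=0)
        di = dispersion_index(rec).di
        assert 0.8 <= di <= 1.3

    def test_supersaturated_image_dominated_by_droplets(self):
        p = DropletFieldParams(shape=(128, 128))
        lo = dispersion_index(generate_droplet_image(0.1 * p.phi_true, p, seed=1)).di
        hi = dispersion_index(generate_droplet_image(3 * p.phi_true, p, seed=1)).di
        assert hi > 10 * lo

    def test_di_monotone_in_droplet_intensity(self):
        base = DropletFieldParams(shape=(96, 96))
        vals = []
        for inten in (500.0, 1500.0, 4000.0):
            p = DropletFieldParams(shape=(96, 96), droplet_intensity=inten)
            vals.append(dispersion_index(generate_droplet_image(20.0, p, seed=7)).di)
        assert vals[0] < vals[1] < vals[2]

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            generate_droplet_image(-1.0, DropletFieldParams(), seed=0)


class TestDiDataset:
    def test_default_is_15_images_per_point(self):
        recs, manifest = generate_di_dataset(
            phi_true=6.7, concentrations=(1.0, 4.0, 10.0, 20.0),
            params=DropletFieldParams(shape=(32, 32)), seed=0,
        )
        assert len(recs) == 4 * 15
        assert (manifest.groupby("concentration_uM").size() == 15).all()

    def test_phi_true_above_range_yields_downstream_fit_failure(self):
        recs, _ = generate_di_dataset(
            phi_true=100.0, concentrations=(0.5, 1, 2, 4, 7, 12), n_per_point=8,
            params=DropletFieldParams(shape=(48, 48)), seed=2,
        )
        from phasesep.imaging import build_di_series, estimate_phi_exp

        series = build_di_series(recs, n_expected=8)
        res = estimate_phi_exp(series, B=0)
        assert not res.success


class TestLogisticSamples:
    def test_zero_noise_samples_lie_on_the_curve(self):
        df = generate_logistic_samples(2.0, 1.0, 0.5, 8.0, 0.0, [4, 8, 12], 2, seed=0)
        from phasesep.saturation import logistic

        expected = logistic(df["concentration"].to_numpy(), 2.0, 1.0, 0.5, 8.0)
        assert np.allclose(df["value"], expected)

    def test_seeded_reproducibility(self):
        a = generate_logistic_samples(1, 0, 1, 10, 0.1, [5, 10, 15], 5, seed=9)
        b = generate_logistic_samples(1, 0, 1, 10, 0.1, [5, 10, 15], 5, seed=9)
        assert np.array_equal(a["value"], b["value"])

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            generate_logistic_samples(1, 0, 0.0, 10, 0.1, [1, 2], 2)


class TestEnumerationOracle:
    def test_single_bead_in_L2_box_has_8_placements(self):
        t = single_sticker("m", "SH3A")
        energy = build_energy_matrix(KdTable([]))
        res = enumerate_tiny_system(TinySystemSpec([t], L=2, energy=energy, beta=1.0))
        assert res.n_placements == 8
        assert res.p_bonded == 0.0
        assert res.mean_energy == 0.0

    def test_near_zero_energy_bond_probability_is_combinatorial(self):
        """With a vanishing bond energy every (placement, bond-state) is
        equally weighted, so P(bonded) reduces to counting adjacent
        placements, which we recount here independently."""
        a, b = single_sticker("a", "SH3B"), single_sticker("b", "PRM4")
        energy = build_energy_matrix(KdTable([KdRecord("SH3B", "PRM4", 1.0 - 1e-12)]))
        assert abs(energy.energy("SH3B", "PRM4")) < 1e-9
        L = 3
        res = enumerate_tiny_system(TinySystemSpec([a, b], L=L, energy=energy, beta=1.0))
        # independent count of adjacent placements on the 3^3 torus:
        # every pair of distinct sites within Chebyshev distance 1
        sites = np.array([(x, y, z) for x in range(L) for y in range(L) for z in range(L)])
        d = np.abs(sites[:, None, :] - sites[None, :, :])
        d = np.minimum(d, L - d)
        adj = (d.max(axis=2) == 1)
        n_pairs_total = L**3 * (L**3 - 1)
        n_adjacent = int(adj.sum())
        expected = n_adjacent / (n_pairs_total + n_adjacent)
        assert res.p_bonded == pytest.approx(expected, rel=1e-12)

    def test_infinitely_strong_bond_is_always_formed(self):
        a, b = single_sticker("a", "SH3B"), single_sticker("b", "PRM4")
        energy = build_energy_matrix(KdTable([KdRecord("SH3B", "PRM4", 1e-13)]))
        res = enumerate_tiny_system(TinySystemSpec([a, b], L=3, energy=energy, beta=2.0))
        assert res.p_bonded == pytest.approx(1.0, abs=1e-8)
        assert res.mean_energy == pytest.approx(energy.energy("SH3B", "PRM4"), rel=1e-8)

    def test_state_space_guard(self):
        a, b = single_sticker("a", "SH3B"), single_sticker("b", "PRM4")
        energy = build_energy_matrix(KdTable([KdRecord("SH3B", "PRM4", 1e-5)]))
        spec = TinySystemSpec([a, b], L=3, energy=energy, beta=1.0, max_configs=10)
        with pytest.raises(ValueError, match="state space"):
            enumerate_tiny_system(spec)

    def test_bond_class_probabilities_sum_to_one(self, single_pair_energy):
        from conftest import two_bead

        a, b = two_bead("a", "SH3B"), two_bead("b", "PRM4")
        res = enumerate_tiny_system(
            TinySystemSpec([a, b], L=3, energy=single_pair_energy, beta=0.5)
        )
        assert sum(res.bond_class_probs.values()) == pytest.approx(1.0, rel=1e-12)
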