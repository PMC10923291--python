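"""Lattice engine: initialization, moves, invariants, determinism,
agreement with the exact enumeration oracle on tiny systems."""

import numpy as np
import pytest

from phasesep.lattice import (
    DEFAULT_BETA,
    InvariantViolation,
    PackingError,
    SimParams,
    apply_move,
    concentration_of,
    init_lattice,
    metropolis_accept,
    run_mc,
    total_energy,
)
from phasesep._mc import MOVE_NAMES
from phasesep.metrics import gdip_of_snapshot
from phasesep.synthetic import TinySystemSpec, enumerate_tiny_system

from conftest import single_sticker, two_bead


class TestConcentration:
    @pytest.mark.parametrize(
        "n, L, expected, rel",
        [(1, 100, 1.0, 1e-12), (2000, 900, 2.743, 1e-3), (2000, 85, 3256.7, 1e-3)],
    )
    def test_micromolecules_per_lattice_unit_cubed(self, n, L, expected, rel):
        assert concentration_of(n, L) == pytest.approx(expected, rel=rel)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            concentration_of(0, 10)
        with pytest.raises(ValueError):
            concentration_of(10, 0)


class TestMetropolis:
    def test_downhill_always_accepted(self):
        for u in (0.0, 0.5, 0.999999):
            assert metropolis_accept(-1.0, DEFAULT_BETA, u)

    def test_uphill_by_RT(self):
        # beta dE = 1 -> acceptance threshold e^-1 ~ 0.368
        RT = 1.0 / DEFAULT_BETA
        assert not metropolis_accept(RT, DEFAULT_BETA, 0.5)
        assert metropolis_accept(RT, DEFAULT_BETA, 0.3)


class TestInitLattice:
    def test_single_bead_occupies_one_of_eight_sites(self):
        t = single_sticker("m", "SH3A")
        state = init_lattice([t], [1], 2, seed=0)
        assert state.pos.shape == (1, 3)
        assert set(np.unique(state.pos)) <= {0, 1}

    def test_mixture_satisfies_all_invariants(self, construct_library, energy_matrix):
        state = init_lattice(
            [construct_library["SLP65_1-330"], construct_library["CIN85-BBB"]],
            [30, 30], 70, seed=3, energy=energy_matrix,
        )
        state.validate()
        assert not (state.partner >= 0).any()  # no initial bonds

    def test_deterministic_under_seed(self, construct_library):
        a = init_lattice([construct_library["CIN85-AB"]], [20], 60, seed=9)
        b = init_lattice([construct_library["CIN85-AB"]], [20], 60, seed=9)
        assert np.array_equal(a.pos, b.pos)

    def test_box_too_small_raises_packing_error(self):
        t = single_sticker("m", "SH3A")
        with pytest.raises(PackingError, match="larger box"):
            init_lattice([t], [9], 2, seed=0)  # 9 beads, 8 sites

    def test_box_below_chain_length_rejected(self, construct_library):
        with pytest.raises(ValueError, match="longest chain"):
            init_lattice([construct_library["SLP65_1-330"]], [1], 20, seed=0)


class TestTotalEnergy:
    def test_no_bonds_zero(self, construct_library, energy_matrix):
        state = init_lattice([construct_library["CIN85-AB"]], [5], 60, seed=1,
                             energy=energy_matrix)
        assert total_energy(state) == 0.0

    def test_single_bond_equals_matrix_entry(self, single_pair_energy):
        a, b = single_sticker("a", "SH3B"), single_sticker("b", "PRM4")
        state = init_lattice([a, b], [1, 1], 4, seed=0, energy=single_pair_energy)
        state.pos[0] = (0, 0, 0)
        state.pos[1] = (0, 0, 1)
        state.partner[:] = [1, 0]
        expected = single_pair_energy.energy("SH3B", "PRM4")
        assert total_energy(state) == pytest.approx(expected)

    def test_bond_between_zero_energy_pair_is_violation(self, single_pair_energy):
        a, b = single_sticker("a", "SH3A"), single_sticker("b", "PRM1")
        state = init_lattice([a, b], [1, 1], 4, seed=0, energy=single_pair_energy)
        state.partner[:] = [1, 0]
        with pytest.raises(InvariantViolation):
            total_energy(state)


class TestMoves:
    def test_every_move_kind_preserves_invariants(self, construct_library, energy_matrix):
        state = init_lattice(
            [construct_library["SLP65_1-330"], construct_library["CIN85-BBB"]],
            [10, 10], 56, seed=5, energy=energy_matrix,
        )
        # pre-bond the system so bond-carrying moves are exercised too
        params = SimParams(n_steps=300_000, seed=8, record_interval=300_000)
        state = run_mc(state, params).final_state
        assert (state.partner >= 0).sum() > 0
        for kind in MOVE_NAMES:
            new, accepted = apply_move(state, kind, seed=123)
            new.validate()
            if not accepted:
                assert np.array_equal(new.pos, state.pos)
                assert np.array_equal(new.partner, state.partner)

    def test_unknown_move_kind_rejected(self, construct_library):
        state = init_lattice([construct_library["CIN85-AB"]], [2], 60, seed=0)
        with pytest.raises(ValueError):
            apply_move(state, "teleport")

    def test_translation_of_isolated_chain_accepted_at_zero_energy(self):
        # one molecule, empty box: excluded volume cannot block it
        t = two_bead("m", "SH3A")
        state = init_lattice([t], [1], 8, seed=1)
        n_acc = 0
        for s in range(40):
            new, acc = apply_move(state, "translation", seed=s)
            new.validate()
            n_acc += acc
        assert n_acc == 40


class TestRunMC:
    def test_identical_seed_gives_identical_snapshot_stream(self, construct_library,
                                                            energy_matrix):
        state = init_lattice(
            [construct_library["SLP65_1-330"], construct_library["CIN85-AB"]],
            [8, 8], 56, seed=2, energy=energy_matrix,
        )
        params = SimParams(n_steps=200_000, seed=77, record_interval=20_000)
        r1, r2 = run_mc(state, params), run_mc(state, params)
        assert len(r1) == len(r2) == 10
        for s1, s2 in zip(r1, r2):
            assert s1.step == s2.step
            assert np.array_equal(s1.pos, s2.pos)
            assert np.array_equal(s1.partner, s2.partner)
            assert s1.energy == s2.energy

    def test_energy_bookkeeping_matches_recomputation(self, construct_library,
                                                      energy_matrix):
        state = init_lattice(
            [construct_library["SLP65_1-330"], construct_library["CIN85-BBB"]],
            [10, 10], 56, seed=4, energy=energy_matrix,
        )
        params = SimParams(n_steps=1_000_000, seed=5, record_interval=100_000)
        res = run_mc(state, params)
        assert len(res) == 10
        for snap in res:
            st = snap.as_state()
            st.validate()
            assert snap.energy == pytest.approx(total_energy(st), abs=1e-9)

    def test_zero_energy_run_stays_homogeneous(self, construct_library):
        # no interactions: ideal-chain gas; GDIP stays below the
        # phase-separation threshold and no bonds ever form
        state = init_lattice(
            [construct_library["SLP65_1-330"], construct_library["CIN85-ABC"]],
            [15, 15], 56, seed=6,
        )
        params = SimParams(n_steps=500_000, seed=7, record_interval=50_000)
        res = run_mc(state, params)
        g = np.mean([gdip_of_snapshot(s).value for s in res.snapshots[5:]])
        assert g < 0.025
        assert all((s.partner < 0).all() for s in res)
        assert res.final_energy == 0.0

    def test_sim_params_validation(self):
        with pytest.raises(ValueError):
            SimParams(n_steps=0)
        with pytest.raises(ValueError):
            SimParams(n_steps=10, move_weights=[1, 2, 3])
        p = SimParams(n_steps=10)
        assert p.normalized_weights.sum() == pytest.approx(1.0, abs=1e-15)


class TestOracleAgreement:
    def test_bound_fraction_of_two_stickers_matches_enumeration(self, single_pair_energy):
        """Two single-sticker chains in a small box: the time-averaged
        bound fraction must match the exact Boltzmann value."""
        beta = 0.45  # reduced coupling so both states are well visited
        a, b = single_sticker("a", "SH3B"), single_sticker("b", "PRM4")
        spec = TinySystemSpec([a, b], L=3, energy=single_pair_energy, beta=beta)
        exact = enumerate_tiny_system(spec)
        state = init_lattice([a, b], [1, 1], 3, seed=3, energy=single_pair_energy)
        thin = 400
        params = SimParams(n_steps=800_000, seed=11, record_interval=thin, beta=beta)
        res = run_mc(state, params)
        bonded = np.array([(s.partner[0] >= 0) for s in res], dtype=float)
        p_hat = bonded.mean()
        # 3-sigma band with an effective-sample-size guard from lag-1
        # autocorrelation of the thinned series
        n = bonded.size
        rho = np.corrcoef(bonded[:-1], bonded[1:])[0, 1]
        n_eff = n * (1 - rho) / (1 + rho) if rho > 0 else n
        se = np.sqrt(exact.p_bonded * (1 - exact.p_bonded) / n_eff)
        assert p_hat == pytest.approx(exact.p_bonded, abs=3 * se)
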