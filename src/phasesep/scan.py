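"""Box-size concentration scans: from a construct pair to phi_sim.

Concentration on the lattice is set by the box size at fixed molecule
number, so a scan runs the same mixture in a series of boxes, measures the
time-averaged GDIP (and percolation value) of the late snapshots of each
replicate run, and fits the logistic saturation model to the per-replicate
values (n = 3 by default) to locate the simulated saturation concentration
phi_sim in micromolecules per lattice-unit^3.

Two presets are shipped: ``desk`` (reduced molecule number and step count;
minutes per scan on one CPU) and ``paper`` (1,000 molecules per species,
2e9 attempted moves, boxes 85-900 — hours to days per box; the scale used
for the published phi_sim values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd

from . import metrics
from .lattice import (
    DEFAULT_BETA,
    LatticeState,
    PackingError,
    RunResult,
    SimParams,
    concentration_of,
    init_lattice,
    run_mc,
)
from .saturation import SaturationModel, SaturationResults
from .stickers import (
    EnergyMatrix,
    MoleculeTopology,
    T_DEFAULT,
    build_energy_matrix,
    build_topology,
)


@dataclass(frozen=True)
class ScanPreset:
    n_per_species: int
    n_steps: int
    box_lengths: tuple[int, ...]
    n_replicates: int = 3


# Desk scale: 100+100 molecules, 2e7 attempted moves per run, boxes chosen
# to bracket the reduced system's percolation transition (it sits at much
# higher lattice concentration than at full scale because small systems
# favor closed stoichiometric complexes over a network).  Bivalent (AB-
# like) mixtures transition roughly an order of magnitude higher than
# trivalent ones, so they get their own deeper box series.  Full ("paper")
# scale: 1,000+1,000 molecules, 2e9 moves, boxes 85-900.
DESK_PRESET = ScanPreset(
    n_per_species=100, n_steps=20_000_000,
    box_lengths=(96, 76, 60, 48, 38),
)
DESK_BOXES_TRIVALENT = DESK_PRESET.box_lengths
DESK_BOXES_BIVALENT = (56, 42, 34, 28, 24, 22)
PAPER_PRESET = ScanPreset(
    n_per_species=1000, n_steps=2_000_000_000,
    box_lengths=(85, 110, 150, 210, 300, 450, 650, 900),
)
PRESETS = {"desk": DESK_PRESET, "paper": PAPER_PRESET}


@dataclass
class ScanResult:
    """Tidy per-(box, replicate) phase metrics plus fit helpers."""

    table: pd.DataFrame
    mixture: "MixtureModel"
    failures: list[tuple[int, str]] = field(default_factory=list)

    def series(self, value_kind: str = "GDIP") -> dict[float, list[float]]:
        col = {"GDIP": "gdip", "percolation": "percolation"}[value_kind]
        out: dict[float, list[float]] = {}
        for _, row in self.table.iterrows():
            out.setdefault(float(row["concentration"]), []).append(float(row[col]))
        return out

    def fit_phi(self, value_kind: str = "GDIP", B: int = 0, seed=None) -> SaturationResults:
        model = SaturationModel.from_series(self.series(value_kind), value_kind=value_kind)
        res = model.fit()
        if B and res.success:
            res.bootstrap(B=B, per_point_n=None, seed=seed)
        return res


@dataclass
class MixtureModel:
    """An equimolar two-species sticker-spacer mixture on the lattice.

    The model object carries the two chain topologies, the energy matrix
    and the molecule number; ``simulate`` runs one box, ``scan`` runs the
    box series and returns per-concentration phase metrics.
    """

    topology_a: MoleculeTopology
    topology_b: MoleculeTopology
    energy: EnergyMatrix
    n_per_species: int = DESK_PRESET.n_per_species
    beta: float = DEFAULT_BETA

    @classmethod
    def from_constructs(
        cls,
        construct_a: str,
        construct_b: str,
        kd_table=None,
        scaling=Fraction(1, 6),
        T: float = T_DEFAULT,
        n_per_species: int = DESK_PRESET.n_per_species,
        linker_spec=None,
    ) -> "MixtureModel":
        if kd_table is None:
            from .synthetic import make_kd_fixture

            kd_table = make_kd_fixture()
        energy = build_energy_matrix(kd_table, T=T)
        return cls(
            topology_a=build_topology(construct_a, scaling, linker_spec),
            topology_b=build_topology(construct_b, scaling, linker_spec),
            energy=energy,
            n_per_species=n_per_species,
            beta=1.0 / (energy.R * T),
        )

    @property
    def n_molecules(self) -> int:
        return 2 * self.n_per_species

    def initial_state(self, box_length: int, seed: int = 0) -> LatticeState:
        # scans deliberately reach boxes smaller than the longest chain
        # (the chain then wraps the torus, which is well-defined); the
        # highest simulated concentrations require it
        return init_lattice(
            [self.topology_a, self.topology_b],
            [self.n_per_species, self.n_per_species],
            box_length,
            seed=seed,
            energy=self.energy,
            enforce_min_box=False,
        )

    def simulate(self, box_length: int, params: SimParams) -> RunResult:
        state = self.initial_state(box_length, seed=params.seed)
        return run_mc(state, replace(params, beta=self.beta))

    def scan(
        self,
        box_lengths=None,
        n_steps: int | None = None,
        n_replicates: int = 3,
        seed: int = 0,
        n_bins: int = metrics.DEFAULT_N_BINS,
        discard_fraction: float = 0.5,
        record_interval: int | None = None,
        max_cluster_molecules: int = 64,
    ) -> ScanResult:
        return run_concentration_scan(
            self, box_lengths=box_lengths, n_steps=n_steps,
            n_replicates=n_replicates, seed=seed, n_bins=n_bins,
            discard_fraction=discard_fraction, record_interval=record_interval,
            max_cluster_molecules=max_cluster_molecules,
        )


def _derived_seed(seed: int, box_index: int, replicate: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(box_index, replicate))
    return int(ss.generate_state(1)[0] % 2**31)


def run_concentration_scan(
    mixture: MixtureModel,
    box_lengths=None,
    n_steps: int | None = None,
    n_replicates: int = 3,
    seed: int = 0,
    n_bins: int = metrics.DEFAULT_N_BINS,
    discard_fraction: float = 0.5,
    record_interval: int | None = None,
    max_cluster_molecules: int = 64,
) -> ScanResult:
    """Run ``n_replicates`` simulations per box size and average GDIP and
    percolation over each run's late snapshots.

    Replicate seeds are derived deterministically from ``seed`` and logged
    in the output table.  A box too small to pack records a failure and the
    scan continues.
    """
    if box_lengths is None:
        box_lengths = DESK_PRESET.box_lengths
    box_lengths = list(box_lengths)
    if len(set(box_lengths)) != len(box_lengths):
        raise ValueError("box_lengths must be distinct")
    if n_steps is None:
        n_steps = DESK_PRESET.n_steps
    rows = []
    failures: list[tuple[int, str]] = []
    for bi, L in enumerate(box_lengths):
        for rep in range(n_replicates):
            s = _derived_seed(seed, bi, rep)
            params = SimParams(
                n_steps=n_steps, seed=s, beta=mixture.beta,
                record_interval=record_interval,
                max_cluster_molecules=max_cluster_molecules,
            )
            try:
                result = mixture.simulate(int(L), params)
            except (PackingError, ValueError) as exc:
                warnings.warn(f"box L={L}: {exc}")
                failures.append((int(L), str(exc)))
                break
            snaps = result.snapshots
            start = int(len(snaps) * discard_fraction)
            used = snaps[start:] or snaps[-1:]
            gdips = [metrics.gdip_of_snapshot(s_, n_bins=n_bins).value for s_ in used]
            percs = [metrics.percolation_value(s_).value for s_ in used]
            rows.append(
                {
                    "box_length": int(L),
                    "replicate": rep,
                    "concentration": concentration_of(mixture.n_molecules, int(L)),
                    "gdip": float(np.mean(gdips)),
                    "percolation": float(np.mean(percs)),
                    "energy": result.final_energy,
                    "seed": s,
                    "n_snapshots_used": len(used),
                }
            )
    table = pd.DataFrame(rows).sort_values(
        ["concentration", "replicate"], ignore_index=True
    ) if rows else pd.DataFrame(
        columns=["box_length", "replicate", "concentration", "gdip",
                 "percolation", "energy", "seed", "n_snapshots_used"]
    )
    return ScanResult(table=table, mixture=mixture, failures=failures)
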