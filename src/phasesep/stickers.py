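"""Sticker kinds, dissociation-constant tables, and chain topologies.

The coarse-grained model represents each folded SH3 domain of CIN85 and
each proline-rich motif (PRM) of SLP65 as a single interaction-competent
lattice bead (a *sticker*); the intrinsically disordered segments between
them become chains of inert *spacer* beads.  Pairwise sticker affinities
enter as Gibbs free energies derived from measured dissociation constants,

    dG = -R T ln(1 / K_D),

with R = 1.987e-3 kcal/mol/K and T = 310 K, so a K_D below 1 M gives a
negative (attractive) contact energy.  Same-side pairs (SH3-SH3, PRM-PRM)
and pairs without a measured K_D carry zero energy, as do all isotropic
(nonspecific) contacts.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from fractions import Fraction
import numpy as np
import yaml

try:  # py3.11+
    from importlib.resources import files as _pkg_files
except ImportError:  # pragma: no cover
    from importlib_resources import files as _pkg_files

R_KCAL = 1.987e-3  # gas constant, kcal / (mol K)
T_DEFAULT = 310.0  # physiological temperature, K

SH3_KINDS = ("SH3A", "SH3B", "SH3C")
PRM_KINDS = ("PRM1", "PRM2", "PRM3", "PRM4", "PRM5", "PRM6", "PRM1star")
ALL_KINDS = SH3_KINDS + PRM_KINDS

DEFAULT_CONSTRUCTS = (
    "SLP65_1-330",
    "SLP65-3xPRM4",
    "SLP65-R247A",
    "CIN85-ABC",
    "CIN85-AB",
    "CIN85-BBB",
    "CIN85-ABC-DM",
)


def sticker_side(label: str) -> str:
    """Return 'SH3' or 'PRM' for a sticker label."""
    if label in SH3_KINDS:
        return "SH3"
    if label in PRM_KINDS:
        return "PRM"
    raise ValueError(f"unknown sticker label: {label!r}")


@dataclass(frozen=True)
class KdRecord:
    """One measured SH3 x PRM dissociation constant."""

    sh3: str
    prm: str
    kd: float  # molar
    method: str = "NMR"
    sd: float = float("nan")  # molar
    approx: bool = False

    def __post_init__(self):
        if sticker_side(self.sh3) != "SH3":
            raise ValueError(f"{self.sh3!r} is not an SH3-side sticker")
        if sticker_side(self.prm) != "PRM":
            raise ValueError(f"{self.prm!r} is not a PRM-side sticker")
        if not self.kd > 0:
            raise ValueError(f"kd must be positive, got {self.kd}")
        if self.method not in ("NMR", "ITC"):
            raise ValueError(f"method must be NMR or ITC, got {self.method!r}")


@dataclass
class KdTable:
    """Collection of pairwise K_D records, one per (SH3, PRM) pair."""

    records: list[KdRecord] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for r in self.records:
            key = (r.sh3, r.prm)
            if key in seen:
                raise ValueError(f"duplicate K_D record for pair {key}")
            seen.add(key)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, sh3: str, prm: str) -> KdRecord | None:
        for r in self.records:
            if r.sh3 == sh3 and r.prm == prm:
                return r
        return None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sh3": [r.sh3 for r in self.records],
                "prm": [r.prm for r in self.records],
                "kd_molar": [r.kd for r in self.records],
                "method": [r.method for r in self.records],
                "sd_molar": [r.sd for r in self.records],
                "approx": [r.approx for r in self.records],
            }
        )

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["sh3", "prm", "kd_molar", "method", "sd_molar", "approx"])
            for r in self.records:
                w.writerow([r.sh3, r.prm, repr(r.kd), r.method, repr(r.sd), str(r.approx).lower()])


def delta_g(kd: float, T: float = T_DEFAULT) -> float:
    """Contact free energy (kcal/mol) for a sticker pair with dissociation
    constant ``kd`` (molar): dG = -R T ln(1/kd).  Negative iff kd < 1 M."""
    if not kd > 0:
        raise ValueError(f"kd must be positive, got {kd}")
    if not T > 0:
        raise ValueError(f"T must be positive, got {T}")
    return -R_KCAL * T * math.log(1.0 / kd)


@dataclass
class EnergyMatrix:
    """Symmetric sticker-pair contact energy table (kcal/mol).

    ``matrix[i, j]`` is the anisotropic bond energy between sticker kinds
    ``kinds[i]`` and ``kinds[j]``; zero means the pair cannot bond.
    """

    kinds: tuple[str, ...]
    matrix: np.ndarray  # (K, K) float64, symmetric
    T: float = T_DEFAULT
    R: float = R_KCAL

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.kinds), len(self.kinds)):
            raise ValueError("matrix shape does not match kinds")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("energy matrix must be symmetric")

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(RT) in (kcal/mol)^-1."""
        return 1.0 / (self.R * self.T)

    def index(self, kind: str) -> int:
        return self.kinds.index(kind)

    def energy(self, a: str, b: str) -> float:
        return float(self.matrix[self.index(a), self.index(b)])


def build_energy_matrix(table: KdTable, T: float = T_DEFAULT) -> EnergyMatrix:
    """Convert a K_D table into the symmetric sticker-pair energy matrix.

    One negative entry per table record (via :func:`delta_g`); every pair
    absent from the table — including all SH3-SH3 and PRM-PRM pairs — is
    zero.  Isotropic energies are zero throughout the model.
    """
    kinds = ALL_KINDS
    n = len(kinds)
    idx = {k: i for i, k in enumerate(kinds)}
    mat = np.zeros((n, n))
    for r in table:
        i, j = idx[r.sh3], idx[r.prm]
        dg = delta_g(r.kd, T)
        mat[i, j] = dg
        mat[j, i] = dg
    return EnergyMatrix(kinds=kinds, matrix=mat, T=T)


def load_kd_table(path) -> KdTable:
    """Read a K_D table from CSV with header (sh3, prm, kd_molar, method,
    sd_molar[, approx]).  Malformed rows raise with their line number."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return KdTable([])
        required = {"sh3", "prm", "kd_molar"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = KdRecord(
                    sh3=row["sh3"].strip(),
                    prm=row["prm"].strip(),
                    kd=float(row["kd_molar"]),
                    method=(row.get("method") or "NMR").strip(),
                    sd=float(row["sd_molar"]) if row.get("sd_molar") else float("nan"),
                    approx=(row.get("approx") or "false").strip().lower() == "true",
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
            records.append(rec)
    return KdTable(records)


def scale_linker(n_aa: int, factor) -> int:
    """Number of spacer beads for an ``n_aa``-residue linker at spacer
    scaling ``factor`` (e.g. 1/6: one bead per PRM-sized 6-residue unit).

    Rounds to the nearest integer, ties to even, exactly on rationals, so
    60 aa at 1/6 gives 10 beads and 25 aa gives round(4.17) = 4.
    """
    if n_aa < 0:
        raise ValueError(f"n_aa must be >= 0, got {n_aa}")
    f = _as_fraction(factor)
    if not (0 < f <= 1):
        raise ValueError(f"scaling factor must be in (0, 1], got {factor}")
    x = Fraction(n_aa) * f
    q, r = divmod(x.numerator, x.denominator)
    frac = Fraction(r, x.denominator)
    half = Fraction(1, 2)
    if frac > half or (frac == half and q % 2 == 1):
        q += 1
    return int(q)


def _as_fraction(factor) -> Fraction:
    if isinstance(factor, Fraction):
        return factor
    if isinstance(factor, int):
        return Fraction(factor)
    if isinstance(factor, str):
        return Fraction(factor)
    if isinstance(factor, tuple):
        return Fraction(*factor)
    # floats like 1/6 are binary approximations; snap to a small rational
    return Fraction(factor).limit_denominator(10_000)


@dataclass(frozen=True)
class Bead:
    """One lattice bead: a sticker of some kind, or an inert spacer."""

    kind: str | None  # None for spacer beads

    @property
    def is_sticker(self) -> bool:
        return self.kind is not None


@dataclass
class MoleculeTopology:
    """Linear bead chain for one construct at one spacer scaling factor."""

    name: str
    beads: tuple[Bead, ...]
    scaling: Fraction

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def stickers(self) -> tuple[str, ...]:
        return tuple(b.kind for b in self.beads if b.is_sticker)

    @property
    def kind_codes(self):
        """Per-bead sticker-kind indices into ALL_KINDS; -1 for spacers."""
        return np.array(
            [ALL_KINDS.index(b.kind) if b.is_sticker else -1 for b in self.beads],
            dtype=np.int8,
        )


def _default_construct_spec() -> dict:
    with (_pkg_files("phasesep") / "data" / "constructs.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_construct_spec(path=None) -> dict:
    """Load the construct definition document (sticker order plus linker
    amino-acid counts per construct)."""
    if path is None:
        return _default_construct_spec()
    with open(path) as fh:
        return yaml.safe_load(fh)


def build_topology(
    construct: str,
    scaling=Fraction(1, 6),
    linker_spec: dict | None = None,
) -> MoleculeTopology:
    """Build the bead chain for a named construct.

    Each segment of the construct definition is either a sticker (one
    bead) or a linker whose amino-acid count is converted to spacer beads
    with :func:`scale_linker`.  Segments flagged ``inert`` (the R247A
    point mutant's PRM4 site) keep their bead but lose the sticker label,
    so deactivation changes binding competence, not geometry.
    """
    spec = linker_spec if linker_spec is not None else _default_construct_spec()
    if construct not in spec:
        raise KeyError(
            f"unknown construct {construct!r}; available: {sorted(spec)}"
        )
    f = _as_fraction(scaling)
    beads: list[Bead] = []
    for seg in spec[construct]["segments"]:
        if "sticker" in seg:
            label = seg["sticker"]
            if label not in ALL_KINDS:
                raise ValueError(f"{construct}: unknown sticker {label!r}")
            if seg.get("inert", False):
                beads.append(Bead(kind=None))
            else:
                beads.append(Bead(kind=label))
        elif "linker" in seg:
            n_aa = int(seg["linker"])
            beads.extend(Bead(kind=None) for _ in range(scale_linker(n_aa, f)))
        else:
            raise ValueError(f"{construct}: segment must have 'sticker' or 'linker'")
    return MoleculeTopology(name=construct, beads=tuple(beads), scaling=f)


def build_construct_library(
    scaling=Fraction(1, 6), linker_spec: dict | None = None
) -> dict[str, MoleculeTopology]:
    """All default constructs at one scaling factor."""
    spec = linker_spec if linker_spec is not None else _default_construct_spec()
    return {name: build_topology(name, scaling, spec) for name in spec}
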