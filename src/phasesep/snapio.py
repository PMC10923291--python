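"""Plain-text snapshot dumps.

One tidy table per run: (step, molecule, bead, kind, x, y, z, partner),
with the box size and sticker-kind labels in a JSON header comment so a
dump is self-contained for downstream analysis (GDIP, percolation)."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .lattice import RunResult, Snapshot, SystemInfo


def dump_snapshots(run: RunResult | list[Snapshot], path) -> None:
    snaps = list(run)
    if not snaps:
        raise ValueError("no snapshots to dump")
    info = snaps[0].info
    header = {
        "L": int(info.L),
        "kinds": list(info.kinds),
        "mol_len": info.mol_len.tolist(),
        "energy": np.asarray(info.energy).tolist(),
    }
    frames = []
    for s in snaps:
        n = info.n_beads
        frames.append(
            pd.DataFrame(
                {
                    "step": np.full(n, s.step, dtype=np.int64),
                    "molecule": info.mol_of,
                    "bead": np.arange(n) - info.mol_start[info.mol_of],
                    "kind": info.kind,
                    "x": s.pos[:, 0],
                    "y": s.pos[:, 1],
                    "z": s.pos[:, 2],
                    "partner": s.partner,
                }
            )
        )
    with open(path, "w") as fh:
        fh.write("#phasesep-snapshots " + json.dumps(header) + "\n")
        pd.concat(frames).to_csv(fh, index=False)


def load_snapshots(path) -> list[Snapshot]:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#phasesep-snapshots "):
            raise ValueError(f"{path}: not a snapshot dump")
        header = json.loads(first[len("#phasesep-snapshots "):])
        df = pd.read_csv(fh)
    mol_len = np.asarray(header["mol_len"], dtype=np.int32)
    mol_start = np.concatenate([[0], np.cumsum(mol_len)[:-1]]).astype(np.int32)
    mol_of = np.repeat(np.arange(len(mol_len), dtype=np.int32), mol_len)
    one = df[df.step == df.step.iloc[0]]
    info = SystemInfo(
        L=int(header["L"]),
        kind=one["kind"].to_numpy(np.int8),
        mol_of=mol_of,
        mol_start=mol_start,
        mol_len=mol_len,
        kinds=tuple(header["kinds"]),
        energy=np.asarray(header["energy"], dtype=float),
    )
    from .lattice import total_energy

    snaps = []
    for step, g in df.groupby("step", sort=True):
        s = Snapshot(
            info=info,
            step=int(step),
            pos=g[["x", "y", "z"]].to_numpy(np.int64),
            partner=g["partner"].to_numpy(np.int32),
            energy=0.0,
        )
        s.energy = total_energy(s)
        snaps.append(s)
    return snaps
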