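"""End-to-end orchestration: parameterize -> scan -> phi_sim; images ->
DI -> phi_exp; compare.

The comparison mirrors how simulated and experimental saturation
concentrations are reconciled: phi values are reduced to ratios between
mixtures (the units of the two arms differ — uM versus micromolecules per
lattice-unit^3 — so only ratios are commensurable), ratios from the two
arms are compared as a mismatch factor (the larger divided by the smaller,
reported to one decimal), and agreement across mixtures is summarized by a
Pearson correlation with designated pairs excluded.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


def phi_ratio(phi_num: float, phi_den: float) -> float:
    """Quotient of two fitted saturation concentrations."""
    if not (phi_den > 0):
        raise ValueError("denominator phi must be positive")
    return phi_num / phi_den


def mismatch_factor(ratio_a: float, ratio_b: float, ndigits: int = 1) -> float:
    """Factor by which two phi-ratios disagree: max(a/b, b/a), rounded to
    one decimal (e.g. simulated 20.2 vs experimental 4.4 -> 4.6)."""
    if ratio_a <= 0 or ratio_b <= 0:
        raise ValueError("ratios must be positive")
    m = max(ratio_a / ratio_b, ratio_b / ratio_a)
    return round(m, ndigits)


@dataclass
class ComparisonEntry:
    mixture: str
    phi_exp: float = float("nan")
    phi_exp_se: float = float("nan")
    phi_sim: float = float("nan")
    phi_sim_se: float = float("nan")
    excluded: bool = False
    note: str = ""


@dataclass
class ComparisonReport:
    """phi_exp vs phi_sim table, ratio entries, and their correlation."""

    entries: list[ComparisonEntry]
    ratios: list[dict] = field(default_factory=list)
    pearson_r: float = float("nan")
    pearson_p: float = float("nan")
    n_pairs: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.entries])

    def to_dict(self) -> dict:
        return {
            "entries": [asdict(e) for e in self.entries],
            "ratios": self.ratios,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "n_pairs": self.n_pairs,
        }

    def excluded_mixtures(self) -> list[str]:
        return [e.mixture for e in self.entries if e.excluded]


def build_comparison_report(
    entries: list[ComparisonEntry],
    ratio_pairs: list[tuple[str, str]] = (),
    exclude: tuple[str, ...] = (),
    log_log: bool = False,
) -> ComparisonReport:
    """Assemble the comparison: per-mixture phi pairs, phi-ratios for the
    requested (numerator, denominator) mixture pairs in both arms with
    their mismatch factor, and the Pearson correlation over non-excluded
    complete pairs (on untransformed phi values unless ``log_log``)."""
    by_name = {e.mixture: e for e in entries}
    for name in exclude:
        if name in by_name:
            by_name[name].excluded = True
    ratios = []
    for num, den in ratio_pairs:
        a, b = by_name[num], by_name[den]
        row = {"pair": f"{num}/{den}"}
        r_exp = r_sim = float("nan")
        if np.isfinite(a.phi_exp) and np.isfinite(b.phi_exp) and b.phi_exp > 0:
            r_exp = phi_ratio(a.phi_exp, b.phi_exp)
        if np.isfinite(a.phi_sim) and np.isfinite(b.phi_sim) and b.phi_sim > 0:
            r_sim = phi_ratio(a.phi_sim, b.phi_sim)
        row["ratio_exp"] = round(r_exp, 1) if np.isfinite(r_exp) else r_exp
        row["ratio_sim"] = round(r_sim, 1) if np.isfinite(r_sim) else r_sim
        if np.isfinite(r_exp) and np.isfinite(r_sim):
            row["mismatch_factor"] = mismatch_factor(r_sim, r_exp)
        ratios.append(row)
    xs, ys = [], []
    for e in entries:
        if e.excluded or not (np.isfinite(e.phi_exp) and np.isfinite(e.phi_sim)):
            continue
        if log_log:
            xs.append(math.log(e.phi_exp))
            ys.append(math.log(e.phi_sim))
        else:
            xs.append(e.phi_exp)
            ys.append(e.phi_sim)
    r = p = float("nan")
    if len(xs) >= 3:
        from scipy import stats

        r, p = stats.pearsonr(xs, ys)
    return ComparisonReport(
        entries=entries, ratios=ratios, pearson_r=float(r), pearson_p=float(p),
        n_pairs=len(xs),
    )


# ---------------------------------------------------------------------------
# full pipeline


DEFAULT_CONFIG = {
    "seed": 1,
    "kd_table": None,  # packaged fixture when null
    "scaling": "1/6",
    "simulation": {
        "n_per_species": 100,
        "n_steps": 30_000_000,
        "boxes": None,  # desk preset when null
        "n_replicates": 3,
        "n_bins": 30,
        "mixtures": [],  # e.g. [{"name": "AB", "a": "SLP65_1-330", "b": "CIN85-AB"}]
    },
    "imaging": {
        "datasets": [],  # e.g. [{"name": "wt", "phi_true": 6.7}] or {"manifest": path}
        "concentrations": [0.5, 1.0, 2.0, 4.0, 7.0, 12.0, 20.0, 40.0],
        "n_per_point": 15,
    },
    "analysis": {
        "bootstrap_B": 1000,
        "gdip_threshold": 0.025,
        # order parameter for the simulation-arm saturation fit; GDIP for
        # full-scale droplet regimes, percolation for reduced-scale scans
        "sim_value_kind": "percolation",
    },
    "comparison": {"ratio_pairs": [], "exclude": [], "log_log": False},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    """Serializable pipeline configuration (echoed verbatim into the output
    directory of every run)."""

    data: dict

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(_merge(DEFAULT_CONFIG, d))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=False)

    def __getitem__(self, k):
        return self.data[k]


def run_pipeline(config: RunConfig, outdir) -> ComparisonReport:
    """Run the configured workflow and write all artifacts under
    ``outdir``: config echo, per-mixture scan tables and fit reports, DI
    tables and phi_exp fits for the imaging datasets, and the comparison
    report.  Every reported number is read back from an artifact file."""
    from .imaging import build_di_series, estimate_phi_exp
    from .scan import DESK_PRESET, MixtureModel
    from .stickers import load_kd_table
    from .synthetic import generate_di_dataset, make_kd_fixture

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    cfg = config.data
    seed = int(cfg["seed"])
    B = int(cfg["analysis"]["bootstrap_B"])
    scaling = Fraction(str(cfg["scaling"]))
    kd = load_kd_table(cfg["kd_table"]) if cfg["kd_table"] else make_kd_fixture()

    sim_cfg = cfg["simulation"]
    boxes = sim_cfg["boxes"] or DESK_PRESET.box_lengths
    phi_sim: dict[str, tuple[float, float]] = {}
    for mi, mx in enumerate(sim_cfg["mixtures"]):
        name = mx["name"]
        model = MixtureModel.from_constructs(
            mx["a"], mx["b"], kd_table=kd, scaling=scaling,
            n_per_species=int(sim_cfg["n_per_species"]),
        )
        scan = model.scan(
            box_lengths=boxes, n_steps=int(sim_cfg["n_steps"]),
            n_replicates=int(sim_cfg["n_replicates"]), seed=seed + 1000 * mi,
            n_bins=int(sim_cfg["n_bins"]),
        )
        scan.table.to_csv(outdir / f"scan_{name}.csv", index=False)
        fit = scan.fit_phi(cfg["analysis"]["sim_value_kind"], B=B,
                           seed=seed + 1000 * mi + 1)
        _write_fit_json(outdir / f"fit_sim_{name}.json", fit, B, seed)
        phi_sim[name] = (fit.phi, fit.phi_se)

    img_cfg = cfg["imaging"]
    phi_exp: dict[str, tuple[float, float]] = {}
    for di_i, ds in enumerate(img_cfg["datasets"]):
        name = ds["name"]
        if "manifest" in ds:
            from .imaging import read_manifest

            records = read_manifest(ds["manifest"])
        else:
            records, _ = generate_di_dataset(
                phi_true=float(ds["phi_true"]),
                concentrations=img_cfg["concentrations"],
                n_per_point=int(img_cfg["n_per_point"]),
                seed=seed + 777 * (di_i + 1),
            )
        series = build_di_series(records, n_expected=int(img_cfg["n_per_point"]))
        series.to_frame().to_csv(outdir / f"di_{name}.csv", index=False)
        fit = estimate_phi_exp(series, B=B, seed=seed + 777 * (di_i + 1) + 1)
        _write_fit_json(outdir / f"fit_exp_{name}.json", fit, B, seed)
        phi_exp[name] = (fit.phi, fit.phi_se)

    # report layer: assembled purely from the artifact files
    entries = []
    for name in sorted(set(phi_sim) | set(phi_exp)):
        e = ComparisonEntry(mixture=name)
        nanify = lambda v: float("nan") if v is None else float(v)
        f = outdir / f"fit_sim_{name}.json"
        if f.exists():
            d = json.loads(f.read_text())
            e.phi_sim, e.phi_sim_se = nanify(d["phi"]), nanify(d["phi_se"])
            if not d["success"]:
                e.note = d["reason"]
        f = outdir / f"fit_exp_{name}.json"
        if f.exists():
            d = json.loads(f.read_text())
            e.phi_exp, e.phi_exp_se = nanify(d["phi"]), nanify(d["phi_se"])
            if not d["success"] and not e.note:
                e.note = d["reason"]
        entries.append(e)
    cmp_cfg = cfg["comparison"]
    report = build_comparison_report(
        entries,
        ratio_pairs=[tuple(p) for p in cmp_cfg["ratio_pairs"]],
        exclude=tuple(cmp_cfg["exclude"]),
        log_log=bool(cmp_cfg["log_log"]),
    )
    (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    report.to_frame().to_csv(outdir / "report.csv", index=False)
    return report


def _write_fit_json(path, fit, B: int, seed: int) -> None:
    d = {
        "success": fit.success,
        "reason": fit.reason,
        "params": fit.params,
        "phi": fit.phi,
        "phi_se": fit.phi_se,
        "rss": fit.rss,
        "pvalue": fit.pvalue,
        "nobs": fit.nobs,
        "bootstrap_B": B,
        "seed": seed,
        "value_kind": fit.model.value_kind,
    }

    def _clean(x):
        if isinstance(x, float) and not math.isfinite(x):
            return None
        if isinstance(x, dict):
            return {k: _clean(v) for k, v in x.items()}
        return x

    Path(path).write_text(json.dumps(_clean(d), indent=2, default=float))
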