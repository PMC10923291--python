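"""Saturation-concentration estimation from a sigmoidal order-parameter
series.

Both arms of the analysis — dispersion indices from microscopy and GDIP or
percolation values from lattice simulations — rise sigmoidally with total
concentration once a dense phase appears.  The series is fitted with the
four-parameter logistic

    y(x) = H / (1 + exp(-k (x - x0))) + C,

and the saturation concentration phi is the location of the maximum of the
fitted curve's second derivative, which for a rising logistic (k > 0) has
the closed form

    phi = x0 - ln(2 + sqrt(3)) / k,

i.e. the onset shoulder of the transition rather than its midpoint.
Uncertainty comes from a bootstrap over the per-concentration replicate
values (resample, refit, take the standard deviation of phi).

Usage follows the Model/Results pattern::

    res = SaturationModel(conc, values, value_kind="DI").fit()
    res.phi, res.params
    boot = res.bootstrap(B=5000, seed=1)
    print(res.summary())

A series with no sigmoidal structure (flat, or a transition above the top
of the concentration range) yields a result with ``success=False`` and a
``reason`` — the analogue of a mixture whose saturation concentration
could not be fitted up to the highest measured concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

PHI_OFFSET = math.log(2.0 + math.sqrt(3.0))  # x0 - phi in units of 1/k

# require the logistic to beat a constant fit at this level before a
# transition is declared
SIGMOID_F_TEST_ALPHA = 0.01


def logistic(x, H, C, k, x0):
    """Four-parameter logistic H/(1+exp(-k(x-x0))) + C."""
    return H / (1.0 + np.exp(-k * (np.asarray(x, dtype=float) - x0))) + C


def _logistic_jac(x, H, C, k, x0):
    x = np.asarray(x, dtype=float)
    z = np.exp(-k * (x - x0))
    s = 1.0 / (1.0 + z)
    sz = s * s * z
    return np.stack(
        [s, np.ones_like(x), H * sz * (x - x0), -H * sz * k], axis=1
    )


def phi_from_params(k: float, x0: float) -> float:
    """Closed-form location of the maximum of the logistic's second
    derivative (the onset of the rise)."""
    return x0 - PHI_OFFSET / k


@dataclass
class BootstrapPhi:
    """Bootstrap uncertainty of the saturation concentration."""

    se: float
    ci95: tuple[float, float]
    samples: np.ndarray
    B: int
    n_failed: int
    seed: int | None

    @property
    def unreliable(self) -> bool:
        return self.n_failed > 0.2 * self.B

    def covers(self, value: float) -> bool:
        return self.ci95[0] <= value <= self.ci95[1]


class SaturationModel:
    """Logistic saturation-concentration model for one mixture's series.

    Parameters
    ----------
    concentration : array-like
        Concentration of each observation (uM for imaging data,
        micromolecules per lattice-unit^3 for simulation data); repeated
        entries mark replicates.
    values : array-like
        The order parameter at each observation (DI, GDIP or percolation).
    value_kind : {"DI", "GDIP", "percolation"}
    """

    def __init__(self, concentration, values, value_kind: str = "DI"):
        x = np.asarray(concentration, dtype=float)
        y = np.asarray(values, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("concentration and values must be equal-length 1-D")
        if np.unique(x).size < 4:
            raise ValueError("need at least 4 distinct concentrations")
        order = np.argsort(x, kind="stable")
        self.x = x[order]
        self.y = y[order]
        self.value_kind = value_kind

    @classmethod
    def from_series(cls, series: dict, value_kind: str = "DI") -> "SaturationModel":
        """Build from a mapping concentration -> list of replicate values."""
        xs, ys = [], []
        for c, vals in series.items():
            vals = np.atleast_1d(np.asarray(vals, dtype=float))
            xs.extend([float(c)] * vals.size)
            ys.extend(vals.tolist())
        return cls(xs, ys, value_kind=value_kind)

    @classmethod
    def from_dataframe(cls, df, x: str = "concentration", y: str = "value",
                       value_kind: str = "DI") -> "SaturationModel":
        return cls(df[x].to_numpy(), df[y].to_numpy(), value_kind=value_kind)

    # -- fitting -----------------------------------------------------------

    def _initial_guess(self) -> np.ndarray:
        xs, ys = self.x, self.y
        ux = np.unique(xs)
        gm = np.array([ys[xs == c].mean() for c in ux])
        c0 = float(gm.min())
        h0 = float(gm.max() - gm.min())
        if h0 <= 0:
            h0 = max(abs(c0), 1.0) * 1e-3
        half = c0 + h0 / 2.0
        above = np.flatnonzero(gm >= half)
        x0 = float(ux[above[0]]) if above.size else float(ux[-1])
        # logistic slope at the midpoint is H k / 4
        if ux.size >= 3:
            i = min(max(int(np.searchsorted(ux, x0)), 1), ux.size - 2)
            dx = ux[i + 1] - ux[i - 1]
            slope = (gm[i + 1] - gm[i - 1]) / dx if dx > 0 else 0.0
        else:
            slope = 0.0
        k0 = 4.0 * slope / h0 if slope > 0 else 4.0 / (ux[-1] - ux[0])
        k0 = max(k0, 1e-6)
        return np.array([h0, c0, k0, x0])

    def fit(self, p0=None, B: int = 0, seed=None) -> "SaturationResults":
        """Least-squares logistic fit; optionally run a phi bootstrap with
        ``B`` repetitions right away."""
        res = self._fit_xy(self.x, self.y, p0)
        results = SaturationResults(model=self, **res)
        if B and results.success:
            results.bootstrap(B=B, seed=seed)
        return results

    def _fit_xy(self, x, y, p0=None) -> dict:
        if p0 is None:
            p0 = self._initial_guess()
        n = x.size
        fail = dict(
            params=None, pcov=None, success=False, rss=np.nan,
            fvalue=np.nan, pvalue=np.nan, nobs=n,
        )
        rss0 = float(((y - y.mean()) ** 2).sum())
        if rss0 <= n * max(1.0, float(np.abs(y).max())) ** 2 * 1e-28:
            return {**fail, "reason": "series is constant; no transition"}
        if self.value_kind == "percolation":
            # the percolation value lives in [1/N, 1]: bound both plateaus
            bounds = ([0.0, 0.0, 1e-12, -np.inf], [1.2, 1.0, np.inf, np.inf])
        else:
            bounds = ([0.0, -np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf, np.inf])
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            popt, pcov = optimize.curve_fit(
                logistic, x, y, p0=p0, jac=_logistic_jac, bounds=bounds,
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            return {**fail, "reason": "least-squares fit did not converge"}
        H, C, k, x0 = popt
        yhat = logistic(x, *popt)
        rss1 = float(((y - yhat) ** 2).sum())
        if n > 4 and rss1 > 0:
            F = ((rss0 - rss1) / 3.0) / (rss1 / (n - 4))
            pval = float(stats.f.sf(F, 3, n - 4))
        else:
            F, pval = np.inf, 0.0
        out = dict(
            params=dict(H=float(H), C=float(C), k=float(k), x0=float(x0)),
            pcov=pcov, rss=rss1, fvalue=float(F), pvalue=pval, nobs=n,
        )
        if H <= 0 or not np.isfinite(k) or k <= 0:
            return {**fail, **{k2: out[k2] for k2 in ("rss", "fvalue", "pvalue")},
                    "reason": "no rising transition (H or k not positive)"}
        if pval > SIGMOID_F_TEST_ALPHA:
            return {**fail, **{k2: out[k2] for k2 in ("rss", "fvalue", "pvalue")},
                    "reason": "no sigmoidal structure beyond noise"}
        if x0 > x.max():
            return {**fail, "params": out["params"],
                    **{k2: out[k2] for k2 in ("rss", "fvalue", "pvalue")},
                    "reason": "not fittable up to max concentration"}
        return {**out, "success": True, "reason": ""}

    def groups(self) -> dict[float, np.ndarray]:
        return {float(c): self.y[self.x == c] for c in np.unique(self.x)}


@dataclass
class SaturationResults:
    """Fit results: logistic parameters, the derived saturation
    concentration phi, fit diagnostics, and bootstrap uncertainty."""

    model: SaturationModel
    params: dict | None
    pcov: np.ndarray | None
    success: bool
    reason: str
    rss: float
    fvalue: float
    pvalue: float
    nobs: int
    _bootstrap: BootstrapPhi | None = field(default=None, repr=False)

    @property
    def phi(self) -> float:
        """Saturation concentration: argmax of the second derivative of the
        fitted logistic, x0 - ln(2 + sqrt(3))/k; NaN for a failed fit."""
        if not self.success or self.params is None:
            return float("nan")
        return phi_from_params(self.params["k"], self.params["x0"])

    @property
    def phi_se(self) -> float:
        return self._bootstrap.se if self._bootstrap is not None else float("nan")

    def predict(self, x):
        if self.params is None:
            raise RuntimeError(f"fit failed: {self.reason}")
        p = self.params
        return logistic(x, p["H"], p["C"], p["k"], p["x0"])

    def bootstrap(self, B: int = 5000, per_point_n: int | None = None,
                  seed=None) -> BootstrapPhi:
        """Resample per-concentration replicate values (with replacement,
        ``per_point_n`` values per concentration), refit, and take the
        spread of phi across ``B`` repetitions."""
        if not self.success:
            raise RuntimeError(f"cannot bootstrap a failed fit: {self.reason}")
        rng = np.random.default_rng(seed)
        groups = self.model.groups()
        concs = list(groups)
        p0 = np.array([self.params[k] for k in ("H", "C", "k", "x0")])
        phis = []
        n_failed = 0
        for _ in range(B):
            xs, ys = [], []
            for c in concs:
                vals = groups[c]
                m = per_point_n if per_point_n is not None else vals.size
                take = rng.integers(0, vals.size, size=m)
                xs.extend([c] * m)
                ys.extend(vals[take].tolist())
            r = self.model._fit_xy(np.asarray(xs), np.asarray(ys), p0=p0)
            if r["success"]:
                phis.append(phi_from_params(r["params"]["k"], r["params"]["x0"]))
            else:
                n_failed += 1
        phis = np.asarray(phis)
        if phis.size >= 2:
            se = float(phis.std(ddof=1))
            ci = (float(np.percentile(phis, 2.5)), float(np.percentile(phis, 97.5)))
        else:
            se, ci = float("nan"), (float("nan"), float("nan"))
        self._bootstrap = BootstrapPhi(
            se=se, ci95=ci, samples=phis, B=B, n_failed=n_failed,
            seed=seed if isinstance(seed, int) else None,
        )
        return self._bootstrap

    def summary(self) -> str:
        lines = [
            "Saturation concentration fit (logistic + 2nd-derivative max)",
            f"  value kind:      {self.model.value_kind}",
            f"  n observations:  {self.nobs}",
            f"  fit success:     {self.success}" + ("" if self.success else f"  ({self.reason})"),
        ]
        if self.params is not None:
            p = self.params
            lines += [
                f"  H = {p['H']:.6g}   C = {p['C']:.6g}",
                f"  k = {p['k']:.6g}   x0 = {p['x0']:.6g}",
                f"  rss = {self.rss:.6g}   F = {self.fvalue:.4g}   p = {self.pvalue:.3g}",
            ]
        if self.success:
            lines.append(f"  phi = {self.phi:.6g}")
            if self._bootstrap is not None:
                b = self._bootstrap
                flag = "  [unreliable: >20% refits failed]" if b.unreliable else ""
                lines.append(
                    f"  phi bootstrap SE = {b.se:.4g}  95% CI = "
                    f"({b.ci95[0]:.6g}, {b.ci95[1]:.6g})  B = {b.B}{flag}"
                )
        return "\n".join(lines)


def fit_phi(series, value_kind: str = "DI", p0=None) -> SaturationResults:
    """Fit a concentration -> replicate-values series (mapping or
    DataFrame with 'concentration'/'value' columns) and return results."""
    if isinstance(series, dict):
        model = SaturationModel.from_series(series, value_kind=value_kind)
    else:
        model = SaturationModel.from_dataframe(series, value_kind=value_kind)
    return model.fit(p0=p0)


def bootstrap_phi(series, B: int = 5000, per_point_n: int | None = None,
                  seed=None, value_kind: str = "DI") -> BootstrapPhi:
    """Convenience wrapper: fit, then bootstrap the saturation
    concentration (B repetitions, ``per_point_n`` draws per concentration,
    e.g. 15 dispersion-index or 3 GDIP values)."""
    res = fit_phi(series, value_kind=value_kind)
    if not res.success:
        raise RuntimeError(f"fit failed: {res.reason}")
    return res.bootstrap(B=B, per_point_n=per_point_n, seed=seed)
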