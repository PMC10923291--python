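# phasesep

Sticker–spacer lattice Monte Carlo and dispersion-index image analysis
for the phase separation of the multivalent SLP65–CIN85 system.

In resting B cells the adaptor SLP65 and its constitutive partner CIN85
form condensates that prime antigen-receptor signaling. The interaction
is built from many weak, promiscuous contacts: six proline-rich motifs
(PRMs) in SLP65's disordered region bind the three SH3 domains of CIN85
with dissociation constants from 6 µM to ~4 mM. `phasesep` asks the
quantitative question behind that observation: do the individual K_D
values, fed into a coarse-grained model, predict which construct
combinations phase separate and at what concentration?

The package provides, for computational and experimental biophysicists:

- **A lattice Monte Carlo engine** for two-species mixtures of
  sticker–spacer chains on a periodic cubic lattice. Each SH3 domain and
  each PRM is a sticker bead; linkers become spacer beads (one per six
  residues). Sticker pair energies are ΔG = −RT ln(1/K_D) at T = 310 K;
  isotropic energies are zero. Nine move kinds (rotational, local,
  colocal, shake, translation, small-cluster translation, cluster
  translation, pivot, double pivot) at fixed per-attempt frequencies,
  with exact detailed balance — validated against a brute-force
  enumeration oracle.
- **Phase diagnostics**: radial density profiles, the global density
  inhomogeneity parameter (GDIP; > 0.025 flags phase separation), and
  the percolation value (fraction of molecules in the largest
  bond-connected cluster).
- **A shared saturation-concentration estimator** for both arms: the
  order parameter y (GDIP, percolation value, or the dispersion index
  σ²/µ of 16-bit fluorescence images) is fitted with the logistic
  y = H/(1+e^(−k(x−x₀))) + C, and the saturation concentration is the
  maximum of the fit's second derivative,
  **φ = x₀ − ln(2+√3)/k**, with bootstrap errors from per-concentration
  resampling.
- **Synthetic data generators** for every input — K_D tables, settled
  droplet image series with a known ground-truth φ, logistic series —
  so the entire pipeline is testable without any raw study data.

## Worked example

Parameterize from the packaged affinity table, build a construct, and
recover a known saturation concentration through the imaging arm:

```python
import phasesep as ps

kd = ps.make_kd_fixture()              # 21 SH3 x PRM dissociation constants
em = ps.build_energy_matrix(kd)
ps.delta_g(6e-6)                       # -> -7.41  (kcal/mol, strongest pair)
em.energy("SH3B", "PRM4")              # -> -7.41

topo = ps.build_topology("CIN85-BBB")  # 29 beads, stickers (SH3B, SH3B, SH3B)

# synthetic microscopy series: 8 concentrations x 15 images around
# phi_true = 6.7 uM, then DI -> logistic fit -> phi with bootstrap error
records, _ = ps.generate_di_dataset(phi_true=6.7, seed=42)
series = ps.build_di_series(records)
fit = ps.estimate_phi_exp(series, B=500, seed=1)
print(fit.summary())
```

```
Saturation concentration fit (logistic + 2nd-derivative max)
  value kind:      DI
  n observations:  120
  fit success:     True
  H = 115.124   C = 1.90275
  k = 0.858304   x0 = 8.38765
  rss = 79928.1   F = 161.1   p = 3.4e-41
  phi = 6.85328
  phi bootstrap SE = 0.2762  95% CI = (6.33959, 7.43945)  B = 500
```

The fitted φ_exp = 6.85 ± 0.28 µM covers the ground truth (6.7 µM): H
and C are intensity-scale parameters, x₀ is the transition midpoint, and
φ sits on the onset shoulder, ln(2+√3)/k below x₀.

Simulation arm, scaled down (minutes, not days):

```python
mix = ps.MixtureModel.from_constructs("SLP65_1-330", "CIN85-BBB",
                                      n_per_species=100)
scan = mix.scan(seed=11)               # box series -> GDIP + percolation
fit = scan.fit_phi("percolation")      # logistic fit on the rising branch
fit.bootstrap(B=300, seed=12)
print(fit.phi, fit.phi_se)             # ~501 +- ~84 micromolecules/LU^3
```

At this reduced scale the bivalent CIN85-AB mixture phase separates at a
several-fold higher concentration than trivalent CIN85-BBB — the valency
ordering that, at full scale, shows up as the AB/BBB ratio 20.2 — while
CIN85-ABC and CIN85-BBB are indistinguishable within bootstrap error.
The full-scale preset (`preset="paper"`: 1,000 molecules per species,
2×10⁹ steps, boxes 85–900) reproduces the published regime but needs
days per scan on one CPU.

A command-line interface wraps the same stages:

```
phasesep simulate --construct-a SLP65_1-330 --construct-b CIN85-BBB \
         --box 60 --steps 1000000 --seed 1 --out snaps.csv
phasesep analyze snaps.csv --out metrics.csv      # per-snapshot GDIP/percolation
phasesep scan --construct-b CIN85-BBB --preset desk --seed 1 --out scan.csv
phasesep fit-phi scan.csv --value-kind percolation --out fit.json
phasesep synth images --phi-true 6.7 --outdir imgs/
phasesep di imgs/manifest.csv --out di.csv
phasesep run --config pipeline.yaml --outdir results/
```

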