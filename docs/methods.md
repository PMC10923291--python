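# Methods

`phasesep` models the phase separation of two multivalent binding
partners — the B-cell adaptor SLP65, whose disordered region carries six
proline-rich motifs (PRMs), and CIN85, whose three SH3 domains bind those
motifs promiscuously — as a sticker-spacer system on a cubic lattice, and
pairs the simulation with the microscopy-side analysis (dispersion indices
of fluorescence images) through one shared saturation-concentration
estimator.

## The lattice model

**Architecture.** Each construct is a linear bead chain. Every SH3 domain
and every PRM is one *sticker* bead; the disordered segments between them
become *spacer* beads, one bead per six residues by default (a PRM is six
residues long and occupies one lattice site, which fixes the length
scale). Fractional spacer lengths round to the nearest integer, ties to
even. The packaged construct table (`data/constructs.yaml`) covers
SLP65_1-330, SLP65-3xPRM4, SLP65-R247A (PRM4 bead present but
binding-inert), CIN85-ABC, CIN85-AB, CIN85-BBB and CIN85-ABC-DM; the
linker residue counts are editable approximations of the real
inter-domain segments. CIN85-ABC-DM shares CIN85-ABC's topology because
the intramolecular SH3C-PRM1 interaction is deliberately outside the
lattice model; comparing the two is precisely what exposes that
interaction's effect. CIN85's own PRM1 motif ("PRM1*") is a defined
sticker kind with measured affinities but excluded from default
topologies for the same reason.

**Energies.** The only configurational energy is the anisotropic bond
energy between sticker pairs, dG = -RT ln(1/K_D) with R = 1.987e-3
kcal/mol/K and T = 310 K; isotropic (nonspecific) contact energies are
zero. The packaged 21-pair K_D table anchors the printed values (6 uM for
SH3B-PRM4, ~4 mM for the weakest PRM2 pair, 720/1140/210 uM for PRM1*
against SH3A/B/C) and fills the remaining pairs with ranking-consistent
values flagged `approx=true` in the CSV; replace the file to use exact
measurements. Sampling uses beta = 1/(RT) at the same temperature, so
parameterization and simulation temperatures coincide.

**Geometry and moves.** Simple cubic lattice, periodic boundaries, at
most one bead per site. "Adjacent" means the 26-site Moore neighborhood,
for chain connectivity and bond eligibility alike. Each sticker holds at
most one bond, only with partners whose energy-matrix entry is nonzero.
Nine move kinds run at per-attempt frequencies 0.25 (rotational), 0.13
(local), 0.25 (colocal), 0.04 each (shake, translation, small-cluster
translation, cluster translation), 0.13 (pivot), 0.10 (double pivot); the
printed set sums to 1.02 and is renormalized. One step is one attempted
move.

Bond changes are confined to the single-bead moves (rotational, local,
shake): the move proposes a position and simultaneously redraws the
bead's bond uniformly from {unbonded} + {eligible neighbors}, with the
Hastings factor |S_fwd|/|S_rev| in the acceptance probability. When the
spatial proposal is geometrically blocked, the bond redraw still runs in
place — without this, bond exchange in dense clusters stalls by orders of
magnitude. All multi-bead moves (colocal pair shifts, molecule and
cluster translations, pivots) preserve the bond list exactly and reject
any proposal that would separate a bonded pair; the popular alternative
of letting spatial moves silently break out-of-range bonds violates
detailed balance (the reverse move cannot re-form the bond) and was not
used. Cluster translations are capped at 64 molecules by default — the
cap is a symmetric, size-based rejection, so reversibility is unaffected,
and translating a box-spanning cluster accomplishes nothing physically.

**Correctness.** The sampler is validated against an exhaustive
enumeration oracle (`enumerate_tiny_system`): for systems of up to two
chains of two beads, all placements x bond pairings are enumerated with
exact Boltzmann weights, and the Monte Carlo bond-class frequencies are
required to match (chi-square) along with the mean energy. Incremental
energy bookkeeping is checked against full recomputation on every
recorded snapshot.

## Phase diagnostics

**Radial density and GDIP.** The radial bead-density profile is measured
about the minimum-image center of mass of the largest bonded cluster
(circular mean per axis), or about the locally densest bead when no bonds
exist; both reference rules are exactly equivariant under global
translation. Bin "volumes" are exact lattice-site counts per shell, so
mass conservation is exact, and the a-priori reference profile is the
analytic uniform density (a zero-energy control run converges to it; one
can be supplied instead). The global density inhomogeneity parameter is
the L2 divergence between the observed and reference radial mass
fractions,

    GDIP = sum_b (p_b - q_b)^2 = sum_b q_b^2 (rho_hat_b - 1)^2,

with p_b the observed bead fraction in shell b, q_b the reference
(volume) fraction and rho_hat the normalized density. It is 0 for a
uniform profile, crosses the conventional 0.025 phase-separation
threshold when roughly a sixth of the material is co-located, approaches
1 for a compact condensate, and decays again when the whole box turns
dense. A shell-volume-weighted chi-square-style divergence
(sum q_b (rho_hat_b - 1)^2) was rejected: it diverges on any small dense
cluster at low bulk density, making it unusable as a rising order
parameter.

**Percolation value.** The fraction of all molecules in the single
largest bond-connected cluster (union-find over the molecule graph);
1/N with no bonds, 1 when the network spans all molecules.

**Which diagnostic carries the transition depends on scale.** At full
scale (1,000 molecules per species, 2e9 steps, boxes 85-900) dense
droplets with a dilute background give GDIP its signal. At the reduced
scale this package uses for routine runs, the transition moves to much
higher lattice concentration and the dense phase is a box-filling
network with no radial density contrast: GDIP stays low and featureless
while the percolation value rises sigmoidally. Saturation concentrations
at reduced scale are therefore fitted on the percolation series — the
standard fallback wherever a transition occurs at concentrations too high
for GDIP to resolve a density contrast.
A corollary: GDIP and percolation are *not* co-monotone in concentration
at reduced scale (GDIP falls as percolation rises), so that property is
not asserted there.

## Saturation-concentration fitting

Both arms fit the four-parameter logistic y = H/(1+exp(-k(x-x0))) + C by
least squares (scipy `curve_fit`, analytic Jacobian; initialization from
the data: C = min, H = range, x0 at half-rise, k from the central finite
difference of the group means). The saturation concentration is the
location of the maximum of the fitted curve's second derivative, which
has the closed form

    phi = x0 - ln(2 + sqrt(3)) / k,

the onset shoulder of the rise. Percolation-value fits constrain the
plateaus to the order parameter's physical range (H <= 1.2, 0 <= C <= 1);
without these bounds a half-observed sigmoid is badly ill-conditioned.

A fit is declared a failure — mirroring mixtures whose saturation
concentration could not be fitted up to the highest measured
concentration — when (i) the optimizer does not converge, (ii) H or k is
not positive, (iii) an F-test cannot reject a constant model at p = 0.01,
or (iv) the fitted midpoint x0 lies above the measured range.

**Bootstrap.** Uncertainty comes from resampling the per-concentration
replicate values with replacement (by default all of them: 15 dispersion
indices or 3 GDIP/percolation values per point), refitting, and taking
the standard deviation and the 2.5/97.5 percentiles of phi over B = 5,000
repetitions (smaller B is used in tests and the acceptance script; the
estimate is insensitive to B beyond a few hundred). If more than 20% of
refits fail the error is flagged unreliable.

## Imaging arm

The dispersion index of a 16-bit grayscale image is the population
variance over the mean of all pixels: ~1 for a Poisson-limited
homogeneous image, >> 1 when bright settled droplets are present, 0 for a
constant image and undefined for an all-zero one. Only the surface plane
(lowest z tag per stack) of each image stack enters the analysis — that
is where settled condensates live — and 15 images per concentration point
is the expected design. No background subtraction or saturation masking
is applied; a warning fires when more than 0.1% of pixels sit at 65535.

## Synthetic data

The droplet-image generator emulates settled condensates on a microscopy
slide: Poisson-distributed bright discs (log-normal radii) on a uniform
background, Gaussian optical blur, then Poisson shot noise. The expected
droplet count follows a logistic in concentration whose location is
chosen as x0 = phi_true + ln(2+sqrt(3))/k, so the resulting DI curve's
*onset* sits at the ground-truth saturation concentration. The defaults
(16 droplets maximum of radius ~2 px on a 128x128 image; 600-count
background vs 3,000-count droplets) keep droplet coverage ~1% so the
image mean is nearly concentration-independent — this is what makes E[DI]
linear in droplet count and hence logistic in concentration; denser
fields bias the recovered phi low. The generator reproduces none of the
optics beyond that (no fluorophore photophysics, no vesicles, no focal
drift), so passing recovery tests demonstrate the correctness of the
pipeline's estimator, not robustness to real acquisition artifacts.

`generate_logistic_samples` provides plain noisy logistic series for
fit-recovery experiments, and `make_kd_fixture` the packaged affinity
table.

## Reduced-scale study conditions

Routine scans use 100 molecules per species and 2e7 attempted moves per
run, three replicates per box. Box edges are 96/76/60/48/38 lattice units
for trivalent CIN85 constructs (concentrations ~226-3,645 micromolecules
per lattice-unit^3) and 56/42/34/28/24/22 for the bivalent CIN85-AB
(~1,139-18,783), whose transition sits roughly an order of magnitude
higher. Boxes smaller than the longest chain are legitimate — the chain
wraps the periodic box — and are required to reach the bivalent
transition. At this scale the absolute phi values are far above the
full-scale ones (hundreds versus ~10 micromolecules per lattice-unit^3):
small systems favor closed stoichiometric complexes — CIN85-BBB's three
SH3B domains can fully satisfy one SLP65's three strong motifs — so
network formation needs a higher driving force. The *ordering* is the
robust observable and the one the package asserts: bivalent CIN85-AB
phase-separates at several-fold higher concentration than trivalent
CIN85-BBB (full-scale ratio: 20.2), while CIN85-ABC and CIN85-BBB are
statistically indistinguishable (full-scale: 10.9 vs 9.1). The
`paper`-scale preset (1,000+1,000 molecules, 2e9 steps, boxes 85-900) is
available but takes days per scan on one CPU.

## Numerical notes and limitations

- All randomness flows through explicit seeds (numpy `SeedSequence` for
  derived per-replicate seeds, which are logged in scan tables); equal
  seeds give byte-identical snapshot streams.
- Initial states are self-avoiding random walks with bounded retries; a
  box that cannot pack raises with a suggestion to enlarge it, and a scan
  records the failure and continues.
- Radial profiles default to 30 bins; shell site counts are cached per
  (box, bins).
- The engine equilibrates by bond exchange through the weaker pairs; the
  strongest pair (SH3B-PRM4, 12 kT) is quasi-permanent on desk-scale run
  lengths. Scan averages use the second half of each run's snapshots, and
  residual equilibration drift at the most dilute boxes is visible as
  replicate scatter — it is absorbed by the replicate-level fit and the
  bootstrap.
- Desk-scale phi values are *not* comparable in absolute terms to
  full-scale ones (different system size, different order parameter
  regime); only directions and ratios are.
- The spacer linker lengths approximate the real constructs; exact
  per-linker residue counts can be dropped into `constructs.yaml` without
  code changes.
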