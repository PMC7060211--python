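# Methods

`fretdyn` implements the quantitative core of a hybrid fluorescence
workflow for resolving short-lived conformational states of a protein in
solution: simulate single-molecule FRET experiments over a kinetic
network, analyze them by burst-wise multiparameter detection (MFD) and
filtered FCS, resolve limiting states by ensemble TCSPC decay fitting,
invert the kinetic network, screen candidate structures with geometric
dye models, and propagate a full distance-uncertainty budget. This note
records the models, the defaults and why, the numerical choices, and the
known limits of the synthetic data.

## Photon-stream simulation (`photon_sim`)

**Model.** Point molecules diffuse by Gaussian displacement steps in a
periodic box (half-lengths 2.5 x 2.5 x 5 um) around a 3D Gaussian
detection profile `W(r) = exp(-2x^2/w_xy^2 - 2y^2/w_xy^2 - 2z^2/w_z^2)`.
Conformational state switching follows a continuous-time Markov chain on
a linear three-state network; dwell times in state *i* are exponential
with the total exit rate. Detected photons are an inhomogeneous Poisson
process with rate `Q_s W(r)` for state *s*; each photon draws a TCSPC
micro-time from the state's donor lifetime (acceptor photons add an
acceptor-lifetime delay), jittered by a Gaussian instrument response and
wrapped onto 4096 channels of the 32 ns excitation period.

**Key defaults and rationale.**

| parameter | default | why |
|---|---|---|
| `w_xy_um`, `w_z_um` | 0.5, 2.0 | typical one-photon confocal volume |
| `diffusion_um2_per_ms` | 0.115 | a ~19 kDa protein; gives t_diff = w_xy^2/(4D) = 0.54 ms |
| `brightness_khz` | 100 per state | typical molecular brightness at the focus |
| time step | `(w_xy/20)^2 / 2D` (~2.7 us) | rms displacement <= w_xy/20, so the detection profile is well sampled |
| `rep_period_ns` / channels | 32 / 4096 | common TCSPC hardware; > 99.9% of a 4 ns decay fits the period |
| donor lifetime / acceptor lifetime | 4.0 / 1.0 ns | green/red dye pair in the Alexa488/647 class |

State switching *within* a diffusion step is resolved exactly by
thinning: candidate photons are generated at the maximum state
brightness and accepted with probability `Q_s(t)/Q_max` using the exact
state at the photon time, so few-microsecond kinetics are not aliased by
the (larger) diffusion step. Seeding uses one master `SeedSequence` with
deterministic per-molecule children; the same seed reproduces a stream
bit for bit.

For the all-rates-positive linear chain the embedded jump chain has a
closed structure (every second visit is the middle state), which the
generator exploits to draw whole trajectories vectorized; the generic
Gillespie loop remains as fallback for absorbing or partial networks.

**What the generator does not emulate:** triplet blinking,
photobleaching, saturation, polarized excitation modulation, detector
dead time and afterpulsing, spectral crosstalk by default (configurable),
and an infinite sample reservoir — the periodic box conserves molecule
number, which produces re-entry correlations at lags far beyond the
diffusion time (see the fFCS fitting window below). Passing tests on
this generator therefore validates the estimators under ideal
photophysics, not robustness to those artifacts.

## Ensemble decay analysis (`decay_fit`)

**Model.** The FRET-induced donor decay for a mixture of conformers,
each with a normal distance distribution `p_i(R) ~ N(<R_i>, w_i)`
truncated to R >= 1 A:

    F(t) = x_D0 f_D(t) + (1 - x_D0) sum_i x_i Int p_i(R) f_D(t) e^{-t kFRET(R)} dR
    kFRET(R) = (1/tau_D0) (R0/R)^6,   f_D(t) = sum_m a_m e^{-t/tau_Dm}

with `tau_D0` the species-averaged donor-only lifetime and kappa^2 = 2/3
assumed for R0. The distance integral uses 441 equidistant quadrature
points over `<R> +/- 5w` (verified against adaptive quadrature to 1e-4
relative; on uniform time grids the exponential table is built by a
cumulative product, which is exact and ~4x faster than repeated `exp`).
The instrument model is iterative reconvolution: `IRF (*) F` plus a
scatter fraction of the IRF and a constant background, with an optional
sub-channel IRF shift; the amplitude is solved analytically by
Poisson-weighted projection.

**Fitting.** Weighted least squares with sigma = sqrt(max(counts, 1)),
all channels retained. Parameters live in log/logit space with bounds
(R in [5, 150] A, w in [0.3, 60] A); species fractions are shared across
datasets through softmax logits, distances and widths stay per dataset,
the donor-only fraction is per dataset. Cold starts run latin-hypercube
restarts (default 8) and each restart is two-stage: first the
distance/fraction skeleton with widths clamped, then everything free —
the full problem has collapsed-width local minima that the staged start
avoids. Components are sorted by mean distance to break label switching.

**Uncertainty.** Support-plane analysis profiles one parameter while
re-optimizing the rest (warm-starting along the scan), with the
confidence threshold
`chi2_thresh = chi2_min [1 + p/(n-p) F_{1-a}(p, n-p)]`, p = free
parameters, n = fitted channels. This convention is deliberately
conservative (it charges the full parameter count, not one degree of
freedom), matching how global multi-dataset analyses in this field quote
intervals; the asymmetric statistical distance errors are the shortest
and longest distances below the 1-sigma threshold. `profile_at` decides
region membership for a single value by walking the profile there — the
value is inside the region iff its profiled chi2r stays below the
threshold. MCMC sampling of the Poisson likelihood (emcee) is available
for single datasets; the global problem has too many degrees of freedom
for exhaustive sampling, which is exactly why the support-plane route
exists.

A deliberate property of this analysis, reproduced by the tests: a
*single* decay only weakly identifies a three-component model — point
estimates wander across statistically equivalent solutions while the
support-plane regions remain honest (they cover the generating values at
better than nominal rate). Sharing fractions across many datasets is
what pins the model down; a 1-component fit of three-conformer data
reports an unphysically broad width, the standard rejection signature.

## Burst analysis and FRET-lines (`burst_mfd`)

Burst search: a photon is kept when >= L = 10 neighbours fall in a
centred T = 120 us window; consecutive kept photons form a burst,
bursts under 60 photons are dropped (typical MFD settings; all
configurable). Per burst, `E = F_A / (F_A + gamma F_G)` after background
subtraction and alpha-crosstalk correction, and the donor lifetime is a
maximum-likelihood single-exponential fit over a micro-time window that
excludes the IRF rise; the expected uniform background inside the window
enters the likelihood as a flat mixture component (without it the
lifetime is biased high by tens of percent at single-molecule
backgrounds).

Static FRET-line: the locus of single conformers, linker-broadened with
a Gaussian of width sigma_link (default 6 A); E uses the species-averaged
lifetime while the abscissa is the fluorescence-weighted
`<tau>_F = <tau^2>/<tau>`, so the line bends right of the naive diagonal.
Dynamic FRET-line between two exchanging states: eliminating the species
fraction from the first two lifetime moments gives
`<tau>_x = tau'_1 tau'_2 / (tau'_1 + tau'_2 - <tau>_F)`. Populations in
fast exchange sit on this line, right-shifted from the static line — the
model-free dynamics indicator. Histogram comparison between burst sets
uses a chi-square distance with a pooled-bootstrap null (a bootstrap
analogue of a permutation test), which is calibrated (p ~ uniform under
the null) and rejects mismatched kinetic solutions.

## Filtered FCS (`ffcs`)

Species filters are the weighted least-squares construction
`w = (M^T D M)^-1 M^T D`, `D = diag(1/total)`, over the flattened
(detector x micro-time) axis, scaled so the filtered sum counts species
photons; unbiasedness (`w_i . expected_j = delta_ij N_j`) is enforced to
1e-8 and rank-deficient pattern sets raise an error naming the most
collinear pair. Correlation uses a multiple-tau accumulator (16 lags per
cascade, doubling bin width) on photon-weight traces binned at 1 us;
per-lag noise is the standard deviation over 8 stream segments.

The fit model is the standard 3D-Gaussian diffusion term times a
kinetic sum, `G = (1/N)(1+t/td)^-1 (1+t/(s^2 td))^-1/2 (1 + sum A_i
e^{-t/tRi}) + offset`, relaxation times shared globally, sCCF amplitudes
negative (anti-correlation). Two systematic effects are handled
explicitly. First, multiple-tau accumulator bins average the kinetic
exponential over their width; each curve carries its per-lag bin width
and the model applies the exact factor `(sinh(x)/x)^2`,
`x = width/(2 t_R)` (up to ~20% at the coarsest cascades carrying a
10 us relaxation — ignoring it fabricates a phantom second component).
Second, fits can bound the lag window (the module-comparison tests use
4 ms, about seven diffusion times): beyond that the periodic simulation
box produces re-entry correlations outside the diffusion model. Nested
models are compared by an F-test; a two-state simulation never demands
a *resolvable* second relaxation — when the two fitted times collapse
within 10% of each other the fit flags the spectrum as unresolvable
rather than reporting a second component — while two resolved
relaxation times imply at least three exchanging species.

## Kinetic networks (`kinetics`)

The linear chain C1 <-> C2 <-> C3 with rates in ms^-1. Relaxation times
are `-1/lambda` over the nonzero eigenvalues of the rate matrix; the
stationary vector comes from the null space and equals the
detailed-balance chain product. Inversion from `(t_R1, t_R2, x1, x2,
x3)` reduces to a quadratic whose two roots are the two competing
kinetic solutions (they swap which state pair carries the fast
relaxation); the companion root is computed product-stably, double roots
within 1e-6 are merged, and the fast-C1C2 solution is listed first. The
cyclic topology is representable but refused by the inversion — two
relaxation times under-determine it. Free-energy landscapes use
`dG0 = -kBT ln(k_back/k_forward)` per transition and activation energies
`-kBT ln(k/k0)` against an arbitrary prefactor (default k0 = 1e3 ms^-1),
in kBT units.

## Dye modelling and screening (`dye_screen`)

Accessible contact volumes (ACV) on a grid (default spacing 0.9 A):
clearance to the protein surface per cell from a KD-tree over heavy
atoms with per-element van der Waals radii; linker paths are Dijkstra
shortest paths through cells with clearance >= half the linker width,
seeded at the attachment atom, bounded by the linker length; each of the
three dye radii contributes a third of the density where its clearance
allows. The attachment residue is removed from the obstacle set (the
label replaces its side chain). The contact shell — cells within 3 A of
the surface — is re-weighted so its total weight equals the trapped-dye
fraction `x_trapped = r_inf/r_0`. Dye geometries default to the
Alexa488 (L = 20 A, width 4.5 A, radii 5/4.5/1.5 A) and Alexa647
(L = 22 A, width 4.5 A, radii 11/3/3.5 A) parameters.

Between two clouds: `R_mp` is the distance of mean positions, `<R_DA>`
the weight-averaged pair distance (what a lifetime measurement reports;
always >= R_mp), `<E>` the pair-averaged isotropic point-dye efficiency.
The exact double sum is used up to 4e6 pairs, beyond that a fixed-seed
weighted Monte-Carlo sample of 2e5 pairs (error ~0.02 A, far below the
0.5 A grid convergence). An empirical cubic `R_mp <-> <R_DA>` conversion
can be calibrated from simulated cloud pairs. Screening computes
`chi2_r,FPS = (1/N) sum (R_exp - R_model)^2 / dR_tot^2` per state and
structure, choosing the asymmetric uncertainty side by the residual sign
(dR_plus when the model overshoots); missing residues are skipped with a
warning and N reduced. Structure ensembles are organized by
complete-linkage clustering on pairwise Calpha RMSD after Kabsch
superposition (default cutoff 1.8 A), with medoid representatives.

## kappa^2 and the distance uncertainty budget (`fret_uncertainty`)

Residual anisotropies give second-rank order parameters
`S = sqrt(r_inf/r_0)` per dye. For each Monte-Carlo sample both cone
axes are drawn uniformly on the sphere and the fast wobbling inside the
cones is averaged exactly through second moments:

    <kappa^2> = Tr[ M_D A M_A A ],  A = I - 3 RR^T,
    M_X = (1-S_X)/3 I + S_X a_X a_X^T

(exact because kappa^2 is quadratic in each dipole). Fully mobile dyes
give kappa^2 = 2/3 identically; fully static isotropic dyes reproduce
the static distribution with mean 2/3. The kappa^2 distribution maps to
the distance ratio `xi = (3 kappa^2/2)^(-1/6)`; SD(xi) is the relative
precision, `<xi> - 1` the accuracy (near zero), and the kappa^2 term of
the budget is the precision. The total is the quadrature sum of dye-model,
kappa^2, reference and statistical terms, kept asymmetric through
dR_noise-/+; with site-specific labeling and a measured donor-only
reference the dye-model and reference terms are exactly zero. The
FRET-sensitized acceptor anisotropy is carried in the input set for
reporting; the cone sampling itself uses the donor and acceptor residual
anisotropies.

## Pipeline and fixtures (`pipeline`)

`run_pipeline` chains simulate -> bursts -> fFCS -> decays -> kinetics
-> screening -> uncertainty on synthetic data with a known three-state
ground truth (fractions 0.44/0.38/0.18, relaxation times 4 us and
230 us), records provenance (config hash, seed, versions) and aborts
downstream stages on failure while keeping partial results. Fixture
kinds: decay trios with recorded truth, photon streams, a toy
three-conformer structure ensemble (two 24-residue helical domains
joined at a hinge, pivoted by 55/35/15 degrees for open/ajar/closed),
and a 33-row distance table generated from the conformers' own ACV
distances plus 0.8 A noise with 2.5 A uncertainties.

The command-line umbrella `fretdyn` (simulate | bursts | ffcs | fitdecay
| kinetics | fps | errors | run | fixtures) is a thin layer over these
functions; photon streams travel in a Photon-HDF5-style layout or CSV,
decays as two-column text with JSON sidecars.

## Problem sizes in the test suite

The suite exercises the same estimators at reduced scale so a full run
stays practical on one CPU: decay-fit recovery uses 50 replicates of
1e7-count, 128-channel histograms with warm-started profile walks for
region membership; fFCS uses one 20 s two-state stream (~1e5 photons);
FRET-line centroids use 40 s streams (~1100 bursts each); screening uses
1.5 A grids on the toy ensemble. The acceptance script regenerates
everything from its seed at the same scales.

## Known limitations

- The decay model fits magic-angle (polarization-free) data only;
  polarized decay fitting and time-resolved anisotropy analysis are out
  of scope (anisotropy enters only as r_0/r_inf inputs).
- Distance distributions are normal per conformer; heavy-tailed or
  multimodal linker distributions are not representable.
- The ACV surface is defined by heavy-atom proximity rather than a
  solvent-excluded surface — cheaper, and consistent across the grid
  convergence checks, but contact-volume assignment near crevices is
  approximate.
- The kinetic inversion covers three states in a chain; larger networks
  or substrate-dependent (Michaelis-Menten) rate fitting are not
  implemented.
- Simulation artifacts listed above (no blinking/bleaching, periodic
  re-entry) bound what a green test suite implies about real data.
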