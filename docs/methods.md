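# Methods

## Scope and model

The package analyses sign-constrained regulatory circuits proposed for
digit–interdigit patterning: the core BMP–SOX9–WNT (BSW) model, a
WNT2/β-catenin/SFRP2 module, their SULF1 extensions, and the merged six-node
network. The biological claims it operationalizes are qualitative — which
circuits can support a diffusion-driven (Turing) instability, by which
classical mechanism, and with which species in or out of phase — so the
kinetic closure is deliberately minimal.

About the homogeneous state, each species deviation `u_i` obeys

    du_i/dt = Σ_j A_ij u_j − s u_i³ + D_i ∇²u_i,     A = S − diag(decay)

with `S[i, j]` the signed strength of the edge j→i (1/time), positive decay
folded into the diagonal, diffusion `D_i ≥ 0` (length²/time; exactly 0 for
cell-autonomous species), and a cubic self-saturation `−s u_i³`. The cubic
term is the smallest bounded closure that (a) leaves `u = 0` an exact fixed
point, so zero noise stays homogeneous forever, and (b) leaves the
linearization — and hence every Turing statement — untouched. No attempt is
made to model absolute expression levels, growth of the domain, or
Hox-modulated wavelength gradients.

### Circuit transcription

The circuits' arrow lists are stored as JSON configs
(`src/digituring/circuits/`), not in code. Edges explicitly supported by the
biology are: BMP2 →+ SOX9 (interdigit BMP promotes digit-territory SOX9),
SOX9 →− BMP2 and SOX9 →− WNT2 (SOX9 restricts both to the interdigit),
WNT2 →+ β-catenin (canonical transduction) with β-catenin →− SOX9 (WNT/SOX9
mutual antagonism), SFRP2 −→ WNT2 as a diffusible extracellular antagonist,
and SULF1 →− WNT2 downstream of SOX9 (hypothetical, `tested=false`). The
three-node WNT module closes its activation loop with β-catenin →+ WNT2 and
induces its antagonist via β-catenin →+ SFRP2 — the wiring required for a
classical activator–inhibitor module with all components in-phase. (At the
level of homogeneous expression SFRP2 behaves as WNT-repressed; the circuit
as modelled treats the patterning-relevant induction as positive. This is
the one place where the transcription makes a choice the source material
leaves open.) β-catenin and SOX9 are non-diffusible; WNT2, SFRP2 and BMP2
diffuse (ligand defaults 1, antagonist/substrate defaults 30, all
overridable); SULF1 defaults to non-diffusible (it acts on cell-surface
heparan sulfates) but is config-overridable.

The six-node network is exactly `merge_topologies(wnt4, bsw5)`: node union
with shared nodes counted once, conflict-checked on diffusibility and edge
signs.

## Linear stability analysis

The dispersion relation is computed numerically: for each wavenumber k on a
grid of 256 points with k² uniform on `[0, 4·max(aᵢᵢ+decayᵢ)/min D⁺]`
(falling back to `max|A|` when self-activation runs through a loop rather
than a self-edge), the growth rate is `max Re eig(A − k² diag(D))`. The grid
argmax is refined by bounded scalar minimization between its neighbors, and
band edges by root bracketing; a band narrower than the grid spacing is
still found through the refinement step. Growth rates within 1e−9 of zero
are treated as marginal and never establish instability (near-degenerate
systems classify as `none`).

Classification: `turing_I` requires a stable homogeneous state, a finite
unstable band, and negative growth at the upper end of the grid (the grid
upper bound provably exceeds the band for these models, so "negative at the
end" is a faithful proxy for k → ∞); positive growth at the upper end gives
`turing_II` (possible only when a self-amplifying species is
non-diffusible). Complex leading eigenvalues are flagged as oscillatory and
the phase prediction uses the real part of the eigenvector, unit-normalized
with its largest-magnitude component positive; eigen-sorting ties break by
larger real part, then smaller |imaginary part|.

The mechanism call is an operational reading of the classical labels: the
node with the largest leading-eigenvector component is the local activator;
a diffusible partner that feeds it positively while patterning out-of-phase
marks **substrate depletion**, one that represses it while patterning
in-phase marks **activator–inhibitor**; when both kinds of partner exist the
more specific substrate signature wins (this also keeps the call invariant
under node relabeling); anything else is `other`. The call is metadata, not
a gate — phase claims are always checked on simulations.

For two-species systems the closed-form conditions (trace < 0, det > 0,
`D₂a + D₁d > 0`, `(D₂a + D₁d)² > 4 D₁D₂ det`, growth at the analytic optimum
`k²* = (D₂a + D₁d)/(2D₁D₂)` above tolerance) serve as an independent oracle;
the test suite requires 100% agreement with the numerical classifier on 1000
seeded random systems.

Note on the reference example `A = [[1, −1], [3, −2]]`, `D = (1, 10)`: the
unstable band is `k² ∈ [(8−√24)/20, (8+√24)/20]` exactly; the minimizer of
`h(k²)` is k² = 0.4 while the argmax of the growth rate itself is
k² ≈ 0.336. `DispersionResult.k_max` reports the latter (the mode that
actually grows fastest); both predict the simulated wavelength within the
15% band used throughout.

## Parameter discovery

Plain rejection sampling — transparent, seed-stable, and adequate at the
scale of these circuits. Magnitudes are log-uniform on [0.1, 10] (1/time),
decay on [0.1, 5] (1/time), diffusion of diffusible nodes on [0.01, 100]
(length²/time): three decades of diffusion span the stiff ratios classical
Turing systems need, and the hit rates observed for the shipped circuits
(~1–4%) confirm the ranges are neither too narrow nor wastefully wide.
Non-diffusible nodes are pinned to D = 0, never sampled. All parameters for
a run come from one seeded uniform block in C order, so the sample prefix —
and therefore the hit list — is identical across budgets with the same seed
(hit counts are monotone in `n_samples`). A cheap cascade (homogeneous
stability by one eigendecomposition, then a coarse 64-point batched
dispersion prescreen) nominates candidates; every returned hit carries a
full re-classification on the fine grid, so hits are sound by construction.

## Realizing a pattern (automated "suitable parameter values")

A Turing-compatible parameterization does not guarantee a clean periodic
pattern: hits whose unstable band spans a decade or more of wavenumber
saturate into spiky, harmonic-rich profiles whose Fourier-dominant mode can
sit at a harmonic of the stripe spacing. `workflow.realize_pattern`
therefore automates what would otherwise be a manual hunt: candidates are
simulated in order — by linear growth rate, or by band-width ratio
(`k_hi/k_lo`, "selectivity" order) when wavelength fidelity is required —
until one converges with the expected phase relations (and optionally the
predicted wavelength within 15%). Narrow-band candidates empirically pattern
at their predicted wavelength with phase correlations near ±1.

## Simulation

Semi-implicit spectral integration: reaction explicit, diffusion implicit in
transform space (FFT for periodic boundaries, DCT-II for zero-flux), which
is unconditionally stable in the stiff diffusion term. Default
`dt = 0.1/max row sum |A|`, halved up to 6 times on numerical blow-up
(|u| > 1e6). Initial condition: `noise_amplitude × N(0,1)` per species and
grid point from `numpy.random.default_rng(seed)` (default amplitude 1e−3);
trajectories are bit-reproducible given (seed, grid, dt), and the integrator
accepts a piecewise-constant schedule of interaction matrices so that a
factor-1 perturbation run is bitwise identical to an unperturbed one. Grids
need ≥16 points per axis; `choose_grid` sizes 1D domains to a whole number
of predicted wavelengths at ≥16 points per wavelength (rounded up to a power
of two). Convergence is declared when the relative L2 change per unit time
between the last two snapshots falls below 1e−3. Halving dt changes the
reference run's final field by <1% in relative L2 (tested).

Concentrations are deviations and may be negative; a shifted-positive view
exists for plotting only.

## Pattern metrics

Amplitude is the spatial standard deviation of the final profile. Dominant
wavelength is the spectrum argmax of the mean-subtracted final profile
(rFFT for periodic domains, DCT for zero-flux, radially averaged power
spectrum in 2D). Stripe count is the number of connected regions above the
spatial mean with periodic adjacency respected. Phase relations are Pearson
correlations of final profiles; calls use a ±0.3 threshold, reporting weak
correlations as undetermined rather than forcing a binary call. Only
relative phases are computable — anchoring a stripe to "digit" vs
"interdigit" identity is biological interpretation outside the model.

## Perturbation protocol

Transient WNT inhibition by a porcupine inhibitor blocks ligand secretion;
the in-silico analogue scales the targeted node's outgoing interaction
strengths by a factor (<1) during a window, leaving decay and diffusion
untouched (`scale_incoming_production` exists for receptor-side
perturbations). `plan_recovery_protocol` sizes the window from the linear
timescales: the pattern establishes for 14 growth e-foldings, collapses for
6 decay e-foldings of the perturbed model's growth rate at the pattern
wavenumber (e⁻⁶ ≈ 0.2% of baseline — far below the 20% collapse criterion
yet far above floating-point extinction, so a remnant re-seeds recovery),
then recovers for 16 growth e-foldings. Recovery is judged on amplitude and
wavelength, not stripe position: a Turing pattern re-forming after
disruption may lock in shifted or locally rearranged stripes, which the
pattern-shift score (1 − correlation between pre- and post-perturbation
profiles) reports separately. Snapshot storage is densified so the window
always contains several snapshots.

## Synthetic systems

`random_topology` generates seeded signed digraphs (each ordered pair,
including self-pairs, carries an edge with the given probability) emitting
the same types and config dialect as the hand-written circuits.
`known_answer_suite` ships five small systems — classical
activator–inhibitor and substrate-depletion pairs, an equal-diffusion stable
pair, pure decay, and a three-species loop-activation system with a
non-diffusible intermediate — whose labels the tests re-derive through the
closed-form oracle or an exhaustive dispersion scan rather than trusting.

## Problem sizes

Default analyses use: 256-point dispersion grids; searches of 10⁵ samples
for the three-node circuit and 3×10⁴ for the larger ones (hundreds of hits
each at the observed hit rates); 1D simulations on 256-point, 8-wavelength
periodic domains integrated for 240 growth e-foldings; 1000 random systems
for oracle agreement; 5×10³ samples per completion in enumeration screens.
These sizes give stable statistics for every reported quantity while a full
acceptance run completes in minutes on one CPU.

## Known limitations

- The kinetic closure is linear-plus-saturation; real regulatory kinetics
  are saturating and positive-valued. Equivalence with richer models is
  claimed only at the level of Turing-pattern existence, mechanism class and
  phase relations.
- Recovered parameter sets are *equivalents* consistent with the circuits'
  sign constraints, not estimates of in-vivo rates; none of the underlying
  rates are measured.
- Domains are static and rectangular; no tissue growth, limb-bud geometry,
  proliferation effects, or anterior–posterior wavelength modulation.
- The synthetic generator produces homogeneous, isotropic, noise-seeded
  initial conditions; real limb buds break symmetry with spatial priors, so
  passing tests demonstrate self-organization capacity, not positional
  fidelity.
- Mechanism labels for networks larger than two nodes follow the operational
  rule above; systems where patterning is genuinely distributed may
  legitimately return `other`.
- The perturbation module extends the experimental disrupt-and-recover logic
  to simulation; the corresponding wet-lab experiment was not itself
  simulated in the source analyses, so its quantitative outputs (collapse
  depth, recovery time) are model predictions, not reproductions.
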