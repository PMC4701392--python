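# Methods

## Observable reduction

**Average emission wavelength (AEW).** Tryptophan emission scans are reduced
to the intensity-weighted mean wavelength, AEW = Σλᵢfᵢ / Σfᵢ, over the full
recorded scan.  The AEW red-shifts as buried tryptophans (W74 in domain 1,
W169 in the helix bundle) become solvent exposed, and it is far less noisy
than the peak position.  It is invariant to uniform intensity scaling and
bounded by the spectral window; a spectrum with non-positive total intensity
is rejected as degenerate.

**ANS band area.** ANS fluorescence reports exposed hydrophobic surface
(the molten-globule probe).  The integrated area over the acquisition
window (450–550 nm by default) is computed by the trapezoidal rule on the
recorded grid; window endpoints falling between grid points are linearly
interpolated so the integral is exactly additive over adjacent windows.

**Mean residue ellipticity.** [θ] = θ·MRW / (10·d·c) with the path d in cm
and the protein concentration c in g/mL, giving deg·cm²·dmol⁻¹.

**Specific activity.** Argininosuccinate lyase activity is followed as
fumarate absorbance at 240 nm (ε = 2440 M⁻¹cm⁻¹).  The initial rate is the
least-squares slope of A240 versus time over an operator-selectable window
(default: the full trace, with a warning if R² < 0.98); Beer–Lambert and the
assay volume convert it to nmol·min⁻¹, normalised per mg protein.  A
negative fitted slope reports zero activity with a warning rather than a
negative rate.

**Blank correction** is pointwise subtraction of a buffer/denaturant blank
spectrum (or a native-protein control trace for turbidity), with linear
interpolation when grids differ.

## Equilibrium unfolding models

All models use the linear extrapolation method: each transition's free
energy is ΔGᵢ(D) = ΔGᵢ⁰ − mᵢ·D.  R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹ and
T = 298.15 K (RT ≈ 0.592 kcal/mol); free energies are in kcal/mol and
m-values in kcal·mol⁻¹·M⁻¹ so midpoints ΔGᵢ⁰/mᵢ come out in molar
denaturant.

The two-state model is the Santoro–Bolen form with linear native and
unfolded baselines.  It is evaluated through a logistic of the transition
free energy (`scipy.special.expit`), which cannot overflow.  The sequential
three- and four-state models weight the state signals by Boltzmann factors
of the cumulative free energies; populations are computed by a shifted
softmax (log-sum-exp) so arbitrarily large ΔG values are safe.  Intermediate
states carry flat signals; optional linear baselines attach to the end
states only.  The tetramer→monomer dissociation is fitted with the
concentration-independent two-state form, exactly as the equilibrium data
were analysed; a true T ⇌ 4M mass-action model would depend on protein
concentration and is documented as out of scope.

### Fitting

Fits are bounded trust-region least squares (`scipy.optimize.least_squares`,
method `trf`) with 20 multi-starts (seeded; the first start is the pure
data-driven heuristic so noiseless round-trips are deterministic).  Start
heuristics: baselines from the first/last concentration quartiles, the
two-state midpoint from the steepest point of the (replicate-averaged)
signal profile, multi-state midpoints from level crossings of the
normalised signal change, m-values initialised at 2 kcal·mol⁻¹·M⁻¹ with
log-normal jitter.

For the multi-state models the thermodynamic block is internally
parametrised as (mid₁, δ₂, …, m₁, …) with mid₂ = mid₁ + δ₂ and positive
lower bounds on the increments (δ ≥ 0.05 M), so the midpoint ordering
mid₁ < mid₂ < … is enforced *during* optimisation rather than checked
afterwards.  Estimates and covariance are transformed back to the
(ΔGᵢ⁰, mᵢ) scale with the analytic Jacobian of the reparametrisation.  An
increment pinned at its bound means the data cannot separate two adjacent
transitions; the fit is kept (ordering holds by construction) and flagged,
as are intermediate state signals indistinguishable from their neighbours
(two-state-shaped data fitted with the four-state model).

Global fits share the thermodynamic parameters across curves and keep
signal/baseline parameters per curve; the Jacobian's block sparsity is
declared to the finite differencer once four or more curves are fitted
jointly.  Standard errors come from the Gauss–Newton covariance at the
optimum scaled by the residual variance; a singular information matrix
raises a non-identifiability error (two-state) or flags degeneracy
(multi-state).  Unfolding and refolding branches are fitted independently
and reversibility is assessed by comparing their midpoints.

Model selection fits the 2-, 3- and 4-state sequential variants and picks
the lowest AICc (ties to fewer states); F-tests against the next-simpler
nested model are reported alongside.

## Aggregation kinetics

Turbidity rises are fitted to y(t) = y₀ + Σᵢ yᵢ(1 − e^(−kᵢt)) with one or
two phases by bounded least squares with the analytic Jacobian; two-phase
rates are reported fast-first.  y₀ is the t = 0 offset and yᵢ the
asymptotic increments, which matches the saturating rises the model
describes.  Iterations are capped at 200 function evaluations: genuine
exponential fits converge in under 20, while a two-phase model on
effectively linear data walks an unbounded amplitude/rate ridge and is
deliberately cut off (such candidates fail and drop out of model
selection).  `select_kinetic_model` compares exp1, exp2 and a straight line
by AICc, with ties resolved toward the simpler model.  ThT enhancement is
the ratio of the 475–495 nm mean intensity to a corrected zero-time
baseline — a stated convention, since only spectra are defined for this
readout.

## Structure geometry

PDB text is parsed with Biopython's `PDBParser` into a flat atom list keyed
by (chain, residue number, insertion code, atom name); author numbering is
kept verbatim.  Multi-MODEL files and ordered lists of single-frame files
both yield trajectories; frame times default to the frame index (ps).
Residue-pair tracks record the per-frame Cα–Cα Euclidean distance and a
least-squares linear separation rate over an operator-selectable time
window (default: the whole trajectory, since flat-then-rising traces such
as a late-separating diagonal pair need an explicit window choice).
Interface contacts use a distance-only donor/acceptor heuristic — all
cross-chain nitrogen/oxygen pairs within a cutoff (default 3.5 Å) — which
suffices for listing hydrogen-bond candidates without angular geometry.

## Synthetic data

Generators are deterministic given their seed and embed the complete ground
truth in output metadata.  Noise is homoscedastic Gaussian on the
observable (AEW in nm, band area, A360), the simplest model consistent with
replicate scatter in this kind of experiment; heteroscedastic options are
deferred.  Default truths are the published thermodynamic tables:
two-state ΔG⁰ = 6.5 kcal/mol, m = 3.8 (urea; signals 350 → 355 nm) and
four-state ΔG = 1.3/2.6/8.9, m = 2.1/1.2/2.3 (GdmCl; signals
348/352/354/357 nm); aggregation rates 0.14 and 4×10⁻⁴ min⁻¹.

Emission spectra are sums of per-state Gaussians (σ = 10 nm on a
300–410 nm grid) whose centres interpolate 335 → 355 nm, the typical
buried→exposed tryptophan shift; with equal widths and amplitudes the AEW
of the composite equals the population-weighted mean of the centres, so the
generator's target AEW is exact up to window truncation (< 0.05 nm).

The toy tetramer places chains A–D on a 40 Å square — A–C/B–D the primary
dimers, A–B/C–D the diagonal pairs — with marker residues (182, 237, 302,
312, 313, 315, 330) whose interface Cα pairs sit at prescribed distances
along coordinate axes, so rigid chain translation along the axis changes
the pair distance at exactly the chain speed; one NZ···O pair at 2.9 Å
provides a hydrogen-bond fixture.  These toys exercise bookkeeping and
estimator correctness, not structural realism: real interfaces have
thousands of atoms, curved separation paths and thermal noise, so passing
tests validate the measurement pipeline, not any force field.

## Recovery benchmarks

`crystfold.recovery` generates 50 replicate noisy datasets from the
published truths (σ = 0.2 nm on curves; 2 % of amplitude on turbidity) and
recovers the generating parameters.  Replicates of the unfolding
experiments are pooled into one joint fit with a single shared parameter
set: replicates are repeated measurements of the same protein, so the state
signals as well as the thermodynamics are common, and pooling avoids both
the heavy-tailed per-curve estimates of the weakly identified middle
transition (signal step 2 nm, m₂ = 1.2 giving a ~2 M-wide transition) and
the incidental-parameter bias that per-replicate nuisance signals would
introduce.  Aggregation traces are fitted independently and the rates
averaged, since a single trace fully identifies its rate.  Problem sizes
(50 replicates, 17–25 point grids, 61-point traces) keep each protocol in
the seconds range on one CPU.

## Known limitations

* The LEM fits assume a single homoscedastic noise scale per curve;
  weights are per-curve, not per-point.
* Oligomer dissociation is treated as concentration-independent; no
  mass-action T ⇌ 4M model.
* Contact detection ignores hydrogen-bond angles and hydrogens.
* The ThT readout is a band-ratio convention; no fibril-mass calibration.
* Synthetic spectra are idealised Gaussians; real tryptophan spectra are
  asymmetric and probe-dependent.
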