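# Methods

`trxss` models time-resolved x-ray solution scattering (TR-XSS) from an
integral membrane protein inside a detergent micelle.  This note records the
model, the numerical choices, what the synthetic fixtures do and do not
emulate, and the design decisions taken where the design was genuinely open.

## Scattering model

For atoms with in-vacuo form factors `f_j(q)` at positions `r_j`, the
isotropic solution intensity is the exact rotational average of `|F(q)|²`
over molecular orientations (the Debye formula):

    S(q) = Σ_i Σ_j f_i(q) f_j(q) · sin(q r_ij)/(q r_ij),

with `q = 4π sin θ / λ` (Å⁻¹).  Form factors use the standard four-Gaussian
(Cromer–Mann) parameterization from International Tables Vol. C, rescaled
multiplicatively (by < 0.2 %) so that `f(0)` equals the integer electron
count exactly — downstream identities (`S(0) = (Σe)²`, forward-phase
coherence = 1) then hold to machine precision.  Hydrogens are explicit
atoms; no united-atom merging.  All intensities carry an arbitrary overall
scale (the sample's molecule count), absorbed by the fit amplitudes.

Two evaluation paths exist.  The direct double sum is the oracle.  The
production path histograms pair distances per element pair (default bin
0.05 Å) and evaluates the sinc transform at each bin's **mean** distance,
which is exact for singly occupied bins and second-order accurate
otherwise.  At the default bin width the worst-case pointwise deviation
from the direct sum on a ~450-atom system is ≈ 0.03 % for q ≤ 2 Å⁻¹
(≤ 0.13 % across the geometries we exercise); convergence to the direct
sum as the bin shrinks is monotone and reaches < 10⁻⁶ relative at 10⁻³ Å.

## Protein–micelle cross term

Writing the combined amplitude as `F_pm = F_p + F_m`, rotational averaging
gives

    S_pm = S_p + S_m + 2 cos Φ_pm √(S_p S_m),

which *defines* the phase-coherence curve `cos Φ_pm(q)`: 1 at q = 0 (all
forward scattering in phase), decaying in magnitude as coherence is lost.
Where `S_p·S_m = 0` (pathological synthetic inputs only) the value is set
to 0 and flagged.

A first-order expansion of a change in `S_pm` produces three terms — a
protein term, a micelle term, and a coherence term; the package computes
all three plus the exact difference, and its tests verify the expansion
error shrinks quadratically with the displacement amplitude.  Because
unrestrained detergents fluctuate grossly between snapshots, the micelle
term would swamp any naive difference.  The micelle-swap protocol cancels
it *exactly*: each protein ensemble is paired with both micelle ensembles,

    ΔS_pm = ½ (S_{p_exc m_exc} − S_{p_rest m_exc}
             + S_{p_exc m_rest} − S_{p_rest m_rest}),

with frame i of each trajectory paired with frame i of the others, and
ensemble means taken per combined system before differencing.  Micelle-only
contributions appear with both signs within each micelle-matched pair and
drop out identically; the surviving cross-term changes are the signal the
protocol exists to capture.

## Helix displacement targets

Candidate conformations are built from per-residue Cα difference vectors
between deposited structure pairs:

    Cα → Cα + γ·ΔCα_EF + δ·ΔCα_C + ΔCα_G,

with the helix-G amplitude fixed at 1 (its motion is tied to chromophore
isomerization; freeing it would invite overfitting).  Displacements are
taken in the deposited frame without re-superposition (the relevant pairs
are isomorphous); a least-squares superposition flag exists but defaults
off.  Side-chain and backbone atoms of a displaced residue are carried
rigidly with their Cα shift — only Cα atoms are restrained upstream, and
rigid carry is the simplest reproducible rule.  Residues whose density is
too poor to trust (e.g. a disordered loop) are filled by interpolation
between the nearest reliable residue on each side with weights inversely
proportional to sequence distance, i.e. a linear ramp across a contiguous
block.  Spans are inclusive and follow author numbering; alternate
locations resolve to the highest-occupancy conformer.

## Solvent-excluded volume

The displaced solvent scatters with opposite sign,
`|F_tot|² = |F_pm − F_solv|²`, giving

    S_tot = S_pm + S_solv − 2 cos Φ_solv √(S_pm S_solv).

`S_solv` is computed from explicit waters selected from an independent bulk
water box: whole molecules with any atom within a cutoff (2 Å working
value) of any protein or micelle atom, never splitting a molecule.  The
over-count from waters protruding beyond the surface is removed by counting
selections at several radii (1–4 Å), extrapolating the least-squares line
back to radius 0, and rescaling the `S_solv` amplitude by the squared count
ratio — forward scattering scales with electron count squared, so intensity
scales with the square of the count correction.  The q-dependent ratio
`S_tot/S_pm` multiplies every predicted difference curve; it is computed
once from the resting ensemble and applied to both states (both
conformations assumed equally modulated).  Below q = 0.05 Å⁻¹ the ratio is
clamped to its value there: the very-low-angle contrast is sensitive to
details of the shell construction, and the clamp prevents that region from
being amplified into the fit.

## Micelle corrections, damping, pink beam

Micelle structural fluctuations and micelle-size polydispersity produce
nearly the same low-angle correction shape (both reflect the micelle's
physical dimensions), and carrying both into a fit risks two large
amplitudes of opposite sign canceling.  A single correction curve
`ΔS_mc(q)` is therefore used: the second SVD component of swap-protocol
difference curves computed across a sweep of micelle sizes (the first
component is the mean signal; the second is the size variation).  SVD
components are orthonormal over the q grid and sign-fixed so each
component's largest-magnitude element is positive, making orientations
reproducible.

Two damping factors enter the theory curve: `exp(−B_p q²/16π²)`, a
pseudo-B-factor for residual protein disorder (with `u = √(B/8π²)` the RMS
displacement), and an erf switch

    w_m(q) = [1 − erf((q − q_pm)/Δq_pm)] / 2,   Δq_pm = 0.25·q_pm,

which turns all micelle-dependent terms off above the refinable onset
`q_pm`.  The printed form of the full model duplicates the `(1−erf)/2`
factor; the algebra is ambiguous as typeset and this package implements the
single-switch reading — one multiplicative `w_m` on the micelle bracket —
which has the correct limits at q → 0 and q → ∞.

Pink-beam data are matched by convolving predictions over the undulator
spectrum: `out(q) = Σ_E w(E)·in(q·E₀/E)` (q scales with photon energy).
The default spectrum is a Gaussian at 18 keV with 4 % FWHM on 21 points
spanning ±3σ; a measured two-column spectrum file overrides it.  A
monochromatic spectrum reproduces the input bit-for-bit and any normalized
spectrum preserves constants exactly.

## Experimental-curve processing

Absolute curves are normalized so their mean over the isosbestic window
(1.6 ± 0.05 Å⁻¹; the half-width is our documented choice) equals 1.
Outlier rejection is two-stage: absolute curves whose 2.0–2.5 Å⁻¹ mean
deviates > 10 % from the median are dropped, then difference curves beyond
3 per-q standard deviations at more than 1 % of grid points are dropped
(the per-curve aggregation rule is ours; the 3σ rule itself does not
specify one).  Laser heating is removed by subtracting a measured
IR-heating reference scaled by the closed-form least-squares coefficient

    α = ⟨ΔS·ΔS_IR⟩ / ⟨ΔS_IR²⟩  on 0.51–1.45 Å⁻¹,

which the tests confirm equals the numerical minimizer to 10⁻⁸ and is
idempotent.  Note that any component of the true signal parallel to the
heat reference inside the window is removed with it — with two kinetic
states this leaves the data exactly rank-2 but biases the recovered basis
shapes; the package makes no attempt to undo that (and the synthetic tests
therefore use in-window-orthogonal bases when asserting shape recovery).

Kinetics: state 1 is formed before the first delay and decays as
`c₁ = exp(−Δt/τ₁)`; state 2 rises complementarily (`c₂ = 1 − c₁`, with an
optional second decay only if requested).  At fixed τ the basis spectra
solve a linear least-squares problem; τ is refined by Levenberg–Marquardt
on log τ.  Unconstrained per-delay populations are also reported from a
linear fit against the refined bases, and the population crossing time is
interpolated on a log-time grid (2000 points).  Guinier analysis fits
`ln S` vs `q²`; the linearity diagnostic is the z-score of a quadratic term
(|z| > 3 flags aggregation or interparticle interference).

## Structural fitting

The theory curve for one candidate (γ, δ) is

    ΔS_theory = [S_tot/S_pm] · exp(−B_p q²/16π²)
                · ( ΔS_p + w_m·{ ΔS_pm − ΔS_p + A2·ΔS_mc } ),

convolved with the spectrum, and scored against an experimental basis
spectrum by

    R = Σ(w(q)·(A1·ΔS_theory − ΔS_expt))² / Σ(w(q)·ΔS_expt)²

on 0.15–0.9 Å⁻¹ with w ≡ 1 (no other weighting is exercised by default).
The model is linear in A1 and A1·A2, so both solve in closed form at each
grid node and q_pm; q_pm is scanned on a grid (default 0.05–0.30 Å⁻¹).
B_p defaults to 0: Cα-restrained ensemble variation already encodes protein
disorder, and freeing B_p has not improved fits.  A1 is shared between the
two states; the implementation first finds each state's independent
optimum, refines a joint A1 at that node pair, then re-evaluates both
contours at fixed A1 with A2 re-solved per node.  Per-parameter
uncertainties are the half-widths of the contour region where
R ≤ 1.25·R_min.  After fitting, the structural pairs best
Pearson-correlated with the experiment on q ≥ 0.20 Å⁻¹ are retained (100
of them by default) and summarized as mean ± sd of per-span mean Cα
displacements.

## Synthetic fixtures: what they emulate, and what they do not

The toy system reproduces the *bookkeeping* of a solubilized membrane
protein: a 7-helix bundle of 231 residues (8 heavy + 8 H atoms per
residue), a shell of 190 pseudo-detergents of 20 heavy + 28 H atoms each
(so a 190-detergent micelle carries 9120 atoms, 5320 of them hydrogen, and
outscatters the protein roughly five-fold at q = 0 by the squared electron
ratio), an optional water lattice at bulk density, Gaussian snapshot jitter
(protein 0.2 Å, the scale of restrained-simulation Cα fluctuations), and a
per-molecule random walk of detergents that makes micelle-only differences
fluctuate between trajectory segments.  It has no chemistry: no packing,
no force field, no solvation structure, no realistic form-factor mix.
Passing tests therefore demonstrate the *algebra and pipelines* — exact
micelle cancellation, correct decompositions, correct fitting machinery —
not agreement with any measured scattering curve.

The desk-scale fitting problem (`make_grid_experiment`) uses a 6 × 5
(γ, δ) grid (γ in steps of 1/6 up to 1.25, δ in steps of 1/3 up to 4/3),
12 frames per node, ~900-atom heavy-only systems, a micelle-size sweep of
20–28 detergents for the correction curve, and a truth curve assembled at
one grid node with A2 = 0.7 and q_pm = 0.2 Å⁻¹.  The unit helix motions
are deliberately orthogonal in direction (EF radial, C tangential, G
axial) with peak amplitudes 3.0 / 4.0 / 0.5 Å chosen so that one grid step
in either fitted amplitude changes the difference scattering by a
comparable, resolvable amount; with collinear motions the two amplitudes
trade off along a flat valley and δ becomes unidentifiable — a real
phenomenon in this kind of fitting, but the fixture's purpose is to test
the machinery, which requires an identifiable problem.  These problem
sizes keep the full test suite and the acceptance script each within a few
minutes on one CPU.

## Numerical choices and degenerate inputs

* Double precision throughout; curves live on explicit strictly increasing
  q grids and are linearly interpolated (flat extrapolation at edges,
  which the convolution flags implicitly by construction).
* `sinc(0) = 1` handled analytically.
* `cos Φ` where a component's intensity vanishes: defined as 0.
* Ensembles with unequal atom counts across snapshots are accepted
  (micelle sizes legitimately differ); mismatched snapshot *counts* in a
  swap quartet are an error.
* Grid-search ties break toward the first node in sorted (γ, δ) order;
  results are bit-reproducible for fixed inputs.
* The two-state fit reports non-convergence with its final residual rather
  than failing silently.

## Known limitations

* No molecular dynamics: ensembles come from files or the synthetic
  module.  No mmCIF writing, no multipole expansion, no analytic
  dummy-atom solvent model, no detector/polarization corrections, no
  azimuthal integration (the pipeline starts from 1D curves).
* The water-shell regression on the toy lattice can extrapolate to a
  negative intercept for very sparse solutes; on realistic dense shells
  the counts grow linearly in the radius as intended.  The intercept is
  used only through the squared count ratio.
* The reconciliation of the micelle damping onset with an equivalent
  B-factor is not modeled; `rms_from_B` converts B to an RMS displacement
  and nothing more.
* Whether the crystallographic EF-displacement summary span ends at
  residue 182 or 186 is ambiguous in the source structures' description;
  the package computes either on request and the acceptance check uses
  152–182.
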