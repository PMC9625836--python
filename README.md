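# trxss

Modeling difference x-ray scattering from an integral membrane protein
inside a detergent micelle.

Time-resolved x-ray solution scattering (TR-XSS) measures 1D changes in
scattering intensity ΔS(q, Δt) as a photoactivated protein moves through
its functional cycle.  For membrane proteins the measurement is
confounded by the surrounding detergent micelle, which typically contains
more atoms than the protein, scatters several times more strongly, and
fluctuates wildly — so the protein–micelle interference (cross) term must
be modeled explicitly, not ignored.  This package is for structural
biologists and beamline scientists who want to fit candidate helix motions
against TR-XSS difference spectra with the micelle handled properly.

## What it computes

* **Isotropic scattering** from tagged atomic coordinates via the Debye
  formula `S(q) = Σᵢⱼ fᵢ(q) fⱼ(q) sinc(q rᵢⱼ)`, with Cromer–Mann form
  factors and a pair-distance-histogram acceleration validated against the
  direct double sum.
* **The protein–micelle cross term** through the phase-coherence curve
  `cos Φ_pm(q) = (S_pm − S_p − S_m)/(2√(S_p S_m))` and a first-order
  decomposition of ΔS_pm into protein, micelle, and coherence terms.
* **The micelle-swap difference protocol**
  `ΔS_pm = ½(S_{p⁺m⁺} − S_{p⁻m⁺} + S_{p⁺m⁻} − S_{p⁻m⁻})`, which cancels
  micelle-only scattering changes exactly while keeping the cross-term
  response to protein motion.
* **Solvent-excluded-volume correction** from an explicit water shell:
  the ratio S_tot/S_pm applied to every predicted difference curve.
* **Micelle corrections, damping, pink beam**: SVD-derived micelle
  correction curve ΔS_mc, erf switch w_m(q) with onset q_pm, protein
  pseudo-B damping, and convolution over the undulator energy spectrum.
* **Experimental-curve processing**: isosbestic normalization, two-stage
  outlier rejection, laser-heat removal with the closed-form scale α,
  two-state kinetic decomposition, Guinier analysis.
* **Structural fitting**: assembly of

      ΔS_theory = [S_tot/S_pm]·e^(−B_p q²/16π²)·(ΔS_p + w_m·{ΔS_pm − ΔS_p + A2·ΔS_mc})

  and minimization of the R-factor
  `R = Σ(w·(A1·ΔS_theory − ΔS_expt))² / Σ(w·ΔS_expt)²`
  over a (γ, δ) grid of helix-displacement amplitudes, with A1 shared
  across the two kinetic states and contour-based uncertainties.
* **Synthetic fixtures** (first-class, tested code): toy
  protein/micelle/water systems, jittered trajectory ensembles with known
  (γ, δ), and two-state TR-XSS datasets with heat contamination — so the
  whole pipeline runs and is validated without simulations or downloads.

## Worked example

```python
import numpy as np, trxss

# a toy solubilized membrane protein: 231-residue bundle in a
# 190-detergent shell (C14H28O6-like composition)
sys_ = trxss.make_toy_system(trxss.ToySystemSpec())
print("micelle atoms:", trxss.count_atoms(sys_, "micelle"))

# protein-micelle phase coherence on a smaller heavy-atom system
small = trxss.ToySystemSpec(n_helices=7, residues_per_helix=8,
                            detergent_count=24, micelle_radius=22.0,
                            hydrogens=False, seed=1)
base = trxss.make_toy_system(small)
prot, mic = base.by_component("protein"), base.by_component("micelle")
q = np.linspace(0.0, 1.0, 51)
cts = trxss.cross_term_set(prot, mic, q)
print("cos_phi(0) = %.6f   min over grid = %.3f"
      % (cts.cos_phi.y[0], cts.cos_phi.y.min()))

# heat removal and two-state kinetics on a synthetic dataset
qd = np.linspace(0.03, 2.5, 400)
heat = trxss.default_heat_curve(qd)
m = (qd >= 0.51) & (qd <= 1.45)
ortho = lambda y: y - (np.dot(y[m], heat.y[m])
                       / np.dot(heat.y[m], heat.y[m])) * heat.y
b1 = trxss.DifferenceCurve(qd, ortho(np.sin(8 * qd) * np.exp(-qd)))
b2 = trxss.DifferenceCurve(qd, ortho(np.cos(6 * qd) * np.exp(-1.5 * qd)))
delays = np.geomspace(5e-6, 3e-2, 10)
ds = trxss.make_trxss_dataset(b1, b2, 35e-6 / np.log(2), delays,
                              heat_amplitudes=0.7, noise_sd=1e-4, seed=5)
ds.remove_heat()
dec = trxss.decompose_two_state(ds)
print("mean heat scale alpha = %.3f" % ds.alphas.mean())
print("tau1 = %.1f us, crossing at %.1f us"
      % (dec.tau1 * 1e6, dec.crossing_time * 1e6))
```

prints

```
micelle atoms: (9120, 5320, 3800)
cos_phi(0) = 1.000000   min over grid = -0.356
mean heat scale alpha = 0.700
tau1 = 50.5 us, crossing at 35.0 us
```

The micelle carries 9120 atoms (5320 hydrogen, 3800 heavy); forward
scattering from protein and micelle is fully in phase (`cos Φ_pm(0) = 1`)
and oscillates toward loss of coherence at higher angle; the planted heat
amplitude 0.7 and the 35 µs population crossing of the two kinetic states
are both recovered from the contaminated synthetic data.

A command-line interface mirrors the pipeline stages — `trxss simulate`,
`trxss swap-diff`, `trxss corrections {svd,size-sweep,convolve}`,
`trxss process`, `trxss fit` — each a thin wrapper over the functions
above; run `trxss --help` for details.

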