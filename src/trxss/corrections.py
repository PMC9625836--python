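"""Micelle correction curves, damping factors, undulator convolution.

Unrestrained detergent molecules make micelle-only difference scattering
fluctuate randomly between trajectory segments, and real samples contain a
distribution of micelle sizes.  Both effects produce nearly the same
low-angle correction shape (their length scale is the micelle diameter in
either case), so a single correction curve dS_mc(q) -- the second SVD
component of a micelle-size sweep of swap-protocol difference curves -- is
carried into the structural fit with a free amplitude.

Two damping factors enter the theory curve: a protein pseudo-B-factor
exp(-B_p q^2 / 16 pi^2), and an erf switch that turns all micelle-dependent
terms off above a refinable onset q_pm (the angle beyond which micelle
scattering changes are drowned by its disorder).

Predictions made for the nominal photon energy are compared with pink-beam
data by convolving over the undulator spectrum: q scales linearly with
photon energy, so each spectral line contributes the input curve evaluated
on a stretched q axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import erf

from .curves import DifferenceCurve

__all__ = ["UndulatorSpectrum", "CorrectionSet", "svd_components",
           "micelle_size_correction", "polychromatic_convolve",
           "erf_switch", "b_damping", "rms_from_B", "gaussian_spectrum"]


@dataclass
class UndulatorSpectrum:
    """Discretized photon-energy spectrum with normalized weights."""

    energies: np.ndarray        # keV, positive
    weights: np.ndarray         # >= 0, sum 1
    nominal_energy: float       # keV; the energy the q axis was computed for

    def __post_init__(self):
        self.energies = np.asarray(self.energies, float)
        self.weights = np.asarray(self.weights, float)
        if self.energies.shape != self.weights.shape or self.energies.ndim != 1:
            raise ValueError("energies and weights must be 1D and equal length")
        if np.any(self.energies <= 0):
            raise ValueError("photon energies must be positive")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("spectrum weights are all zero")
        self.weights = self.weights / total

    @property
    def fractional_bandwidth(self) -> float:
        """Weighted RMS bandwidth dE/E about the nominal energy."""
        mu = np.sum(self.weights * self.energies)
        var = np.sum(self.weights * (self.energies - mu) ** 2)
        return float(np.sqrt(var) / self.nominal_energy)

    @classmethod
    def load(cls, path, nominal_energy: float | None = None):
        """Two-column text (energy keV, weight); nominal = weighted peak."""
        data = np.loadtxt(path, comments="#", ndmin=2)
        e, w = data[:, 0], data[:, 1]
        if nominal_energy is None:
            nominal_energy = float(e[np.argmax(w)])
        return cls(e, w, nominal_energy)


def gaussian_spectrum(nominal_energy: float = 18.0,
                      fwhm_fraction: float = 0.04,
                      n_points: int = 21,
                      span_sigmas: float = 3.0) -> UndulatorSpectrum:
    """Single-peak pink-beam model: Gaussian at 18 keV, 4% FWHM by default."""
    sigma = fwhm_fraction * nominal_energy / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    e = np.linspace(nominal_energy - span_sigmas * sigma,
                    nominal_energy + span_sigmas * sigma, n_points)
    w = np.exp(-0.5 * ((e - nominal_energy) / sigma) ** 2)
    return UndulatorSpectrum(e, w, nominal_energy)


@dataclass
class CorrectionSet:
    """SVD decomposition of a stack of difference curves.

    ``components`` holds orthonormal curves over q (columns of U), ordered
    by singular value, sign-fixed so each component's largest-magnitude
    element is positive.  ``correction`` is the curve selected for fitting.
    """

    q: np.ndarray
    components: np.ndarray        # (nq, k)
    singular_values: np.ndarray   # (k,)
    correction: DifferenceCurve
    source: str = ""              # "fluctuation-SVD" | "size-SVD"


def svd_components(q, curves: np.ndarray, k: int | None = None,
                   source: str = "", pick: int = 0) -> CorrectionSet:
    """SVD of difference curves stacked as rows of ``curves`` (n_curves, nq).

    Left-singular vectors of the (nq, n_curves) matrix -- i.e. curves over
    q -- are returned ordered by singular value.  ``pick`` selects which
    component becomes the carried correction curve.
    """
    q = np.asarray(q, float)
    curves = np.atleast_2d(np.asarray(curves, float))
    if curves.shape[0] < 2:
        raise ValueError("need at least 2 curves for an SVD")
    if k is None:
        k = min(curves.shape)
    if k > curves.shape[0]:
        raise ValueError("k exceeds the number of curves")
    U, s, _ = np.linalg.svd(curves.T, full_matrices=False)
    U, s = U[:, :k], s[:k]
    # sign convention: largest-|element| of each component positive
    for j in range(U.shape[1]):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
    corr = DifferenceCurve(q, U[:, pick] * s[pick], label=f"dS_mc ({source})")
    return CorrectionSet(q, U, s, corr, source=source)


def micelle_size_correction(size_curves, q=None) -> CorrectionSet:
    """Micelle correction from a sweep of swap differences over micelle sizes.

    ``size_curves`` is a list of :class:`DifferenceCurve` (one per micelle
    size, e.g. 170..230 detergents in steps of 5) or an array stack with
    ``q`` given separately.  The first SVD component is the mean difference
    signal; the *second* captures the variation with micelle size and is
    returned as the correction curve dS_mc(q).
    """
    if q is None:
        from .curves import same_grid
        q = same_grid(*size_curves)
        stack = np.array([c.y for c in size_curves])
    else:
        stack = np.atleast_2d(np.asarray(size_curves, float))
    if stack.shape[0] < 3:
        raise ValueError("need at least 3 micelle sizes for a size sweep")
    return svd_components(q, stack, source="size-SVD", pick=1)


def polychromatic_convolve(curve, spectrum: UndulatorSpectrum):
    """Smear a predicted curve over the undulator spectrum.

    output(q) = sum_E w(E) * input(q * E0 / E); a monochromatic spectrum at
    the nominal energy reproduces the input exactly.  Edges are extrapolated
    flat where the stretched axis leaves the input grid.
    """
    q = curve.q
    out = np.zeros_like(curve.y)
    for e_i, w_i in zip(spectrum.energies, spectrum.weights):
        if w_i == 0.0:
            continue
        scale = spectrum.nominal_energy / e_i
        if scale == 1.0:
            out += w_i * curve.y
        else:
            out += w_i * np.interp(q * scale, q, curve.y)
    return replace(curve, y=out)


def erf_switch(q, q_pm: float, dq_pm: float) -> np.ndarray:
    """Micelle switch w_m(q) = (1 - erf((q - q_pm)/dq_pm)) / 2.

    Multiplies every micelle-dependent term of the theory curve: 1 at
    q -> 0 (micelle contributes fully), 1/2 at the onset q_pm, -> 0 beyond
    it (micelle scattering changes negligible at high angle).
    """
    if q_pm <= 0 or dq_pm <= 0:
        raise ValueError("q_pm and dq_pm must be positive")
    q = np.asarray(q, float)
    return 0.5 * (1.0 - erf((q - q_pm) / dq_pm))


def b_damping(q, B: float) -> np.ndarray:
    """Pseudo-B-factor damping exp(-B q^2 / 16 pi^2) (B in A^2)."""
    if B < 0:
        raise ValueError("B must be non-negative")
    q = np.asarray(q, float)
    return np.exp(-B * q**2 / (16.0 * np.pi**2))


def rms_from_B(B: float) -> float:
    """RMS atomic displacement u (A) from B = 8 pi^2 <u^2>."""
    if B < 0:
        raise ValueError("B must be non-negative")
    return float(np.sqrt(B / (8.0 * np.pi**2)))
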