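"""Isotropic solution scattering via the Debye formula.

For a rigid assembly of atoms with vacuum form factors f_j(q) at positions
r_j, the exact rotational average of |F(q)|^2 over molecular orientations is

    S(q) = sum_i sum_j f_i(q) f_j(q) sinc(q r_ij),      sinc(x) = sin(x)/x,

the Debye formula.  Two evaluation paths are provided: a direct double sum
(the oracle, O(n^2) per q point in pairs) and a pair-distance-histogram
acceleration that bins r_ij per element pair and evaluates the sinc
transform on bin centers.  The histogram path converges to the direct sum
as the bin width shrinks and is the default for systems of thousands of
atoms.

All intensities are on an arbitrary overall scale (the solution's molecule
count N is a constant factor absorbed downstream).
"""

from __future__ import annotations

import numpy as np

from .curves import ScatteringCurve
from .formfactors import form_factor
from .structure_io import AtomSet

__all__ = [
    "debye_intensity",
    "debye_intensity_histogram",
    "ensemble_mean_intensity",
]

_PAIR_CHUNK = 2_000_000  # pair-elements per block in the direct sum


def _element_groups(atoms: AtomSet):
    """Unique elements, per-atom group index, and counts."""
    elems, idx, counts = np.unique(atoms.element, return_inverse=True,
                                   return_counts=True)
    return elems, idx, counts


def _form_factor_matrix(elems, qgrid):
    return np.array([form_factor(e, qgrid) for e in elems])  # (n_elem, nq)


def _sinc(x: np.ndarray) -> np.ndarray:
    # sin(x)/x with sinc(0) = 1 handled analytically
    return np.sinc(x / np.pi)


def debye_intensity(atoms: AtomSet, qgrid) -> ScatteringCurve:
    """Direct Debye double sum (exact; O(n^2) pairs).

    Use for small systems and as the oracle for the histogram path.
    At q = 0 the result equals the squared total electron count.
    """
    if len(atoms) == 0:
        raise ValueError("cannot compute scattering of an empty AtomSet")
    qgrid = np.asarray(qgrid, dtype=float)
    elems, gidx, counts = _element_groups(atoms)
    F = _form_factor_matrix(elems, qgrid)
    # self terms
    S = (counts[:, None] * F**2).sum(axis=0)
    n = len(atoms)
    if n == 1:
        return ScatteringCurve(qgrid, S, label="debye")
    ii, jj = np.triu_indices(n, k=1)
    # chunk the pair list to bound memory (n_pairs x nq intermediates)
    step = max(1, _PAIR_CHUNK // max(1, len(qgrid)))
    coords = atoms.coords
    for lo in range(0, len(ii), step):
        i, j = ii[lo:lo + step], jj[lo:lo + step]
        d = np.linalg.norm(coords[i] - coords[j], axis=1)
        fifj = F[gidx[i]] * F[gidx[j]]                     # (chunk, nq)
        S = S + 2.0 * np.einsum("pq,pq->q", fifj, _sinc(np.outer(d, qgrid)))
    return ScatteringCurve(qgrid, np.maximum(S, 0.0), label="debye")


def debye_intensity_histogram(atoms: AtomSet, qgrid,
                              bin_width: float = 0.05) -> ScatteringCurve:
    """Debye sum accelerated by per-element-pair distance histograms.

    Pair distances are binned at ``bin_width`` (Angstrom) and the sinc
    transform is evaluated on bin centers with f_a f_b weights per element
    pair.  Converges to :func:`debye_intensity` as ``bin_width`` -> 0; the
    0.05 A default keeps the error well below 0.5% for q <= 2 1/A.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(atoms) == 0:
        raise ValueError("cannot compute scattering of an empty AtomSet")
    qgrid = np.asarray(qgrid, dtype=float)
    elems, gidx, counts = _element_groups(atoms)
    F = _form_factor_matrix(elems, qgrid)
    S = (counts[:, None] * F**2).sum(axis=0)
    n = len(atoms)
    if n == 1:
        return ScatteringCurve(qgrid, S, label="debye-hist")
    coords = atoms.coords
    # max distance bounds the histogram range
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    rmax = float(np.linalg.norm(hi - lo)) + bin_width
    nbins = int(np.ceil(rmax / bin_width))
    edges = np.arange(nbins + 1) * bin_width
    ne = len(elems)
    for a in range(ne):
        ca = coords[gidx == a]
        for b in range(a, ne):
            cb = coords[gidx == b]
            if a == b:
                if len(ca) < 2:
                    continue
                from scipy.spatial.distance import pdist
                d = pdist(ca)
                weight = 2.0  # unordered pairs counted once
            else:
                from scipy.spatial.distance import cdist
                d = cdist(ca, cb).ravel()
                weight = 2.0  # (a,b) and (b,a)
            hist, _ = np.histogram(d, bins=edges)
            nz = hist > 0
            if not nz.any():
                continue
            # evaluate sinc at the per-bin mean distance, not the bin
            # center: exact for singly occupied bins, second-order
            # accurate otherwise
            dsum, _ = np.histogram(d, bins=edges, weights=d)
            r_eff = dsum[nz] / hist[nz]
            S = S + weight * (F[a] * F[b]) * (hist[nz]
                                              @ _sinc(np.outer(r_eff, qgrid)))
    return ScatteringCurve(qgrid, np.maximum(S, 0.0), label="debye-hist")


def ensemble_mean_intensity(snapshots, qgrid, bin_width: float | None = 0.05,
                            ) -> ScatteringCurve:
    """Arithmetic mean of per-snapshot Debye curves.

    ``snapshots`` is an :class:`AtomSet` ensemble (multi-model) or an
    iterable of single-model AtomSets.  Snapshots may differ in atom count
    (micelle sizes vary across trajectories); that is accepted silently.
    ``bin_width=None`` selects the direct sum.
    """
    if isinstance(snapshots, AtomSet):
        snapshots = list(snapshots.models())
    else:
        snapshots = list(snapshots)
    if not snapshots:
        raise ValueError("need at least one snapshot")
    qgrid = np.asarray(qgrid, dtype=float)
    acc = np.zeros_like(qgrid)
    for snap in snapshots:
        if bin_width is None:
            acc += debye_intensity(snap, qgrid).y
        else:
            acc += debye_intensity_histogram(snap, qgrid, bin_width).y
    return ScatteringCurve(qgrid, acc / len(snapshots), label="ensemble-mean")
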