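"""Protein-micelle cross term and the micelle-swap difference protocol.

The combined structure factor of a protein (p) inside a detergent micelle
(m) is F_pm = F_p + F_m, so the rotationally averaged intensity picks up an
interference term,

    S_pm(q) = S_p(q) + S_m(q) + 2 cos Phi_pm(q) sqrt(S_p(q) S_m(q)),

which *defines* the phase-coherence curve cos Phi_pm(q).  It is 1 at q = 0
(forward scattering is in phase) and decays in magnitude as the two
components lose coherence.

A first-order expansion of a change in S_pm splits it into a protein term,
a micelle term, and a coherence term.  Because unrestrained detergent
molecules fluctuate wildly between simulation snapshots, the micelle term
would dominate any naive difference; the micelle-swap protocol cancels it
exactly by pairing each protein conformation with *both* micelle ensembles:

    dS_pm = 1/2 ( S_{p_exc m_exc} - S_{p_rest m_exc}
                + S_{p_exc m_rest} - S_{p_rest m_rest} ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import DifferenceCurve, GridMismatchError, ScatteringCurve, same_grid
from .scattering import ensemble_mean_intensity
from .structure_io import AtomSet

__all__ = ["CrossTermSet", "SwapQuartet", "cos_phi", "cross_term_set",
           "decompose_delta_S", "swap_difference"]


@dataclass
class CrossTermSet:
    """(S_p, S_m, S_pm, cos Phi_pm) on a shared q grid."""

    q: np.ndarray
    S_p: ScatteringCurve
    S_m: ScatteringCurve
    S_pm: ScatteringCurve
    cos_phi: DifferenceCurve

    def __post_init__(self):
        same_grid(self.S_p, self.S_m, self.S_pm, self.cos_phi)


def cos_phi(S_a: ScatteringCurve, S_b: ScatteringCurve,
            S_ab: ScatteringCurve) -> DifferenceCurve:
    """Phase-coherence curve (S_ab - S_a - S_b) / (2 sqrt(S_a S_b)).

    Where S_a * S_b vanishes (pathological synthetic inputs only) the value
    is defined as 0.  The result lies in [-1, 1] wherever both components
    scatter (Cauchy-Schwarz on the rotational average) and equals 1 at
    q = 0.
    """
    q = same_grid(S_a, S_b, S_ab)
    denom = 2.0 * np.sqrt(S_a.y * S_b.y)
    out = np.zeros_like(denom)
    ok = denom > 0
    out[ok] = (S_ab.y[ok] - S_a.y[ok] - S_b.y[ok]) / denom[ok]
    return DifferenceCurve(q, out, label="cos_phi")


def cross_term_set(protein: AtomSet, micelle: AtomSet, qgrid,
                   bin_width: float | None = 0.05) -> CrossTermSet:
    """Compute (S_p, S_m, S_pm, cos Phi_pm) for one snapshot or ensemble."""
    S_p = ensemble_mean_intensity(protein, qgrid, bin_width)
    S_m = ensemble_mean_intensity(micelle, qgrid, bin_width)
    combined = [AtomSet.concatenate([p, m])
                for p, m in zip(protein.models(), micelle.models())]
    S_pm = ensemble_mean_intensity(combined, qgrid, bin_width)
    return CrossTermSet(np.asarray(qgrid, float), S_p, S_m, S_pm,
                        cos_phi(S_p, S_m, S_pm))


def decompose_delta_S(rest: CrossTermSet, exc: CrossTermSet) -> dict:
    """First-order decomposition of dS_pm into protein/micelle/coherence terms.

    Returns a dict of DifferenceCurves: ``dS_p``, ``dS_m``, ``dcos_phi``,
    the three assembled terms

        term_p   = dS_p  * (1 + sqrt(S_m/S_p) cos Phi_pm)
        term_m   = dS_m  * (1 + sqrt(S_p/S_m) cos Phi_pm)
        term_phi = 2 sqrt(S_p S_m) * d[cos Phi_pm]

    their ``sum``, and the exact difference ``dS_pm_exact``.  The sum
    matches the exact difference to first order in the perturbation
    (error quadratic in the displacement amplitude).  Ratios are evaluated
    with the resting-state S_p, S_m, cos Phi_pm.
    """
    if rest.q.shape != exc.q.shape or not np.allclose(rest.q, exc.q):
        raise GridMismatchError("resting and excited sets on different grids")
    q = rest.q
    dSp = exc.S_p.y - rest.S_p.y
    dSm = exc.S_m.y - rest.S_m.y
    dcos = exc.cos_phi.y - rest.cos_phi.y
    Sp, Sm, cphi = rest.S_p.y, rest.S_m.y, rest.cos_phi.y
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_mp = np.where(Sp > 0, np.sqrt(Sm / np.where(Sp > 0, Sp, 1.0)), 0.0)
        ratio_pm = np.where(Sm > 0, np.sqrt(Sp / np.where(Sm > 0, Sm, 1.0)), 0.0)
    term_p = dSp * (1.0 + ratio_mp * cphi)
    term_m = dSm * (1.0 + ratio_pm * cphi)
    term_phi = 2.0 * np.sqrt(Sp * Sm) * dcos
    total = term_p + term_m + term_phi
    return {
        "dS_p": DifferenceCurve(q, dSp, "dS_p"),
        "dS_m": DifferenceCurve(q, dSm, "dS_m"),
        "dcos_phi": DifferenceCurve(q, dcos, "dcos_phi"),
        "term_p": DifferenceCurve(q, term_p, "protein term"),
        "term_m": DifferenceCurve(q, term_m, "micelle term"),
        "term_phi": DifferenceCurve(q, term_phi, "coherence term"),
        "sum": DifferenceCurve(q, total, "first-order sum"),
        "dS_pm_exact": DifferenceCurve(q, exc.S_pm.y - rest.S_pm.y, "exact"),
    }


@dataclass
class SwapQuartet:
    """Frame-matched protein/micelle ensembles for the swap protocol.

    ``p_rest``/``p_exc`` are protein ensembles from the resting and excited
    trajectories; ``m_rest``/``m_exc`` the corresponding micelle ensembles.
    Snapshot i of each ensemble is paired with snapshot i of the others.
    """

    p_rest: AtomSet
    p_exc: AtomSet
    m_rest: AtomSet
    m_exc: AtomSet

    def __post_init__(self):
        ns = {a.n_models for a in (self.p_rest, self.p_exc,
                                   self.m_rest, self.m_exc)}
        if len(ns) != 1:
            raise ValueError(f"mismatched snapshot counts across ensembles: {ns}")
        self.n_frames = ns.pop()


def swap_difference(quartet: SwapQuartet, qgrid,
                    bin_width: float | None = 0.05) -> DifferenceCurve:
    """Micelle-swap difference curve dS_pm(q).

    Each of the four combined systems (protein from one trajectory placed
    in the micelle of either trajectory) is scattered per frame, ensemble
    means taken, and combined as

        dS_pm = 1/2 (S_pe_me - S_pr_me + S_pe_mr - S_pr_mr),

    so micelle-only scattering changes cancel exactly by construction.
    """
    qgrid = np.asarray(qgrid, float)

    def combined_mean(p: AtomSet, m: AtomSet) -> np.ndarray:
        frames = [AtomSet.concatenate([pf, mf])
                  for pf, mf in zip(p.models(), m.models())]
        return ensemble_mean_intensity(frames, qgrid, bin_width).y

    S_pe_me = combined_mean(quartet.p_exc, quartet.m_exc)
    S_pr_me = combined_mean(quartet.p_rest, quartet.m_exc)
    S_pe_mr = combined_mean(quartet.p_exc, quartet.m_rest)
    S_pr_mr = combined_mean(quartet.p_rest, quartet.m_rest)
    y = 0.5 * (S_pe_me - S_pr_me + S_pe_mr - S_pr_mr)
    return DifferenceCurve(qgrid, y, label="dS_pm (swap)")
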