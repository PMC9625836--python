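"""Solvent-excluded-volume correction from an explicit water shell.

The solvent displaced by the solute scatters with opposite sign,
|F_tot|^2 = |F_pm - F_solv|^2, giving on rotational averaging

    S_tot = S_pm + S_solv - 2 cos Phi_solv sqrt(S_pm S_solv),

which defines cos Phi_solv when S_tot is known, or reconstructs S_tot when
cos Phi_solv is known.  S_solv is computed from explicit water molecules
selected within a small radius of any solute atom from an independent bulk
water box; the over-count from waters protruding beyond the molecular
surface is removed by counting selected waters at several radii and
extrapolating linearly back to radius 0, then rescaling the S_solv
amplitude by the squared count ratio (forward scattering scales with
electron count squared).

The resulting q-dependent ratio S_tot/S_pm multiplies predicted difference
curves; it is computed once from the resting ensemble and applied to both
states (both conformations assumed equally modulated by solvent exclusion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .curves import DifferenceCurve, ScatteringCurve, same_grid
from .structure_io import AtomSet, DataError

__all__ = ["SolventCorrection", "select_shell_waters", "count_water_molecules",
           "extrapolate_water_count", "reconstruct_S_tot", "solvent_coherence",
           "solvent_ratio"]

#: below this q the ratio is clamped to its local value; the contrast between
#: protein and micelle makes the very-low-angle region model-sensitive
RATIO_CLAMP_Q = 0.05


@dataclass
class SolventCorrection:
    """S_tot/S_pm ratio plus the pieces it was built from."""

    q: np.ndarray
    S_solv: ScatteringCurve | None
    S_tot: ScatteringCurve
    cos_phi_solv: DifferenceCurve | None
    ratio: np.ndarray                     # S_tot / S_pm, clamped below RATIO_CLAMP_Q
    masked: np.ndarray = None             # bool: grid points where S_pm was 0
    regression: dict = field(default_factory=dict)  # radii, counts, intercept

    def apply(self, dS: DifferenceCurve) -> DifferenceCurve:
        """Scale a predicted difference curve by the ratio (dS_theory)."""
        if dS.q.shape != self.q.shape or not np.allclose(dS.q, self.q):
            raise ValueError("difference curve not on the correction grid")
        return DifferenceCurve(self.q, dS.y * self.ratio,
                               label=f"{dS.label} x Stot/Spm")


def select_shell_waters(system: AtomSet, waterbox: AtomSet,
                        radius: float) -> AtomSet:
    """Whole water molecules with any atom within *radius* of any solute atom.

    The solute is every protein or micelle atom of *system*; water-molecule
    membership (per chain + residue id + model) is never split.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    waters = waterbox.by_component("water")
    if len(waters) == 0:
        raise DataError("waterbox contains no water atoms")
    solute_mask = np.isin(system.component, ("protein", "micelle"))
    solute = system.select(solute_mask)
    if len(solute) == 0:
        raise DataError("system contains no protein or micelle atoms")
    tree = cKDTree(solute.coords)
    hit = np.array(tree.query_ball_point(waters.coords, r=radius),
                   dtype=object)
    atom_hit = np.array([len(h) > 0 for h in hit])
    # promote atom hits to whole molecules
    mol_key = np.char.add(np.char.add(waters.chain, "/"),
                          np.char.add(waters.res_id.astype("U12"),
                                      np.char.add("@", waters.model.astype("U12"))))
    hit_keys = np.unique(mol_key[atom_hit])
    return waters.select(np.isin(mol_key, hit_keys))


def count_water_molecules(waters: AtomSet) -> int:
    """Number of distinct water molecules (chain, residue, model) in a set."""
    if len(waters) == 0:
        return 0
    keys = {(c, int(r), int(m)) for c, r, m
            in zip(waters.chain, waters.res_id, waters.model)}
    return len(keys)


def extrapolate_water_count(radii, counts) -> float:
    """Intercept at radius 0 of the least-squares line through (radius, count).

    Selected-water counts grow with the selection radius because waters
    protruding beyond the surface are over-counted; the radius-0 intercept
    estimates the solvent actually displaced and rescales S_solv.
    """
    radii = np.asarray(radii, float)
    counts = np.asarray(counts, float)
    if radii.size < 2 or np.unique(radii).size < 2:
        raise ValueError("need at least two distinct radii")
    order = np.argsort(radii)
    if np.any(np.diff(counts[order]) < 0):
        raise ValueError("counts must be non-decreasing in radius")
    slope, intercept = np.polyfit(radii, counts, 1)
    return float(intercept)


def reconstruct_S_tot(S_pm: ScatteringCurve, S_solv: ScatteringCurve,
                      cos_phi_solv: DifferenceCurve) -> ScatteringCurve:
    """S_tot from S_pm, S_solv and a known coherence curve (inverse of Eq. for cos)."""
    q = same_grid(S_pm, S_solv, cos_phi_solv)
    y = S_pm.y + S_solv.y - 2.0 * cos_phi_solv.y * np.sqrt(S_pm.y * S_solv.y)
    return ScatteringCurve(q, np.maximum(y, 0.0), label="S_tot")


def solvent_ratio(S_pm: ScatteringCurve,
                  S_solv: ScatteringCurve | None = None,
                  S_tot: ScatteringCurve | None = None,
                  cos_phi_solv: DifferenceCurve | None = None,
                  amplitude_scale: float = 1.0,
                  regression: dict | None = None,
                  clamp_q: float = RATIO_CLAMP_Q) -> SolventCorrection:
    """Build the S_tot/S_pm correction.

    Either pass ``S_tot`` directly (cos Phi_solv is then derived, when
    ``S_solv`` is also given), or pass ``S_solv`` plus ``cos_phi_solv`` and
    S_tot is reconstructed.  ``amplitude_scale`` multiplies S_solv before
    use -- pass (intercept / selected_count)**2 from the water-count
    regression.  Below ``clamp_q`` the ratio is clamped to its value at
    ``clamp_q``.  Grid points where S_pm = 0 are masked and carry ratio 1.
    """
    if S_solv is not None and amplitude_scale != 1.0:
        S_solv = ScatteringCurve(S_solv.q, S_solv.y * amplitude_scale,
                                 label=S_solv.label)
    if S_tot is None:
        if S_solv is None or cos_phi_solv is None:
            raise ValueError("need S_tot, or S_solv plus cos_phi_solv")
        S_tot = reconstruct_S_tot(S_pm, S_solv, cos_phi_solv)
    elif cos_phi_solv is None and S_solv is not None:
        cos_phi_solv = solvent_coherence(S_pm, S_solv, S_tot)
    q = same_grid(S_pm, S_tot)
    masked = S_pm.y <= 0
    ratio = np.ones_like(S_pm.y)
    ratio[~masked] = S_tot.y[~masked] / S_pm.y[~masked]
    if clamp_q is not None and q.max() > clamp_q:
        i0 = int(np.searchsorted(q, clamp_q))
        i0 = min(i0, len(q) - 1)
        ratio[:i0] = ratio[i0]
    return SolventCorrection(q, S_solv, S_tot, cos_phi_solv, ratio,
                             masked=masked, regression=regression or {})


def solvent_coherence(S_pm: ScatteringCurve, S_solv: ScatteringCurve,
                      S_tot: ScatteringCurve) -> DifferenceCurve:
    """Solvent coherence curve (S_pm + S_solv - S_tot) / (2 sqrt(S_pm S_solv)).

    Note the sign flip relative to the protein-micelle coherence: the
    excluded-volume amplitude is subtracted, so the cross term enters
    S_tot with a minus sign.
    """
    q = same_grid(S_pm, S_solv, S_tot)
    denom = 2.0 * np.sqrt(S_pm.y * S_solv.y)
    out = np.zeros_like(denom)
    ok = denom > 0
    out[ok] = (S_pm.y[ok] + S_solv.y[ok] - S_tot.y[ok]) / denom[ok]
    return DifferenceCurve(q, out, label="cos_phi_solv")
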