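"""Structural fitting: theory-curve assembly, R-factor, (gamma, delta) grids.

The theory curve for one candidate deformation (gamma, delta) is

    dS_theory(q) = [S_tot/S_pm] * exp(-B_p q^2 / 16 pi^2)
                   * ( dS_p(q) + w_m(q) * { dS_pm(q) - dS_p(q)
                                            + A2 * dS_mc(q) } ),

convolved with the undulator spectrum;  w_m is the erf switch that turns
micelle-dependent terms off above q_pm.  Agreement with an experimental
basis spectrum is scored by the R-factor

    R = sum( w(q) (A1 dS_theory - dS_expt) )^2 / sum( w(q) dS_expt )^2

on the fitting window (default 0.15-0.9 1/A, w = 1).  The model is linear
in A1 and A1*A2, so both amplitudes solve in closed form at each grid node
and q_pm; q_pm is scanned on a coarse grid; B_p is fixed at 0 by default
(Ca-restrained trajectory variation already encodes protein disorder).
A1 is shared between the two states: it is refined jointly at the best
node pair and then held fixed while the contours are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corrections import (UndulatorSpectrum, b_damping, erf_switch,
                          polychromatic_convolve)
from .curves import DifferenceCurve, GridMismatchError, same_grid
from .solvent import SolventCorrection

__all__ = ["FitParameters", "FitResult", "assemble_theory", "r_factor",
           "grid_search", "select_top_pairs", "DEFAULT_GAMMA_GRID",
           "DEFAULT_DELTA_GRID", "DEFAULT_QPM_GRID", "FIT_WINDOW"]

FIT_WINDOW = (0.15, 0.9)

# gamma: 0 .. 1.5 in steps of 1/6;  delta: 0 .. 4/3 in steps of 1/3
DEFAULT_GAMMA_GRID = np.arange(0, 10) / 6.0
DEFAULT_DELTA_GRID = np.arange(0, 5) / 3.0
DEFAULT_QPM_GRID = np.arange(0.05, 0.301, 0.001)


@dataclass
class FitParameters:
    """Parameters of the theory curve and R-factor.

    dq_pm is tied to q_pm (25% of it); at most six quantities are ever
    free: gamma, delta, A1, A2, B_p, q_pm.
    """

    gamma: float = 0.0
    delta: float = 0.0
    A1: float = 1.0
    A2: float = 0.0
    B_p: float = 0.0           # A^2
    q_pm: float = 0.129        # 1/A
    w: np.ndarray | None = None   # weighting curve on the fit grid; None = 1
    window: tuple = FIT_WINDOW
    #: False reverts to protein-only modeling (w_m = 0 and A2 = 0), the
    #: approximation the micelle terms exist to improve upon
    micelle_terms: bool = True

    @property
    def dq_pm(self) -> float:
        return 0.25 * self.q_pm


@dataclass
class FitResult:
    """R-factor contour over (gamma, delta) with the refined parameters."""

    gammas: np.ndarray
    deltas: np.ndarray
    r_grid: np.ndarray              # (n_gamma, n_delta)
    best: FitParameters
    best_r: float
    best_theory: DifferenceCurve
    uncertainties: dict = field(default_factory=dict)
    a2_grid: np.ndarray | None = None
    qpm_grid_best: np.ndarray | None = None


def _micelle_bracket(dS_p, dS_pm, dS_mc, params):
    """The two linear pieces X1, X2 with model = A1*X1 + (A1*A2)*X2."""
    q = dS_p.q
    if not params.micelle_terms:
        return dS_p.y.copy(), np.zeros_like(q)
    wm = erf_switch(q, params.q_pm, params.dq_pm)
    x1 = dS_p.y + wm * (dS_pm.y - dS_p.y)
    x2 = wm * (dS_mc.y if dS_mc is not None else np.zeros_like(q))
    return x1, x2


def assemble_theory(dS_p: DifferenceCurve, dS_pm: DifferenceCurve,
                    dS_mc, solvent: SolventCorrection | None,
                    params: FitParameters,
                    spectrum: UndulatorSpectrum | None = None) -> DifferenceCurve:
    """Full theory difference curve for one parameter set (A1 not applied)."""
    q = same_grid(dS_p, dS_pm)
    if dS_mc is not None and (dS_mc.q.shape != q.shape
                              or not np.allclose(dS_mc.q, q)):
        raise GridMismatchError("micelle correction not on the shared grid")
    x1, x2 = _micelle_bracket(dS_p, dS_pm, dS_mc, params)
    y = x1 + params.A2 * x2
    ratio = solvent.ratio if solvent is not None else 1.0
    y = ratio * b_damping(q, params.B_p) * y
    out = DifferenceCurve(q, y, label="dS_theory")
    if spectrum is not None:
        out = polychromatic_convolve(out, spectrum)
    return out


def r_factor(theory: DifferenceCurve, expt: DifferenceCurve,
             A1: float = 1.0, w: np.ndarray | None = None,
             window: tuple = FIT_WINDOW) -> float:
    """Weighted, windowed relative squared misfit of A1*theory to expt."""
    q = same_grid(theory, expt)
    m = (q >= window[0]) & (q <= window[1])
    if not m.any():
        raise ValueError(f"fit window {window} outside the q grid")
    wv = np.ones(m.sum()) if w is None else np.asarray(w, float)[m]
    num = np.sum((wv * (A1 * theory.y[m] - expt.y[m])) ** 2)
    den = np.sum((wv * expt.y[m]) ** 2)
    if den == 0:
        raise ValueError("experimental curve vanishes on the fit window")
    return float(num / den)


def _design(dS_p, dS_pm, dS_mc, solvent, params, spectrum, mask):
    """Windowed, convolved design vectors for the linear amplitudes."""
    q = dS_p.q
    x1, x2 = _micelle_bracket(dS_p, dS_pm, dS_mc, params)
    ratio = solvent.ratio if solvent is not None else 1.0
    damp = b_damping(q, params.B_p)
    c1 = DifferenceCurve(q, ratio * damp * x1)
    c2 = DifferenceCurve(q, ratio * damp * x2)
    if spectrum is not None:
        c1 = polychromatic_convolve(c1, spectrum)
        c2 = polychromatic_convolve(c2, spectrum)
    return c1.y[mask], c2.y[mask]


def _solve_amplitudes(X1, X2, y):
    """Least-squares (a, b) for y ~ a*X1 + b*X2; returns (a, A2, rss)."""
    A = np.column_stack([X1, X2])
    if np.allclose(X2, 0):
        a = float(np.dot(X1, y) / max(np.dot(X1, X1), 1e-300))
        b = 0.0
    else:
        (a, b), *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - a * X1 - b * X2
    A2 = b / a if a != 0 else 0.0
    return float(a), float(A2), float(np.dot(resid, resid))


def grid_search(node_curves: dict, expt_bases: list, dS_mc=None,
                solvent: SolventCorrection | None = None,
                spectrum: UndulatorSpectrum | None = None,
                qpm_grid=None, B_p: float = 0.0, w=None,
                window: tuple = FIT_WINDOW,
                micelle_terms: bool = True) -> list[FitResult]:
    """R-factor contours over a rectangular (gamma, delta) grid.

    ``node_curves`` maps (gamma, delta) -> dict with DifferenceCurves
    ``"dS_p"`` and ``"dS_pm"`` (precomputed from trajectory ensembles via
    the swap protocol); ``expt_bases`` is one or two experimental basis
    difference curves (states).  At every node and q_pm the amplitudes
    solve in closed form; A1 is then refined shared across states at the
    best node pair and the contours re-evaluated at fixed A1.  Returns one
    :class:`FitResult` per state.
    """
    nodes = sorted(node_curves)
    gammas = np.array(sorted({g for g, _ in nodes}))
    deltas = np.array(sorted({d for _, d in nodes}))
    if len(nodes) != len(gammas) * len(deltas):
        raise ValueError("(gamma, delta) nodes do not form a rectangular grid")
    if qpm_grid is None:
        qpm_grid = DEFAULT_QPM_GRID
    qpm_grid = np.atleast_1d(np.asarray(qpm_grid, float))

    q = same_grid(*(expt_bases))
    mask = (q >= window[0]) & (q <= window[1])
    wv = np.ones(mask.sum()) if w is None else np.asarray(w, float)[mask]

    # cache design vectors: node -> qpm index -> (X1, X2)
    def design_for(node, qpm):
        p = FitParameters(q_pm=qpm, B_p=B_p, window=window,
                          micelle_terms=micelle_terms)
        nc = node_curves[node]
        return _design(nc["dS_p"], nc["dS_pm"], dS_mc, solvent, p,
                       spectrum, mask)

    cache = {}
    for node in nodes:
        cache[node] = [design_for(node, qpm) for qpm in qpm_grid]

    # pass 1: independent best per state (free A1 per state)
    per_state = []
    for expt in expt_bases:
        y = (wv * expt.y[mask])
        den = float(np.dot(y, y))
        best = None
        for node in nodes:
            for k, qpm in enumerate(qpm_grid):
                X1, X2 = cache[node][k]
                a, A2, rss = _solve_amplitudes(wv * X1, wv * X2, y)
                R = rss / den
                if best is None or R < best[0]:
                    best = (R, node, k, a, A2)
        per_state.append(best)

    # pass 2: shared A1 at the per-state best nodes and q_pm values
    num = den = 0.0
    prepared = []
    for expt, (R, node, k, a, A2) in zip(expt_bases, per_state):
        X1, X2 = cache[node][k]
        y = wv * expt.y[mask]
        # at fixed A2 the model is linear in A1 alone
        Xs = wv * (X1 + A2 * X2)
        prepared.append((y, Xs))
        num += np.dot(Xs, y)
        den += np.dot(Xs, Xs)
    A1_shared = float(num / den) if den > 0 else 1.0

    # pass 3: contours at fixed shared A1 (A2 re-solved per node/state)
    results = []
    for expt, (R0, node0, k0, _, _) in zip(expt_bases, per_state):
        y = expt.y[mask] * wv
        dfac = float(np.dot(y, y))
        r_grid = np.empty((len(gammas), len(deltas)))
        a2_grid = np.empty_like(r_grid)
        qpm_best = np.empty_like(r_grid)
        for i, g in enumerate(gammas):
            for j, d in enumerate(deltas):
                bestR, bestA2, bestQ = np.inf, 0.0, qpm_grid[0]
                for k, qpm in enumerate(qpm_grid):
                    X1, X2 = cache[(g, d)][k]
                    # A1 fixed: solve only A2 (linear) for the bracket
                    r = y - A1_shared * wv * X1
                    xb = A1_shared * wv * X2
                    denom = np.dot(xb, xb)
                    b = np.dot(xb, r) / denom if denom > 0 else 0.0
                    resid = r - b * xb
                    R = float(np.dot(resid, resid) / dfac)
                    if R < bestR:
                        bestR, bestA2, bestQ = R, float(b), float(qpm)
                r_grid[i, j] = bestR
                a2_grid[i, j] = bestA2
                qpm_best[i, j] = bestQ
        i0, j0 = np.unravel_index(np.argmin(r_grid), r_grid.shape)
        best_params = FitParameters(gamma=float(gammas[i0]),
                                    delta=float(deltas[j0]),
                                    A1=A1_shared, A2=a2_grid[i0, j0],
                                    B_p=B_p, q_pm=qpm_best[i0, j0],
                                    window=window,
                                    micelle_terms=micelle_terms)
        nc = node_curves[(gammas[i0], deltas[j0])]
        theory = assemble_theory(nc["dS_p"], nc["dS_pm"], dS_mc, solvent,
                                 best_params, spectrum)
        results.append(FitResult(
            gammas=gammas, deltas=deltas, r_grid=r_grid, best=best_params,
            best_r=float(r_grid[i0, j0]), best_theory=theory,
            uncertainties=_contour_uncertainties(gammas, deltas, r_grid),
            a2_grid=a2_grid, qpm_grid_best=qpm_best))
    return results


def _contour_uncertainties(gammas, deltas, r_grid, factor: float = 1.25):
    """Per-parameter half-width of the region where R <= factor * R_min."""
    rmin = r_grid.min()
    region = r_grid <= factor * rmin
    gi, di = np.nonzero(region)
    return {
        "gamma": float((gammas[gi].max() - gammas[gi].min()) / 2.0),
        "delta": float((deltas[di].max() - deltas[di].min()) / 2.0),
    }


def select_top_pairs(pairs, expt: DifferenceCurve, n: int = 100,
                     qmin: float = 0.20):
    """Keep the n structural pairs best Pearson-correlated with experiment.

    ``pairs`` is a list of (prediction: DifferenceCurve, stats: dict) where
    stats maps a span label to that pair's mean C-alpha displacement (A).
    Correlation is computed on q >= qmin.  Returns (kept_indices,
    summaries) with summaries mapping each span label to (mean, sd) over
    the kept subset.  Zero-variance predictions are excluded with a
    warning entry in the summaries.
    """
    if n > len(pairs):
        raise ValueError("n exceeds the number of pairs")
    m = expt.q >= qmin
    ye = expt.y[m]
    ye_c = ye - ye.mean()
    se = np.sqrt(np.dot(ye_c, ye_c))
    scores, excluded = [], []
    for idx, (pred, _) in enumerate(pairs):
        same_grid(pred, expt)
        yp = pred.y[m]
        yp_c = yp - yp.mean()
        sp = np.sqrt(np.dot(yp_c, yp_c))
        if sp == 0 or se == 0:
            excluded.append(idx)
            scores.append(-np.inf)
        else:
            scores.append(float(np.dot(yp_c, ye_c) / (sp * se)))
    order = np.argsort(scores)[::-1]
    kept = [int(i) for i in order[:n] if np.isfinite(scores[i])]
    labels = set()
    for _, stats in pairs:
        labels |= set(stats)
    summaries = {}
    for lab in sorted(labels):
        vals = np.array([pairs[i][1][lab] for i in kept if lab in pairs[i][1]])
        summaries[lab] = (float(vals.mean()), float(vals.std(ddof=0)))
    if excluded:
        summaries["_excluded"] = excluded
    return kept, summaries
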