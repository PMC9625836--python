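"""Processing of experimental (or synthetic) 1D TR-XSS difference curves.

Pipeline, in the order the beamline data flow: isosbestic normalization of
absolute curves, two-stage outlier rejection, removal of the laser-heating
signature using an IR-heating reference curve, two-state kinetic
decomposition of the heat-corrected time series, and Guinier analysis of
absolute curves as an aggregation diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .curves import DifferenceCurve, ScatteringCurve, same_grid

__all__ = ["TimeSeriesDataset", "BasisDecomposition", "normalize_isosbestic",
           "reject_outliers", "remove_heat", "decompose_two_state", "guinier",
           "HEAT_WINDOW", "load_dataset_directory"]

#: q window (1/A) over which the heat scale alpha is fitted
HEAT_WINDOW = (0.51, 1.45)


@dataclass
class TimeSeriesDataset:
    """Difference curves dS(q, dt) on a shared grid with an IR-heat reference."""

    q: np.ndarray
    delays: np.ndarray                     # seconds, strictly increasing
    curves: np.ndarray                     # (n_delays, nq), raw differences
    ir_curve: DifferenceCurve | None = None
    alphas: np.ndarray | None = None       # per-delay heat scale
    corrected: np.ndarray | None = None    # (n_delays, nq) after heat removal
    truth: dict = field(default_factory=dict)  # synthetic ground truth, if any

    def __post_init__(self):
        self.q = np.asarray(self.q, float)
        self.delays = np.asarray(self.delays, float)
        self.curves = np.atleast_2d(np.asarray(self.curves, float))
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("time delays must be strictly increasing")
        if self.curves.shape != (len(self.delays), len(self.q)):
            raise ValueError("curve matrix shape does not match delays x q")

    def remove_heat(self, qwindow=HEAT_WINDOW) -> "TimeSeriesDataset":
        """Heat-correct every delay; stores alphas and corrected curves."""
        if self.ir_curve is None:
            raise ValueError("dataset has no IR-heating reference curve")
        alphas, corrected = [], []
        for row in self.curves:
            a, hc = remove_heat(DifferenceCurve(self.q, row), self.ir_curve,
                                qwindow)
            alphas.append(a)
            corrected.append(hc.y)
        self.alphas = np.array(alphas)
        self.corrected = np.array(corrected)
        return self


@dataclass
class BasisDecomposition:
    """Two-state kinetic decomposition of a heat-corrected time series."""

    q: np.ndarray
    basis1: np.ndarray
    basis2: np.ndarray
    delays: np.ndarray
    c1: np.ndarray                 # model populations exp(-dt/tau)
    c2: np.ndarray                 # 1 - c1 (times optional second decay)
    tau1: float                    # seconds
    tau2: float | None             # None: state 2 does not decay
    free_c1: np.ndarray            # per-delay unconstrained linear populations
    free_c2: np.ndarray
    crossing_time: float | None    # seconds, None if populations never cross
    residual: float                # RMS of model reconstruction
    converged: bool = True

    def reconstruction(self) -> np.ndarray:
        return np.outer(self.c1, self.basis1) + np.outer(self.c2, self.basis2)


def normalize_isosbestic(curve: ScatteringCurve, q0: float = 1.6,
                         half_width: float = 0.05) -> ScatteringCurve:
    """Scale a curve so its mean over [q0 - hw, q0 + hw] equals 1.

    Intensity at the isosbestic point is insensitive to the photoreaction,
    so this puts repeated exposures on a common scale.
    """
    m = (curve.q >= q0 - half_width) & (curve.q <= q0 + half_width)
    if not m.any():
        raise ValueError(f"normalization window around q={q0} outside grid")
    mean = curve.y[m].mean()
    if mean == 0:
        raise ValueError("zero mean intensity in the normalization window")
    return ScatteringCurve(curve.q, curve.y / mean, label=curve.label)


def reject_outliers(absolute_curves, difference_curves,
                    abs_window=(2.0, 2.5), abs_tol: float = 0.10,
                    n_sigma: float = 3.0, max_fraction: float = 0.01):
    """Two-stage outlier filter; returns (kept_abs_idx, kept_diff_idx).

    Stage 1: absolute curves whose mean over ``abs_window`` deviates more
    than ``abs_tol`` (10%) from the median of those means are dropped.
    Stage 2: difference curves are dropped when they exceed ``n_sigma``
    per-q standard deviations from the per-q mean at more than
    ``max_fraction`` of grid points (the per-curve aggregation of the
    3-sigma rule).
    """
    abs_means = []
    for c in absolute_curves:
        m = (c.q >= abs_window[0]) & (c.q <= abs_window[1])
        if not m.any():
            raise ValueError("stage-1 window outside the q grid")
        abs_means.append(c.y[m].mean())
    abs_means = np.array(abs_means)
    med = np.median(abs_means)
    kept_abs = np.flatnonzero(np.abs(abs_means - med) <= abs_tol * np.abs(med))

    diffs = np.array([c.y for c in difference_curves])
    if len(diffs) < 3:
        raise ValueError("need at least 3 difference curves for the sigma filter")
    mu = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, np.inf)
    frac_out = (np.abs(diffs - mu) > n_sigma * sd).mean(axis=1)
    kept_diff = np.flatnonzero(frac_out <= max_fraction)
    if kept_abs.size == 0 or kept_diff.size == 0:
        raise RuntimeError(
            "all curves rejected "
            f"(stage-1 means {abs_means.tolist()}, "
            f"stage-2 outlier fractions {frac_out.tolist()})")
    return kept_abs, kept_diff


def remove_heat(dS: DifferenceCurve, dS_IR: DifferenceCurve,
                qwindow=HEAT_WINDOW) -> tuple[float, DifferenceCurve]:
    """Subtract the scaled IR-heating signature from a difference curve.

    alpha minimizes sum_window |dS - alpha dS_IR|^2, i.e. the projection
    alpha = <dS, dS_IR> / <dS_IR, dS_IR> on the fit window; returns
    (alpha, dS - alpha * dS_IR on the full grid).
    """
    q = same_grid(dS, dS_IR)
    m = (q >= qwindow[0]) & (q <= qwindow[1])
    if not m.any():
        raise ValueError(f"heat window {qwindow} outside the q grid")
    denom = np.dot(dS_IR.y[m], dS_IR.y[m])
    if denom == 0:
        raise ZeroDivisionError("IR reference vanishes on the fit window")
    alpha = float(np.dot(dS.y[m], dS_IR.y[m]) / denom)
    hc = DifferenceCurve(q, dS.y - alpha * dS_IR.y, label=f"{dS.label} HC")
    return alpha, hc


def _kinetic_matrix(delays, tau1, tau2=None):
    c1 = np.exp(-delays / tau1)
    c2 = 1.0 - c1
    if tau2 is not None:
        c2 = c2 * np.exp(-delays / tau2)
    return c1, c2


def decompose_two_state(dataset: TimeSeriesDataset,
                        fit_tau2: bool = False) -> BasisDecomposition:
    """Fit c1(dt) = exp(-dt/tau1) with a complementary rise of state 2.

    At fixed kinetics the two basis spectra solve a linear least-squares
    problem; tau1 (and optionally a second decay tau2) is refined by
    nonlinear least squares on the residual.  Also reports unconstrained
    per-delay populations from a linear fit against the refined bases, and
    the c1/c2 crossing time interpolated on a log-time grid.
    """
    if dataset.corrected is None:
        data = dataset.curves
    else:
        data = dataset.corrected
    delays = dataset.delays
    if len(delays) < 4:
        raise ValueError("need at least 4 time delays")

    def solve_bases(theta):
        tau1 = np.exp(theta[0])
        tau2 = np.exp(theta[1]) if fit_tau2 else None
        c1, c2 = _kinetic_matrix(delays, tau1, tau2)
        C = np.column_stack([c1, c2])            # (n_delays, 2)
        B, *_ = np.linalg.lstsq(C, data, rcond=None)   # (2, nq)
        resid = data - C @ B
        return tau1, tau2, c1, c2, B, resid

    def cost(theta):
        return solve_bases(theta)[-1].ravel()

    # initialize tau1 from the geometric mean of the delay range
    theta0 = [0.5 * (np.log(delays[0]) + np.log(delays[-1]))]
    if fit_tau2:
        theta0.append(np.log(delays[-1]))
    res = optimize.least_squares(cost, theta0, method="lm", max_nfev=2000)
    tau1, tau2, c1, c2, B, resid = solve_bases(res.x)
    basis1, basis2 = B[0], B[1]

    # per-delay free populations against the refined bases
    Bmat = np.column_stack([basis1, basis2])     # (nq, 2)
    free = np.linalg.lstsq(Bmat, data.T, rcond=None)[0].T  # (n_delays, 2)

    crossing = _crossing_time(delays, c1, c2)
    return BasisDecomposition(
        q=dataset.q, basis1=basis1, basis2=basis2, delays=delays,
        c1=c1, c2=c2, tau1=float(tau1),
        tau2=(float(tau2) if tau2 is not None else None),
        free_c1=free[:, 0], free_c2=free[:, 1],
        crossing_time=crossing,
        residual=float(np.sqrt(np.mean(resid**2))),
        converged=bool(res.success),
    )


def _crossing_time(delays, c1, c2, n_grid: int = 2000):
    """First time where c2 overtakes c1, interpolated on a log-time grid."""
    t = np.geomspace(delays[0], delays[-1], n_grid)
    d = np.interp(np.log(t), np.log(delays), c1 - c2)
    sign_change = np.flatnonzero(np.diff(np.sign(d)) != 0)
    if sign_change.size == 0:
        return None
    i = sign_change[0]
    # linear interpolation in log t
    f = d[i] / (d[i] - d[i + 1])
    return float(np.exp(np.log(t[i]) + f * (np.log(t[i + 1]) - np.log(t[i]))))


def guinier(curve: ScatteringCurve, q2_window=(0.0, 1e-3)):
    """Guinier fit ln S = ln I0 - Rg^2 q^2 / 3 on a q^2 window.

    Returns (Rg, I0, diagnostic) where the diagnostic dict carries the
    residual curvature statistic: the z-score of a quadratic term in q^2
    added to the line.  A large |z| (> 3) flags departure from linearity
    (aggregation or interparticle interference); ``diagnostic["linear"]``
    is the boolean verdict.
    """
    q2 = curve.q**2
    m = (q2 >= q2_window[0]) & (q2 <= q2_window[1]) & (curve.y > 0)
    if m.sum() < 3:
        raise ValueError("fewer than 3 usable points in the Guinier window")
    x, y = q2[m], np.log(curve.y[m])
    slope, intercept = np.polyfit(x, y, 1)
    Rg = float(np.sqrt(max(-3.0 * slope, 0.0)))
    I0 = float(np.exp(intercept))
    # curvature probe: quadratic fit, z-score of the q^4 coefficient
    coef, cov = np.polyfit(x, y, 2, cov=True) if m.sum() > 3 else (None, None)
    if coef is not None and np.isfinite(cov[0, 0]) and cov[0, 0] > 0:
        z = float(coef[0] / np.sqrt(cov[0, 0]))
    else:
        z = 0.0
    diagnostic = {"curvature_z": z, "linear": abs(z) <= 3.0,
                  "n_points": int(m.sum())}
    return Rg, I0, diagnostic


def load_dataset_directory(path, delays_and_files, ir_file="dS_IR.dat",
                           qgrid=None) -> TimeSeriesDataset:
    """Assemble a dataset from two-column text files, one per time delay.

    ``delays_and_files`` is a list of (delay_seconds, filename) pairs; all
    curves are linearly resampled to ``qgrid`` (default: the first file's
    grid).
    """
    from pathlib import Path
    root = Path(path)
    pairs = sorted(delays_and_files)
    curves = []
    q = None
    for _, fname in pairs:
        c = DifferenceCurve.load(root / fname)
        if qgrid is not None:
            c = c.interp(np.asarray(qgrid, float))
        if q is None:
            q = c.q
        elif c.q.shape != q.shape or not np.allclose(c.q, q):
            c = c.interp(q)
        curves.append(c.y)
    ir = DifferenceCurve.load(root / ir_file).interp(q)
    return TimeSeriesDataset(q, np.array([d for d, _ in pairs]),
                             np.array(curves), ir_curve=ir)
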