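"""1D scattering-curve containers.

Two containers share one layout: ``ScatteringCurve`` for non-negative
absolute intensities S(q), and ``DifferenceCurve`` for signed difference
intensities dS(q).  Both live on a strictly increasing q grid in
1/Angstrom (q = 4 pi sin(theta) / lambda) and carry an arbitrary overall
scale: the molecule count N of the monodisperse-solution average is an
overall factor that the fitting step absorbs into its amplitude
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ScatteringCurve",
    "DifferenceCurve",
    "GridMismatchError",
    "default_q_grid",
    "same_grid",
]


class GridMismatchError(ValueError):
    """Two curves expected on a shared q grid are on different grids."""


def default_q_grid(qmax: float = 2.0, dq: float = 0.005) -> np.ndarray:
    """Default working grid: 0 .. qmax (inclusive) in steps of dq (1/A).

    Covers the structural fitting window (0.15-0.9 1/A) and the
    isosbestic normalization point at 1.6 1/A.
    """
    n = int(round(qmax / dq))
    return np.linspace(0.0, qmax, n + 1)


@dataclass
class _Curve:
    q: np.ndarray
    y: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.y.shape:
            raise ValueError("q and intensity must be 1D arrays of equal length")
        if not np.all(np.isfinite(self.q)) or not np.all(np.isfinite(self.y)):
            raise ValueError("curve contains non-finite values")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if self.q[0] < 0:
            raise ValueError("q must be non-negative")

    def interp(self, qgrid: np.ndarray):
        """Linear interpolation onto *qgrid* (flat extrapolation at edges)."""
        qgrid = np.asarray(qgrid, dtype=float)
        y = np.interp(qgrid, self.q, self.y)
        return replace(self, q=qgrid, y=y)

    def window(self, qmin: float, qmax: float):
        """Restrict to qmin <= q <= qmax (inclusive)."""
        m = (self.q >= qmin) & (self.q <= qmax)
        if not m.any():
            raise ValueError(f"window [{qmin}, {qmax}] outside grid")
        return replace(self, q=self.q[m], y=self.y[m])

    def save(self, path, header: str | None = None) -> None:
        """Write as two-column whitespace text with a one-line header."""
        if header is None:
            header = f"q(1/A) intensity {self.label}".strip()
        np.savetxt(path, np.column_stack([self.q, self.y]), header=header)

    @classmethod
    def load(cls, path, label: str = ""):
        """Read two-column text; '#'-comment lines and blank lines ignored."""
        data = np.loadtxt(path, comments="#", ndmin=2)
        if data.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (q, intensity)")
        return cls(data[:, 0], data[:, 1], label=label)


@dataclass
class ScatteringCurve(_Curve):
    """Isotropic solution scattering S(q) of a single component (arbitrary scale)."""

    def __post_init__(self):
        super().__post_init__()
        if np.any(self.y < -1e-9 * max(1.0, np.abs(self.y).max())):
            raise ValueError("single-component intensity must be non-negative")

    @property
    def intensity(self) -> np.ndarray:
        return self.y


@dataclass
class DifferenceCurve(_Curve):
    """Signed difference scattering dS(q) (arbitrary scale)."""

    @property
    def values(self) -> np.ndarray:
        return self.y


def same_grid(*curves: _Curve) -> np.ndarray:
    """Return the shared q grid of *curves* or raise :class:`GridMismatchError`."""
    q0 = curves[0].q
    for c in curves[1:]:
        if c.q.shape != q0.shape or not np.allclose(c.q, q0, rtol=0, atol=1e-12):
            raise GridMismatchError("curves are not on a shared q grid")
    return q0
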