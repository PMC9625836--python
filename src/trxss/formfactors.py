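"""Atomic x-ray form factors.

In-vacuo atomic scattering factors f(q) from the standard four-Gaussian
(Cromer-Mann) parameterization,

    f(q) = sum_i a_i * exp(-b_i * (q / 4 pi)^2) + c,

with coefficients from International Tables for Crystallography, Vol. C.
The published coefficient sums differ from the integer electron count by
up to ~0.01 e; each entry is rescaled multiplicatively so that f(0)
equals the element's electron count exactly, which downstream code relies
on (forward scattering adds in phase, S(0) = (total electrons)^2).

Solvent contrast is *not* applied here: these are vacuum form factors,
and excluded-volume effects are handled by the ratio S_tot/S_pm in
:mod:`trxss.solvent`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["form_factor", "electron_count", "known_elements", "UnknownElementError"]


class UnknownElementError(KeyError):
    """Raised when an element symbol has no form-factor entry."""


# element -> (a1..a4, b1..b4, c), International Tables Vol. C, Table 6.1.1.4
_CROMER_MANN = {
    "H": ((0.489918, 0.262003, 0.196767, 0.049879),
          (20.6593, 7.74039, 49.5519, 2.20159), 0.001305),
    "C": ((2.31000, 1.02000, 1.58860, 0.865000),
          (20.8439, 10.2075, 0.568700, 51.6512), 0.215600),
    "N": ((12.2126, 3.13220, 2.01250, 1.16630),
          (0.005700, 9.89330, 28.9975, 0.582600), -11.5290),
    "O": ((3.04850, 2.28680, 1.54630, 0.867000),
          (13.2771, 5.70110, 0.323900, 32.9089), 0.250800),
    "NA": ((4.76260, 3.17360, 1.26740, 1.11280),
           (3.28500, 8.84220, 0.313600, 129.424), 0.676000),
    "MG": ((5.42040, 2.17350, 1.22690, 2.30730),
           (2.82750, 79.2611, 0.380800, 7.19370), 0.858400),
    "P": ((6.43450, 4.17910, 1.78000, 1.49080),
          (1.90670, 27.1570, 0.526000, 68.1645), 1.11490),
    "S": ((6.90530, 5.20340, 1.43790, 1.58630),
          (1.46790, 22.2151, 0.253600, 56.1720), 0.866900),
    "CL": ((11.4604, 7.19640, 6.25560, 1.64550),
           (0.010400, 1.16620, 18.5194, 47.7784), -9.55740),
    "K": ((8.21860, 7.43980, 1.05190, 0.865900),
          (12.7949, 0.774800, 213.187, 41.6841), 1.42280),
    "CA": ((8.62660, 7.38730, 1.58990, 1.02110),
           (10.4421, 0.659900, 85.7484, 178.437), 1.37510),
    "FE": ((11.7695, 7.35730, 3.52220, 2.30450),
           (4.76110, 0.307200, 15.3535, 76.8805), 1.03690),
}

_ELECTRONS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "NA": 11, "MG": 12,
    "P": 15, "S": 16, "CL": 17, "K": 19, "CA": 20, "FE": 26,
}


def known_elements() -> tuple[str, ...]:
    """Element symbols with a form-factor entry (upper case)."""
    return tuple(_CROMER_MANN)


def electron_count(element: str) -> int:
    """Number of electrons of a neutral atom of *element*."""
    try:
        return _ELECTRONS[element.upper()]
    except KeyError:
        raise UnknownElementError(f"no electron count for element {element!r}")


def form_factor(element: str, q) -> np.ndarray | float:
    """In-vacuo atomic scattering factor f(q).

    Parameters
    ----------
    element
        Element symbol (case-insensitive).
    q
        Momentum transfer, q = 4 pi sin(theta) / lambda, in 1/Angstrom.
        Scalar or array; must be >= 0.

    Returns
    -------
    f(q), same shape as ``q``; f(0) equals the electron count exactly.
    """
    sym = element.upper().strip()
    if sym not in _CROMER_MANN:
        raise UnknownElementError(f"no form-factor entry for element {element!r}")
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    a, b, c = _CROMER_MANN[sym]
    s2 = (q / (4.0 * np.pi)) ** 2
    f = c + sum(ai * np.exp(-bi * s2) for ai, bi in zip(a, b))
    # normalize so forward scattering equals the integer electron count
    f0 = c + sum(a)
    f = f * (_ELECTRONS[sym] / f0)
    return f if f.shape else float(f)
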