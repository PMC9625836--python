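"""Synthetic fixtures: toy protein/micelle/water systems and TR-XSS datasets.

Everything here exists so the rest of the package is testable without
molecular dynamics or downloads.  The toy system mimics the bookkeeping of
a solubilized membrane protein: an idealized helical bundle (default 7
helices x 33 residues = 231 residues) surrounded by a noisy shell of
pseudo-detergent molecules whose composition mirrors a C14 H28 O6 detergent
(20 heavy + 28 hydrogen atoms per molecule; 190 molecules by default, size
sweeps 170-230 in steps of 5) plus an optional water lattice.  No chemistry
is implied -- the geometry exists to exercise scattering algebra, component
bookkeeping, and the fitting pipeline with known ground truth.

Trajectory-like ensembles add Gaussian positional jitter (protein default
0.2 A, the order of restrained-simulation Ca fluctuations) and a slow
random walk of whole detergent molecules so micelle-only difference curves
fluctuate between ensemble segments, which is what the micelle-swap
protocol exists to cancel.

Every generator is a pure function of its seed and spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import DifferenceCurve
from .dataset import TimeSeriesDataset
from .structure_io import AtomSet, DisplacementField, apply_deformation

__all__ = ["ToySystemSpec", "GridExperiment", "make_toy_system",
           "make_trajectory", "make_trxss_dataset", "make_grid_experiment",
           "toy_displacement_fields", "default_heat_curve", "GeometryError"]


class GeometryError(ValueError):
    """The requested toy geometry is not realizable."""


@dataclass
class ToySystemSpec:
    """Parameters of the toy protein/micelle/water system."""

    n_helices: int = 7
    residues_per_helix: int = 33          # 7 x 33 = 231 residues
    detergent_count: int = 190
    detergent_heavy: int = 20             # 14 C + 6 O per molecule
    detergent_hydrogens: int = 28
    micelle_radius: float = 30.0          # A, shell radius
    micelle_radius_sd: float = 2.0        # A, shell roughness
    water_box: tuple = (0.0, 0.0, 0.0)    # A; zero dimension -> no water
    water_density: float = 0.0334         # molecules / A^3 (bulk water)
    hydrogens: bool = True                # explicit H on protein and detergent
    seed: int = 0

    # geometry constants of the helical bundle
    ring_radius: float = 11.0             # A, helix axes from bundle axis
    helix_radius: float = 2.3             # A, Ca from helix axis
    rise_per_residue: float = 1.5         # A
    twist_per_residue: float = 100.0      # degrees

    def helix_span(self, i: int) -> tuple[int, int]:
        """Inclusive residue-id span of helix i (0-based)."""
        start = i * self.residues_per_helix + 1
        return start, start + self.residues_per_helix - 1


# local heavy-atom offsets from Ca: names and (element, offset) pseudo-geometry
_PROTEIN_HEAVIES = [
    ("N", "N", (-1.2, 0.5, -0.6)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (1.3, 0.4, 0.5)),
    ("O", "O", (2.1, 1.2, 0.3)),
    ("CB", "C", (-0.4, -1.4, 0.6)),
    ("CG1", "C", (-0.9, -2.5, -0.2)),
    ("CG2", "C", (0.8, -2.2, 1.5)),
    ("CD1", "C", (-0.3, -3.6, 0.9)),
]


def _protein_atoms(spec: ToySystemSpec, rng) -> AtomSet:
    names, elements, coords, res_ids = [], [], [], []
    twist = np.deg2rad(spec.twist_per_residue)
    for h in range(spec.n_helices):
        phi = 2.0 * np.pi * h / spec.n_helices
        axis_xy = spec.ring_radius * np.array([np.cos(phi), np.sin(phi), 0.0])
        direction = 1.0 if h % 2 == 0 else -1.0
        start, _ = spec.helix_span(h)
        for r in range(spec.residues_per_helix):
            rid = start + r
            ang = twist * r + phi
            ca = axis_xy + np.array([
                spec.helix_radius * np.cos(ang),
                spec.helix_radius * np.sin(ang),
                direction * spec.rise_per_residue
                * (r - spec.residues_per_helix / 2.0),
            ])
            for name, elem, off in _PROTEIN_HEAVIES:
                names.append(name)
                elements.append(elem)
                coords.append(ca + off)
                res_ids.append(rid)
            if spec.hydrogens:
                for k in range(8):
                    heavy = coords[-8 + k % 8]
                    names.append(f"H{k+1}")
                    elements.append("H")
                    coords.append(heavy + _unit(rng) * 1.0)
                    res_ids.append(rid)
    n = len(coords)
    return AtomSet(np.array(elements), np.array(coords), np.array(res_ids),
                   np.full(n, "ALA"), np.full(n, "A"), np.array(names),
                   np.full(n, "protein"), np.zeros(n, int))


def _unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _detergent_molecule(spec: ToySystemSpec, anchor, inward, rng):
    """One pseudo-detergent: a heavy-atom chain pointing inward plus H."""
    names, elements, coords = [], [], []
    length = 12.0
    n_heavy = spec.detergent_heavy
    # 14 carbons (tail) then 6 oxygens (head) along the chain
    heavy_elems = ["C"] * max(n_heavy - 6, 0) + ["O"] * min(6, n_heavy)
    for k in range(n_heavy):
        t = k / max(n_heavy - 1, 1)
        pos = anchor + inward * (t * length) + rng.normal(scale=0.35, size=3)
        names.append(f"{heavy_elems[k]}{k+1}")
        elements.append(heavy_elems[k])
        coords.append(pos)
    if spec.hydrogens:
        for k in range(spec.detergent_hydrogens):
            heavy = coords[k % n_heavy]
            names.append(f"H{k+1}")
            elements.append("H")
            coords.append(heavy + _unit(rng) * 1.0)
    return names, elements, coords


def _micelle_atoms(spec: ToySystemSpec, protein_extent: float, rng) -> AtomSet:
    if spec.micelle_radius <= protein_extent:
        raise GeometryError(
            f"micelle shell radius {spec.micelle_radius} A does not clear the "
            f"protein (extent {protein_extent:.1f} A)")
    names, elements, coords, res_ids = [], [], [], []
    # quasi-uniform anchors on the sphere (Fibonacci spiral) plus roughness
    n = spec.detergent_count
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for i in range(n):
        z = 1.0 - 2.0 * (i + 0.5) / n
        rho = np.sqrt(max(1.0 - z * z, 0.0))
        ang = golden * i
        u = np.array([rho * np.cos(ang), rho * np.sin(ang), z])
        radius = spec.micelle_radius + rng.normal(scale=spec.micelle_radius_sd)
        anchor = u * radius
        nm, el, xyz = _detergent_molecule(spec, anchor, -u, rng)
        names += nm
        elements += el
        coords += xyz
        res_ids += [i + 1] * len(nm)
    n_at = len(coords)
    return AtomSet(np.array(elements), np.array(coords), np.array(res_ids),
                   np.full(n_at, "DET"), np.full(n_at, "M"), np.array(names),
                   np.full(n_at, "micelle"), np.zeros(n_at, int))


def _water_atoms(spec: ToySystemSpec) -> AtomSet:
    dims = np.asarray(spec.water_box, float)
    if np.any(dims <= 0):
        n = 0
        return AtomSet(np.empty(0, "U4"), np.empty((0, 3)), np.empty(0, int),
                       np.empty(0, "U5"), np.empty(0, "U4"), np.empty(0, "U6"),
                       np.empty(0, "U7"), np.empty(0, int))
    spacing = spec.water_density ** (-1.0 / 3.0)
    axes = [np.arange(-d / 2.0 + spacing / 2.0, d / 2.0, spacing) for d in dims]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    names, elements, coords, res_ids = [], [], [], []
    for i, o in enumerate(grid):
        for name, elem, off in (("O", "O", (0.0, 0.0, 0.0)),
                                ("H1", "H", (0.76, 0.59, 0.0)),
                                ("H2", "H", (-0.76, 0.59, 0.0))):
            names.append(name)
            elements.append(elem)
            coords.append(o + np.array(off))
            res_ids.append(i + 1)
    n = len(coords)
    return AtomSet(np.array(elements), np.array(coords), np.array(res_ids),
                   np.full(n, "HOH"), np.full(n, "W"), np.array(names),
                   np.full(n, "water"), np.zeros(n, int))


def make_toy_system(spec: ToySystemSpec | None = None) -> AtomSet:
    """Deterministic toy system: helical bundle + detergent shell + water."""
    spec = spec or ToySystemSpec()
    rng = np.random.default_rng(spec.seed)
    protein = _protein_atoms(spec, rng)
    extent = float(np.linalg.norm(protein.coords[:, :2], axis=1).max())
    micelle = _micelle_atoms(spec, extent, rng)
    water = _water_atoms(spec)
    return AtomSet.concatenate([protein, micelle, water])


def toy_displacement_fields(spec: ToySystemSpec | None = None,
                            ef_amplitude: float = 1.0,
                            c_amplitude: float = 1.0,
                            g_amplitude: float = 0.5) -> dict:
    """Displacement fields on toy helices (C, EF pair, G by position).

    Helix indices scale with the bundle size: C is helix n//3, EF the one
    or two helices around 2n//3, G the last helix (for the default 7-helix
    bundle: C = 2, EF = 4+5, G = 6).

    Each field is a smooth ramp peaking mid-span with the given peak
    amplitude (A).  The EF motion is directed radially outward from the
    bundle axis, the C motion tangentially (perpendicular to its helix's
    radial direction) and the G motion axially, so the three amplitudes
    leave distinguishable signatures in the difference scattering rather
    than collinear ones.  Amplitudes are *unit* motions: the fit's gamma
    and delta scale them.
    """
    spec = spec or ToySystemSpec()
    n = spec.n_helices
    if n < 4:
        raise GeometryError("displacement fields need at least 4 helices")
    c_helix = n // 3
    g_helix = n - 1
    ef_helices = [(2 * n) // 3]
    if ef_helices[0] + 1 < g_helix:
        ef_helices.append(ef_helices[0] + 1)

    def ramp_field(h_indices, amplitude, label, direction):
        spans = [spec.helix_span(h) for h in h_indices]
        start = min(s for s, _ in spans)
        stop = max(e for _, e in spans)
        n = stop - start + 1
        vecs = np.zeros((n, 3))
        for h in h_indices:
            phi = 2.0 * np.pi * h / spec.n_helices
            radial = np.array([np.cos(phi), np.sin(phi), 0.0])
            tangential = np.array([-np.sin(phi), np.cos(phi), 0.0])
            axial = np.array([0.0, 0.0, 1.0])
            u = {"radial": radial, "tangential": tangential,
                 "axial": axial}[direction]
            s, e = spec.helix_span(h)
            for rid in range(s, e + 1):
                t = (rid - s) / max(e - s, 1)
                vecs[rid - start] = amplitude * np.sin(np.pi * t) * u
        return DisplacementField(start, stop, vecs, label=label)

    return {"C": ramp_field([c_helix], c_amplitude, "C", "tangential"),
            "EF": ramp_field(ef_helices, ef_amplitude, "EF", "radial"),
            "G": ramp_field([g_helix], g_amplitude, "G", "axial")}


def make_trajectory(base: AtomSet, n_frames: int,
                    protein_jitter: float = 0.2,
                    micelle_jitter: float = 0.5,
                    micelle_drift: float = 0.8,
                    displacement: tuple | None = None,
                    seed: int = 0) -> AtomSet:
    """Trajectory-like ensemble of jittered snapshots of *base*.

    ``displacement`` is (fields, gamma, delta): the protein is deformed
    toward the target before jittering.  Each frame draws independent
    Gaussian jitter per atom (protein/water at ``protein_jitter``, micelle
    at ``micelle_jitter``); whole detergent molecules additionally follow a
    random walk with per-frame step ``micelle_drift`` so the micelle
    decorrelates from its start the way an unrestrained simulation does.
    """
    if protein_jitter < 0 or micelle_jitter < 0 or micelle_drift < 0:
        raise ValueError("jitter amplitudes must be non-negative")
    rng = np.random.default_rng(seed)
    if displacement is not None:
        fields, gamma, delta = displacement
        base = apply_deformation(base, fields, gamma, delta)
    is_mic = base.component == "micelle"
    mol_ids = np.unique(base.res_id[is_mic])
    drift = {int(m): np.zeros(3) for m in mol_ids}
    frames = []
    for f in range(n_frames):
        coords = base.coords.copy()
        jit = np.where(is_mic[:, None], micelle_jitter, protein_jitter)
        if protein_jitter or micelle_jitter:
            coords = coords + rng.normal(size=coords.shape) * jit
        if micelle_drift and len(mol_ids):
            for m in mol_ids:
                drift[int(m)] = drift[int(m)] + rng.normal(
                    scale=micelle_drift, size=3)
                coords[is_mic & (base.res_id == m)] += drift[int(m)]
        frames.append(base.with_coords(coords).with_model_index(f))
    return AtomSet.concatenate(frames)


@dataclass
class GridExperiment:
    """A complete synthetic structural-fitting problem with known truth."""

    q: np.ndarray
    gammas: list
    deltas: list
    node_curves: dict            # (gamma, delta) -> {"dS_p", "dS_pm"}
    correction: DifferenceCurve  # micelle-size-sweep second SVD component
    spectrum: object             # UndulatorSpectrum
    truth_node: tuple            # (gamma*, delta*)
    truth_params: object         # FitParameters used to assemble the truth
    truth: DifferenceCurve       # noise-free synthetic "experimental" curve
    qpm_grid: np.ndarray


def make_grid_experiment(seed: int = 0, n_frames: int = 12,
                         ef_amplitude: float = 3.0, c_amplitude: float = 4.0,
                         truth_index: tuple = (3, 2),
                         detergent_count: int = 24,
                         sweep_sizes=(20, 22, 24, 26, 28),
                         true_A2: float = 0.7, true_qpm: float = 0.2,
                         qmax: float = 1.0, nq: int = 101) -> GridExperiment:
    """Build a desk-scale (gamma, delta) fitting problem with known truth.

    Thirty grid nodes (gamma 0..1.25 in steps of 1/6 x delta 0..4/3 in
    steps of 1/3) each get a short jittered trajectory of a small toy
    system; swap-protocol and protein-only difference curves are computed
    per node, a micelle-size sweep supplies the correction curve, and the
    "experimental" curve is the assembled theory at one grid node.  The EF
    unit motion is radial and the C unit motion tangential with amplitudes
    chosen so one grid step in either parameter moves the difference
    scattering by a comparable, resolvable amount.
    """
    from .corrections import gaussian_spectrum
    from .cross_term import SwapQuartet, swap_difference
    from .fit import FitParameters, assemble_theory
    from .scattering import ensemble_mean_intensity

    spec = ToySystemSpec(n_helices=7, residues_per_helix=8,
                         detergent_count=detergent_count,
                         micelle_radius=22.0, hydrogens=False, seed=seed)
    base = make_toy_system(spec)
    fields = toy_displacement_fields(spec, ef_amplitude=ef_amplitude,
                                     c_amplitude=c_amplitude)
    q = np.linspace(0.0, qmax, nq)
    gammas = [round(x, 6) for x in np.arange(6) / 6.0 * 1.5]
    deltas = [round(x, 6) for x in np.arange(5) / 3.0]

    def components(traj):
        return (traj.select(traj.component == "protein"),
                traj.select(traj.component == "micelle"))

    rest = make_trajectory(base, n_frames, seed=seed * 7919 + 100)
    p_rest, m_rest = components(rest)
    Sp_rest = ensemble_mean_intensity(p_rest, q)
    node_curves = {}
    for i, g in enumerate(gammas):
        for j, d in enumerate(deltas):
            traj = make_trajectory(base, n_frames,
                                   displacement=(fields, g, d),
                                   seed=seed * 7919 + 1000 + 31 * i + j)
            p_exc, m_exc = components(traj)
            dS_pm = swap_difference(
                SwapQuartet(p_rest, p_exc, m_rest, m_exc), q)
            Sp_exc = ensemble_mean_intensity(p_exc, q)
            node_curves[(g, d)] = {
                "dS_p": DifferenceCurve(q, Sp_exc.y - Sp_rest.y, "dS_p"),
                "dS_pm": dS_pm}

    # micelle-size sweep at a fixed deformation for the correction curve
    from .corrections import micelle_size_correction
    sweep = []
    for k, size in enumerate(sweep_sizes):
        sspec = ToySystemSpec(n_helices=7, residues_per_helix=8,
                              detergent_count=size, micelle_radius=22.0,
                              hydrogens=False, seed=seed)
        sbase = make_toy_system(sspec)
        r2 = make_trajectory(sbase, max(n_frames // 2, 2),
                             seed=seed * 7919 + 5000 + k)
        e2 = make_trajectory(sbase, max(n_frames // 2, 2),
                             displacement=(fields, 1.0, 0.0),
                             seed=seed * 7919 + 6000 + k)
        pr2, mr2 = components(r2)
        pe2, me2 = components(e2)
        sweep.append(swap_difference(SwapQuartet(pr2, pe2, mr2, me2), q))
    correction = micelle_size_correction(sweep).correction

    spectrum = gaussian_spectrum()
    gstar, dstar = gammas[truth_index[0]], deltas[truth_index[1]]
    params = FitParameters(gamma=gstar, delta=dstar, A2=true_A2,
                           q_pm=true_qpm)
    nc = node_curves[(gstar, dstar)]
    truth = assemble_theory(nc["dS_p"], nc["dS_pm"], correction, None,
                            params, spectrum)
    return GridExperiment(q=q, gammas=gammas, deltas=deltas,
                          node_curves=node_curves, correction=correction,
                          spectrum=spectrum, truth_node=(gstar, dstar),
                          truth_params=params, truth=truth,
                          qpm_grid=np.arange(0.05, 0.301, 0.01))


def default_heat_curve(q) -> DifferenceCurve:
    """Smooth solvent-heating signature overlapping the 0.51-1.45 window."""
    q = np.asarray(q, float)
    y = np.exp(-0.5 * ((q - 1.5) / 0.4) ** 2) - 0.3 * np.exp(
        -0.5 * ((q - 0.3) / 0.25) ** 2)
    return DifferenceCurve(q, y, label="heat")


def make_trxss_dataset(basis1: DifferenceCurve, basis2: DifferenceCurve,
                       tau1: float, delays,
                       heat_curve: DifferenceCurve | None = None,
                       heat_amplitudes=None, noise_sd: float = 0.0,
                       seed: int = 0) -> TimeSeriesDataset:
    """Two-state synthetic time series with heat contamination.

    dS(q, dt) = c1 b1 + c2 b2 + h(dt) heat + noise, with c1 = exp(-dt/tau1)
    and c2 = 1 - c1 (populations cross at tau1 ln 2).  Ground truth is kept
    in ``dataset.truth``.
    """
    from .curves import same_grid
    q = same_grid(basis1, basis2)
    delays = np.asarray(delays, float)
    rng = np.random.default_rng(seed)
    c1 = np.exp(-delays / tau1)
    c2 = 1.0 - c1
    if heat_curve is None:
        heat_curve = default_heat_curve(q)
    else:
        same_grid(basis1, heat_curve)
    if heat_amplitudes is None:
        h = np.zeros_like(delays)
    else:
        h = np.broadcast_to(np.asarray(heat_amplitudes, float),
                            delays.shape).copy()
    curves = (np.outer(c1, basis1.y) + np.outer(c2, basis2.y)
              + np.outer(h, heat_curve.y))
    if noise_sd > 0:
        curves = curves + rng.normal(scale=noise_sd, size=curves.shape)
    return TimeSeriesDataset(
        q, delays, curves, ir_curve=heat_curve,
        truth={"tau1": tau1, "c1": c1, "c2": c2, "heat": h,
               "basis1": basis1.y.copy(), "basis2": basis2.y.copy(),
               "crossing": tau1 * np.log(2.0), "noise_sd": noise_sd,
               "seed": seed})
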