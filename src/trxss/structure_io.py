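"""Atomic structures: reading, writing, component tagging, helix displacements.

The central container is :class:`AtomSet`, a flat record of atoms tagged by
component (protein / micelle / water) with a model index so that one object
can hold a whole trajectory-like ensemble of snapshots.

Helix displacement fields are per-residue C-alpha difference vectors between
two deposited structures (e.g. a light-activated minus a resting
conformation).  A target conformation is built by adding scaled fields to
the resting C-alpha coordinates,

    Ca  ->  Ca + gamma * dCa_EF + delta * dCa_C + dCa_G,

where gamma scales the E/F-helix motion, delta the C-helix motion, and the
G-helix motion enters with fixed unit amplitude.  Displacements are taken in
the deposited coordinate frame without re-superposition (isomorphous pairs);
an optional least-squares superposition flag exists but defaults off.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .formfactors import UnknownElementError, known_elements

__all__ = [
    "AtomSet",
    "DisplacementField",
    "FormatError",
    "DataError",
    "COMPONENT_TAGS",
    "DEFAULT_WATER_RESNAMES",
    "read_structure",
    "write_structure",
    "count_atoms",
    "extract_displacement_field",
    "adjust_disordered",
    "apply_deformation",
    "displaced_residue_count",
    "mean_ca_displacement",
]

COMPONENT_TAGS = ("protein", "micelle", "water")

#: residue names tagged ``water`` when the component rules do not say otherwise
DEFAULT_WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL", "TIP3", "TIP", "SPC"})


class FormatError(ValueError):
    """A structure file could not be parsed."""


class DataError(ValueError):
    """Structurally valid input lacks the data an operation needs."""


@dataclass
class AtomSet:
    """Tagged atomic coordinates for one snapshot or an ensemble.

    All fields are parallel arrays of length ``n_atoms``.  ``model`` indexes
    snapshots of a multi-model ensemble (0-based, contiguous is not
    required but conventional).
    """

    element: np.ndarray       # str, upper-case symbols
    coords: np.ndarray        # (n, 3) float, Angstrom
    res_id: np.ndarray        # int
    res_name: np.ndarray      # str
    chain: np.ndarray         # str
    atom_name: np.ndarray     # str
    component: np.ndarray     # str in COMPONENT_TAGS
    model: np.ndarray = None  # int

    def __post_init__(self):
        n = len(self.coords)
        self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)
        self.element = np.asarray(self.element, dtype="U4")
        self.res_id = np.asarray(self.res_id, dtype=int)
        self.res_name = np.asarray(self.res_name, dtype="U5")
        self.chain = np.asarray(self.chain, dtype="U4")
        self.atom_name = np.asarray(self.atom_name, dtype="U6")
        self.component = np.asarray(self.component, dtype="U7")
        if self.model is None:
            self.model = np.zeros(n, dtype=int)
        self.model = np.asarray(self.model, dtype=int)
        for arr in (self.element, self.res_id, self.res_name, self.chain,
                    self.atom_name, self.component, self.model):
            if len(arr) != n:
                raise ValueError("AtomSet fields must be parallel arrays")
        self.validate()

    def validate(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        bad = set(np.unique(self.component)) - set(COMPONENT_TAGS)
        if bad and len(self):
            raise ValueError(f"unknown component tags: {sorted(bad)}")
        table = set(known_elements())
        unknown = set(np.unique(self.element)) - table
        if unknown and len(self):
            raise UnknownElementError(
                f"elements without form-factor entries: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.coords)

    def select(self, mask: np.ndarray) -> "AtomSet":
        return AtomSet(self.element[mask], self.coords[mask], self.res_id[mask],
                       self.res_name[mask], self.chain[mask], self.atom_name[mask],
                       self.component[mask], self.model[mask])

    def by_component(self, tag: str) -> "AtomSet":
        if tag == "all":
            return self
        if tag not in COMPONENT_TAGS:
            raise ValueError(f"unknown component {tag!r}")
        return self.select(self.component == tag)

    @property
    def model_indices(self) -> np.ndarray:
        return np.unique(self.model)

    @property
    def n_models(self) -> int:
        return len(self.model_indices)

    def get_model(self, index: int) -> "AtomSet":
        return self.select(self.model == index)

    def models(self):
        """Iterate over single-model AtomSets in model-index order."""
        for i in self.model_indices:
            yield self.get_model(i)

    def with_coords(self, coords: np.ndarray) -> "AtomSet":
        return AtomSet(self.element, coords, self.res_id, self.res_name,
                       self.chain, self.atom_name, self.component, self.model)

    def with_model_index(self, index: int) -> "AtomSet":
        return AtomSet(self.element, self.coords, self.res_id, self.res_name,
                       self.chain, self.atom_name, self.component,
                       np.full(len(self), index, dtype=int))

    @staticmethod
    def concatenate(parts: "list[AtomSet]") -> "AtomSet":
        if not parts:
            return empty_atomset()
        return AtomSet(
            np.concatenate([p.element for p in parts]),
            np.concatenate([p.coords for p in parts]),
            np.concatenate([p.res_id for p in parts]),
            np.concatenate([p.res_name for p in parts]),
            np.concatenate([p.chain for p in parts]),
            np.concatenate([p.atom_name for p in parts]),
            np.concatenate([p.component for p in parts]),
            np.concatenate([p.model for p in parts]),
        )


def empty_atomset() -> AtomSet:
    z = np.empty(0)
    return AtomSet(np.empty(0, "U4"), np.empty((0, 3)), np.empty(0, int),
                   np.empty(0, "U5"), np.empty(0, "U4"), np.empty(0, "U6"),
                   np.empty(0, "U7"), np.empty(0, int))


def _resolve_component(res_name: str, chain: str, rules: dict | None) -> str:
    rules = rules or {}
    if res_name in rules:
        return rules[res_name]
    if chain in rules:
        return rules[chain]
    if res_name in DEFAULT_WATER_RESNAMES:
        return "water"
    return "protein"


def read_structure(path, component_rules: dict | None = None) -> AtomSet:
    """Read a (possibly multi-model) PDB file into a tagged :class:`AtomSet`.

    ``component_rules`` maps residue names and/or chain identifiers to
    component tags (``protein`` / ``micelle`` / ``water``); residue-name
    matches win over chain matches.  Untagged residues default to
    ``protein`` except for common water residue names.  Hydrogens are kept.
    Alternate locations resolve to the highest-occupancy conformer.
    """
    from biotite.structure.io import pdb

    if component_rules:
        bad = set(component_rules.values()) - set(COMPONENT_TAGS)
        if bad:
            raise ValueError(f"component rules map to unknown tags: {sorted(bad)}")
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        n_models = pdb_file.get_model_count()
    except Exception as exc:
        raise FormatError(f"{path}: not a parseable PDB file ({exc})") from exc
    parts = []
    for i in range(1, n_models + 1):
        try:
            arr = pdb_file.get_structure(model=i, altloc="occupancy")
        except Exception as exc:
            raise FormatError(f"{path}: model {i}: {exc}") from exc
        n = arr.array_length()
        comp = np.array([_resolve_component(rn, ch, component_rules)
                         for rn, ch in zip(arr.res_name, arr.chain_id)], dtype="U7")
        element = np.char.upper(arr.element.astype("U4"))
        parts.append(AtomSet(element, arr.coord, arr.res_id, arr.res_name,
                             arr.chain_id, arr.atom_name, comp,
                             np.full(n, i - 1, dtype=int)))
    if not parts:
        return empty_atomset()
    return AtomSet.concatenate(parts)


def write_structure(atoms: AtomSet, path) -> None:
    """Write an :class:`AtomSet` as a PDB file (one MODEL per model index)."""
    import biotite.structure as struc
    from biotite.structure.io import pdb

    pdb_file = pdb.PDBFile()
    arrays = []
    for sub in atoms.models() if len(atoms) else []:
        arr = struc.AtomArray(len(sub))
        arr.coord = sub.coords
        arr.res_id = sub.res_id
        arr.res_name = sub.res_name
        arr.chain_id = sub.chain
        arr.atom_name = sub.atom_name
        arr.element = sub.element
        arr.hetero = sub.component != "protein"
        arrays.append(arr)
    if not arrays:
        pdb_file.write(str(path))
        return
    if len(arrays) == 1:
        pdb_file.set_structure(arrays[0])
    else:
        stack = struc.stack(arrays)
        pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def count_atoms(atoms: AtomSet, component: str = "all") -> tuple[int, int, int]:
    """(total, hydrogen, non-hydrogen) atom counts for one component or all."""
    sub = atoms.by_component(component)
    n_h = int(np.count_nonzero(sub.element == "H"))
    return len(sub), n_h, len(sub) - n_h


def _ca_lookup(atoms: AtomSet, span: range) -> dict[int, np.ndarray]:
    first = atoms.get_model(atoms.model_indices[0]) if len(atoms) else atoms
    is_ca = first.atom_name == "CA"
    out = {}
    for rid, xyz in zip(first.res_id[is_ca], first.coords[is_ca]):
        if rid in span:
            out.setdefault(int(rid), xyz)
    return out


@dataclass
class DisplacementField:
    """Per-residue C-alpha displacement vectors on an inclusive residue span."""

    start: int
    stop: int                 # inclusive
    vectors: np.ndarray       # (stop - start + 1, 3); NaN rows need adjustment
    label: str = ""           # conventionally "C", "EF" or "G"
    needs_adjustment: list = dfield(default_factory=list)

    def __post_init__(self):
        n = self.stop - self.start + 1
        if n <= 0:
            raise ValueError("empty residue span")
        self.vectors = np.asarray(self.vectors, dtype=float).reshape(n, 3)
        finite = np.isfinite(self.vectors).all(axis=1)
        for i, ok in enumerate(finite):
            if not ok and (self.start + i) not in self.needs_adjustment:
                self.needs_adjustment.append(self.start + i)

    @property
    def residues(self) -> np.ndarray:
        return np.arange(self.start, self.stop + 1)

    def vector_for(self, res_id: int) -> np.ndarray:
        if not (self.start <= res_id <= self.stop):
            raise KeyError(res_id)
        return self.vectors[res_id - self.start]

    def __len__(self) -> int:
        return self.stop - self.start + 1


def extract_displacement_field(reference: AtomSet, target: AtomSet,
                               span: tuple[int, int], label: str = "",
                               superpose: bool = False) -> DisplacementField:
    """Per-residue target-minus-reference C-alpha vectors over *span*.

    *span* is inclusive on both ends.  Residues lacking a C-alpha in either
    structure get a NaN vector and are listed in ``needs_adjustment`` (fill
    them with :func:`adjust_disordered`).  With ``superpose=True`` the
    target is first least-squares superposed onto the reference over the
    shared C-alphas (off by default: deposited frames are used as-is).
    """
    start, stop = int(span[0]), int(span[1])
    if stop < start:
        raise ValueError(f"empty residue span ({start}, {stop})")
    rng = range(start, stop + 1)
    ref_ca = _ca_lookup(reference, rng)
    tgt_ca = _ca_lookup(target, rng)
    if not ref_ca or not tgt_ca:
        raise DataError(f"no C-alpha atoms found in span {start}-{stop}")
    if superpose:
        shared = sorted(set(ref_ca) & set(tgt_ca))
        if len(shared) >= 3:
            A = np.array([tgt_ca[r] for r in shared])
            B = np.array([ref_ca[r] for r in shared])
            R, t = _kabsch(A, B)
            tgt_ca = {r: R @ v + t for r, v in tgt_ca.items()}
    vecs = np.full((stop - start + 1, 3), np.nan)
    missing = []
    for rid in rng:
        if rid in ref_ca and rid in tgt_ca:
            vecs[rid - start] = tgt_ca[rid] - ref_ca[rid]
        else:
            missing.append(rid)
    return DisplacementField(start, stop, vecs, label=label,
                             needs_adjustment=missing)


def _kabsch(A: np.ndarray, B: np.ndarray):
    """Rotation R and translation t minimizing ||R A + t - B||."""
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, cb - R @ ca


def adjust_disordered(field: DisplacementField,
                      residues: list[int] | None = None) -> DisplacementField:
    """Replace listed residues' vectors by distance-weighted interpolation.

    Each listed residue (default: the field's ``needs_adjustment`` list)
    takes a weighted average of the nearest non-listed residue on each side,
    with weights inversely proportional to sequence distance -- a linear
    ramp across a contiguous block.  Listed residues at a span boundary
    have no flanking anchor and raise :class:`DataError`.
    """
    listed = sorted(set(residues if residues is not None
                        else field.needs_adjustment))
    if not listed:
        return field
    for r in listed:
        if not (field.start < r < field.stop):
            raise DataError(
                f"residue {r} at or outside span boundary; no flanking anchors")
    vecs = field.vectors.copy()
    anchors = [r for r in field.residues if r not in listed]
    for r in listed:
        left = max((a for a in anchors if a < r), default=None)
        right = min((a for a in anchors if a > r), default=None)
        if left is None or right is None:
            raise DataError(f"residue {r}: missing flanking anchor")
        dl, dr = r - left, right - r
        vl = field.vectors[left - field.start]
        vr = field.vectors[right - field.start]
        if not (np.isfinite(vl).all() and np.isfinite(vr).all()):
            raise DataError(f"residue {r}: anchor vectors are themselves missing")
        # weights 1/dl, 1/dr  =>  v = (dr*vl + dl*vr) / (dl + dr)
        vecs[r - field.start] = (dr * vl + dl * vr) / (dl + dr)
    return DisplacementField(field.start, field.stop, vecs, label=field.label,
                             needs_adjustment=[])


def displaced_residue_count(fields) -> int:
    """Total number of residues covered by the given displacement fields."""
    return sum(len(f) for f in fields)


def apply_deformation(atoms: AtomSet, fields: dict, gamma: float,
                      delta: float) -> AtomSet:
    """Build target coordinates  Ca + gamma*dCa_EF + delta*dCa_C + dCa_G.

    ``fields`` maps labels ``"C"``, ``"EF"``, ``"G"`` (any subset) to
    :class:`DisplacementField` objects on non-overlapping residue spans.
    Every atom of a displaced residue is carried rigidly with its residue's
    C-alpha shift (only C-alphas are restrained upstream; rigid carry is the
    simplest reproducible rule for the rest).  The G-helix amplitude is
    fixed at 1.  Returns a new :class:`AtomSet`.
    """
    scales = {"C": delta, "EF": gamma, "G": 1.0}
    unknown = set(fields) - set(scales)
    if unknown:
        raise ValueError(f"unknown field labels: {sorted(unknown)}")
    covered: set[int] = set()
    for f in fields.values():
        span = set(range(f.start, f.stop + 1))
        if covered & span:
            raise ValueError("displacement field spans overlap")
        covered |= span
    coords = atoms.coords.copy()
    for label, f in fields.items():
        if f.needs_adjustment:
            raise DataError(
                f"field {label!r} has unadjusted residues {f.needs_adjustment}")
        s = scales[label]
        for i, rid in enumerate(f.residues):
            mask = atoms.res_id == rid
            if mask.any():
                coords[mask] += s * f.vectors[i]
    return atoms.with_coords(coords)


def mean_ca_displacement(a: AtomSet, b: AtomSet, span: tuple[int, int]) -> float:
    """Unweighted mean C-alpha-to-C-alpha distance (A) over an inclusive span."""
    start, stop = int(span[0]), int(span[1])
    rng = range(start, stop + 1)
    ca_a = _ca_lookup(a, rng)
    ca_b = _ca_lookup(b, rng)
    shared = sorted(set(ca_a) & set(ca_b))
    if not shared:
        raise DataError(f"no shared C-alpha residues in span {start}-{stop}")
    d = [np.linalg.norm(ca_a[r] - ca_b[r]) for r in shared]
    return float(np.mean(d))
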