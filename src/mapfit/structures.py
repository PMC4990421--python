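"""Coarse-grained molecular model: one bead per residue at the C-alpha position.

The internal force field standing in for a full MD potential is a
structure-based (Go-like) model built from a reference conformation: harmonic
bonds/angles/dihedrals at their reference values, Gaussian-well native contacts
between sequence-distant bead pairs that are close in the reference, and a soft
excluded-volume repulsion.  Deforming the model away from its reference costs
internal energy, which the map-derived fitting potential must pay for -- the
same competition that drives density-guided fitting with an all-atom force
field, at a fraction of the cost.

Secondary-structure restraints (harmonic terms on pseudo-dihedrals and 1-4
distances inside helix/strand segments) protect local geometry from strong map
forces, mirroring the restraint term of the fitting potential's total energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.transform import Rotation

from .errors import StructureFormatError

__all__ = [
    "Structure",
    "Topology",
    "TopologyParams",
    "RestraintSet",
    "read_structure",
    "write_structure",
    "build_topology",
    "assign_ss_restraints",
    "ss_segments",
    "rmsd",
]

#: Average residue mass used for coarse-grained beads, amu.
DEFAULT_BEAD_MASS = 110.0


@dataclass
class Structure:
    """A bead-per-residue model.

    Arrays are index-aligned; ``ss`` holds one of ``'H'`` (helix), ``'E'``
    (strand) or ``'C'`` (coil) per bead.  ``weight`` is the per-bead coupling
    weight for the map potential (the bead mass by default).
    """

    ids: np.ndarray
    res_index: np.ndarray
    chain_id: np.ndarray
    xyz: np.ndarray
    mass: np.ndarray
    weight: np.ndarray
    ss: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.res_index = np.asarray(self.res_index, dtype=int)
        self.chain_id = np.asarray(self.chain_id, dtype="U4")
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.mass = np.asarray(self.mass, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        self.ss = np.asarray(self.ss, dtype="U1")
        n = self.xyz.shape[0]
        for name in ("ids", "res_index", "chain_id", "mass", "weight", "ss"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"field {name} length mismatch with coordinates")
        if len(np.unique(self.ids)) != n:
            raise ValueError("bead ids must be unique")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("bead positions must be finite")
        if np.any(self.mass <= 0) or np.any(self.weight <= 0):
            raise ValueError("masses and coupling weights must be positive")

    @property
    def n_beads(self) -> int:
        return self.xyz.shape[0]

    def copy(self) -> "Structure":
        return Structure(
            self.ids.copy(), self.res_index.copy(), self.chain_id.copy(),
            self.xyz.copy(), self.mass.copy(), self.weight.copy(), self.ss.copy(),
        )

    def with_positions(self, xyz: np.ndarray) -> "Structure":
        out = self.copy()
        out.xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        if out.xyz.shape[0] != self.n_beads:
            raise ValueError("replacement coordinates have wrong bead count")
        return out

    @classmethod
    def from_xyz(cls, xyz, chain_id="A", ss=None, mass=DEFAULT_BEAD_MASS) -> "Structure":
        """Build a single-chain model from raw coordinates (uniform masses/weights)."""
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        n = xyz.shape[0]
        if ss is None:
            ss = np.full(n, "C")
        masses = np.full(n, float(mass))
        return cls(np.arange(n), np.arange(1, n + 1), np.full(n, chain_id),
                   xyz, masses, masses.copy(), np.asarray(ss, dtype="U1"))


# ---------------------------------------------------------------------------
# PDB I/O (via biotite)
# ---------------------------------------------------------------------------

def read_structure(path) -> Structure:
    """Read a PDB file as one bead per residue at the C-alpha position.

    All-atom files are reduced to their CA atoms; duplicate residue numbers
    within a chain or missing coordinates raise a format error.
    """
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1, extra_fields=["b_factor"])
    except Exception as exc:  # biotite raises several parser error types
        raise StructureFormatError(f"cannot parse PDB file {path!r}: {exc}") from exc
    ca = atoms[atoms.atom_name == "CA"]
    if ca.array_length() == 0:
        raise StructureFormatError(f"no CA atom records found in {path!r}")
    if not np.all(np.isfinite(ca.coord)):
        raise StructureFormatError(f"non-finite coordinates in {path!r}")
    chains = ca.chain_id
    res = ca.res_id
    for ch in np.unique(chains):
        r = res[chains == ch]
        if len(np.unique(r)) != len(r):
            raise StructureFormatError(f"duplicate residue index within chain {ch!r} in {path!r}")
    n = ca.array_length()
    mass = np.full(n, DEFAULT_BEAD_MASS)
    bfac = ca.get_annotation("b_factor") if "b_factor" in ca.get_annotation_categories() else None
    struct = Structure(np.arange(n), res, chains, ca.coord.astype(float), mass, mass.copy(),
                       np.full(n, "C"))
    if bfac is not None:
        struct.b_factor = np.asarray(bfac, dtype=float)  # carried for round-trips
    return struct


def write_structure(structure: Structure, path, b_factor: np.ndarray | None = None) -> None:
    """Write the bead model as a CA-only PDB; optional values for the B column."""
    n = structure.n_beads
    arr = bst.AtomArray(n)
    arr.coord = structure.xyz.astype(np.float32)
    arr.chain_id = structure.chain_id
    arr.res_id = structure.res_index
    arr.res_name = np.full(n, "ALA")
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.hetero = np.full(n, False)
    if b_factor is None:
        b_factor = np.zeros(n)
    b = np.asarray(b_factor, dtype=float).copy()
    if np.any(b > 999.99):
        warnings.warn("B-factors above 999.99 clipped to the PDB column limit")
        b = np.clip(b, None, 999.99)
    arr.set_annotation("b_factor", b)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def write_trajectory_pdb(frames: np.ndarray, template: Structure, path) -> None:
    """Write trajectory frames as a multi-model CA-only PDB."""
    n = template.n_beads
    stack = bst.AtomArrayStack(len(frames), n)
    stack.coord = np.asarray(frames, dtype=np.float32)
    stack.chain_id = template.chain_id
    stack.res_id = template.res_index
    stack.res_name = np.full(n, "ALA")
    stack.atom_name = np.full(n, "CA")
    stack.element = np.full(n, "C")
    stack.hetero = np.full(n, False)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

@dataclass
class TopologyParams:
    """Force-field constants of the structure-based surrogate potential.

    Units: kcal/mol, Angstrom, radian.  Defaults give bond/angle stiffness well
    above the map forces (chain connectivity is never broken by fitting) and
    finite-depth native contacts that can yield under sustained map force.
    """

    bond_k: float = 100.0
    angle_k: float = 20.0
    dihedral_k: float = 2.0
    contact_cutoff: float = 8.0
    contact_epsilon: float = 8.0
    contact_width: float = 1.5
    excluded_radius: float = 4.5
    excluded_k: float = 20.0


@dataclass
class Topology:
    """Bonded terms, native contacts and excluded-volume pairs of a reference model."""

    bond_idx: np.ndarray
    bond_r0: np.ndarray
    angle_idx: np.ndarray
    angle_t0: np.ndarray
    dihedral_idx: np.ndarray
    dihedral_p0: np.ndarray
    contact_idx: np.ndarray
    contact_r0: np.ndarray
    excluded_idx: np.ndarray
    excluded_r: np.ndarray
    params: TopologyParams

    def __post_init__(self) -> None:
        for name in ("bond_idx", "angle_idx", "dihedral_idx", "contact_idx", "excluded_idx"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        for name in ("bond_r0", "angle_t0", "dihedral_p0", "contact_r0", "excluded_r"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.bond_idx.size and np.any(self.bond_r0 <= 0):
            raise ValueError("bond equilibrium lengths must be positive")
        if self.contact_idx.size and np.any(self.contact_r0 <= 0):
            raise ValueError("contact equilibrium distances must be positive")
        if self.bond_idx.size:
            key = {tuple(sorted(p)) for p in self.bond_idx}
            if len(key) != len(self.bond_idx):
                raise ValueError("duplicate bond")

    @property
    def n_contacts(self) -> int:
        return len(self.contact_idx)


def _chain_runs(structure: Structure):
    """Consecutive index runs sharing a chain id (beads assumed chain-ordered)."""
    runs = []
    start = 0
    for i in range(1, structure.n_beads + 1):
        if i == structure.n_beads or structure.chain_id[i] != structure.chain_id[start]:
            runs.append((start, i))
            start = i
    return runs


def dihedral_angle(p0, p1, p2, p3):
    """Signed dihedral(s) for the four position arrays, in radians."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m * n2, axis=-1)
    return np.arctan2(y, x)


def bend_angle(p0, p1, p2):
    v1 = p0 - p1
    v2 = p2 - p1
    cosang = np.sum(v1 * v2, axis=-1) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
    )
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def build_topology(reference: Structure, params: TopologyParams | None = None) -> Topology:
    """Build the structure-based surrogate topology from a reference conformation.

    Bonds link consecutive beads of each chain at their reference separation;
    angles and dihedrals take their reference values; native contacts join
    pairs at least 4 residues apart (or on different chains) within the cutoff.
    The reference conformation is an exact stationary point of the resulting
    energy.  Deterministic given (reference, params).
    """
    if params is None:
        params = TopologyParams()
    runs = _chain_runs(reference)
    for s, e in runs:
        if e - s < 3:
            raise ValueError(
                f"chain {reference.chain_id[s]!r} has {e - s} beads; need at least 3"
            )
    xyz = reference.xyz
    bond_idx, angle_idx, dih_idx = [], [], []
    for s, e in runs:
        idx = np.arange(s, e)
        bond_idx += [(i, i + 1) for i in idx[:-1]]
        angle_idx += [(i, i + 1, i + 2) for i in idx[:-2]]
        dih_idx += [(i, i + 1, i + 2, i + 3) for i in idx[:-3]]
    bond_idx = np.array(bond_idx, dtype=int).reshape(-1, 2)
    angle_idx = np.array(angle_idx, dtype=int).reshape(-1, 3)
    dih_idx = np.array(dih_idx, dtype=int).reshape(-1, 4)
    bond_r0 = np.linalg.norm(xyz[bond_idx[:, 0]] - xyz[bond_idx[:, 1]], axis=1)
    angle_t0 = bend_angle(xyz[angle_idx[:, 0]], xyz[angle_idx[:, 1]], xyz[angle_idx[:, 2]])
    dih_p0 = (
        dihedral_angle(xyz[dih_idx[:, 0]], xyz[dih_idx[:, 1]], xyz[dih_idx[:, 2]], xyz[dih_idx[:, 3]])
        if len(dih_idx) else np.empty(0)
    )
    # sequence separation (same chain) for pair classification
    n = reference.n_beads
    seq = np.arange(n)
    same_chain = reference.chain_id[:, None] == reference.chain_id[None, :]
    sep = np.abs(seq[:, None] - seq[None, :])
    nonlocal_pair = (~same_chain) | (sep >= 4)
    iu, ju = np.triu_indices(n, k=1)
    keep = nonlocal_pair[iu, ju]
    iu, ju = iu[keep], ju[keep]
    dist = np.linalg.norm(xyz[iu] - xyz[ju], axis=1)
    is_contact = dist <= params.contact_cutoff
    contact_idx = np.stack([iu[is_contact], ju[is_contact]], axis=1)
    contact_r0 = dist[is_contact]
    # soft repulsion applies to every non-local pair, contacts included, so the
    # model resists compression into dense map regions; the per-pair onset
    # distance never exceeds 90% of the reference separation, which keeps the
    # reference conformation an exact stationary point
    excluded_idx = np.stack([iu, ju], axis=1)
    excluded_r = np.minimum(params.excluded_radius, 0.9 * dist)
    return Topology(bond_idx, bond_r0, angle_idx, angle_t0, dih_idx, dih_p0,
                    contact_idx, contact_r0, excluded_idx, excluded_r, params)


# ---------------------------------------------------------------------------
# Secondary-structure restraints
# ---------------------------------------------------------------------------

@dataclass
class RestraintSet:
    """Harmonic restraints on pseudo-dihedrals and 1-4 distances within SS segments."""

    dihedral_idx: np.ndarray
    dihedral_p0: np.ndarray
    pair_idx: np.ndarray
    pair_r0: np.ndarray
    k: float

    def __post_init__(self) -> None:
        self.dihedral_idx = np.asarray(self.dihedral_idx, dtype=int).reshape(-1, 4)
        self.pair_idx = np.asarray(self.pair_idx, dtype=int).reshape(-1, 2)
        self.dihedral_p0 = np.asarray(self.dihedral_p0, dtype=float)
        self.pair_r0 = np.asarray(self.pair_r0, dtype=float)

    @classmethod
    def empty(cls) -> "RestraintSet":
        return cls(np.empty((0, 4), int), np.empty(0), np.empty((0, 2), int), np.empty(0), 0.0)

    @property
    def n_restraints(self) -> int:
        return len(self.dihedral_idx) + len(self.pair_idx)


def ss_segments(structure: Structure, kinds=("H", "E")):
    """Contiguous runs of helix/strand labels, as (start, end) bead-index ranges
    (end exclusive)."""
    segs = []
    n = structure.n_beads
    i = 0
    while i < n:
        if structure.ss[i] in kinds:
            j = i
            while (j + 1 < n and structure.ss[j + 1] == structure.ss[i]
                   and structure.chain_id[j + 1] == structure.chain_id[i]):
                j += 1
            segs.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    return segs


def assign_ss_restraints(structure: Structure, segments, k: float = 5.0) -> RestraintSet:
    """Restrain every in-segment pseudo-dihedral and 1-4 distance at its current value.

    ``segments`` is a list of (start, end) bead-index ranges (end exclusive);
    ranges must be disjoint.  A segment of m beads yields m-3 dihedral and m-3
    distance restraints.
    """
    segments = sorted(segments)
    for (a0, a1), (b0, b1) in zip(segments, segments[1:]):
        if b0 < a1:
            raise ValueError(f"overlapping segments ({a0},{a1}) and ({b0},{b1})")
    dih, pairs = [], []
    for s, e in segments:
        if not (0 <= s < e <= structure.n_beads):
            raise ValueError(f"segment ({s},{e}) out of range")
        for i in range(s, e - 3):
            dih.append((i, i + 1, i + 2, i + 3))
            pairs.append((i, i + 3))
    xyz = structure.xyz
    dih = np.array(dih, dtype=int).reshape(-1, 4)
    pairs = np.array(pairs, dtype=int).reshape(-1, 2)
    p0 = (dihedral_angle(xyz[dih[:, 0]], xyz[dih[:, 1]], xyz[dih[:, 2]], xyz[dih[:, 3]])
          if len(dih) else np.empty(0))
    r0 = np.linalg.norm(xyz[pairs[:, 0]] - xyz[pairs[:, 1]], axis=1) if len(pairs) else np.empty(0)
    return RestraintSet(dih, p0, pairs, r0, float(k))


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def rmsd(a: Structure, b: Structure, superpose: bool = False) -> float:
    """Root-mean-square coordinate deviation between matched bead models.

    With ``superpose`` the deviation is minimized over rigid transforms
    (Kabsch).  Default is off: fitted and target structures share the fixed
    frame of the map.
    """
    if a.n_beads != b.n_beads:
        raise ValueError(f"bead count mismatch: {a.n_beads} vs {b.n_beads}")
    xa, xb = a.xyz, b.xyz
    if superpose:
        ca, cb = xa.mean(axis=0), xb.mean(axis=0)
        rot, _ = Rotation.align_vectors(xb - cb, xa - ca)
        xa = rot.apply(xa - ca) + cb
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))
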