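"""Unit cell, space-group symmetry, atom sites and structure transforms.

Conventions: fractional coordinates for atoms, integer Miller indices for
reflections, the direct metric tensor G = A^T A with A holding the basis
vectors as columns, and the a.a* = 1 reciprocal convention (no 2*pi).

Space groups are carried as explicit operator lists (parsed from
``x,y,z``-style triplets with gemmi); no symbol-to-operator tables are
embedded beyond the fixture lists shipped with :mod:`aspher.fixtures`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

#: tolerance (fractional units) below which two symmetry images are one site
MERGE_TOL = 1e-4


class CellError(ValueError):
    pass


@dataclass(frozen=True)
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise CellError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise CellError("cell angles must lie in (0, 180) degrees")
        if np.linalg.det(self.metric) <= 0:
            raise CellError("direct metric tensor is not positive definite")

    @property
    def orthogonalization(self) -> np.ndarray:
        """3x3 matrix A with the basis vectors a, b, c as columns (A)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if v2 <= 0:
            raise CellError("cell angles do not define a positive volume")
        v = math.sqrt(v2)
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * v / sg],
        ])

    @property
    def metric(self) -> np.ndarray:
        A = self.orthogonalization
        return A.T @ A

    @property
    def reciprocal_metric(self) -> np.ndarray:
        return np.linalg.inv(self.metric)

    @property
    def volume(self) -> float:
        return float(math.sqrt(np.linalg.det(self.metric)))

    @property
    def reciprocal_lengths(self) -> np.ndarray:
        """(a*, b*, c*) moduli in 1/A."""
        return np.sqrt(np.diag(self.reciprocal_metric))

    @property
    def reciprocal_matrix(self) -> np.ndarray:
        """3x3 matrix B with the reciprocal basis vectors as columns: B = (A^-1)^T."""
        return np.linalg.inv(self.orthogonalization).T

    def frac_to_cart(self, xyz) -> np.ndarray:
        return np.asarray(xyz) @ self.orthogonalization.T

    def cart_to_frac(self, xyz) -> np.ndarray:
        return np.asarray(xyz) @ np.linalg.inv(self.orthogonalization).T

    def hkl_to_cart(self, hkl) -> np.ndarray:
        """Reciprocal-space vector(s) in Cartesian 1/A for integer indices."""
        return np.asarray(hkl, dtype=float) @ self.reciprocal_matrix.T

    def d_spacing(self, hkl) -> np.ndarray | float:
        hkl = np.asarray(hkl, dtype=float)
        inv_d2 = np.einsum('...i,ij,...j->...', hkl, self.reciprocal_metric, hkl)
        if np.any(inv_d2 <= 0):
            raise CellError("d-spacing undefined for the (0,0,0) reflection")
        d = 1.0 / np.sqrt(inv_d2)
        return float(d) if d.ndim == 0 else d


def build_cell(a, b, c, alpha=90.0, beta=90.0, gamma=90.0) -> UnitCell:
    return UnitCell(a, b, c, alpha, beta, gamma)


@dataclass(frozen=True)
class SymOp:
    """Rotation (integer matrix, det +-1) and translation (mod 1)."""
    rot: tuple
    tran: tuple

    @classmethod
    def from_xyz(cls, triplet: str) -> "SymOp":
        op = gemmi.Op(triplet)
        rot = np.array(op.rot) // 24
        tran = np.array(op.tran) / 24.0
        return cls(tuple(map(tuple, rot.tolist())), tuple(np.mod(tran, 1.0).tolist()))

    @property
    def rot_array(self) -> np.ndarray:
        return np.array(self.rot, dtype=int)

    @property
    def tran_array(self) -> np.ndarray:
        return np.array(self.tran, dtype=float)

    def triplet(self) -> str:
        op = gemmi.Op()
        op.rot = [[int(v) * 24 for v in row] for row in self.rot]
        op.tran = [int(round(v * 24)) for v in self.tran]
        return op.triplet()

    def apply(self, xyz) -> np.ndarray:
        return np.asarray(xyz) @ self.rot_array.T + self.tran_array

    def __mul__(self, other: "SymOp") -> "SymOp":
        rot = self.rot_array @ other.rot_array
        tran = np.mod(self.rot_array @ other.tran_array + self.tran_array, 1.0)
        return SymOp(tuple(map(tuple, rot.tolist())), tuple(np.round(tran, 12).tolist()))


IDENTITY_OP = SymOp.from_xyz("x,y,z")


@dataclass(frozen=True)
class SpaceGroup:
    symbol: str
    ops: tuple

    @classmethod
    def from_triplets(cls, symbol: str, triplets) -> "SpaceGroup":
        ops = tuple(SymOp.from_xyz(t) for t in triplets)
        for op in ops:
            if abs(round(float(np.linalg.det(op.rot_array)))) != 1:
                raise ValueError(f"operator {op.triplet()} has |det| != 1")
        return cls(symbol, ops)

    def __len__(self):
        return len(self.ops)

    def is_closed(self) -> bool:
        keys = {self._key(op) for op in self.ops}
        return all(self._key(a * b) in keys for a in self.ops for b in self.ops)

    @staticmethod
    def _key(op: SymOp):
        return (op.rot, tuple(np.round(np.mod(op.tran_array, 1.0), 6).tolist()))

    def stabilizer(self, xyz, tol: float = MERGE_TOL) -> list:
        """Operators fixing the site modulo lattice translations."""
        xyz = np.asarray(xyz, dtype=float)
        out = []
        for op in self.ops:
            delta = op.apply(xyz) - xyz
            delta -= np.round(delta)
            if np.max(np.abs(delta)) < tol:
                out.append(op)
        return out

    def orbit(self, xyz, tol: float = MERGE_TOL) -> list:
        """Distinct images of a site (fractional, wrapped into [0,1))."""
        xyz = np.asarray(xyz, dtype=float)
        images = []
        for op in self.ops:
            pos = np.mod(op.apply(xyz), 1.0)
            if not any(np.max(np.abs(np.mod(pos - q + 0.5, 1.0) - 0.5)) < tol for q in images):
                images.append(pos)
        return images

    def laue_rotations(self) -> list:
        """Distinct rotation parts completed with the inversion (Friedel)."""
        seen, rots = set(), []
        for op in self.ops:
            for sign in (1, -1):
                r = sign * op.rot_array
                key = tuple(r.ravel().tolist())
                if key not in seen:
                    seen.add(key)
                    rots.append(r)
        return rots

    def is_centrosymmetric(self) -> bool:
        inv = -np.eye(3, dtype=int)
        return any(np.array_equal(op.rot_array, inv) for op in self.ops)


P1 = SpaceGroup.from_triplets("P1", ["x,y,z"])

# CIF-order anisotropic components
U_COMPONENTS = ("U11", "U22", "U33", "U12", "U13", "U23")


def u_vector_to_matrix(u6) -> np.ndarray:
    u11, u22, u33, u12, u13, u23 = u6
    return np.array([[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]])


def u_matrix_to_vector(m) -> np.ndarray:
    return np.array([m[0, 0], m[1, 1], m[2, 2], m[0, 1], m[0, 2], m[1, 2]])


@dataclass
class AtomSite:
    label: str
    element: str
    xyz: np.ndarray
    occupancy: float = 1.0
    u_iso: float | None = None
    u_aniso: np.ndarray | None = None  # (U11, U22, U33, U12, U13, U23)

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError(f"occupancy of {self.label} outside (0, 1]")
        if self.u_aniso is not None:
            self.u_aniso = np.asarray(self.u_aniso, dtype=float)
            if np.linalg.eigvalsh(u_vector_to_matrix(self.u_aniso)).min() < -1e-10:
                raise ValueError(f"U tensor of {self.label} not positive semidefinite")
        elif self.u_iso is not None and self.u_iso < 0:
            raise ValueError(f"U_iso of {self.label} negative")

    @property
    def is_anisotropic(self) -> bool:
        return self.u_aniso is not None

    def u_matrix(self) -> np.ndarray:
        if self.u_aniso is not None:
            return u_vector_to_matrix(self.u_aniso)
        u = self.u_iso or 0.0
        return u * np.eye(3)

    def copy(self) -> "AtomSite":
        return AtomSite(self.label, self.element, self.xyz.copy(), self.occupancy,
                        self.u_iso,
                        None if self.u_aniso is None else self.u_aniso.copy())


def u_equivalent(site: AtomSite, cell: UnitCell) -> float:
    """U_eq: one third of the trace of the Cartesianized U tensor."""
    if site.u_aniso is None:
        return float(site.u_iso or 0.0)
    n = cell.orthogonalization @ np.diag(cell.reciprocal_lengths)
    u_cart = n @ u_vector_to_matrix(site.u_aniso) @ n.T
    return float(np.trace(u_cart) / 3.0)


@dataclass
class CrystalStructure:
    cell: UnitCell
    spacegroup: SpaceGroup
    sites: list  # asymmetric unit

    def site(self, label: str) -> AtomSite:
        for s in self.sites:
            if s.label == label:
                return s
        raise KeyError(f"no atom site labelled {label!r}")

    def multiplicity(self, site: AtomSite) -> int:
        return len(self.spacegroup) // len(self.spacegroup.stabilizer(site.xyz))

    def expand_to_unit_cell(self, tol: float = MERGE_TOL) -> "CrystalStructure":
        """Full unit-cell content in P1; merged special-position images."""
        expanded = []
        positions, labels = [], []
        for s in self.sites:
            for pos in self.spacegroup.orbit(s.xyz, tol):
                for q, lab in zip(positions, labels):
                    if np.max(np.abs(np.mod(pos - q + 0.5, 1.0) - 0.5)) < tol and lab != s.label:
                        raise ValueError(
                            f"distinct sites {lab!r} and {s.label!r} overlap within tolerance")
                positions.append(pos)
                labels.append(s.label)
                img = s.copy()
                img.xyz = pos
                expanded.append(img)
        return CrystalStructure(self.cell, P1, expanded)

    def cartesian_positions(self, expand: bool = True) -> tuple:
        st = self.expand_to_unit_cell() if expand and len(self.spacegroup) > 1 else self
        labels = [s.label for s in st.sites]
        return labels, st.cell.frac_to_cart(np.array([s.xyz for s in st.sites]))

    def distance(self, label_a: str, label_b: str) -> float:
        """Shortest intersite distance including periodic/symmetry images."""
        pa = self.cell.frac_to_cart(self.site(label_a).xyz)
        b = self.site(label_b).xyz
        best = np.inf
        for op in self.spacegroup.ops:
            base = op.apply(b)
            for shift in np.ndindex(3, 3, 3):
                q = base + np.array(shift) - 1
                d = np.linalg.norm(self.cell.frac_to_cart(q) - pa)
                if 1e-6 < d < best:
                    best = d
        return float(best)

    def copy(self) -> "CrystalStructure":
        return CrystalStructure(self.cell, self.spacegroup, [s.copy() for s in self.sites])


def transform_structure(structure: CrystalStructure, matrix) -> CrystalStructure:
    """Re-express the structure in the basis (a', b', c')^T = P (a, b, c)^T.

    Miller indices map as h' = P h; fractional coordinates as x' = P^-T x.
    Interatomic distances and corresponding d-spacings are invariant.
    """
    P = np.asarray(matrix, dtype=float)
    det = np.linalg.det(P)
    if abs(det) < 1e-12:
        raise ValueError("transformation matrix is singular")
    cell = structure.cell
    G = P @ cell.metric @ P.T
    lengths = np.sqrt(np.diag(G))
    angles = [
        math.degrees(math.acos(G[1, 2] / (lengths[1] * lengths[2]))),
        math.degrees(math.acos(G[0, 2] / (lengths[0] * lengths[2]))),
        math.degrees(math.acos(G[0, 1] / (lengths[0] * lengths[1]))),
    ]
    new_cell = UnitCell(*lengths, *angles)
    Pti = np.linalg.inv(P.T)
    ops = []
    for op in structure.spacegroup.ops:
        rot = Pti @ op.rot_array @ P.T
        rot_int = np.round(rot).astype(int)
        if np.max(np.abs(rot - rot_int)) > 1e-9:
            raise ValueError("operator does not remain integral under this transform")
        tran = np.mod(Pti @ op.tran_array, 1.0)
        ops.append(SymOp(tuple(map(tuple, rot_int.tolist())), tuple(np.round(tran, 12).tolist())))
    sg = SpaceGroup(structure.spacegroup.symbol + "'", tuple(ops))
    d_old = np.diag(cell.reciprocal_lengths)
    d_new_inv = np.diag(1.0 / new_cell.reciprocal_lengths)
    sites = []
    for s in structure.sites:
        ns = s.copy()
        ns.xyz = Pti @ s.xyz
        if s.u_aniso is not None:
            c_frac = d_old @ u_vector_to_matrix(s.u_aniso) @ d_old
            c_new = Pti @ c_frac @ Pti.T
            ns.u_aniso = u_matrix_to_vector(d_new_inv @ c_new @ d_new_inv)
        sites.append(ns)
    return CrystalStructure(new_cell, sg, sites)


def position_free_basis(spacegroup: SpaceGroup, xyz, tol: float = MERGE_TOL) -> np.ndarray:
    """Rows span the coordinate shifts allowed by the site's stabilizer.

    The averaging projector over stabilizer rotations maps any shift onto the
    invariant subspace; its eigenvalue-1 eigenvectors are the free directions.
    """
    stab = spacegroup.stabilizer(xyz, tol)
    proj = np.mean([op.rot_array for op in stab], axis=0)
    w, v = np.linalg.eig(proj)
    cols = [np.real(v[:, i]) for i in range(3) if abs(w[i] - 1.0) < 1e-9]
    if not cols:
        return np.zeros((0, 3))
    basis = np.array(cols)
    q, _ = np.linalg.qr(basis.T)
    return q.T[: len(cols)]


def adp_free_basis(spacegroup: SpaceGroup, cell: UnitCell, xyz,
                   tol: float = MERGE_TOL) -> np.ndarray:
    """Rows span the U11..U23 combinations allowed by the site symmetry."""
    stab = spacegroup.stabilizer(xyz, tol)
    d = np.diag(cell.reciprocal_lengths)
    d_inv = np.diag(1.0 / cell.reciprocal_lengths)
    mats = []
    for op in stab:
        m = np.zeros((6, 6))
        for j in range(6):
            e = np.zeros(6)
            e[j] = 1.0
            c = d @ u_vector_to_matrix(e) @ d
            r = op.rot_array.astype(float)
            c2 = r @ c @ r.T
            m[:, j] = u_matrix_to_vector(d_inv @ c2 @ d_inv)
        mats.append(m)
    proj = np.mean(mats, axis=0)
    w, v = np.linalg.eig(proj)
    cols = [np.real(v[:, i]) for i in range(6) if abs(w[i] - 1.0) < 1e-9]
    if not cols:
        return np.zeros((0, 6))
    q, _ = np.linalg.qr(np.array(cols).T)
    return q.T[: len(cols)]


# ---------------------------------------------------------------------------
# CIF input/output (small-molecule subset) via gemmi's CIF parser
# ---------------------------------------------------------------------------

def write_cif(structure: CrystalStructure, path) -> None:
    doc = gemmi.cif.Document()
    block = doc.add_new_block("aspher")
    cell = structure.cell
    for tag, val in [("_cell_length_a", cell.a), ("_cell_length_b", cell.b),
                     ("_cell_length_c", cell.c), ("_cell_angle_alpha", cell.alpha),
                     ("_cell_angle_beta", cell.beta), ("_cell_angle_gamma", cell.gamma)]:
        block.set_pair(tag, f"{val:.6f}")
    block.set_pair("_symmetry_space_group_name_H-M", gemmi.cif.quote(structure.spacegroup.symbol))
    loop = block.init_loop("_symmetry_equiv_pos_as_", ["xyz"])
    for op in structure.spacegroup.ops:
        loop.add_row([gemmi.cif.quote(op.triplet())])
    loop = block.init_loop("_atom_site_", ["label", "type_symbol", "fract_x", "fract_y",
                                           "fract_z", "occupancy", "U_iso_or_equiv",
                                           "adp_type"])
    for s in structure.sites:
        u_eq = u_equivalent(s, cell)
        loop.add_row([s.label, s.element,
                      f"{s.xyz[0]:.6f}", f"{s.xyz[1]:.6f}", f"{s.xyz[2]:.6f}",
                      f"{s.occupancy:.4f}", f"{u_eq:.6f}",
                      "Uani" if s.is_anisotropic else "Uiso"])
    aniso = [s for s in structure.sites if s.is_anisotropic]
    if aniso:
        loop = block.init_loop("_atom_site_aniso_", ["label", "U_11", "U_22", "U_33",
                                                     "U_12", "U_13", "U_23"])
        for s in aniso:
            u = s.u_aniso
            loop.add_row([s.label] + [f"{v:.6f}" for v in [u[0], u[1], u[2], u[3], u[4], u[5]]])
    doc.write_file(str(path))


def read_cif(path) -> CrystalStructure:
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()

    def num(tag):
        return float(block.find_pair(tag)[1])

    cell = UnitCell(num("_cell_length_a"), num("_cell_length_b"), num("_cell_length_c"),
                    num("_cell_angle_alpha"), num("_cell_angle_beta"), num("_cell_angle_gamma"))
    symbol = "P1"
    pair = block.find_pair("_symmetry_space_group_name_H-M")
    if pair:
        symbol = gemmi.cif.as_string(pair[1])
    triplets = [gemmi.cif.as_string(row[0])
                for row in block.find("_symmetry_equiv_pos_as_", ["xyz"])] or ["x,y,z"]
    sg = SpaceGroup.from_triplets(symbol, triplets)
    aniso = {}
    for row in block.find("_atom_site_aniso_", ["label", "U_11", "U_22", "U_33",
                                               "U_12", "U_13", "U_23"]):
        aniso[gemmi.cif.as_string(row[0])] = np.array([float(row[i]) for i in range(1, 7)])
    sites = []
    for row in block.find("_atom_site_", ["label", "type_symbol", "fract_x", "fract_y",
                                          "fract_z", "occupancy", "U_iso_or_equiv",
                                          "adp_type"]):
        label = gemmi.cif.as_string(row[0])
        xyz = np.array([float(row[2]), float(row[3]), float(row[4])])
        if label in aniso:
            site = AtomSite(label, gemmi.cif.as_string(row[1]), xyz,
                            float(row[5]), u_aniso=aniso[label])
        else:
            site = AtomSite(label, gemmi.cif.as_string(row[1]), xyz,
                            float(row[5]), u_iso=float(row[6]))
        sites.append(site)
    return CrystalStructure(cell, sg, sites)
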