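"""Rigid superposition and cofactor geometry.

The measurements here quantify how a chlorophyll sits in its binding pocket
when two structures are compared: a least-squares (Kabsch/SVD) superposition
on matched backbone atoms local to the site, a total-least-squares ring-plane
fit of the tetrapyrrole, an in-plane rotation angle with the pivot ring
identified as the ring whose centroid moves least, and heavy-atom
hydrogen-bond detection with an acceptor-angle quality score relative to the
~120 degree optimum for a carbonyl acceptor.

Deposited cryo-EM/X-ray models carry no hydrogens, so H-bonds are inferred
from heavy-atom geometry alone: donor/acceptor N, O or S pairs within a
distance cutoff whose antecedent-acceptor-donor angle lies in a 90-180
degree window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structio import (
    PYRROLE_NITROGENS,
    RING_DEFINITIONS,
    Cofactor,
    StructureModel,
)

BACKBONE_ATOMS = ("N", "CA", "C", "O")
POLAR_ELEMENTS = ("N", "O", "S")


class GeometryError(ValueError):
    pass


# --- superposition ----------------------------------------------------------


@dataclass
class Superposition:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms_used: int
    atom_selection: str = ""

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(
    reference: np.ndarray, mobile: np.ndarray, atom_selection: str = ""
) -> Superposition:
    """Optimal rigid transform taking *mobile* onto *reference* (Kabsch).

    Reflections are excluded: the returned rotation has determinant +1.
    Requires at least three non-collinear matched pairs.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise GeometryError("matched Nx3 coordinate arrays required")
    n = ref.shape[0]
    if n < 3:
        raise GeometryError(f"need >= 3 matched pairs, got {n}")
    cr, cm = ref.mean(axis=0), mob.mean(axis=0)
    P, Q = mob - cm, ref - cr
    if np.linalg.matrix_rank(Q, tol=1e-8) < 2 or np.linalg.matrix_rank(P, tol=1e-8) < 2:
        raise GeometryError("matched pairs are collinear")
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cr - R @ cm
    moved = mob @ R.T + t
    rmsd = float(np.sqrt(((moved - ref) ** 2).sum(axis=1).mean()))
    return Superposition(R, t, rmsd, n, atom_selection)


# --- ring planes ------------------------------------------------------------


@dataclass
class RingPlane:
    centroid: np.ndarray
    unit_normal: np.ndarray
    in_plane_axis: np.ndarray | None
    rms_residual: float


def fit_ring_plane(
    atoms: np.ndarray, orient_along: np.ndarray | None = None
) -> RingPlane:
    """Total-least-squares plane through >= 3 atoms.

    The normal is the singular vector of the centred coordinates with the
    smallest singular value; *orient_along* fixes its sign.
    """
    X = np.asarray(atoms, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 3:
        raise GeometryError("need >= 3 atoms to fit a plane")
    centroid = X.mean(axis=0)
    C = X - centroid
    U, S, Vt = np.linalg.svd(C, full_matrices=False)
    if S[1] < 1e-8 * max(S[0], 1.0):
        raise GeometryError("atoms are collinear; plane undefined")
    normal = Vt[2]
    if orient_along is not None and np.dot(normal, orient_along) < 0:
        normal = -normal
    residuals = C @ normal
    rms = float(np.sqrt((residuals**2).mean()))
    return RingPlane(centroid, normal, None, rms)


def _project_onto_plane(v: np.ndarray, normal: np.ndarray) -> np.ndarray:
    return v - np.dot(v, normal) * normal


def tetrapyrrole_plane(cofactor: Cofactor) -> RingPlane:
    """Macrocycle plane of a chlorophyll with the conventional orientation.

    Fits all ring A-D atoms; the normal sign follows (NA->NB) x (NA->NC) and
    the in-plane axis is NA->NC projected into the plane.
    """
    names = sorted({n for r in "ABCD" for n in RING_DEFINITIONS[r]})
    coords = np.array([cofactor.atom(n).xyz for n in names if cofactor.has_atoms([n])])
    na, nb, nc = (cofactor.atom(n).xyz for n in ("NA", "NB", "NC"))
    orient = np.cross(nb - na, nc - na)
    plane = fit_ring_plane(coords, orient_along=orient)
    axis = _project_onto_plane(nc - na, plane.unit_normal)
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise GeometryError("degenerate NA->NC axis")
    plane.in_plane_axis = axis / norm
    return plane


# --- cofactor rotation ------------------------------------------------------


@dataclass
class RotationMeasurement:
    angle_deg: float  # least-squares in-plane rotation over macrocycle atoms
    pivot_ring: str
    per_ring_centroid_shift: dict[str, float]
    axis_angle_deg: float  # angle between the two macrocycle plane normals
    nanc_axis_angle_deg: float  # angle between the NA->NC in-plane axes
    superposition: Superposition


def _transformed_cofactor(cof: Cofactor, sup: Superposition) -> Cofactor:
    from .structio import Atom

    atoms = [Atom(a.name, a.element, sup.apply(a.xyz[None])[0]) for a in cof.atoms]
    return Cofactor(cof.component_id, cof.chain, cof.number, atoms)


def _local_backbone_pairs(
    ref: StructureModel, mobile: StructureModel, center: np.ndarray, radius: float
) -> tuple[np.ndarray, np.ndarray]:
    ref_atoms: list[np.ndarray] = []
    mob_atoms: list[np.ndarray] = []
    mob_index = {}
    for ch in mobile.chains:
        for res in ch.residues:
            for a in res.atoms:
                if a.name in BACKBONE_ATOMS:
                    mob_index[(ch.chain_id, res.author_number, a.name)] = a.xyz
    for ch in ref.chains:
        for res in ch.residues:
            ca = next((a for a in res.atoms if a.name == "CA"), None)
            if ca is None or np.linalg.norm(ca.xyz - center) > radius:
                continue
            for a in res.atoms:
                if a.name not in BACKBONE_ATOMS:
                    continue
                key = (ch.chain_id, res.author_number, a.name)
                if key in mob_index:
                    ref_atoms.append(a.xyz)
                    mob_atoms.append(mob_index[key])
    if len(ref_atoms) < 3:
        raise GeometryError(
            f"only {len(ref_atoms)} matched backbone atoms within {radius} A"
        )
    return np.array(ref_atoms), np.array(mob_atoms)


def measure_cofactor_rotation(
    ref_structure: StructureModel,
    mobile_structure: StructureModel,
    site: tuple[str, int],
    mobile_site: tuple[str, int] | None = None,
    local_superposition_radius: float = 12.0,
) -> RotationMeasurement:
    """In-plane rotation of one cofactor between two structures.

    *site* is the (chain, residue number) of the cofactor in the reference;
    *mobile_site* defaults to the same address.  Backbone atoms of residues
    whose C-alpha lies within the radius of the reference cofactor centroid
    are matched by (chain, residue number, atom name) and superposed; the
    mobile cofactor is then carried by that local transform.  The reported
    angle is the least-squares in-plane rotation of the shared macrocycle
    atoms after projecting both structures into the bisecting plane of the
    two macrocycle normals; the pivot ring is the ring whose centroid moves
    least.
    """
    chain, num = site
    mchain, mnum = mobile_site or site
    try:
        ref_cof = ref_structure.cofactor(chain, num)
    except KeyError:
        raise GeometryError(
            f"structure {ref_structure.structure_id} lacks cofactor {chain}:{num}"
        )
    try:
        mob_cof = mobile_structure.cofactor(mchain, mnum)
    except KeyError:
        raise GeometryError(
            f"structure {mobile_structure.structure_id} lacks cofactor {mchain}:{mnum}"
        )
    for cof, sid in ((ref_cof, ref_structure), (mob_cof, mobile_structure)):
        if not cof.has_atoms(PYRROLE_NITROGENS):
            raise GeometryError(
                f"{sid.structure_id} cofactor lacks pyrrole nitrogens NA-ND"
            )
    center = np.array([a.xyz for a in ref_cof.atoms]).mean(axis=0)
    ref_xyz, mob_xyz = _local_backbone_pairs(
        ref_structure, mobile_structure, center, local_superposition_radius
    )
    sup = superpose(ref_xyz, mob_xyz, atom_selection=f"backbone within {local_superposition_radius} A")
    mob_cof_t = _transformed_cofactor(mob_cof, sup)

    ref_plane = tetrapyrrole_plane(ref_cof)
    mob_plane = tetrapyrrole_plane(mob_cof_t)
    n1, n2 = ref_plane.unit_normal, mob_plane.unit_normal
    axis_angle = math.degrees(math.acos(np.clip(np.dot(n1, n2), -1.0, 1.0)))
    n_bis = n1 + n2
    norm = np.linalg.norm(n_bis)
    n_bis = n_bis / norm if norm > 1e-9 else n1
    a1 = _project_onto_plane(ref_plane.in_plane_axis, n_bis)
    a2 = _project_onto_plane(mob_plane.in_plane_axis, n_bis)
    a1 /= np.linalg.norm(a1)
    a2 /= np.linalg.norm(a2)
    nanc_angle = math.degrees(math.acos(np.clip(np.dot(a1, a2), -1.0, 1.0)))
    # least-squares in-plane rotation over all shared macrocycle atoms:
    # a two-atom axis carries ~1 degree of error already at 0.05 A
    # coordinate noise, which would swamp a ~5 degree signal
    names = sorted({n for r in "ABCD" for n in RING_DEFINITIONS[r]})
    shared = [
        n for n in names
        if ref_cof.has_atoms([n]) and mob_cof_t.has_atoms([n])
    ]
    X = np.array([ref_cof.atom(n).xyz for n in shared])
    Y = np.array([mob_cof_t.atom(n).xyz for n in shared])
    e1 = a1 - np.dot(a1, n_bis) * n_bis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n_bis, e1)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    x2 = np.stack([Xc @ e1, Xc @ e2], axis=1)
    y2 = np.stack([Yc @ e1, Yc @ e2], axis=1)
    cross = float((x2[:, 0] * y2[:, 1] - x2[:, 1] * y2[:, 0]).sum())
    dot = float((x2 * y2).sum())
    angle = abs(math.degrees(math.atan2(cross, dot)))

    shifts = {}
    for ring in RING_DEFINITIONS:
        try:
            c_ref = ref_cof.ring_coordinates(ring).mean(axis=0)
            c_mob = mob_cof_t.ring_coordinates(ring).mean(axis=0)
        except KeyError:
            continue
        shifts[ring] = float(np.linalg.norm(c_ref - c_mob))
    if not shifts:
        raise GeometryError("no complete rings for centroid shifts")
    pivot = min(sorted(shifts), key=lambda r: shifts[r])
    return RotationMeasurement(
        angle_deg=angle,
        pivot_ring=pivot,
        per_ring_centroid_shift=shifts,
        axis_angle_deg=axis_angle,
        nanc_axis_angle_deg=nanc_angle,
        superposition=sup,
    )


# --- hydrogen bonds ---------------------------------------------------------


@dataclass
class HydrogenBond:
    donor: tuple[str, int, str]  # (chain/cofactor id, resnum, atom)
    acceptor: tuple[str, int, str]
    distance: float
    acceptor_angle_deg: float
    quality: float  # |acceptor angle - 120|


@dataclass
class _PolarAtom:
    key: tuple[str, int, str]
    element: str
    xyz: np.ndarray
    entity: tuple[str, int]  # residue or cofactor identity


def _all_heavy_atoms(structure: StructureModel):
    out = []
    for ch in structure.chains:
        for res in ch.residues:
            for a in res.atoms:
                if a.element != "H":
                    out.append(
                        _PolarAtom(
                            (ch.chain_id, res.author_number, a.name),
                            a.element,
                            a.xyz,
                            (ch.chain_id, res.author_number),
                        )
                    )
    for cof in structure.cofactors:
        for a in cof.atoms:
            if a.element != "H":
                out.append(
                    _PolarAtom(
                        (cof.chain, cof.number, a.name),
                        a.element,
                        a.xyz,
                        (cof.chain, cof.number),
                    )
                )
    return out


def _bond_graph(atoms: list[_PolarAtom]) -> dict[int, set[int]]:
    """Distance-based covalent bonds (< 1.85 A, 2.1 A when S involved)."""
    xyz = np.array([a.xyz for a in atoms])
    tree = cKDTree(xyz)
    graph: dict[int, set[int]] = {i: set() for i in range(len(atoms))}
    for i, j in tree.query_pairs(2.1):
        cutoff = 2.1 if "S" in (atoms[i].element, atoms[j].element) else 1.85
        if np.linalg.norm(xyz[i] - xyz[j]) < cutoff:
            graph[i].add(j)
            graph[j].add(i)
    return graph


def _graph_distance_le(graph: dict[int, set[int]], i: int, j: int, k: int) -> bool:
    """True when i and j are within k bonds of each other."""
    frontier = {i}
    seen = {i}
    for _ in range(k):
        frontier = {n for f in frontier for n in graph[f]} - seen
        if j in frontier:
            return True
        seen |= frontier
    return False


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def detect_hbonds(
    structure: StructureModel,
    around: list[tuple[str, int]] | None = None,
    distance_cutoff: float = 3.5,
    angle_window: tuple[float, float] = (90.0, 180.0),
) -> list[HydrogenBond]:
    """Heavy-atom hydrogen bonds involving the *around* residues/cofactors.

    All N/O/S atom pairs within the cutoff are considered, excluding
    covalently bonded and 1-3 pairs.  With no hydrogens in the model the
    donor/acceptor assignment is heuristic: between O and N the oxygen is
    taken as the acceptor; otherwise the atom whose antecedent
    (nearest bonded heavy atom) gives an angle inside the window, preferring
    the one closer to 120 degrees.  Bonds are returned sorted by distance.
    """
    atoms = _all_heavy_atoms(structure)
    polar = [i for i, a in enumerate(atoms) if a.element in POLAR_ELEMENTS]
    graph = _bond_graph(atoms)
    xyz = np.array([a.xyz for a in atoms])
    sel = None if around is None else set(around)
    tree = cKDTree(xyz[polar])
    bonds: list[HydrogenBond] = []
    seen = set()
    for pi, pj in tree.query_pairs(distance_cutoff):
        i, j = polar[pi], polar[pj]
        ai, aj = atoms[i], atoms[j]
        if sel is not None and ai.entity not in sel and aj.entity not in sel:
            continue
        if ai.entity == aj.entity and _graph_distance_le(graph, i, j, 2):
            continue
        if ai.entity != aj.entity and _graph_distance_le(graph, i, j, 2):
            continue  # e.g. peptide-bonded neighbours
        dist = float(np.linalg.norm(ai.xyz - aj.xyz))

        def acceptor_angle(acc: int, don: int) -> float | None:
            neigh = graph[acc]
            if not neigh:
                return None
            ante = min(neigh, key=lambda n: np.linalg.norm(xyz[n] - xyz[acc]))
            return _angle_deg(xyz[ante], xyz[acc], xyz[don])

        # candidate assignments: (donor, acceptor)
        if ai.element == "O" and aj.element == "N":
            candidates = [(j, i)]
        elif ai.element == "N" and aj.element == "O":
            candidates = [(i, j)]
        else:
            candidates = [(i, j), (j, i)]
        best = None
        for don, acc in candidates:
            ang = acceptor_angle(acc, don)
            if ang is None or not angle_window[0] <= ang <= angle_window[1]:
                continue
            if best is None or abs(ang - 120.0) < abs(best[2] - 120.0):
                best = (don, acc, ang)
        if best is None:
            continue
        don, acc, ang = best
        key = frozenset((i, j))
        if key in seen:
            continue
        seen.add(key)
        bonds.append(
            HydrogenBond(
                donor=atoms[don].key,
                acceptor=atoms[acc].key,
                distance=dist,
                acceptor_angle_deg=ang,
                quality=abs(ang - 120.0),
            )
        )
    bonds.sort(key=lambda b: b.distance)
    return bonds


def compare_hbond_quality(
    bond_set_a: dict[str, HydrogenBond],
    bond_set_b: dict[str, HydrogenBond],
    target_angle: float = 120.0,
    tie_tolerance: float = 0.5,
) -> list[dict]:
    """Per-role comparison of acceptor-angle quality between two bond sets.

    Bonds are paired by their role key; the verdict says whose angle is
    closer to the target (ties within *tie_tolerance* degrees are 'equal';
    roles present on one side only are 'unpaired').
    """
    rows = []
    for role in sorted(set(bond_set_a) | set(bond_set_b)):
        a = bond_set_a.get(role)
        b = bond_set_b.get(role)
        if a is None or b is None:
            rows.append(
                {"role": role, "angle_a": a and a.acceptor_angle_deg,
                 "angle_b": b and b.acceptor_angle_deg, "closer": "unpaired"}
            )
            continue
        da = abs(a.acceptor_angle_deg - target_angle)
        db = abs(b.acceptor_angle_deg - target_angle)
        if abs(da - db) <= tie_tolerance:
            closer = "equal"
        else:
            closer = "a" if da < db else "b"
        rows.append(
            {"role": role, "angle_a": a.acceptor_angle_deg,
             "angle_b": b.acceptor_angle_deg, "closer": closer}
        )
    return rows
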