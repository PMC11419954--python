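"""Molecular surface construction and per-vertex featureization.

The surface of a peptide (or complex) is built as a triangulated
isosurface of an atom-centered Gaussian density evaluated at the van der
Waals radius (marching cubes), then regularized by an isotropic remesher
to a target edge length of 1.0 A. The mesh is decomposed into
overlapping radial patches of 6.0 A geodesic radius with polar
coordinates, and each vertex carries geometric descriptors (principal
curvatures, shape index, distance-dependent curvature) and chemical
descriptors (Kyte-Doolittle hydropathy, Coulomb electrostatics with a
distance-dependent dielectric, hydrogen-bond density), each normalized
to [-1, 1].
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _dijkstra
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from . import chemdata
from .structure import Atom, Chain, PHLAComplex

PATCH_RADIUS = 6.0
MESH_RESOLUTION = 1.0
PROBE_RADIUS = 1.5
FEATURE_CHANNELS = ("shape_index", "ddc", "hydropathy", "electrostatics",
                    "hbond", "phla_distance")


class SurfaceError(ValueError):
    pass


@dataclasses.dataclass
class SurfaceVertex:
    """View of one mesh vertex: position, outward unit normal, principal
    curvatures (k1 >= k2) and its feature map."""

    r: np.ndarray
    n: np.ndarray
    k1: float
    k2: float
    features: dict[str, float]


class SurfaceMesh:
    """Triangulated molecular surface with per-vertex attributes."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray,
                 resolution: float = MESH_RESOLUTION):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=int)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise SurfaceError("face references an invalid vertex")
        self.resolution = resolution
        self.k1: np.ndarray | None = None
        self.k2: np.ndarray | None = None
        self.principal_direction: np.ndarray | None = None
        self.features: dict[str, np.ndarray] = {}
        self._normals: np.ndarray | None = None

    # -- geometry helpers ----------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges(self, unique: bool = True) -> np.ndarray:
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        if unique:
            e = np.unique(np.sort(e, axis=1), axis=0)
        return e

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    def median_edge_length(self) -> float:
        return float(np.median(self.edge_lengths()))

    def is_edge_manifold(self) -> bool:
        e = np.sort(np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                               self.faces[:, [2, 0]]]), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts <= 2))

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (consistent face winding)."""
        if self._normals is None:
            v = self.vertices
            f = self.faces
            fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
            n = np.zeros_like(v)
            for k in range(3):
                np.add.at(n, f[:, k], fn)
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            norm[norm < 1e-12] = 1.0
            self._normals = n / norm
        return self._normals

    def invalidate_cache(self) -> None:
        self._normals = None

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_vertices)]
        for a, b in self.edges():
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def vertex(self, i: int) -> SurfaceVertex:
        feats = {k: float(v[i]) for k, v in self.features.items()}
        k1 = float(self.k1[i]) if self.k1 is not None else float("nan")
        k2 = float(self.k2[i]) if self.k2 is not None else float("nan")
        return SurfaceVertex(r=self.vertices[i], n=self.vertex_normals()[i],
                             k1=k1, k2=k2, features=feats)

    def connected_components(self) -> int:
        from scipy.sparse.csgraph import connected_components

        n, _ = connected_components(self._edge_graph(weighted=False))
        return n

    def _edge_graph(self, weighted: bool = True):
        e = self.edges()
        w = (np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
             if weighted else np.ones(len(e)))
        n = self.n_vertices
        return coo_matrix((np.concatenate([w, w]),
                           (np.concatenate([e[:, 0], e[:, 1]]),
                            np.concatenate([e[:, 1], e[:, 0]]))), shape=(n, n)).tocsr()


@dataclasses.dataclass
class SurfacePatch:
    """Radial surface patch around a center vertex, with geodesic polar
    coordinates (rho = geodesic distance, phi in [0, 2pi))."""

    center: int
    members: np.ndarray
    radius: float
    rho: np.ndarray
    phi: np.ndarray
    grid: dict[str, np.ndarray] | None = None


# ---------------------------------------------------------------------
# surface construction
# ---------------------------------------------------------------------

def _collect_atoms(obj) -> list[Atom]:
    if isinstance(obj, PHLAComplex):
        return obj.hla.atoms + obj.peptide.atoms
    if isinstance(obj, Chain):
        return obj.atoms
    return list(obj)


def build_surface(complex_or_chain, probe_radius: float = PROBE_RADIUS,
                  resolution: float = MESH_RESOLUTION,
                  regularize_mesh: bool = True) -> SurfaceMesh:
    """Triangulated molecular surface from atom-centered Gaussian density.

    The density of atom i is exp(-B (|x-xi|^2/Ri^2 - 1)) with Ri its van
    der Waals radius, so the isosurface at level 1 passes exactly through
    the vdW sphere of an isolated atom. The blobbyness B = 6/probe_radius
    controls how readily nearby atoms bridge, emulating the smoothing
    role of the solvent probe. Outward normals follow the descending
    density gradient.
    """
    atoms = _collect_atoms(complex_or_chain)
    if len(atoms) < 4:
        raise SurfaceError(f"need >= 4 atoms to build a surface, got {len(atoms)}")
    xyz = np.array([a.coords for a in atoms])
    radii = np.array([chemdata.vdw_radius(a.element) for a in atoms])
    B = 6.0 / probe_radius
    spacing = 0.8 * resolution
    pad = radii.max() + 2.0
    lo = xyz.min(axis=0) - pad
    hi = xyz.max(axis=0) + pad
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    grid_axes = [lo[k] + spacing * np.arange(shape[k]) for k in range(3)]
    gx, gy, gz = np.meshgrid(*grid_axes, indexing="ij")
    density = np.zeros(tuple(shape))
    pts = np.stack([gx, gy, gz], axis=-1)
    # per-atom local stamps keep memory/time linear in atom count
    reach = np.sqrt(1.0 + 12.0 / B)  # density < e^-12 beyond Ri*reach
    for p, R in zip(xyz, radii):
        r_cut = R * reach
        i0 = np.maximum(((p - r_cut - lo) / spacing).astype(int), 0)
        i1 = np.minimum(((p + r_cut - lo) / spacing).astype(int) + 2, shape)
        sl = tuple(slice(a, b) for a, b in zip(i0, i1))
        d2 = ((pts[sl] - p) ** 2).sum(axis=-1)
        density[sl] += np.exp(-B * (d2 / R ** 2 - 1.0))
    try:
        verts, faces, _, _ = marching_cubes(density, level=1.0,
                                            spacing=(spacing,) * 3)
    except (ValueError, RuntimeError) as exc:
        raise SurfaceError(f"isosurface extraction failed: {exc}") from exc
    mesh = SurfaceMesh(verts + lo, faces, resolution=resolution)
    # orient faces so vertex normals point outward (along decreasing density)
    tree = cKDTree(xyz)
    _, nearest = tree.query(mesh.vertices)
    outward = ((mesh.vertices - xyz[nearest]) * mesh.vertex_normals()).sum(axis=1)
    if np.median(outward) < 0:
        mesh = SurfaceMesh(mesh.vertices, mesh.faces[:, ::-1],
                           resolution=resolution)
    if regularize_mesh:
        mesh = regularize(mesh, resolution)
    return mesh


# ---------------------------------------------------------------------
# isotropic remeshing
# ---------------------------------------------------------------------

def _split_long_edges(verts: list[np.ndarray], faces: np.ndarray,
                      max_len: float) -> tuple[list[np.ndarray], np.ndarray, bool]:
    """Split every edge longer than ``max_len`` at its midpoint.

    Edges are marked globally first so both adjacent faces split
    consistently (no T-vertices); a face with 1, 2 or 3 marked edges is
    replaced by 2, 3 or 4 triangles.
    """
    V = np.array(verts)
    all_edges = np.unique(np.sort(np.vstack([faces[:, [0, 1]], faces[:, [1, 2]],
                                             faces[:, [2, 0]]]), axis=1), axis=0)
    lens = np.linalg.norm(V[all_edges[:, 0]] - V[all_edges[:, 1]], axis=1)
    marked = all_edges[lens > max_len]
    if len(marked) == 0:
        return verts, faces, False
    midpoint: dict[tuple[int, int], int] = {}
    for a, b in marked:
        verts.append(0.5 * (V[a] + V[b]))
        midpoint[(int(a), int(b))] = len(verts) - 1

    def mid(a: int, b: int) -> int | None:
        return midpoint.get((min(a, b), max(a, b)))

    new_faces = []
    for tri in faces:
        i, j, k = (int(x) for x in tri)
        mij, mjk, mki = mid(i, j), mid(j, k), mid(k, i)
        n_marked = sum(m is not None for m in (mij, mjk, mki))
        if n_marked == 0:
            new_faces.append((i, j, k))
        elif n_marked == 3:
            new_faces += [(i, mij, mki), (mij, j, mjk), (mki, mjk, k),
                          (mij, mjk, mki)]
        elif n_marked == 1:
            if mij is not None:
                new_faces += [(i, mij, k), (mij, j, k)]
            elif mjk is not None:
                new_faces += [(i, j, mjk), (i, mjk, k)]
            else:
                new_faces += [(i, j, mki), (mki, j, k)]
        else:  # two marked edges
            if mij is None:
                new_faces += [(k, mki, mjk), (mki, i, j), (mki, j, mjk)]
            elif mjk is None:
                new_faces += [(i, mij, mki), (mij, j, k), (mij, k, mki)]
            else:
                new_faces += [(j, mjk, mij), (mjk, k, i), (mjk, i, mij)]
    return verts, np.array(new_faces, dtype=int), True


def _collapse_short_edges(verts: np.ndarray, faces: np.ndarray,
                          min_len: float, max_len: float
                          ) -> tuple[np.ndarray, np.ndarray, bool]:
    adj: dict[int, set[int]] = {}
    for a, b in np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]):
        adj.setdefault(int(a), set()).add(int(b))
        adj.setdefault(int(b), set()).add(int(a))
    e = np.unique(np.sort(np.vstack([faces[:, [0, 1]], faces[:, [1, 2]],
                                     faces[:, [2, 0]]]), axis=1), axis=0)
    lens = np.linalg.norm(verts[e[:, 0]] - verts[e[:, 1]], axis=1)
    order = np.argsort(lens)
    mapping = np.arange(len(verts))
    dirty = np.zeros(len(verts), dtype=bool)
    changed = False
    for idx in order:
        if lens[idx] >= min_len:
            break
        a, b = int(e[idx, 0]), int(e[idx, 1])
        if dirty[a] or dirty[b]:
            continue
        # adjacency sets go stale once a neighbor has collapsed this pass
        if any(dirty[v] for v in (adj.get(a, set()) | adj.get(b, set()))):
            continue
        # link condition: endpoints must share exactly two neighbors,
        # and those two must not be adjacent (a "diamond" collapse would
        # duplicate the two opposite faces and break manifoldness)
        common = adj.get(a, set()) & adj.get(b, set())
        if len(common) != 2:
            continue
        x, y = common
        if y in adj.get(x, set()):
            continue
        target = 0.5 * (verts[a] + verts[b])
        # collapsing must not create overlong edges
        nb = (adj[a] | adj[b]) - {a, b}
        if any(np.linalg.norm(verts[v] - target) > max_len for v in nb):
            continue
        verts[a] = target
        mapping[b] = a
        dirty[a] = dirty[b] = True
        changed = True
    if not changed:
        return verts, faces, False
    faces = mapping[faces]
    keep = ((faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2])
            & (faces[:, 2] != faces[:, 0]))
    faces = faces[keep]
    _, first = np.unique(np.sort(faces, axis=1), axis=0, return_index=True)
    faces = faces[np.sort(first)]  # drop duplicated triangles
    used = np.unique(faces)
    remap = -np.ones(len(verts), dtype=int)
    remap[used] = np.arange(len(used))
    return verts[used], remap[faces], True


def _tangential_smooth(mesh: SurfaceMesh, iterations: int = 2,
                       step: float = 0.5) -> None:
    for _ in range(iterations):
        v = mesh.vertices
        n = mesh.vertex_normals()
        acc = np.zeros_like(v)
        cnt = np.zeros(len(v))
        e = mesh.edges()
        np.add.at(acc, e[:, 0], v[e[:, 1]])
        np.add.at(acc, e[:, 1], v[e[:, 0]])
        np.add.at(cnt, e[:, 0], 1)
        np.add.at(cnt, e[:, 1], 1)
        cnt[cnt == 0] = 1
        lap = acc / cnt[:, None] - v
        lap -= (lap * n).sum(axis=1, keepdims=True) * n  # tangential only
        mesh.vertices = v + step * lap
        mesh.invalidate_cache()


def regularize(mesh: SurfaceMesh, resolution: float = MESH_RESOLUTION,
               max_passes: int = 30) -> SurfaceMesh:
    """Isotropic remesh toward a target edge length.

    Alternates splitting of edges longer than 4/3 of the target,
    collapsing of edges shorter than 4/5 of the target (guarded by a
    link condition so edge-manifoldness is preserved), and tangential
    Laplacian smoothing, until the edge lengths settle.
    """
    if not mesh.is_edge_manifold():
        raise SurfaceError("refusing to regularize a non-manifold mesh")
    verts = [v for v in mesh.vertices]
    faces = mesh.faces.copy()
    hi, lo = 4.0 / 3.0 * resolution, 0.8 * resolution
    for _ in range(max_passes):
        changed = False
        for _ in range(4):
            verts, faces, ch = _split_long_edges(verts, faces, hi)
            changed |= ch
            if not ch:
                break
        varr = np.array(verts)
        varr, faces, ch = _collapse_short_edges(varr, faces, lo, hi * 1.2)
        changed |= ch
        verts = [v for v in varr]
        m = SurfaceMesh(np.array(verts), faces, resolution)
        _tangential_smooth(m, iterations=1)
        verts = [v for v in m.vertices]
        if not changed:
            break
    faces = _drop_overshared_faces(faces)
    out = SurfaceMesh(np.array(verts), faces, resolution)
    _tangential_smooth(out, iterations=1)
    return out


def _drop_overshared_faces(faces: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Remove fin triangles so every edge borders at most two faces."""
    for _ in range(max_iter):
        e = np.sort(np.stack([faces[:, [0, 1]], faces[:, [1, 2]],
                              faces[:, [2, 0]]], axis=1), axis=2)  # (F,3,2)
        flat = e.reshape(-1, 2)
        uniq, inv, counts = np.unique(flat, axis=0, return_inverse=True,
                                      return_counts=True)
        bad = counts[inv].reshape(-1, 3) > 2
        score = bad.sum(axis=1)
        if score.max(initial=0) == 0:
            return faces
        faces = np.delete(faces, int(np.argmax(score)), axis=0)
    return faces


# ---------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------

def principal_curvatures(mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex principal curvatures (k1 >= k2) by 2-ring quadric fit.

    In each vertex's tangent frame the neighbor heights are fit with
    h = D x + E y + A x^2 + B xy + C y^2; curvatures are the eigenvalues
    of the negated Hessian (convex regions positive for outward normals).
    Also records the k1 eigendirection used as the patch reference
    direction. Isolated vertices get NaN curvatures.
    """
    v = mesh.vertices
    n = mesh.vertex_normals()
    adj = mesh.adjacency()
    two_ring: list[np.ndarray] = []
    for i, nb in enumerate(adj):
        ring = set(nb)
        for j in nb:
            ring |= adj[j]
        ring.discard(i)
        two_ring.append(np.fromiter(ring, dtype=int))
    max_m = max((len(r) for r in two_ring), default=0)
    V = len(v)
    k1 = np.full(V, np.nan)
    k2 = np.full(V, np.nan)
    pdir = np.zeros((V, 3))
    if max_m == 0:
        mesh.k1, mesh.k2, mesh.principal_direction = k1, k2, pdir
        return k1, k2
    # batched design matrices with zero-weighted padding rows
    Amat = np.zeros((V, max_m, 5))
    hvec = np.zeros((V, max_m))
    wmask = np.zeros((V, max_m))
    # tangent frames
    ref = np.where(np.abs(n[:, 0:1]) < 0.9,
                   np.tile([1.0, 0.0, 0.0], (V, 1)),
                   np.tile([0.0, 1.0, 0.0], (V, 1)))
    t1 = np.cross(n, ref)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(n, t1)
    for i, ring in enumerate(two_ring):
        if len(ring) < 5:
            continue
        d = v[ring] - v[i]
        x = d @ t1[i]
        y = d @ t2[i]
        h = d @ n[i]
        m = len(ring)
        Amat[i, :m] = np.column_stack([x, y, x ** 2, x * y, y ** 2])
        hvec[i, :m] = h
        # Gaussian distance weights: distant 2-ring points otherwise bias
        # the parabolic fit high on tightly curved surfaces
        d2 = (d ** 2).sum(axis=1)
        wmask[i, :m] = np.exp(-d2 / (2.0 * (0.5 * mesh.resolution) ** 2))
    Aw = Amat * wmask[..., None]
    G = np.einsum("vmi,vmj->vij", Aw, Amat) + 1e-9 * np.eye(5)
    rhs = np.einsum("vmi,vm->vi", Aw, hvec)
    coef = np.linalg.solve(G, rhs[..., None])[..., 0]  # (V,5): D,E,A,B,C
    A, Bc, C = coef[:, 2], coef[:, 3], coef[:, 4]
    hess = np.empty((V, 2, 2))
    hess[:, 0, 0] = 2 * A
    hess[:, 0, 1] = hess[:, 1, 0] = Bc
    hess[:, 1, 1] = 2 * C
    evals, evecs = np.linalg.eigh(-hess)  # ascending
    ok = np.array([len(r) >= 5 for r in two_ring])
    k1[ok] = evals[ok, 1]
    k2[ok] = evals[ok, 0]
    dir2d = evecs[:, :, 1]  # eigenvector of the larger curvature
    pdir_all = dir2d[:, 0:1] * t1 + dir2d[:, 1:2] * t2
    pdir[ok] = pdir_all[ok]
    mesh.k1, mesh.k2, mesh.principal_direction = k1, k2, pdir
    return k1, k2


def shape_index(k1, k2) -> np.ndarray | float:
    """Scale-free curvature descriptor (2/pi) atan((k1+k2)/(k1-k2)) in [-1, 1].

    Requires k1 >= k2. Umbilic points (k1 == k2) map to sign(k1), and to
    0 when both curvatures vanish.
    """
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    diff = k1 - k2
    umbilic = np.abs(diff) < 1e-12
    safe = np.where(umbilic, 1.0, diff)
    si = (2.0 / np.pi) * np.arctan((k1 + k2) / safe)
    si = np.where(umbilic, np.sign(k1), si)
    return si if si.shape else float(si)


def distance_dependent_curvature(r_i, n_i, r_j, n_j):
    """Signed curvature between a patch center i and member j.

    theta(|r_j + n_j - r_i - n_i| - d_ij) * |n_j - n_i| / d_ij with d_ij
    the center-member distance and theta the +/-1 sign step encoding
    convex (tips apart) versus concave (tips approaching) geometry.
    """
    r_i, n_i = np.asarray(r_i, dtype=float), np.asarray(n_i, dtype=float)
    r_j, n_j = np.asarray(r_j, dtype=float), np.asarray(n_j, dtype=float)
    d = np.linalg.norm(r_j - r_i, axis=-1)
    if np.any(d == 0):
        raise SurfaceError("coincident vertices in DDC")
    tip = np.linalg.norm((r_j + n_j) - (r_i + n_i), axis=-1)
    theta = np.where(tip - d >= 0, 1.0, -1.0)
    val = theta * np.linalg.norm(n_j - n_i, axis=-1) / d
    return val if val.shape else float(val)


# ---------------------------------------------------------------------
# chemical features
# ---------------------------------------------------------------------

def chemical_features(mesh: SurfaceMesh, structure,
                      electrostatics_solver=None) -> dict[str, np.ndarray]:
    """Per-vertex hydropathy, electrostatics and hydrogen-bond features.

    hydropathy: Kyte-Doolittle value of the residue owning the nearest
    atom, scaled by 1/4.5 into [-1, 1]. electrostatics: Coulomb
    potential sum q/(eps(r) r) with eps(r) = 4r over bundled formal
    charges (Arg/Lys +1, Asp/Glu -1, chain termini +/-1), clamped to
    [-1, 1]; pass ``electrostatics_solver(mesh, atoms) -> array`` to
    substitute an external solver. hbond: donor-minus-acceptor proximity
    with linear falloff over 3.5 A, clamped to [-1, 1].
    """
    atoms = _collect_atoms(structure)
    xyz = np.array([a.coords for a in atoms])
    tree = cKDTree(xyz)
    _, nearest = tree.query(mesh.vertices)

    hydro = np.zeros(mesh.n_vertices)
    unknown = set()
    for vi, ai in enumerate(nearest):
        a = atoms[ai]
        one = chemdata.THREE_TO_ONE.get(a.residue_name)
        if one is None:
            unknown.add(a.residue_name)
            continue
        hydro[vi] = chemdata.KYTE_DOOLITTLE[one] / 4.5
    if unknown:
        warnings.warn(f"unknown residues treated as neutral: {sorted(unknown)}")

    if electrostatics_solver is not None:
        elec = np.asarray(electrostatics_solver(mesh, atoms), dtype=float)
    else:
        charges, charge_xyz = [], []
        chain_res: dict[str, list] = {}
        for a in atoms:
            q = chemdata.FORMAL_CHARGES.get((a.residue_name, a.name))
            if q:
                charges.append(q)
                charge_xyz.append(a.coords)
            chain_res.setdefault(a.chain_id, []).append(a)
        for chain_atoms in chain_res.values():  # termini carry +/-1
            first_idx = min(a.residue_index for a in chain_atoms)
            last_idx = max(a.residue_index for a in chain_atoms)
            for a in chain_atoms:
                if a.residue_index == first_idx and a.name == "N":
                    charges.append(1.0)
                    charge_xyz.append(a.coords)
                if a.residue_index == last_idx and a.name in ("OXT", "C"):
                    charges.append(-1.0)
                    charge_xyz.append(a.coords)
                    break
        elec = np.zeros(mesh.n_vertices)
        if charges:
            q = np.array(charges)
            cx = np.array(charge_xyz)
            r = np.linalg.norm(mesh.vertices[:, None] - cx[None], axis=-1)
            r = np.maximum(r, 0.5)
            elec = (q[None] / (4.0 * r * r)).sum(axis=1)  # eps(r) = 4r
    elec = np.clip(elec, -1.0, 1.0)

    donors, acceptors = [], []
    for a in atoms:
        key = (a.residue_name, a.name)
        if a.name == "N" and a.residue_name != "PRO":
            donors.append(a.coords)
        elif a.name == "O":
            acceptors.append(a.coords)
        if key in chemdata.HBOND_DONORS:
            donors.append(a.coords)
        if key in chemdata.HBOND_ACCEPTORS:
            acceptors.append(a.coords)
    hb = np.zeros(mesh.n_vertices)
    for sign, group in ((1.0, donors), (-1.0, acceptors)):
        if group:
            r = np.linalg.norm(mesh.vertices[:, None] - np.array(group)[None],
                               axis=-1)
            hb += sign * np.maximum(0.0, 1.0 - r / 3.5).sum(axis=1)
    hb = np.clip(hb, -1.0, 1.0)

    feats = {"hydropathy": hydro, "electrostatics": elec, "hbond": hb}
    mesh.features.update(feats)
    return feats


def geometric_features(mesh: SurfaceMesh) -> dict[str, np.ndarray]:
    """Attach shape-index (and curvatures) to the mesh feature map."""
    if mesh.k1 is None:
        principal_curvatures(mesh)
    si = shape_index(np.nan_to_num(mesh.k1), np.nan_to_num(mesh.k2))
    mesh.features["shape_index"] = si
    return {"shape_index": si}


# ---------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------

def decompose_patches(mesh: SurfaceMesh, radius: float = PATCH_RADIUS,
                      centers: Sequence[int] | None = None,
                      seed: int = 0) -> list[SurfacePatch]:
    """Overlapping radial patches around center vertices.

    Geodesic distances are Dijkstra shortest paths over mesh edges. The
    angular coordinate phi is measured in the center's tangent plane
    against the projected k1 eigendirection (a seeded random tangent
    direction at umbilic centers).
    """
    if centers is None:
        centers = np.arange(mesh.n_vertices)
    centers = np.asarray(centers, dtype=int)
    if mesh.principal_direction is None:
        principal_curvatures(mesh)
    graph = mesh._edge_graph(weighted=True)
    dist = _dijkstra(graph, indices=centers, limit=radius)
    normals = mesh.vertex_normals()
    rng = np.random.default_rng(seed)
    patches = []
    for row, c in enumerate(centers):
        members = np.where(np.isfinite(dist[row]))[0]
        if len(members) <= 1:
            warnings.warn(f"patch center {c} is isolated; singleton patch")
            patches.append(SurfacePatch(center=int(c), members=np.array([c]),
                                        radius=radius, rho=np.zeros(1),
                                        phi=np.zeros(1)))
            continue
        n = normals[c]
        refdir = mesh.principal_direction[c]
        refdir = refdir - (refdir @ n) * n
        if np.linalg.norm(refdir) < 1e-8:  # umbilic: seeded random tangent
            rr = rng.standard_normal(3)
            refdir = rr - (rr @ n) * n
        refdir = refdir / np.linalg.norm(refdir)
        t2 = np.cross(n, refdir)
        u = mesh.vertices[members] - mesh.vertices[c]
        ut = u - (u @ n)[:, None] * n[None]
        phi = np.mod(np.arctan2(ut @ t2, ut @ refdir), 2 * np.pi)
        phi[members == c] = 0.0
        patches.append(SurfacePatch(center=int(c), members=members,
                                    radius=radius, rho=dist[row, members],
                                    phi=phi))
    return patches


def map_patch_to_grid(patch: SurfacePatch,
                      features: Mapping[str, np.ndarray],
                      R: int = 5, A: int = 16) -> dict[str, np.ndarray]:
    """Mean-pool patch features onto an R x A polar grid.

    Empty bins are zero; an ``occupancy`` channel records bin counts > 0.
    """
    ri = np.minimum((patch.rho / patch.radius * R).astype(int), R - 1)
    ai = np.minimum((patch.phi / (2 * np.pi) * A).astype(int), A - 1)
    flat = ri * A + ai
    counts = np.bincount(flat, minlength=R * A).astype(float)
    occupied = counts > 0
    grids: dict[str, np.ndarray] = {}
    for name, vals in features.items():
        sums = np.bincount(flat, weights=np.nan_to_num(vals[patch.members]),
                           minlength=R * A)
        g = np.zeros(R * A)
        g[occupied] = sums[occupied] / counts[occupied]
        grids[name] = g.reshape(R, A)
    grids["occupancy"] = occupied.astype(float).reshape(R, A)
    patch.grid = grids
    return grids


# ---------------------------------------------------------------------
# mesh / feature I/O
# ---------------------------------------------------------------------

def save_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write the mesh to OFF or PLY (by extension)."""
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path))


def load_mesh(path: str | Path, resolution: float = MESH_RESOLUTION) -> SurfaceMesh:
    import trimesh

    tm = trimesh.load_mesh(str(path), process=False)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), resolution)


def save_features(mesh: SurfaceMesh, prefix: str | Path) -> None:
    """Write feature arrays as NPZ with a JSON sidecar naming channels."""
    prefix = Path(prefix)
    np.savez(str(prefix) + ".npz", **mesh.features)
    with open(str(prefix) + ".json", "w") as fh:
        json.dump({"channels": sorted(mesh.features)}, fh, indent=2)
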