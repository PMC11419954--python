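"""HLA groove virtual plane and outer-surface selection.

T-cell receptors dock on top of the pHLA-I complex, so only the part of
the peptide surface facing away from the binding groove is available
for recognition. A virtual plane is placed through the Cα atoms of
three conserved groove residues (Gln72, Thr143, Tyr159 in the canonical
class-I fold), oriented toward the peptide; peptide surface vertices
more than 4.0 A above this plane constitute the TCR-exposed outer
surface.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .structure import Chain
from .surface import SurfaceMesh

GROOVE_ANCHORS = (72, 143, 159)
OUTER_SURFACE_THRESHOLD = 4.0  # Angstrom, strict >
MIN_ANCHOR_TRIANGLE_AREA = 0.1  # Angstrom^2

#: Outer-surface feature channels fed to the foreignness model.
OUTER_SURFACE_CHANNELS = ("shape_index", "ddc", "hydropathy",
                          "electrostatics", "hbond", "phla_distance")


class GrooveError(ValueError):
    pass


@dataclasses.dataclass
class GroovePlane:
    """Plane through three anchor Cα positions, unit normal oriented
    toward the peptide centroid."""

    anchors: np.ndarray  # (3, 3)
    point: np.ndarray
    normal: np.ndarray

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return (points - self.point) @ self.normal


def _ca_of(chain: Chain, residue_index: int) -> np.ndarray:
    try:
        res = chain.get_residue(residue_index)
    except KeyError as exc:
        raise GrooveError(f"anchor residue {residue_index} missing") from exc
    for a in res:
        if a.name == "CA":
            return a.coords
    raise GrooveError(f"anchor residue {residue_index} has no CA atom")


def plane_from_anchors(hla: Chain, peptide: Chain,
                       anchor_indices: Sequence[int] = GROOVE_ANCHORS) -> GroovePlane:
    """Groove plane from three anchor residues' Cα atoms.

    The normal is chosen so the peptide centroid lies at positive signed
    distance. Collinear anchors (triangle area <= 0.1 A^2) are rejected.
    """
    anchors = np.array([_ca_of(hla, i) for i in anchor_indices])
    v1, v2 = anchors[1] - anchors[0], anchors[2] - anchors[0]
    cr = np.cross(v1, v2)
    area = 0.5 * np.linalg.norm(cr)
    if area <= MIN_ANCHOR_TRIANGLE_AREA:
        raise GrooveError(f"anchor triangle degenerate (area {area:.3g} A^2)")
    normal = cr / np.linalg.norm(cr)
    centroid = peptide.atom_coords().mean(axis=0)
    if (centroid - anchors[0]) @ normal < 0:
        normal = -normal
    return GroovePlane(anchors=anchors, point=anchors[0], normal=normal)


def vertex_plane_distance(mesh: SurfaceMesh | np.ndarray,
                          plane: GroovePlane) -> np.ndarray:
    """Signed point–plane distance per vertex (positive on the peptide side)."""
    points = mesh.vertices if isinstance(mesh, SurfaceMesh) else np.asarray(mesh)
    d = plane.signed_distance(points)
    if isinstance(mesh, SurfaceMesh):
        mesh.features["phla_distance"] = d
    return d


def outer_surface_mask(distances: np.ndarray,
                       threshold: float = OUTER_SURFACE_THRESHOLD) -> np.ndarray:
    """True exactly where the signed distance is strictly above threshold."""
    mask = np.asarray(distances, dtype=float) > threshold
    if mask.size and not mask.any():
        warnings.warn("no vertex above the outer-surface threshold")
    return mask


def outer_patch_centers(patches, mask: np.ndarray) -> list:
    """Retain patches whose center vertex passes the outer-surface mask."""
    return [p for p in patches if mask[p.center]]
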