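"""Shared fixtures: synthetic structures and analytic reference meshes."""

import numpy as np
import pytest

from neoasurf import fixtures, structure, surface


@pytest.fixture(scope="session")
def groove_chain():
    return fixtures.make_groove(fixtures.GrooveSpec(seed=7))


@pytest.fixture(scope="session")
def arch_peptide():
    return fixtures.make_arch_peptide(fixtures.ArchSpec(seed=7))


@pytest.fixture(scope="session")
def arch_complex(groove_chain, arch_peptide):
    return structure.PHLAComplex(hla=groove_chain, peptide=arch_peptide)


@pytest.fixture(scope="session")
def arch_mesh(arch_peptide):
    """Regularized 1.0 A surface of the arch peptide."""
    return surface.build_surface(arch_peptide)


def icosphere(radius: float, subdivisions: int) -> tuple[np.ndarray, np.ndarray]:
    """Subdivided icosahedron projected onto a sphere."""
    t = (1 + 5 ** 0.5) / 2
    verts = [np.array(v, dtype=float) for v in [
        (-1, t, 0), (1, t, 0), (-1, -t, 0), (1, -t, 0),
        (0, -1, t), (0, 1, t), (0, -1, -t), (0, 1, -t),
        (t, 0, -1), (t, 0, 1), (-t, 0, -1), (-t, 0, 1)]]
    verts = [v / np.linalg.norm(v) for v in verts]
    faces = [(0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
             (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
             (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
             (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1)]
    for _ in range(subdivisions):
        cache = {}
        new_faces = []

        def midpoint(a, b):
            key = (min(a, b), max(a, b))
            if key not in cache:
                m = (verts[a] + verts[b]) / 2
                verts.append(m / np.linalg.norm(m))
                cache[key] = len(verts) - 1
            return cache[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    return np.array(verts) * radius, np.array(faces)


def cylinder_mesh(radius: float, n_around: int, height: float,
                  dz: float) -> tuple[np.ndarray, np.ndarray]:
    """Open triangulated cylinder along z."""
    th = np.linspace(0, 2 * np.pi, n_around + 1)[:-1]
    zs = np.arange(0, height + dz / 2, dz)
    verts = np.array([[radius * np.cos(t), radius * np.sin(t), z]
                      for z in zs for t in th])
    faces = []
    for i in range(len(zs) - 1):
        for j in range(n_around):
            a = i * n_around + j
            b = i * n_around + (j + 1) % n_around
            c = (i + 1) * n_around + j
            d = (i + 1) * n_around + (j + 1) % n_around
            faces += [[a, b, c], [b, d, c]]
    return verts, np.array(faces)


def plane_mesh(n: int, spacing: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing)
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a, b = i * n + j, i * n + j + 1
            c, d = (i + 1) * n + j, (i + 1) * n + j + 1
            faces += [[a, b, c], [b, d, c]]
    return verts, np.array(faces)
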