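"""Deterministic synthetic fixtures: grooves, arch peptides, pair corpora.

Real pHLA-I structures are not redistributable at package scale, so
every test and demonstration input is generated here: an idealized HLA
groove (a floor slab with two wall ridges and the three plane-anchor
residues at controlled coordinates), peptides in the characteristic
"arch" binding conformation (termini bent down toward the groove floor
where they anchor, center bulged up toward the TCR), Gaussian
structure perturbations, and labelled WT/Mut pair corpora whose signal
is placed in a chosen comparison block.

All generators are bit-reproducible: one global seed fans out to fixed
per-generator substreams (groove=1, arch=2, corpus=3, perturb=4), so
adding a generator never shifts existing fixtures.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import chemdata
from .structure import Atom, Chain, PHLAComplex
from .pepfore import WTMutPair

_STREAM = {"groove": 1, "arch": 2, "corpus": 3, "perturb": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAM[stream]]))


class FixtureError(ValueError):
    pass


@dataclasses.dataclass
class GrooveSpec:
    """Idealized HLA groove: floor plane at z=0 plus two wall ridges."""

    width: float = 14.0
    length: float = 32.0
    wall_height: float = 3.0
    n_wall_atoms: int = 40
    anchor_positions: tuple = ((-8.0, -4.0, 0.0), (8.0, -4.0, 0.0),
                              (0.0, 5.0, 0.0))
    seed: int = 0

    def __post_init__(self):
        a = np.asarray(self.anchor_positions, dtype=float)
        area = 0.5 * np.linalg.norm(np.cross(a[1] - a[0], a[2] - a[0]))
        if area <= 0.1:
            raise FixtureError("groove anchors are (near-)collinear")


@dataclasses.dataclass
class ArchSpec:
    """Bound-peptide arch: termini low (HLA anchors), center bulged."""

    length: int = 9
    terminal_height: float = 1.0
    bulge_height: float = 6.0
    ca_spacing: float = 3.8
    seed: int = 0

    def __post_init__(self):
        if not self.bulge_height > self.terminal_height >= 0:
            raise FixtureError("need bulge_height > terminal_height >= 0")
        if not 1 <= self.length <= 16:
            raise FixtureError("peptide length must be 1-16")


def _backbone_residue(index: int, resname: str, ca: np.ndarray,
                      t: np.ndarray, u: np.ndarray, chain_id: str,
                      with_cb: bool = False) -> list[Atom]:
    """Backbone atoms around a Cα given the chain tangent t and up vector u."""
    s = np.cross(t, u)
    n = ca - 1.2 * t + 0.8 * u
    c = ca + 1.2 * t + 0.8 * u
    o = c + 1.1 * s + 0.55 * u
    atoms = [
        Atom("N", "N", n, index, resname, chain_id),
        Atom("CA", "C", ca, index, resname, chain_id),
        Atom("C", "C", c, index, resname, chain_id),
        Atom("O", "O", o, index, resname, chain_id),
    ]
    if with_cb and resname != "GLY":
        cb = ca + 1.2 * s - 0.95 * u
        atoms.insert(4, Atom("CB", "C", cb, index, resname, chain_id))
    return atoms


def make_groove(spec: GrooveSpec | None = None, chain_id: str = "A") -> Chain:
    """Toy 180-residue backbone-only HLA groove chain.

    Floor residues tile the z=0 plane; wall residues form two ridges at
    y = ±width/2; residues 72, 143 and 159 sit exactly at the specified
    anchor coordinates (their Cα), so the groove plane is recoverable by
    construction.
    """
    spec = spec or GrooveSpec()
    rng = _rng(spec.seed, "groove")
    n_total = 180
    n_wall = spec.n_wall_atoms
    n_floor = n_total - n_wall
    # floor lattice
    nx = int(np.ceil(np.sqrt(n_floor * spec.length / spec.width)))
    ny = int(np.ceil(n_floor / nx))
    xs = np.linspace(-spec.length / 2, spec.length / 2, nx)
    ys = np.linspace(-spec.width / 2 + 1.0, spec.width / 2 - 1.0, ny)
    floor = np.array([(x, y, 0.0) for y in ys for x in xs])[:n_floor]
    half = n_wall // 2
    wx = np.linspace(-spec.length / 2, spec.length / 2, half)
    wall = np.array([(x, -spec.width / 2, spec.wall_height) for x in wx]
                    + [(x, spec.width / 2, spec.wall_height)
                       for x in np.linspace(-spec.length / 2, spec.length / 2,
                                            n_wall - half)])
    ca = np.vstack([floor, wall])
    ca = ca + rng.normal(scale=0.05, size=ca.shape)  # break exact degeneracies
    for rank, anchor in zip((72, 143, 159), spec.anchor_positions):
        ca[rank - 1] = anchor
    t = np.array([1.0, 0.0, 0.0])
    u = np.array([0.0, 0.0, 1.0])
    residues = [_backbone_residue(i + 1, "GLY", ca[i], t, u, chain_id)
                for i in range(n_total)]
    return Chain(chain_id, residues)


def make_arch_peptide(spec: ArchSpec | None = None, sequence: str | None = None,
                      chain_id: str = "C") -> Chain:
    """Peptide chain along a parabolic arch over the groove floor.

    Cα heights interpolate from ``terminal_height`` at both termini to
    ``bulge_height`` at the center; backbone N/C/O and Cβ are placed by
    idealized local geometry. A random sequence is drawn from the seeded
    stream when none is given.
    """
    spec = spec or ArchSpec()
    rng = _rng(spec.seed, "arch")
    L = spec.length
    if sequence is None:
        sequence = "".join(rng.choice(list(chemdata.AMINO_ACIDS), size=L))
    if len(sequence) != L:
        raise FixtureError("sequence length disagrees with spec.length")
    xs = (np.arange(L) - (L - 1) / 2) * spec.ca_spacing
    c = max((L - 1) / 2, 1)
    zs = spec.terminal_height + (spec.bulge_height - spec.terminal_height) * (
        1.0 - ((np.arange(L) - (L - 1) / 2) / c) ** 2)
    ca = np.column_stack([xs, np.zeros(L), zs])
    residues = []
    for i in range(L):
        lo, hi = max(i - 1, 0), min(i + 1, L - 1)
        t = ca[hi] - ca[lo]
        t = t / np.linalg.norm(t)
        u = np.array([0.0, 0.0, 1.0])
        u = u - (u @ t) * t
        u = u / np.linalg.norm(u)
        resname = chemdata.ONE_TO_THREE[sequence[i]]
        residues.append(_backbone_residue(i + 1, resname, ca[i], t, u,
                                          chain_id, with_cb=True))
    return Chain(chain_id, residues)


def make_arch_complex(groove_spec: GrooveSpec | None = None,
                      arch_spec: ArchSpec | None = None,
                      sequence: str | None = None,
                      allele: str = "TOY*01:01") -> PHLAComplex:
    """Groove + arch peptide assembled into a complex."""
    return PHLAComplex(hla=make_groove(groove_spec),
                       peptide=make_arch_peptide(arch_spec, sequence=sequence),
                       allele_name=allele)


def perturb_structure(cplx: PHLAComplex, sigma: float,
                      region: str = "all", seed: int = 0) -> PHLAComplex:
    """Gaussian displacement of peptide atoms in a region; HLA untouched.

    region: "all", "cterm" (final third of residues) or "center"
    (middle third).
    """
    if sigma < 0:
        raise FixtureError("sigma must be >= 0")
    if region not in ("all", "cterm", "center"):
        raise FixtureError(f"unknown region {region!r}")
    rng = _rng(seed, "perturb")
    L = len(cplx.peptide)
    lo, hi = 0, L
    if region == "cterm":
        lo = L - max(L // 3, 1)
    elif region == "center":
        third = max(L // 3, 1)
        lo, hi = third, L - third
        if lo >= hi:
            lo, hi = L // 2, L // 2 + 1
    residues = []
    for i, res in enumerate(cplx.peptide.residues):
        if lo <= i < hi and sigma > 0:
            res = [dataclasses.replace(
                a, coords=a.coords + rng.normal(scale=sigma, size=3))
                for a in res]
        else:
            res = [dataclasses.replace(a) for a in res]
        residues.append(res)
    return PHLAComplex(hla=cplx.hla,
                       peptide=Chain(cplx.peptide.chain_id, residues),
                       allele_name=cplx.allele_name)


# ---------------------------------------------------------------------
# labelled WT/Mut corpora with controlled signal placement
# ---------------------------------------------------------------------

# substitution vocabularies: the atom-group signal distinguishes Thr vs
# Ser targets (nearly identical hydropathy and H-bond chemistry, so the
# label is carried by residue identity alone); the surface signal
# contrasts strongly hydrophobic vs charged targets; the structure
# signal uses a controlled conformational displacement.
_ATOM_GROUP_POS, _ATOM_GROUP_NEG = "T", "S"
_SURFACE_POS, _SURFACE_NEG = "I", "D"
_NEUTRAL_SWAP = {"A": "G", "G": "A"}
_WT_ALPHABET = "AVLGMFKQE"


def make_pair_corpus(n: int, effect_size: float = 4.0,
                     signal_block: str = "atom_group",
                     noise_sd: float = 0.0, seed: int = 0,
                     with_structures: bool = True,
                     two_mismatch_fraction: float = 0.25) -> list[WTMutPair]:
    """Labelled WT/Mut pairs whose signal lives in one comparison block.

    WT peptides are random 9-mers; the mutant carries one substitution
    (plus, in a fraction of pairs, a second label-neutral A<->G swap).
    The latent signal s = ±1 selects the substitution target (or, for
    the structure block, a large vs small conformational displacement of
    the mutant), and the label is Bernoulli(sigmoid(effect_size·s +
    noise)). With a large effect size and zero noise the labels are
    deterministic in the signal.
    """
    if n < 2:
        raise FixtureError("need n >= 2 pairs")
    if signal_block not in ("surface", "structure", "atom_group"):
        raise FixtureError(f"unknown signal block {signal_block!r}")
    rng = _rng(seed, "corpus")
    groove_chain = make_groove(GrooveSpec(seed=seed))
    pairs = []
    for k in range(n):
        wt = "".join(rng.choice(list(_WT_ALPHABET), size=9))
        s_latent = 1.0 if rng.random() < 0.5 else -1.0
        noise = rng.normal(scale=noise_sd) if noise_sd > 0 else 0.0
        p1 = 1.0 / (1.0 + np.exp(-(effect_size * s_latent + noise)))
        label = int(rng.random() < p1)
        pos = int(rng.integers(1, 8))  # keep termini as HLA anchors
        displacement = 0.1
        if signal_block == "atom_group":
            target = _ATOM_GROUP_POS if s_latent > 0 else _ATOM_GROUP_NEG
        elif signal_block == "surface":
            target = _SURFACE_POS if s_latent > 0 else _SURFACE_NEG
        else:  # structure: identity of the target carries no signal
            target = "M" if wt[pos] != "M" else "F"
            displacement = 2.0 if s_latent > 0 else 0.1
        if target == wt[pos]:
            target = "N" if target != "N" else "Q"
        mut = wt[:pos] + target + wt[pos + 1:]
        if rng.random() < two_mismatch_fraction:
            cand = [i for i, ch in enumerate(wt)
                    if i != pos and ch in _NEUTRAL_SWAP]
            if cand:
                j = int(rng.choice(cand))
                mut = mut[:j] + _NEUTRAL_SWAP[mut[j]] + mut[j + 1:]
        mut_structure = wt_structure = None
        if with_structures:
            arch = ArchSpec(seed=seed)
            wt_structure = PHLAComplex(hla=groove_chain,
                                       peptide=make_arch_peptide(arch, sequence=wt))
            base = PHLAComplex(hla=groove_chain,
                               peptide=make_arch_peptide(arch, sequence=mut))
            mut_structure = perturb_structure(base, displacement,
                                              region="center",
                                              seed=seed * 100003 + k)
        pairs.append(WTMutPair(mut_seq=mut, wt_seq=wt, allele="TOY*01:01",
                               label=label, mut_structure=mut_structure,
                               wt_structure=wt_structure))
    return pairs
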