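"""Data model for peptide–HLA class I complexes.

A pHLA-I complex is a two-chain structure: the HLA heavy chain (binding
groove domain, residues 1–180) and a short bound peptide (7–14 residues
in crystal structures; up to 16 accepted here). This module provides the
atom/chain containers, PDB reading and writing (through gemmi), chain
role assignment, trimming of the HLA chain to the groove domain, and
padding of peptide sequences to the fixed model length of 16.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from . import chemdata

PEPTIDE_MIN, PEPTIDE_MAX = 7, 16
PADDED_LENGTH = 16
HLA_LAST_RESIDUE = 180


class StructureError(Exception):
    """Base error for structure handling."""


class EmptyStructureError(StructureError):
    """No ATOM records / no usable chains."""


class NoPeptideError(StructureError):
    """No chain satisfies the peptide length criterion."""


class PaddingError(ValueError, StructureError):
    """Peptide sequence cannot be padded (too long or bad alphabet)."""


@dataclasses.dataclass
class Atom:
    """A heavy atom with Cartesian coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray
    residue_index: int
    residue_name: str
    chain_id: str

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coords must be a finite 3-vector")
        if self.residue_index < 1:
            raise StructureError("residue_index must be >= 1")


class Chain:
    """An ordered list of residues, each an ordered list of Atoms."""

    def __init__(self, chain_id: str, residues: Sequence[Sequence[Atom]]):
        self.chain_id = chain_id
        self.residues = [list(r) for r in residues]
        idx = self.residue_indices
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise StructureError(f"chain {chain_id}: residue_index not strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def residue_indices(self) -> list[int]:
        return [r[0].residue_index for r in self.residues]

    @property
    def residue_names(self) -> list[str]:
        return [r[0].residue_name for r in self.residues]

    @property
    def sequence(self) -> str:
        return "".join(chemdata.THREE_TO_ONE.get(n, "X") for n in self.residue_names)

    @property
    def atoms(self) -> list[Atom]:
        return [a for res in self.residues for a in res]

    def atom_coords(self) -> np.ndarray:
        """All atom coordinates, shape (n_atoms, 3)."""
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def ca_coords(self) -> np.ndarray:
        """Per-residue Cα coordinates (falls back to the first atom)."""
        out = []
        for res in self.residues:
            ca = next((a for a in res if a.name == "CA"), res[0])
            out.append(ca.coords)
        return np.array(out, dtype=float).reshape(-1, 3)

    def get_residue(self, residue_index: int) -> list[Atom]:
        for res in self.residues:
            if res[0].residue_index == residue_index:
                return res
        raise KeyError(f"residue {residue_index} not in chain {self.chain_id}")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Chain":
        """Return a copy with coords -> coords @ rotation.T + translation."""
        res = [[dataclasses.replace(a, coords=rotation @ a.coords + translation)
                for a in r] for r in self.residues]
        return Chain(self.chain_id, res)


@dataclasses.dataclass
class PHLAComplex:
    """HLA groove domain plus bound peptide."""

    hla: Chain
    peptide: Chain
    allele_name: str | None = None

    def __post_init__(self):
        if len(self.peptide) > PADDED_LENGTH:
            raise StructureError("peptide longer than 16 residues")
        bad = [i for i in self.hla.residue_indices if i > HLA_LAST_RESIDUE]
        if bad:
            raise StructureError(f"HLA residues beyond {HLA_LAST_RESIDUE}: {bad[:3]}")

    def all_atom_coords(self) -> np.ndarray:
        return np.vstack([self.hla.atom_coords(), self.peptide.atom_coords()])


@dataclasses.dataclass(frozen=True)
class PaddedPeptideSeq:
    """Peptide sequence padded to the fixed model length of 16 tokens."""

    tokens: tuple[str, ...]
    true_length: int

    @property
    def sequence(self) -> str:
        """Un-padded 1-letter sequence."""
        return "".join(self.tokens[: self.true_length])


def read_pdb(path: str | Path) -> list[Chain]:
    """Read ATOM records from a PDB file into Chains.

    HETATM ligands and waters are excluded. For alternate conformers the
    highest-occupancy altloc is kept (ties broken by altloc letter);
    insertion codes are rejected.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (OSError, RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    chains: list[Chain] = []
    for gchain in st[0]:
        residues = []
        for gres in gchain:
            if gres.het_flag != "A" or gres.name not in chemdata.THREE_TO_ONE:
                continue  # skip HETATM (waters, ligands) and non-standard residues
            if gres.seqid.icode not in ("", " "):
                raise StructureError(
                    f"{path}: insertion code {gres.seqid.icode!r} at residue "
                    f"{gres.seqid.num} not supported")
            by_name: dict[str, gemmi.Atom] = {}
            for ga in gres:
                prev = by_name.get(ga.name)
                if prev is None or (ga.occ, -ord(ga.altloc or "A")) > (
                        prev.occ, -ord(prev.altloc or "A")):
                    by_name[ga.name] = ga
            atoms = [Atom(name=ga.name,
                          element=ga.element.name or chemdata.element_of(ga.name),
                          coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                          residue_index=gres.seqid.num,
                          residue_name=gres.name,
                          chain_id=gchain.name)
                     for ga in by_name.values()]
            if atoms:
                residues.append(atoms)
        if residues:
            chains.append(Chain(gchain.name, residues))
    if not chains:
        raise EmptyStructureError(f"{path}: no ATOM records for standard residues")
    return chains


def trim_hla(chain: Chain, last_residue: int = HLA_LAST_RESIDUE) -> Chain:
    """Keep only residues with author residue number <= ``last_residue``."""
    if len(chain) == 0:
        raise StructureError("cannot trim an empty chain")
    kept = [r for r in chain.residues if r[0].residue_index <= last_residue]
    return Chain(chain.chain_id, kept)


def split_phla(chains: Iterable[Chain], *,
               hla_chain_id: str | None = None,
               pep_chain_id: str | None = None,
               allele_name: str | None = None) -> PHLAComplex:
    """Assign chain roles and assemble a trimmed complex.

    Default rule: the longest chain is the HLA heavy chain; among chains
    of length 7–16, the one whose centroid is nearest the HLA centroid
    is the peptide. Explicit chain ids override the rule.
    """
    chains = list(chains)
    if len(chains) < 2:
        raise StructureError("need at least two chains to split a pHLA complex")
    by_id = {c.chain_id: c for c in chains}
    if hla_chain_id is not None:
        hla = by_id[hla_chain_id]
    else:
        hla = max(chains, key=len)
    if pep_chain_id is not None:
        pep = by_id[pep_chain_id]
    else:
        candidates = [c for c in chains
                      if c is not hla and PEPTIDE_MIN <= len(c) <= PEPTIDE_MAX]
        if not candidates:
            raise NoPeptideError(
                f"no chain of length {PEPTIDE_MIN}-{PEPTIDE_MAX} among "
                f"{[len(c) for c in chains]}")
        hla_centroid = hla.atom_coords().mean(axis=0)
        pep = min(candidates,
                  key=lambda c: float(np.linalg.norm(c.atom_coords().mean(axis=0)
                                                     - hla_centroid)))
    return PHLAComplex(hla=trim_hla(hla), peptide=pep, allele_name=allele_name)


def pad_peptide(seq: str) -> PaddedPeptideSeq:
    """Pad a 1-letter peptide sequence to 16 tokens with PAD sentinels."""
    if not 1 <= len(seq) <= PADDED_LENGTH:
        raise PaddingError(f"peptide length {len(seq)} outside [1, {PADDED_LENGTH}]")
    seq = seq.upper()
    bad = sorted(set(seq) - set(chemdata.AMINO_ACIDS))
    if bad:
        raise PaddingError(f"non-standard amino acids: {bad}")
    tokens = tuple(seq) + (chemdata.PAD_TOKEN,) * (PADDED_LENGTH - len(seq))
    return PaddedPeptideSeq(tokens=tokens, true_length=len(seq))


def write_pdb(complex_or_chains: PHLAComplex | Iterable[Chain],
              path: str | Path) -> None:
    """Write standard PDB ATOM records (coordinates to 3 decimals)."""
    if isinstance(complex_or_chains, PHLAComplex):
        chains = [complex_or_chains.hla, complex_or_chains.peptide]
    else:
        chains = list(complex_or_chains)
    if any(len(c) == 0 for c in chains):
        raise StructureError("refusing to write an empty chain")
    st = gemmi.Structure()
    st.name = "neoasurf"
    model = gemmi.Model("1")
    for chain in chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res[0].residue_name
            gres.seqid = gemmi.SeqId(res[0].residue_index, " ")
            gres.het_flag = "A"
            for a in res:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = 1.0
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise StructureError(f"cannot write {path}: {exc}") from exc


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences from a FASTA file, keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
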