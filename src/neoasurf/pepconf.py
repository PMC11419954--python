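"""Miniature trainable peptide-conformation engine.

The architecture follows the template-based design for peptide–HLA-I
structure prediction: the HLA groove coordinates are an input template
(never predicted), the padded peptide sequence is embedded, a
peptide–HLA spatial distance matrix computed after embedding biases the
attention encoder, and the decoder heads emit backbone coordinates,
torsion angles, per-pair distance distributions (within the peptide and
across the peptide–HLA interface) and a 50-bin per-residue pLDDT
estimate. The loss is the weighted composition

    L       = L_pep + L_pHLA
    L_pep   = L_FAPE + 0.3 L_dist + L_angle + L_viol
    L_pHLA  = 9.5 L_pHLA-FAPE + 0.5 L_pHLA-dist

where the pHLA terms measure peptide atoms in HLA residue frames and
the peptide–HLA distance distribution, tying the peptide into the
groove. The network is a deliberately small single-head attention
miniature sized for CPU training on synthetic fixtures; the loss
composition, frame construction and distance-matrix machinery are exact.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import autodiff as ad
from . import chemdata
from .autodiff import Parameter, Tensor
from .metrics import PLDDTRecord, filter_by_plddt
from .structure import Chain, PaddedPeptideSeq, PADDED_LENGTH

FAPE_CLAMP = 10.0  # Angstrom
FAPE_SCALE = 10.0  # Angstrom
DIST_BINS = 64
DIST_MIN, DIST_MAX = 2.0, 22.0
PLDDT_BINS = 50
W_DIST, W_PHLA_FAPE, W_PHLA_DIST = 0.3, 9.5, 0.5
N_TORSIONS = 2 + chemdata.MAX_CHI  # phi, psi, chi1..chi4


class PepConfError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


@dataclasses.dataclass
class ModelConfig:
    """Size and determinism knobs for the miniature model."""

    h: int = 180
    p: int = PADDED_LENGTH
    d: int = 32
    n_blocks: int = 2
    n_rbf: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.d < 8 or self.n_blocks < 1:
            raise PepConfError("config requires d >= 8 and n_blocks >= 1")


@dataclasses.dataclass
class ResidueFrame:
    """Backbone rigid frame from N-CA-C Gram-Schmidt."""

    rotation: np.ndarray
    origin: np.ndarray


@dataclasses.dataclass
class LossBreakdown:
    """All auxiliary loss terms and their weighted composition."""

    fape: float
    dist: float
    angle: float
    viol: float
    phla_fape: float
    phla_dist: float
    pep: float
    phla: float
    total: float


@dataclasses.dataclass
class FoldPrediction:
    """Predicted peptide: per-residue atom dictionaries plus confidence."""

    residue_names: list[str]
    atoms: list[dict[str, np.ndarray]]
    plddt: PLDDTRecord

    @property
    def n_atoms(self) -> int:
        return sum(len(d) for d in self.atoms)

    def ca_coords(self) -> np.ndarray:
        return np.array([d["CA"] for d in self.atoms])

    def to_chain(self, chain_id: str = "C") -> Chain:
        from .structure import Atom

        residues = []
        for i, (rn, d) in enumerate(zip(self.residue_names, self.atoms), start=1):
            residues.append([
                Atom(name=n, element=chemdata.element_of(n), coords=c,
                     residue_index=i, residue_name=rn, chain_id=chain_id)
                for n, c in d.items()])
        return Chain(chain_id, residues)


# ---------------------------------------------------------------------
# geometry: frames, distance matrices
# ---------------------------------------------------------------------

def gram_schmidt_frames(N: np.ndarray, CA: np.ndarray, C: np.ndarray
                        ) -> list[ResidueFrame]:
    """Backbone frames: e1 along CA->C, e2 in the N-CA-C plane."""
    frames = []
    for n, ca, c in zip(N, CA, C):
        e1 = c - ca
        e1 = e1 / np.linalg.norm(e1)
        u2 = (n - ca) - ((n - ca) @ e1) * e1
        nrm = np.linalg.norm(u2)
        if nrm < 1e-8:
            raise PepConfError("collinear N-CA-C; frame undefined")
        e2 = u2 / nrm
        e3 = np.cross(e1, e2)
        frames.append(ResidueFrame(rotation=np.column_stack([e1, e2, e3]),
                                   origin=ca))
    return frames


def frames_of_chain(chain: Chain) -> list[ResidueFrame]:
    coords = {"N": [], "CA": [], "C": []}
    for res in chain.residues:
        have = {a.name: a.coords for a in res}
        for k in coords:
            if k not in have:
                raise PepConfError(f"residue {res[0].residue_index} lacks {k}")
            coords[k].append(have[k])
    return gram_schmidt_frames(*(np.array(coords[k]) for k in ("N", "CA", "C")))


def _frames_tensor(N: Tensor, CA: Tensor, C: Tensor) -> tuple[Tensor, Tensor]:
    """Differentiable Gram-Schmidt frames; returns (rotations (n,3,3), origins)."""
    v1 = C - CA
    e1 = v1 / v1.norm(axis=-1, keepdims=True)
    v2 = N - CA
    u2 = v2 - (v2 * e1).sum(axis=-1, keepdims=True) * e1
    e2 = u2 / u2.norm(axis=-1, keepdims=True)
    e3 = ad.cross(e1, e2)
    R = ad.stack([e1, e2, e3], axis=-1)  # columns e1,e2,e3
    return R, CA


def representative_coords(chain: Chain) -> np.ndarray:
    """Per-residue Cβ coordinate (Cα for glycine or when Cβ is absent)."""
    out = []
    for res in chain.residues:
        have = {a.name: a.coords for a in res}
        if res[0].residue_name != "GLY" and "CB" in have:
            out.append(have["CB"])
        elif "CA" in have:
            out.append(have["CA"])
        else:
            raise PepConfError(
                f"residue {res[0].residue_index} has neither CB nor CA")
    return np.array(out)


def phla_distance_matrix(hla: Chain, peptide_coords: np.ndarray | Chain,
                         pad_to: int = PADDED_LENGTH
                         ) -> tuple[np.ndarray, np.ndarray]:
    """(p+h) x (p+h) pairwise residue distance matrix with PAD masking.

    Residues are represented by Cβ (Cα for Gly). Peptide rows come
    first; PAD rows/columns are zeroed and flagged False in the mask.
    """
    hla_rep = representative_coords(hla)
    pep_rep = (representative_coords(peptide_coords)
               if isinstance(peptide_coords, Chain)
               else np.asarray(peptide_coords, dtype=float))
    p_true = len(pep_rep)
    coords = np.vstack([pep_rep, np.zeros((pad_to - p_true, 3)), hla_rep])
    valid = np.ones(len(coords), dtype=bool)
    valid[p_true:pad_to] = False
    D = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
    mask = valid[:, None] & valid[None, :]
    D[~mask] = 0.0
    return D, mask


# ---------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------

def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def fape(pred_frames, pred_atoms, true_frames, true_atoms,
         clamp: float = FAPE_CLAMP, scale: float = FAPE_SCALE) -> Tensor:
    """Frame-aligned point error.

    Every atom is expressed in every residue frame of its own structure;
    the loss is the mean over (frame, atom) of the clamped local-error
    norm divided by ``scale``. Invariant to joint rigid motion of frames
    and atoms.

    Frames are (rotations (F,3,3), origins (F,3)) tuples (Tensor or
    ndarray) or lists of ResidueFrame; atoms are (A,3).
    """
    Rp, tp = _frames_as_arrays(pred_frames)
    Rt, tt = _frames_as_arrays(true_frames)
    pa = _as_tensor(pred_atoms)
    ta = _as_tensor(true_atoms)
    if pa.shape != ta.shape or pa.shape[0] == 0:
        raise PepConfError("paired non-empty atom sets required")
    local_p = _to_local(Rp, tp, pa)
    local_t = _to_local(Rt, tt, ta)
    err = (local_p - local_t).norm(axis=-1)
    return err.clamp_max(clamp).mean() * (1.0 / scale)


def _frames_as_arrays(frames) -> tuple[Tensor, Tensor]:
    if isinstance(frames, tuple):
        R, t = frames
        return _as_tensor(R), _as_tensor(t)
    R = np.stack([f.rotation for f in frames])
    t = np.stack([f.origin for f in frames])
    return Tensor(R), Tensor(t)


def _to_local(R: Tensor, t: Tensor, atoms: Tensor) -> Tensor:
    F = R.shape[0]
    A = atoms.shape[0]
    diff = atoms.reshape(1, A, 3) - t.reshape(F, 1, 3)
    return diff @ R  # (R^T d)_i = d_j R_ji

def phla_fape(hla_frames, pred_peptide_atoms, true_peptide_atoms,
              clamp: float = FAPE_CLAMP, scale: float = FAPE_SCALE) -> Tensor:
    """FAPE of peptide atoms measured in fixed HLA residue frames.

    Unlike intra-peptide FAPE this is *not* invariant to moving the
    peptide alone, which is the point: it anchors the peptide pose in
    the groove.
    """
    return fape(hla_frames, pred_peptide_atoms, hla_frames,
                true_peptide_atoms, clamp=clamp, scale=scale)


def distance_bins(d: np.ndarray, n_bins: int = DIST_BINS,
                  lo: float = DIST_MIN, hi: float = DIST_MAX) -> np.ndarray:
    """Bin index per distance; the last bin catches >= hi."""
    width = (hi - lo) / (n_bins - 1)
    idx = np.floor((np.asarray(d) - lo) / width).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def distogram_loss(logits: Tensor, true_distances: np.ndarray,
                   mask: np.ndarray | None = None,
                   n_bins: int = DIST_BINS) -> Tensor:
    """Mean softmax cross-entropy of binned pair distances."""
    logits = _as_tensor(logits)
    if not np.all(np.isfinite(logits.data)):
        raise PepConfError("non-finite distogram logits")
    target = distance_bins(true_distances, n_bins=n_bins)
    if mask is None:
        mask = np.ones(target.shape, dtype=bool)
    flat_logits = logits.reshape(-1, n_bins)[np.where(mask.reshape(-1))[0]]
    return ad.cross_entropy(flat_logits, target[mask])


def torsion_angle_loss(pred_sin_cos: Tensor, true_angles: np.ndarray,
                       mask: np.ndarray | None = None,
                       norm_weight: float = 0.02) -> Tensor:
    """Squared chord distance on the unit circle plus a normalization
    penalty on the raw (cos, sin) magnitudes."""
    pred = _as_tensor(pred_sin_cos)
    true_angles = np.asarray(true_angles, dtype=float)
    if mask is None:
        mask = np.ones(true_angles.shape, dtype=bool)
    nrm = pred.norm(axis=-1)
    unit = pred / nrm.reshape(*nrm.shape, 1)
    target = np.stack([np.cos(true_angles), np.sin(true_angles)], axis=-1)
    chord2 = ((unit - Tensor(target)) ** 2.0).sum(axis=-1)
    midx = np.where(mask.reshape(-1))[0]
    chord_term = chord2.reshape(-1)[midx].mean()
    norm_term = (nrm - 1.0).abs().reshape(-1)[midx].mean()
    return chord_term + norm_weight * norm_term


def violation_loss(N: Tensor, CA: Tensor, C: Tensor,
                   bond_tol: float = 0.2, cos_tol: float = 0.15,
                   clash_dist: float = 2.0) -> Tensor:
    """One-sided penalties for non-ideal backbone geometry and clashes.

    Bond lengths (N-CA, CA-C, C-N') and the N-CA-C angle are penalized
    beyond a tolerance around their ideal values; non-bonded atom pairs
    from residues >= 2 apart are penalized below ``clash_dist``.
    """
    N, CA, C = _as_tensor(N), _as_tensor(CA), _as_tensor(C)
    n = N.shape[0]
    terms = []
    for a, b, ideal in ((N, CA, chemdata.BOND_N_CA), (CA, C, chemdata.BOND_CA_C)):
        d = (a - b).norm(axis=-1)
        terms.append(((d - ideal).abs() - bond_tol).clamp_min(0.0).mean())
    if n > 1:
        d = (C[:-1] - N[1:]).norm(axis=-1)
        terms.append(((d - chemdata.BOND_C_N).abs() - bond_tol).clamp_min(0.0).mean())
    v1 = N - CA
    v2 = C - CA
    cosang = (v1 * v2).sum(axis=-1) / (v1.norm(axis=-1) * v2.norm(axis=-1))
    ideal_cos = float(np.cos(np.deg2rad(chemdata.ANGLE_N_CA_C)))
    terms.append(((cosang - ideal_cos).abs() - cos_tol).clamp_min(0.0).mean())
    if n > 2:
        atoms = ad.concat([N, CA, C], axis=0)  # (3n, 3)
        res_id = np.tile(np.arange(n), 3)
        ii, jj = np.where(np.abs(res_id[:, None] - res_id[None, :]) >= 2)
        keep = ii < jj
        ii, jj = ii[keep], jj[keep]
        d = (atoms[ii] - atoms[jj]).norm(axis=-1)
        terms.append((clash_dist - d).clamp_min(0.0).mean())
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total


def total_loss(fape_l, dist_l, angle_l, viol_l, phla_fape_l, phla_dist_l
               ) -> tuple[LossBreakdown, Tensor]:
    """Compose the six auxiliary losses with the fixed weights
    (0.3 on the peptide distogram; 9.5 / 0.5 on the intermolecular pair).

    Returns the float breakdown and the total as a differentiable scalar.
    """
    parts = [fape_l, dist_l, angle_l, viol_l, phla_fape_l, phla_dist_l]
    vals = [float(p.data) if isinstance(p, Tensor) else float(p) for p in parts]
    if any(v < 0 for v in vals):
        raise PepConfError("auxiliary losses must be nonnegative")
    t = [_as_tensor(p) for p in parts]
    pep = t[0] + W_DIST * t[1] + t[2] + t[3]
    phla = W_PHLA_FAPE * t[4] + W_PHLA_DIST * t[5]
    total = pep + phla
    bd = LossBreakdown(fape=vals[0], dist=vals[1], angle=vals[2], viol=vals[3],
                       phla_fape=vals[4], phla_dist=vals[5],
                       pep=float(pep.data), phla=float(phla.data),
                       total=float(total.data))
    return bd, total


# ---------------------------------------------------------------------
# model
# ---------------------------------------------------------------------

_TOKENS = chemdata.AMINO_ACIDS + chemdata.PAD_TOKEN
TOKEN_INDEX = {t: i for i, t in enumerate(_TOKENS)}


def _token_ids(seq: PaddedPeptideSeq) -> np.ndarray:
    return np.array([TOKEN_INDEX[t] for t in seq.tokens])


def _rbf(d: np.ndarray, n: int, lo: float = 0.0, hi: float = 24.0) -> np.ndarray:
    centers = np.linspace(lo, hi, n)
    width = (hi - lo) / n
    return np.exp(-((d[..., None] - centers) / width) ** 2)


class PepConfModel:
    """Single-head attention miniature with a pHLA distance-matrix bias."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.d

        def W(*shape, scale=None):
            scale = scale if scale is not None else 1.0 / np.sqrt(shape[0])
            return Parameter(rng.standard_normal(shape) * scale)

        self.params: dict = {
            "embed": W(21, d, scale=0.3),
            "pos": W(config.p, d, scale=0.3),
            "hla_embed": W(21, d, scale=0.3),
            "hla_coord": W(3, d, scale=0.1),
            "blocks": [],
            "w_ca": W(d, 3, scale=0.01), "b_ca": Parameter(np.zeros(3)),
            "w_n": W(d, 3, scale=0.01), "w_c": W(d, 3, scale=0.01),
            "w_tors": W(d, N_TORSIONS * 2, scale=0.1),
            "b_tors": Parameter(np.tile([1.0, 0.0], N_TORSIONS)),
            "dist_l": W(d, d), "dist_r": W(d, d), "dist_o": W(d, DIST_BINS, scale=0.1),
            "ph_l": W(d, d), "ph_r": W(d, d), "ph_o": W(d, DIST_BINS, scale=0.1),
            "w_plddt": W(d, PLDDT_BINS, scale=0.1),
        }
        for _ in range(config.n_blocks):
            self.params["blocks"].append({
                "wq": W(d, d), "wk": W(d, d), "wv": W(d, d), "wo": W(d, d),
                "pair_b": W(config.n_rbf, 1, scale=0.1),
                "hq": W(d, d), "hk": W(d, d), "hv": W(d, d), "ho": W(d, d),
                "hpair_b": W(config.n_rbf, 1, scale=0.1),
                "t1": W(d, 2 * d), "t2": W(2 * d, d),
            })
        # constant frame-forming offsets keep Gram-Schmidt well-posed at init
        self.base_n = np.array([-1.2, 0.8, 0.0])
        self.base_c = np.array([1.2, 0.8, 0.0])

    def parameters(self) -> list[Parameter]:
        return ad.parameters_of(self.params)

    # -- forward -------------------------------------------------------
    def _trunk(self, hla: Chain, peptide: PaddedPeptideSeq) -> dict:
        cfg = self.config
        ids = _token_ids(peptide)
        p_mask = np.array([t != chemdata.PAD_TOKEN for t in peptide.tokens])
        s = self.params["embed"][ids] + self.params["pos"]
        hla_ids = np.array([TOKEN_INDEX.get(c, TOKEN_INDEX[chemdata.PAD_TOKEN])
                            for c in hla.sequence])
        hla_ca = hla.ca_coords()
        center = hla_ca.mean(axis=0)
        hfeat = (self.params["hla_embed"][hla_ids]
                 + Tensor((hla_ca - center) * 0.1) @ self.params["hla_coord"])
        # pHLA spatial distance matrix from the template and an initial
        # peptide guess laid along the groove above the template center
        guess = np.tile(center + np.array([0.0, 0.0, 4.0]), (cfg.p, 1))
        guess[:, 0] += np.linspace(-12, 12, cfg.p)
        D, _ = phla_distance_matrix(hla, guess[p_mask][: peptide.true_length],
                                    pad_to=cfg.p)
        D_pp = _rbf(D[:cfg.p, :cfg.p], cfg.n_rbf)
        D_ph = _rbf(D[:cfg.p, cfg.p:], cfg.n_rbf)
        neg = -1e9 * (~p_mask).astype(float)
        scale = 1.0 / np.sqrt(cfg.d)
        for blk in self.params["blocks"]:
            q = s @ blk["wq"]
            k = s @ blk["wk"]
            v = s @ blk["wv"]
            bias_pp = (Tensor(D_pp) @ blk["pair_b"]).reshape(cfg.p, cfg.p)
            att = ad.softmax(q @ k.transpose() * scale + bias_pp + neg[None, :],
                             axis=-1)
            s = s + (att @ v) @ blk["wo"]
            hq = s @ blk["hq"]
            hk = hfeat @ blk["hk"]
            hv = hfeat @ blk["hv"]
            bias_ph = (Tensor(D_ph) @ blk["hpair_b"]).reshape(cfg.p, len(hla))
            hatt = ad.softmax(hq @ hk.transpose() * scale + bias_ph, axis=-1)
            s = s + (hatt @ hv) @ blk["ho"]
            s = s + (s @ blk["t1"]).tanh() @ blk["t2"]
        return {"s": s, "p_mask": p_mask, "hfeat": hfeat, "center": center}

    def heads(self, hla: Chain, peptide: PaddedPeptideSeq) -> dict:
        """Run the trunk and all output heads (differentiable)."""
        cfg = self.config
        tr = self._trunk(hla, peptide)
        s = tr["s"]
        ca = s @ self.params["w_ca"] + self.params["b_ca"] + Tensor(
            np.tile(tr["center"] + [0.0, 0.0, 4.0], (cfg.p, 1)))
        n = ca + s @ self.params["w_n"] + Tensor(self.base_n)
        c = ca + s @ self.params["w_c"] + Tensor(self.base_c)
        tors = (s @ self.params["w_tors"] + self.params["b_tors"]
                ).reshape(cfg.p, N_TORSIONS, 2)
        L = len(hla)
        dist_logits = ((s @ self.params["dist_l"]).reshape(cfg.p, 1, cfg.d)
                       + (s @ self.params["dist_r"]).reshape(1, cfg.p, cfg.d)
                       ).tanh() @ self.params["dist_o"]
        ph_logits = ((s @ self.params["ph_l"]).reshape(cfg.p, 1, cfg.d)
                     + (tr["hfeat"] @ self.params["ph_r"]).reshape(1, L, cfg.d)
                     ).tanh() @ self.params["ph_o"]
        plddt_logits = s @ self.params["w_plddt"]
        return {"ca": ca, "n": n, "c": c, "torsions": tors,
                "dist_logits": dist_logits, "ph_logits": ph_logits,
                "plddt_logits": plddt_logits, "p_mask": tr["p_mask"]}


def _plddt_from_logits(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    prob = np.exp(z)
    prob /= prob.sum(axis=-1, keepdims=True)
    centers = (np.arange(PLDDT_BINS) + 0.5) * (100.0 / PLDDT_BINS)
    return prob @ centers


def realize_atoms(residue_names: Sequence[str], N: np.ndarray, CA: np.ndarray,
                  C: np.ndarray, chi_angles: np.ndarray) -> list[dict[str, np.ndarray]]:
    """Build all heavy atoms from backbone coordinates and chi torsions
    using the bundled ideal-geometry topology."""
    out = []
    n_res = len(residue_names)
    for i, rn in enumerate(residue_names):
        pos: dict[str, np.ndarray] = {"N": N[i], "CA": CA[i], "C": C[i]}
        # carbonyl O in the peptide plane (trans to the next N when present)
        psi_ref = N[i + 1] if i + 1 < n_res else N[i]
        o_tors = 180.0 if i + 1 < n_res else 0.0
        base = chemdata.place_atom(psi_ref if i + 1 < n_res else N[i],
                                   CA[i], C[i], chemdata.BOND_C_O,
                                   chemdata.ANGLE_CA_C_O, o_tors)
        pos["O"] = base
        if rn != "GLY":
            pos["CB"] = chemdata.place_atom(C[i], N[i], CA[i],
                                            chemdata.BOND_CA_CB, 110.5, 122.5)
        for rec in chemdata.SIDE_CHAIN_TOPOLOGY[rn]:
            name, r3, r2, r1, bond, angle, tors = rec
            if isinstance(tors, tuple):
                _, k, off = tors
                tors_val = np.rad2deg(chi_angles[i, k - 1]) + off
            else:
                tors_val = tors
            pos[name] = chemdata.place_atom(pos[r3], pos[r2], pos[r1],
                                            bond, angle, tors_val)
        out.append(pos)
    return out


def forward(config: ModelConfig, hla: Chain, peptide: PaddedPeptideSeq,
            model: PepConfModel | None = None) -> FoldPrediction:
    """Deterministic forward pass to a full-atom peptide prediction.

    PAD positions emit no atoms; per-residue pLDDT is the expectation
    over the 50-bin confidence head.
    """
    model = model or PepConfModel(config)
    heads = model.heads(hla, peptide)
    mask = heads["p_mask"]
    L = int(mask.sum())
    N = heads["n"].data[:L]
    CA = heads["ca"].data[:L]
    C = heads["c"].data[:L]
    tors = heads["torsions"].data[:L]
    angles = np.arctan2(tors[..., 1], tors[..., 0])
    chi = angles[:, 2:]
    resnames = [chemdata.ONE_TO_THREE[t] for t in peptide.tokens[:L]]
    atoms = realize_atoms(resnames, N, CA, C, chi)
    plddt = _plddt_from_logits(heads["plddt_logits"].data[:L])
    return FoldPrediction(residue_names=resnames, atoms=atoms,
                          plddt=PLDDTRecord(per_residue=plddt))


# ---------------------------------------------------------------------
# training
# ---------------------------------------------------------------------

def backbone_torsions(N: np.ndarray, CA: np.ndarray, C: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """phi/psi dihedrals of a backbone trace (radians; ends masked NaN)."""
    n = len(CA)

    def dihedral(p0, p1, p2, p3):
        b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
        b1n = b1 / np.linalg.norm(b1)
        v = b0 - (b0 @ b1n) * b1n
        w = b2 - (b2 @ b1n) * b1n
        return np.arctan2(np.cross(v, w) @ b1n, v @ w)

    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    for i in range(n):
        if i > 0:
            phi[i] = dihedral(C[i - 1], N[i], CA[i], C[i])
        if i < n - 1:
            psi[i] = dihedral(N[i], CA[i], C[i], N[i + 1])
    return phi, psi


def example_losses(model: PepConfModel, hla: Chain,
                   peptide: PaddedPeptideSeq, true_peptide: Chain
                   ) -> tuple[LossBreakdown, Tensor]:
    """Full loss graph for one training example."""
    heads = model.heads(hla, peptide)
    L = peptide.true_length
    coords = {k: [] for k in ("N", "CA", "C")}
    for res in true_peptide.residues:
        have = {a.name: a.coords for a in res}
        for k in coords:
            coords[k].append(have[k])
    tN, tCA, tC = (np.array(coords[k]) for k in ("N", "CA", "C"))
    pN, pCA, pC = heads["n"][:L], heads["ca"][:L], heads["c"][:L]

    pred_frames = _frames_tensor(pN, pCA, pC)
    true_frames = _frames_as_arrays(gram_schmidt_frames(tN, tCA, tC))
    pred_atoms = ad.concat([pN, pCA, pC], axis=0)
    true_atoms = np.vstack([tN, tCA, tC])
    l_fape = fape(pred_frames, pred_atoms, true_frames, true_atoms)

    rep_true = representative_coords(true_peptide)
    D_pp = np.linalg.norm(rep_true[:, None] - rep_true[None], axis=-1)
    pair_mask = ~np.eye(L, dtype=bool)
    l_dist = distogram_loss(heads["dist_logits"][:L, :L], D_pp, mask=pair_mask)

    phi, psi = backbone_torsions(tN, tCA, tC)
    true_ang = np.zeros((L, N_TORSIONS))
    ang_mask = np.zeros((L, N_TORSIONS), dtype=bool)
    true_ang[:, 0] = np.nan_to_num(phi)
    true_ang[:, 1] = np.nan_to_num(psi)
    ang_mask[:, 0] = ~np.isnan(phi)
    ang_mask[:, 1] = ~np.isnan(psi)
    l_angle = torsion_angle_loss(heads["torsions"][:L], true_ang, mask=ang_mask)

    l_viol = violation_loss(pN, pCA, pC)

    hla_frames = _frames_as_arrays(frames_of_chain(hla))
    l_phla_fape = phla_fape(hla_frames, pred_atoms, true_atoms)

    hla_rep = representative_coords(hla)
    D_ph = np.linalg.norm(rep_true[:, None] - hla_rep[None], axis=-1)
    l_phla_dist = distogram_loss(heads["ph_logits"][:L], D_ph)

    return total_loss(l_fape, l_dist, l_angle, l_viol, l_phla_fape, l_phla_dist)


def train_toy(config: ModelConfig,
              dataset: Sequence[tuple[Chain, PaddedPeptideSeq, Chain]],
              steps: int = 500, seed: int | None = None,
              lr: float = 1e-3, optimizer: str = "sgd",
              ) -> tuple[PepConfModel, list[LossBreakdown]]:
    """Gradient training of the miniature on (HLA, peptide, truth) triples.

    ``optimizer``: "sgd" (momentum 0.9, the default training rule) or
    "adam" (used for fast single-example overfitting demonstrations).
    Raises TrainingError on divergence.
    """
    if len(dataset) == 0:
        raise PepConfError("dataset must contain at least one example")
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    model = PepConfModel(config)
    params = model.parameters()
    opt = (ad.Adam(params, lr=lr) if optimizer == "adam"
           else ad.SGD(params, lr=lr, momentum=0.9))
    curve: list[LossBreakdown] = []
    for _ in range(steps):
        step_bd = None
        for hla, pep, truth in dataset:
            opt.zero_grad()
            bd, total = example_losses(model, hla, pep, truth)
            if not np.isfinite(bd.total):
                raise TrainingError(f"loss diverged: {bd}")
            total.backward()
            opt.step()
            step_bd = bd
        curve.append(step_bd)
    return model, curve


def self_distill_select(predictions: Sequence[FoldPrediction],
                        threshold: float = 92.0
                        ) -> tuple[list[FoldPrediction], dict]:
    """Confidence filtering of self-predicted structures.

    Retains predictions whose aggregate pLDDT is >= threshold and
    reports how many were kept/removed.
    """
    records = [p.plddt for p in predictions]
    kept_records = set(id(r) for r in filter_by_plddt(records, threshold))
    retained = [p for p in predictions if id(p.plddt) in kept_records]
    report = {"total": len(predictions), "retained": len(retained),
              "removed": len(predictions) - len(retained),
              "threshold": threshold}
    return retained, report
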