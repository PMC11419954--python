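"""Foreignness scoring of wild-type / mutant peptide pairs.

A mutant peptide's foreignness — how different it looks to the immune
system from its self counterpart — is scored from three comparison
blocks applied to the WT/Mut pair: (1) TCR-exposed outer-surface
feature grids compared through a quadruple-linear difference map
w[x; y; x⊙y − 1; |x−y|]; (2) the cross spatial distance matrix between
the two structures in a common HLA frame; (3) position-wise residue
("atom group") embeddings broadcast into position x position product
and absolute-difference maps. Each block feeds a small shared-weight
grid CNN and dense net; a projection block fuses the three outputs into
a sigmoid score in [0, 1], trained with an L2 loss against binary
immunogenicity labels.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import autodiff as ad
from . import chemdata, groove, surface
from .autodiff import Parameter, Tensor
from .metrics import auroc, kabsch_superpose
from .structure import PHLAComplex, pad_peptide

BLOCK_NAMES = ("surface", "structure", "atom_group")


class PepForeError(ValueError):
    pass


class EmptySurfaceError(PepForeError):
    pass


@dataclasses.dataclass
class WTMutPair:
    """A mutant peptide, its wild-type counterpart, and the label."""

    mut_seq: str
    wt_seq: str
    allele: str
    label: int
    mut_structure: PHLAComplex | None = None
    wt_structure: PHLAComplex | None = None
    mismatches: int | None = None

    def __post_init__(self):
        if len(self.mut_seq) != len(self.wt_seq):
            raise PepForeError("WT and Mut sequences must have equal length")
        count = sum(a != b for a, b in zip(self.mut_seq, self.wt_seq))
        if self.mismatches is None:
            self.mismatches = count
        if self.mismatches < 1:
            raise PepForeError("a WT/Mut pair must differ somewhere")


@dataclasses.dataclass
class PatchDescriptor:
    vector: np.ndarray
    patch_id: int


@dataclasses.dataclass
class ForeignnessResult:
    score: float
    block_contributions: dict[str, np.ndarray]


@dataclasses.dataclass
class PepForeConfig:
    """Widths of the comparison blocks (all unspecified upstream; these
    are the package defaults) plus the ablation set."""

    descriptor_dim: int = 16
    conv_channels: int = 8
    hidden: int = 32
    grid_r: int = 5
    grid_a: int = 16
    embed_dim: int = 8
    seq_len: int = 16
    n_patches: int = 8
    seed: int = 0
    pooling: str = "mean"  # or "max"
    product_inverse: bool = False  # read (x*y)^-1 instead of x*y - 1
    ablated: frozenset = frozenset()

    def with_ablation(self, *blocks: str) -> "PepForeConfig":
        return dataclasses.replace(self, ablated=self.ablated | set(blocks))


def ablate(config: PepForeConfig, block_name: str) -> PepForeConfig:
    """Zero the named block's output at fusion."""
    if block_name not in BLOCK_NAMES:
        raise PepForeError(f"unknown block {block_name!r}; choose from {BLOCK_NAMES}")
    return config.with_ablation(block_name)


def split_by_mismatch(pairs: Sequence[WTMutPair]
                      ) -> tuple[list[WTMutPair], list[WTMutPair]]:
    """Precise/rough validation splits: exactly-one-mismatch pairs, and
    one-or-two-mismatch pairs (a superset of the first)."""
    set1 = [p for p in pairs if p.mismatches == 1]
    set2 = [p for p in pairs if p.mismatches in (1, 2)]
    return set1, set2


# ---------------------------------------------------------------------
# featureization
# ---------------------------------------------------------------------

@dataclasses.dataclass
class PairFeatures:
    """Precomputed model inputs for one WT/Mut pair."""

    mut_grids: np.ndarray    # (n_patches, C, R, A)
    wt_grids: np.ndarray
    structure_matrix: np.ndarray  # (seq_len, seq_len)
    mut_tokens: np.ndarray   # (seq_len,) int
    wt_tokens: np.ndarray
    label: int


_TOKENS = chemdata.AMINO_ACIDS + chemdata.PAD_TOKEN
_TOKEN_INDEX = {t: i for i, t in enumerate(_TOKENS)}


def _tokens(seq: str, seq_len: int) -> np.ndarray:
    padded = pad_peptide(seq)
    ids = [_TOKEN_INDEX[t] for t in padded.tokens]
    return np.array(ids[:seq_len])


def peptide_surface_grids(cplx: PHLAComplex, config: PepForeConfig,
                          resolution: float = 1.0) -> np.ndarray:
    """Outer-surface patch grids for one peptide, shape (n_patches, C, R, A).

    Builds the peptide surface, computes the six per-vertex channels,
    masks to the TCR-exposed outer surface via the groove plane, and
    grids ``n_patches`` evenly chosen outer patches. Channels:
    shape_index, ddc, hydropathy, electrostatics, hbond, phla_distance,
    plus the bin-occupancy mask.
    """
    mesh = surface.build_surface(cplx.peptide, resolution=resolution,
                                 regularize_mesh=False)
    surface.principal_curvatures(mesh)
    surface.geometric_features(mesh)
    surface.chemical_features(mesh, cplx.peptide)
    plane = groove.plane_from_anchors(cplx.hla, cplx.peptide)
    dist = groove.vertex_plane_distance(mesh, plane)
    mask = groove.outer_surface_mask(dist)
    outer = np.where(mask)[0]
    if len(outer) == 0:
        raise EmptySurfaceError("no TCR-exposed surface above the groove plane")
    pick = outer[np.linspace(0, len(outer) - 1, config.n_patches).astype(int)]
    patches = surface.decompose_patches(mesh, centers=pick, seed=config.seed)
    # normalize the plane-distance channel to [-1, 1]
    span = max(np.abs(dist).max(), 1e-9)
    feats = dict(mesh.features)
    feats["phla_distance"] = dist / span
    feats["shape_index"] = np.nan_to_num(feats["shape_index"])
    grids = []
    normals = mesh.vertex_normals()
    for patch in patches:
        ddc = np.zeros(mesh.n_vertices)
        others = patch.members[patch.members != patch.center]
        if len(others):
            ddc[others] = surface.distance_dependent_curvature(
                mesh.vertices[patch.center], normals[patch.center],
                mesh.vertices[others], normals[others])
        feats["ddc"] = np.clip(ddc, -1.0, 1.0)
        g = surface.map_patch_to_grid(patch, {k: feats[k] for k in
                                              groove.OUTER_SURFACE_CHANNELS},
                                      R=config.grid_r, A=config.grid_a)
        order = list(groove.OUTER_SURFACE_CHANNELS) + ["occupancy"]
        grids.append(np.stack([g[k] for k in order]))
    return np.stack(grids)


def structure_distance_matrix(mut: PHLAComplex, wt: PHLAComplex,
                              seq_len: int = 16) -> np.ndarray:
    """Cross distance matrix M[i, j] = |centroid_i(Mut) - centroid_j(WT)|.

    Residue centroids are compared in a common HLA frame: when the two
    complexes do not share a template, the mutant HLA is superposed on
    the wild-type HLA by a Cα Kabsch fit first. Padded to seq_len.
    """
    if len(mut.peptide) != len(wt.peptide):
        raise PepForeError("substitution pairs must have equal residue counts")
    mut_pep = mut.peptide
    hla_m, hla_w = mut.hla.ca_coords(), wt.hla.ca_coords()
    if hla_m.shape == hla_w.shape and not np.allclose(hla_m, hla_w, atol=1e-6):
        sup = kabsch_superpose(hla_m, hla_w)
        mut_pep = mut_pep.transformed(sup.rotation, sup.translation)
    cm = np.array([np.mean([a.coords for a in r], axis=0)
                   for r in mut_pep.residues])
    cw = np.array([np.mean([a.coords for a in r], axis=0)
                   for r in wt.peptide.residues])
    L = len(cm)
    M = np.zeros((seq_len, seq_len))
    M[:L, :L] = np.linalg.norm(cm[:, None] - cw[None], axis=-1)
    return M


def featurize_pair(pair: WTMutPair, config: PepForeConfig,
                   resolution: float = 1.0) -> PairFeatures:
    if pair.mut_structure is None or pair.wt_structure is None:
        raise PepForeError("pair lacks structures; run the fold step first")
    return PairFeatures(
        mut_grids=peptide_surface_grids(pair.mut_structure, config, resolution),
        wt_grids=peptide_surface_grids(pair.wt_structure, config, resolution),
        structure_matrix=structure_distance_matrix(pair.mut_structure,
                                                   pair.wt_structure,
                                                   config.seq_len),
        mut_tokens=_tokens(pair.mut_seq, config.seq_len),
        wt_tokens=_tokens(pair.wt_seq, config.seq_len),
        label=pair.label,
    )


# ---------------------------------------------------------------------
# model
# ---------------------------------------------------------------------

def qualinear_difference(x: Tensor | np.ndarray, y: Tensor | np.ndarray,
                         w: Tensor | np.ndarray,
                         product_inverse: bool = False) -> Tensor:
    """Quadruple-linear difference w @ [x; y; x⊙y − 1; |x − y|].

    The third part is elementwise product minus the scalar one;
    ``product_inverse`` switches to the elementwise inverse
    (x⊙y)^(-1) reading for sensitivity analysis. Works on batched
    (..., n) inputs with w of shape (out, 4n).
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    y = y if isinstance(y, Tensor) else Tensor(y)
    w = w if isinstance(w, Tensor) else Tensor(w)
    if x.shape != y.shape:
        raise PepForeError("qualinear inputs must have equal shape")
    if product_inverse:
        third = (x * y + 1e-6) ** -1.0
    else:
        third = x * y - 1.0
    parts = ad.concat([x, y, third, (x - y).abs()], axis=-1)
    return parts @ w.transpose() if w.ndim == 2 else parts @ w


def qualinear_parts(x: np.ndarray, y: np.ndarray,
                    product_inverse: bool = False) -> np.ndarray:
    """The raw 4-part concatenation (no weights); used for algebra checks."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    third = 1.0 / (x * y + 1e-6) if product_inverse else x * y - 1.0
    return np.concatenate([x, y, third, np.abs(x - y)], axis=-1)


def broadcast_maps(e_w: Tensor, e_m: Tensor) -> Tensor:
    """Position x position channel maps Concat(B(e_w ⊙ e_m), |B(e_w − e_m)|).

    B broadcasts a per-position vector u (L, d) into an (L, L, d) map
    B(u)[i, j] = u[i] + u[j]; the product and absolute-difference maps
    are concatenated along the channel axis, giving (2d, L, L). For
    identical sequences the difference half is exactly zero, and a
    single substitution at position k is supported only on row/column k.
    Batched (B, L, d) inputs give (B, 2d, L, L).
    """
    batched = e_w.ndim == 3
    if not batched:
        e_w = e_w.reshape(1, *e_w.shape)
        e_m = e_m.reshape(1, *e_m.shape)
    Bn, L, d = e_w.shape
    u = e_w * e_m
    v = e_w - e_m
    bu = u.reshape(Bn, L, 1, d) + u.reshape(Bn, 1, L, d)
    bv = (v.reshape(Bn, L, 1, d) + v.reshape(Bn, 1, L, d)).abs()
    maps = ad.concat([bu, bv], axis=-1).transpose(0, 3, 1, 2)
    return maps if batched else maps[0]


class PepForeModel:
    """Three comparison blocks, shared-weight grid CNNs, and a projection
    head producing the foreignness score."""

    def __init__(self, config: PepForeConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        cc, dd, hh = config.conv_channels, config.descriptor_dim, config.hidden
        n_ch = len(groove.OUTER_SURFACE_CHANNELS) + 1

        def W(*shape, scale=None):
            scale = scale if scale is not None else 1.0 / np.sqrt(np.prod(shape[1:]))
            return Parameter(rng.standard_normal(shape) * scale)

        def Z(*shape):
            return Parameter(np.zeros(shape))

        self.params = {
            "surf": {"conv_w": W(cc, n_ch, 3, 3), "conv_b": Z(cc),
                     "proj": W(dd, cc), "qua": W(dd, 4 * dd),
                     "fc": W(dd, dd), "fc_b": Z(dd)},
            "struct": {"conv_w": W(cc, 1, 3, 3), "conv_b": Z(cc),
                       "proj": W(dd, cc), "fc": W(dd, dd), "fc_b": Z(dd)},
            "atom": {"embed": W(21, config.embed_dim, scale=0.5),
                     "conv_w": W(cc, 2 * config.embed_dim, 3, 3), "conv_b": Z(cc),
                     "proj": W(dd, cc), "fc": W(dd, dd), "fc_b": Z(dd)},
            "proj1": W(hh, 3 * dd), "proj1_b": Z(hh),
            "proj2": W(1, hh), "proj2_b": Z(1),
        }

    def parameters(self) -> list[Parameter]:
        return ad.parameters_of(self.params)

    # -- blocks (batched: leading axis = pairs) --------------------------
    def _grid_descriptor(self, grids: Tensor, p: dict) -> Tensor:
        """(B, C, H, W) grids -> (B, descriptor_dim) via conv + pool."""
        h = ad.conv2d(grids, p["conv_w"], p["conv_b"], padding=1).tanh()
        pooled = h.mean(axis=(2, 3))
        return (pooled @ p["proj"].transpose()).tanh()

    def surface_block(self, mut_grids: np.ndarray, wt_grids: np.ndarray) -> Tensor:
        """Shared-weight grid CNN per patch, pooled to one descriptor per
        peptide, compared by the quadruple-linear difference, then a
        dense layer. Accepts (P, C, R, A) or batched (B, P, C, R, A)."""
        mut_grids = np.asarray(mut_grids, dtype=float)
        wt_grids = np.asarray(wt_grids, dtype=float)
        batched = mut_grids.ndim == 5
        if not batched:
            mut_grids = mut_grids[None]
            wt_grids = wt_grids[None]
        if mut_grids.shape[1] == 0 or wt_grids.shape[1] == 0:
            raise EmptySurfaceError("no outer-surface patches on one side")
        p = self.params["surf"]
        Bn, P = mut_grids.shape[:2]
        dm = self._pool(self._grid_descriptor(
            Tensor(mut_grids.reshape(Bn * P, *mut_grids.shape[2:])), p
        ).reshape(Bn, P, self.config.descriptor_dim))
        dw = self._pool(self._grid_descriptor(
            Tensor(wt_grids.reshape(Bn * P, *wt_grids.shape[2:])), p
        ).reshape(Bn, P, self.config.descriptor_dim))
        q = qualinear_difference(dm, dw, p["qua"],
                                 product_inverse=self.config.product_inverse)
        out = (q @ p["fc"].transpose() + p["fc_b"]).tanh()
        return out if batched else out[0]

    def _pool(self, descs: Tensor) -> Tensor:
        """Pool per-patch descriptors (B, P, d) to per-peptide (B, d)."""
        if self.config.pooling == "max":
            idx = descs.data.sum(axis=2).argmax(axis=1)
            rows = np.arange(descs.shape[0])
            return descs[(rows, idx)]
        return descs.mean(axis=1)

    def structure_block(self, M: np.ndarray) -> Tensor:
        M = np.asarray(M, dtype=float)
        batched = M.ndim == 3
        if not batched:
            M = M[None]
        p = self.params["struct"]
        g = Tensor(M[:, None] * 0.1)
        d = self._grid_descriptor(g, p)
        out = (d @ p["fc"].transpose() + p["fc_b"]).tanh()
        return out if batched else out[0]

    def atom_group_block(self, mut_tokens: np.ndarray,
                         wt_tokens: np.ndarray) -> Tensor:
        mut_tokens = np.asarray(mut_tokens)
        wt_tokens = np.asarray(wt_tokens)
        batched = mut_tokens.ndim == 2
        if not batched:
            mut_tokens = mut_tokens[None]
            wt_tokens = wt_tokens[None]
        p = self.params["atom"]
        e_m = p["embed"][mut_tokens]
        e_w = p["embed"][wt_tokens]
        maps = broadcast_maps(e_w, e_m)
        d = self._grid_descriptor(maps, p)
        out = (d @ p["fc"].transpose() + p["fc_b"]).tanh()
        return out if batched else out[0]

    # -- fusion ----------------------------------------------------------
    def block_outputs(self, feats: "PairFeatures | Sequence[PairFeatures]"
                      ) -> dict[str, Tensor]:
        single = isinstance(feats, PairFeatures)
        batch = [feats] if single else list(feats)
        dd = self.config.descriptor_dim
        Bn = len(batch)
        zeros = Tensor(np.zeros((Bn, dd)))
        out = {}
        out["surface"] = (zeros if "surface" in self.config.ablated
                          else self.surface_block(
                              np.stack([f.mut_grids for f in batch]),
                              np.stack([f.wt_grids for f in batch])))
        out["structure"] = (zeros if "structure" in self.config.ablated
                            else self.structure_block(
                                np.stack([f.structure_matrix for f in batch])))
        out["atom_group"] = (zeros if "atom_group" in self.config.ablated
                             else self.atom_group_block(
                                 np.stack([f.mut_tokens for f in batch]),
                                 np.stack([f.wt_tokens for f in batch])))
        if single:
            out = {k: v[0] for k, v in out.items()}
        return out

    def project_and_score(self, blocks: dict[str, Tensor]) -> Tensor:
        missing = set(BLOCK_NAMES) - set(blocks)
        if missing:
            raise PepForeError(f"missing block outputs: {sorted(missing)}")
        z = ad.concat([blocks[b] for b in BLOCK_NAMES], axis=-1)
        h = (z @ self.params["proj1"].transpose() + self.params["proj1_b"]).tanh()
        s = h @ self.params["proj2"].transpose() + self.params["proj2_b"]
        return s.sigmoid()

    def score_batch(self, feats: Sequence[PairFeatures]) -> Tensor:
        """Scores for a batch of pairs, shape (B,)."""
        s = self.project_and_score(self.block_outputs(list(feats)))
        return s.reshape(len(feats))

    def score(self, feats: PairFeatures) -> ForeignnessResult:
        blocks = self.block_outputs(feats)
        s = self.project_and_score(blocks)
        return ForeignnessResult(
            score=float(s.data.reshape(())),
            block_contributions={k: v.data.copy() for k, v in blocks.items()})


def predict(model: PepForeModel, features: Sequence[PairFeatures]) -> np.ndarray:
    return model.score_batch(list(features)).data.copy()


def train_pepfore(features: Sequence[PairFeatures], config: PepForeConfig,
                  steps: int = 300, seed: int | None = None,
                  lr: float = 1e-2, batch_size: int = 32,
                  ) -> tuple[PepForeModel, list[float]]:
    """L2 training of the foreignness score against binary labels."""
    labels = np.array([f.label for f in features])
    if len(np.unique(labels)) < 2:
        raise PepForeError("training data must contain both classes")
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    model = PepForeModel(config)
    params = model.parameters()
    opt = ad.Adam(params, lr=lr)
    rng = np.random.default_rng(config.seed + 1)
    curve: list[float] = []
    n = len(features)
    for _ in range(steps):
        idx = rng.choice(n, size=min(batch_size, n), replace=False)
        opt.zero_grad()
        s = model.score_batch([features[i] for i in idx])
        loss = ((s - Tensor(labels[idx].astype(float))) ** 2.0).mean()
        loss.backward()
        if lr > 0:
            opt.step()
        curve.append(float(loss.data))
    return model, curve


def heldout_auroc(model: PepForeModel, features: Sequence[PairFeatures]) -> float:
    scores = predict(model, features)
    labels = [f.label for f in features]
    return auroc(scores, labels)
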