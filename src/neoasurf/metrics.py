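"""Structural comparison metrics and evaluation statistics.

Kabsch superposition RMSD, TM-score for short peptides, superposition-free
lDDT, pLDDT aggregation and confidence filtering, per-residue
peptide–HLA interaction strength, Pearson correlation, and AUROC/AUPRC.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy import stats as _scipy_stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .structure import PHLAComplex

PLDDT_THRESHOLD = 92.0
INTERACTION_DISTANCE_FLOOR = 0.1  # Angstrom; avoids infinities on clashes


class MetricError(ValueError):
    pass


@dataclasses.dataclass
class SuperpositionResult:
    """Optimal rigid-body superposition of paired point sets."""

    rotation: np.ndarray   # 3x3 proper orthonormal
    translation: np.ndarray
    rmsd: float

    def apply(self, P: np.ndarray) -> np.ndarray:
        return P @ self.rotation.T + self.translation


@dataclasses.dataclass
class InteractionProfile:
    """Per-peptide-residue interaction strength, in inverse square Angstrom."""

    per_residue_strength: np.ndarray


@dataclasses.dataclass
class PLDDTRecord:
    """Per-residue predicted lDDT in [0, 100] with its unweighted mean."""

    per_residue: np.ndarray
    name: str | None = None

    def __post_init__(self):
        self.per_residue = np.asarray(self.per_residue, dtype=float)
        if self.per_residue.size and (
                self.per_residue.min() < 0 or self.per_residue.max() > 100):
            raise MetricError("pLDDT values must lie in [0, 100]")

    @property
    def aggregate(self) -> float:
        return float(self.per_residue.mean())


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of P onto Q (paired points).

    Returns the proper rotation R and translation t minimizing
    ||P @ R.T + t - Q||, and the RMSD after the transform.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise MetricError(f"paired Nx3 arrays required, got {P.shape} vs {Q.shape}")
    if len(P) < 3:
        raise MetricError("need at least 3 points for a unique superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    diff = P @ R.T + t - Q
    rmsd = float(np.sqrt((diff ** 2).sum(axis=1).mean()))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def tm_d0(L: int, floor: float = 0.5) -> float:
    """Zhang–Skolnick length normalization with a floor for short peptides."""
    if L > 15:
        d0 = 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8
    else:
        d0 = floor
    return max(d0, floor)


def _tm_sum(P: np.ndarray, Q: np.ndarray, d0: float) -> float:
    d = np.linalg.norm(P - Q, axis=1)
    return float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))


def tm_score(P: np.ndarray, Q: np.ndarray, *, min_fragment: int = 4) -> float:
    """TM-score of model Cα trace P against reference Q.

    The superposition maximizing the score is searched by seeding from
    every contiguous fragment of length >= ``min_fragment`` plus the
    global Kabsch fit, each refined by iteratively re-superposing on the
    best-scoring residue subset until convergence.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise MetricError("model/reference length mismatch")
    L = len(P)
    if L == 0:
        raise MetricError("empty structures")
    d0 = tm_d0(L)
    if L < 3:
        # too short for a unique fit; superpose by centroid only
        Pc = P - P.mean(axis=0) + Q.mean(axis=0)
        return _tm_sum(Pc, Q, d0)

    seeds = [np.arange(L)]
    for flen in range(min_fragment, L + 1):
        for start in range(0, L - flen + 1):
            seeds.append(np.arange(start, start + flen))
    best = 0.0
    for idx in seeds:
        if len(idx) < 3:
            continue
        sel = idx
        for _ in range(20):
            sup = kabsch_superpose(P[sel], Q[sel])
            Pt = sup.apply(P)
            score = _tm_sum(Pt, Q, d0)
            best = max(best, score)
            d = np.linalg.norm(Pt - Q, axis=1)
            cutoff = max(d0, np.median(d))
            new_sel = np.where(d <= cutoff)[0]
            if len(new_sel) < 3 or np.array_equal(new_sel, sel):
                break
            sel = new_sel
    return min(best, 1.0)


def lddt(model: Sequence[np.ndarray], reference: Sequence[np.ndarray],
         cutoff: float = 15.0,
         thresholds: Sequence[float] = (0.5, 1.0, 2.0, 4.0)) -> np.ndarray:
    """Per-residue local distance difference test, in [0, 100].

    ``model``/``reference`` are paired sequences of per-residue atom
    coordinate arrays. The score is superposition-free: for every
    inter-residue atom pair within ``cutoff`` in the reference, the
    fraction whose distance is preserved within each threshold is
    averaged over thresholds and scaled to 100.
    """
    if len(model) != len(reference):
        raise MetricError("model/reference residue count mismatch")
    if len(model) < 2:
        raise MetricError("lDDT undefined for fewer than 2 residues")
    m = np.vstack([np.atleast_2d(a) for a in model]).astype(float)
    r = np.vstack([np.atleast_2d(a) for a in reference]).astype(float)
    if m.shape != r.shape:
        raise MetricError("paired atoms required")
    res_id = np.concatenate([np.full(len(np.atleast_2d(a)), i)
                             for i, a in enumerate(reference)])
    dr = np.linalg.norm(r[:, None] - r[None, :], axis=-1)
    dm = np.linalg.norm(m[:, None] - m[None, :], axis=-1)
    mask = (dr < cutoff) & (res_id[:, None] != res_id[None, :])
    delta = np.abs(dm - dr)
    frac = np.zeros_like(dr)
    for t in thresholds:
        frac += (delta < t).astype(float)
    frac /= len(thresholds)
    n_res = len(model)
    out = np.zeros(n_res)
    for i in range(n_res):
        rows = res_id == i
        pair_mask = mask[rows]
        n_pairs = pair_mask.sum()
        out[i] = 100.0 * frac[rows][pair_mask].sum() / n_pairs if n_pairs else 0.0
    return out


def filter_by_plddt(records: Sequence[PLDDTRecord],
                    threshold: float = PLDDT_THRESHOLD) -> list[PLDDTRecord]:
    """Retain records whose aggregate pLDDT is >= threshold (order kept).

    The boundary is inclusive: only strictly low-confidence predictions
    (aggregate < threshold) are removed.
    """
    return [r for r in records if r.aggregate >= threshold]


def interaction_strength(cplx: PHLAComplex) -> InteractionProfile:
    """Per-peptide-residue interaction strength 1/d^2.

    d is the minimum distance between any atom of the peptide residue
    and any HLA atom, floored at 0.1 A to keep clashed synthetic input
    finite (a warning is emitted when the floor engages).
    """
    hla_xyz = cplx.hla.atom_coords()
    if hla_xyz.size == 0 or len(cplx.peptide) == 0:
        raise MetricError("both chains must be non-empty")
    strengths = []
    for res in cplx.peptide.residues:
        xyz = np.array([a.coords for a in res])
        d = np.linalg.norm(xyz[:, None] - hla_xyz[None, :], axis=-1).min()
        if d < INTERACTION_DISTANCE_FLOOR:
            warnings.warn(f"clash at peptide residue {res[0].residue_index}: "
                          f"min distance {d:.3f} A floored")
            d = INTERACTION_DISTANCE_FLOOR
        strengths.append(1.0 / d ** 2)
    return InteractionProfile(per_residue_strength=np.array(strengths))


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise MetricError("both classes must be present")


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUROC; ties receive half credit (Mann–Whitney)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision–recall curve by step-wise integration."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(average_precision_score(labels, scores))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise MetricError("need paired samples, n >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise MetricError("zero variance input")
    return float(_scipy_stats.pearsonr(x, y).statistic)
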