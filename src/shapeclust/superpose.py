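"""Structural superposition: Kabsch fitting, TM-score, and an iterative aligner.

The TM-score of an alignment with residue-pair distances d_i against a target
of length L is

    TM = (1/L) * sum_i 1 / (1 + (d_i / d0(L))^2),   d0(L) = 1.24 (L-15)^(1/3) - 1.8

with d0 clamped below at 0.5 A (the raw formula is negative for L <= 18).
``tm_align`` is a simplified re-implementation of the classic heuristic: three
seed alignments (best gapless threading, secondary-structure dynamic
programming, and their equally weighted combination) are each refined by
alternating Kabsch superposition on the current residue pairs with a dynamic
programming pass over the TM score matrix, keeping the best-scoring alignment
seen. The score is asymmetric in the choice of target; both normalizations are
reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .pdb_io import ProteinModel

__all__ = [
    "ResidueAlignment",
    "SuperpositionResult",
    "kabsch",
    "d0",
    "tm_score",
    "assign_secondary_structure",
    "dp_align",
    "tm_align",
]

DEFAULT_GAP_PENALTY = -0.6

#: C-alpha pseudo-geometry windows (Angstrom) used for secondary structure.
#: d_k is the CA(i)-CA(i+k) distance. Helix requires all three windows;
#: strand requires an extended i,i+2 / i,i+3 pattern.
SS_THRESHOLDS = {
    "helix_d2": (4.8, 6.2),
    "helix_d3": (4.2, 5.8),
    "helix_d4": (5.2, 7.2),
    "strand_d2_min": 6.3,
    "strand_d3_min": 9.0,
}


@dataclass
class ResidueAlignment:
    """Aligned residue index pairs, strictly increasing in both coordinates."""

    pairs: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def validate(self) -> None:
        last_a, last_b = -1, -1
        for ia, ib in self.pairs:
            if ia <= last_a or ib <= last_b:
                raise ValueError("alignment pairs are not strictly increasing")
            last_a, last_b = ia, ib


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det +1; maps the second structure onto the first
    translation: np.ndarray  # 3-vector (A)
    rmsd: float
    tm_score_ab: float | None = None  # normalized by the second model's length
    tm_score_ba: float | None = None  # normalized by the first model's length
    alignment: ResidueAlignment | None = None

    def validate(self) -> None:
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation is not proper (det != +1)")
        if self.rmsd < 0:
            raise ValueError("negative rmsd")


def kabsch(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Optimal rigid superposition of P onto Q (minimizing RMSD).

    Returns rotation R and translation t with R @ P[i] + t matching Q[i] in the
    least-squares sense. Reflections are excluded (det R = +1).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"point sets must both be n x 3, got {P.shape} and {Q.shape}")
    n = len(P)
    if n < 3:
        raise ValueError(f"need at least 3 point pairs, got {n}")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    Pc = P - cp
    Qc = Q - cq
    sv = np.linalg.svd(Pc, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        warnings.warn("points are (nearly) collinear; rotation is ill-determined")
    rot, _ = Rotation.align_vectors(Qc, Pc)
    R = rot.as_matrix()
    t = cq - R @ cp
    diffs = (Pc @ R.T) - Qc
    rmsd = float(np.sqrt(np.mean(np.sum(diffs**2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def d0(l_target: int) -> float:
    """TM-score distance scale for a target of ``l_target`` residues (A)."""
    if l_target < 1:
        raise ValueError("target length must be >= 1")
    raw = 1.24 * np.cbrt(l_target - 15.0) - 1.8
    return float(max(raw, 0.5))


def tm_score(distances, l_target: int) -> float:
    """TM-score of aligned residue-pair distances against a target length."""
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        warnings.warn("empty alignment: TM-score is 0")
        return 0.0
    if l_target < distances.size:
        raise ValueError("target length shorter than the alignment")
    scale = d0(l_target)
    return float(np.sum(1.0 / (1.0 + (distances / scale) ** 2)) / l_target)


def _chain_ca_coords(model: ProteinModel):
    """Residue keys and C-alpha coordinates, chain by chain, in file order."""
    keys, coords = [], []
    for chain_id, res in model.iter_residues():
        for atom in res.atoms:
            if atom.name == "CA":
                keys.append((chain_id, res.number))
                coords.append(atom.coord)
                break
    return keys, np.array(coords, dtype=float) if coords else np.empty((0, 3))


def assign_secondary_structure(model: ProteinModel,
                               thresholds: dict | None = None) -> list[str]:
    """Per-residue H/E/C labels from C-alpha pseudo-geometry.

    Labels follow residue order over all chains; residues without a C-alpha,
    and termini lacking the i..i+4 window, are labelled C.
    """
    th = dict(SS_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    labels = []
    for chain in model.chains:
        ca = []
        has_ca = []
        for res in chain.residues:
            atom = next((a for a in res.atoms if a.name == "CA"), None)
            has_ca.append(atom is not None)
            if atom is not None:
                ca.append(atom.coord)
        ca = np.array(ca) if ca else np.empty((0, 3))
        n = len(ca)
        chain_labels = ["C"] * n
        for i in range(n - 4):
            d2 = np.linalg.norm(ca[i] - ca[i + 2])
            d3 = np.linalg.norm(ca[i] - ca[i + 3])
            d4 = np.linalg.norm(ca[i] - ca[i + 4])
            if (th["helix_d2"][0] <= d2 <= th["helix_d2"][1]
                    and th["helix_d3"][0] <= d3 <= th["helix_d3"][1]
                    and th["helix_d4"][0] <= d4 <= th["helix_d4"][1]):
                chain_labels[i] = "H"
            elif d2 >= th["strand_d2_min"] and d3 >= th["strand_d3_min"]:
                chain_labels[i] = "E"
        it = iter(chain_labels)
        for flag in has_ca:
            labels.append(next(it) if flag else "C")
    return labels


@njit(cache=False)
def _nw_fill(S, gap):  # pragma: no cover - exercised via dp_align
    n, m = S.shape
    H = np.zeros((n + 1, m + 1))
    P = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    for i in range(1, n + 1):
        H[i, 0] = i * gap
        P[i, 0] = 1
    for j in range(1, m + 1):
        H[0, j] = j * gap
        P[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            up = H[i - 1, j] + gap
            left = H[i, j - 1] + gap
            if diag >= up and diag >= left:
                H[i, j] = diag
                P[i, j] = 0
            elif up >= left:
                H[i, j] = up
                P[i, j] = 1
            else:
                H[i, j] = left
                P[i, j] = 2
    return H, P


def dp_align(score_matrix: np.ndarray,
             gap_open: float = DEFAULT_GAP_PENALTY) -> ResidueAlignment:
    """Global alignment maximizing total score with a linear gap penalty.

    Ties are broken deterministically: diagonal over up over left.
    """
    S = np.ascontiguousarray(score_matrix, dtype=np.float64)
    if S.ndim != 2 or S.size == 0:
        raise ValueError("score matrix must be a non-empty 2D array")
    if not np.all(np.isfinite(S)):
        raise ValueError("score matrix has non-finite entries")
    _, P = _nw_fill(S, float(gap_open))
    pairs = []
    i, j = S.shape
    while i > 0 or j > 0:
        move = P[i, j]
        if move == 0:
            i -= 1
            j -= 1
            pairs.append((i, j))
        elif move == 1:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    aln = ResidueAlignment(pairs)
    aln.validate()
    return aln


def _score_matrix(dmat: np.ndarray, scale: float) -> np.ndarray:
    return 1.0 / (1.0 + (dmat / scale) ** 2)


def _pairs_tm(ca_a, ca_b, pairs, l_target):
    """Kabsch on the pairs, then TM-score of the paired distances."""
    ia = [p[0] for p in pairs]
    ib = [p[1] for p in pairs]
    sup = kabsch(ca_b[ib], ca_a[ia])
    moved = ca_b @ sup.rotation.T + sup.translation
    dists = np.linalg.norm(moved[ib] - ca_a[ia], axis=1)
    return tm_score(dists, l_target), sup, moved, dists


def _best_gapless(ca_a, ca_b, l_target, min_overlap=5):
    """Best gapless threading of B along A by TM-score."""
    la, lb = len(ca_a), len(ca_b)
    best = (-1.0, None)
    for offset in range(-(la - min_overlap), lb - min_overlap + 1):
        ia0 = max(0, -offset)
        ib0 = ia0 + offset
        length = min(la - ia0, lb - ib0)
        if length < min_overlap:
            continue
        pairs = [(ia0 + t, ib0 + t) for t in range(length)]
        tm, _, _, _ = _pairs_tm(ca_a, ca_b, pairs, l_target)
        if tm > best[0]:
            best = (tm, pairs)
    return best[1]


def tm_align(model_a: ProteinModel, model_b: ProteinModel,
             gap_open: float = DEFAULT_GAP_PENALTY,
             max_iter: int = 30) -> SuperpositionResult:
    """Iterative structural alignment of two models.

    Returns the best alignment found over the three seeds; the rotation and
    translation map ``model_b`` coordinates into ``model_a``'s frame.
    ``tm_score_ab`` treats B as the target (normalizes by len(B)),
    ``tm_score_ba`` treats A as the target.
    """
    keys_a, ca_a = _chain_ca_coords(model_a)
    keys_b, ca_b = _chain_ca_coords(model_b)
    la, lb = len(ca_a), len(ca_b)
    if la < 5 or lb < 5:
        raise ValueError("both models need at least 5 C-alpha atoms")
    scale_b = d0(lb)

    seeds: list[list[tuple[int, int]]] = []
    gapless = _best_gapless(ca_a, ca_b, lb)
    if gapless:
        seeds.append(gapless)
    ss_a = _ss_for_cas(model_a)
    ss_b = _ss_for_cas(model_b)
    ss_matrix = (np.array(ss_a)[:, None] == np.array(ss_b)[None, :]).astype(float)
    ss_seed = dp_align(ss_matrix, gap_open).pairs
    if len(ss_seed) >= 3:
        seeds.append(ss_seed)
    if gapless:
        # Equally weighted combination of the gapless geometry and the
        # secondary-structure agreement.
        _, _, moved, _ = _pairs_tm(ca_a, ca_b, gapless, lb)
        dmat = cdist(ca_a, moved)
        combo = 0.5 * ss_matrix + 0.5 * _score_matrix(dmat, scale_b)
        combo_seed = dp_align(combo, gap_open).pairs
        if len(combo_seed) >= 3:
            seeds.append(combo_seed)
    if not seeds:
        raise ValueError("no usable seed alignment")

    best_tm = -1.0
    best_pairs = None
    best_sup = None
    for seed in seeds:
        pairs = seed
        for _ in range(max_iter):
            if len(pairs) < 3:
                break
            tm, sup, moved, _ = _pairs_tm(ca_a, ca_b, pairs, lb)
            if tm > best_tm:
                best_tm, best_pairs, best_sup = tm, pairs, sup
            dmat = cdist(ca_a, moved)
            new_pairs = dp_align(_score_matrix(dmat, scale_b), gap_open).pairs
            if new_pairs == pairs:
                break
            pairs = new_pairs

    ia = [p[0] for p in best_pairs]
    ib = [p[1] for p in best_pairs]
    moved = ca_b @ best_sup.rotation.T + best_sup.translation
    dists = np.linalg.norm(moved[ib] - ca_a[ia], axis=1)
    result = SuperpositionResult(
        rotation=best_sup.rotation,
        translation=best_sup.translation,
        rmsd=float(np.sqrt(np.mean(dists**2))),
        tm_score_ab=tm_score(dists, lb),
        tm_score_ba=tm_score(dists, la),
        alignment=ResidueAlignment(list(best_pairs)),
    )
    result.validate()
    return result


def _ss_for_cas(model: ProteinModel) -> list[str]:
    """Secondary-structure labels restricted to residues that have a C-alpha."""
    labels = assign_secondary_structure(model)
    out = []
    idx = 0
    for _, res in model.iter_residues():
        has_ca = any(a.name == "CA" for a in res.atoms)
        if has_ca:
            out.append(labels[idx])
        idx += 1
    return out
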