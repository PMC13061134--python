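"""Backbone frames and oracle aligned-error scores.

When a structure-prediction network reports a predicted aligned error
(PAE), the quantity it estimates is the error in the C-alpha position of
residue ``j`` when prediction and truth are superposed on the backbone
frame of residue ``i``.  Given both the predicted and the experimental
structure of the same (cropped) sequence, that quantity can be computed
exactly: the *aligned error* matrix

    e_ij = || T_Xi^-1 . x_j  -  T_Yi^-1 . y_j ||

where ``T_Xi`` / ``T_Yi`` are the backbone frames of residue ``i`` in query
and reference and ``x_j`` / ``y_j`` the C-alpha positions of residue ``j``.

From the AE matrix the oracle analogues of the network's confidence
aggregates follow:

    aeTM      = max_i (1/N)     sum_j   f(e_ij, N)
    aeiTM     = max_i (1/|D_i|) sum_{j in D_i} f(e_ij, |D_i|)
    aeRankConf = 0.2 * aeTM + 0.8 * aeiTM

with the TM-score kernel f(d, n) = 1 / (1 + (d/d0(n))^2),
d0(n) = 1.24 (max(n,19) - 15)^(1/3) - 1.8, and ``D_i`` the set of all
residues except ``i`` (an "interchain" variant restricting ``D_i`` to
residues on other chains is available).  aeTM is bounded above by the
TM-score: aligning on any single residue frame is one admissible rigid
superposition, while the TM-score optimizes over all of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure_io import ResidueKey, StructureModel

__all__ = [
    "FrameSet",
    "AEMatrix",
    "AeScores",
    "build_frames",
    "aligned_error_matrix",
    "tm_d0",
    "tm_weight",
    "ae_scores",
]


@dataclass
class FrameSet:
    """Per-residue rigid backbone frames.

    ``rotations[k]`` is a proper orthonormal 3x3 matrix and
    ``translations[k]`` the C-alpha position; a global point ``p`` expressed
    in frame ``k`` is ``R_k^T (p - t_k)``.
    """

    rotations: np.ndarray        # (M, 3, 3)
    translations: np.ndarray     # (M, 3)
    residue_keys: list[ResidueKey]
    skipped: list[ResidueKey]

    @property
    def residue_index(self) -> dict[ResidueKey, int]:
        return {k: i for i, k in enumerate(self.residue_keys)}

    def __len__(self) -> int:
        return len(self.residue_keys)


@dataclass
class AEMatrix:
    """Non-symmetric Nres x Nres aligned-error matrix in Angstrom.

    Row ``i`` = aligning residue frame, column ``j`` = scored residue.
    Values are not capped ("unlimited error values").
    """

    e: np.ndarray
    residue_keys: list[ResidueKey]
    chain_labels: np.ndarray  # integer chain label per residue

    @property
    def n_res(self) -> int:
        return self.e.shape[0]

    def chain_blocks(self) -> list[tuple[int, int, int]]:
        """(label, start, stop) ranges of consecutive same-chain residues."""
        blocks = []
        labels = self.chain_labels
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                blocks.append((int(labels[start]), start, i))
                start = i
        return blocks


@dataclass
class AeScores:
    ae_tm: float
    ae_itm: float
    ae_rank_conf: float
    argmax_residue_tm: ResidueKey
    argmax_residue_itm: ResidueKey


def tm_d0(n: int | np.ndarray) -> float | np.ndarray:
    """TM-score normalization distance d0(n) = 1.24 (max(n,19)-15)^(1/3) - 1.8."""
    n_eff = np.maximum(np.asarray(n, dtype=float), 19.0)
    return 1.24 * np.cbrt(n_eff - 15.0) - 1.8


def tm_weight(d: np.ndarray | float, n: int | np.ndarray) -> np.ndarray | float:
    """TM-score kernel f(d, n) = 1 / (1 + (d / d0(n))^2).

    Decreasing in d, f(0, n) = 1 and f(d0(n), n) = 1/2.
    """
    d0 = tm_d0(n)
    return 1.0 / (1.0 + (np.asarray(d, dtype=float) / d0) ** 2)


def seq_row_sum(w: np.ndarray) -> np.ndarray:
    """Row sums with strict left-to-right accumulation.

    The score definitions are plain sums over residues; accumulating in
    index order keeps the result bit-identical to a scalar double-loop
    evaluation, which pairwise (blocked) summation would not.
    """
    return np.cumsum(w, axis=1)[:, -1]


def build_frames(model: StructureModel) -> FrameSet:
    """Construct a rigid frame per residue from its N, CA, C atoms.

    The frame origin is CA and the basis comes from Gram-Schmidt on
    (C - CA, N - CA), completed right-handed.  Residues lacking a backbone
    atom, or with collinear N/CA/C, are skipped and recorded.
    """
    rotations, translations, keys, skipped = [], [], [], []
    for chain_id, res in model.iter_residues():
        key = (chain_id, res.res_number, res.insertion_code)
        if not res.has_frame:
            skipped.append(key)
            continue
        v1 = res.c_xyz - res.ca_xyz
        v2 = res.n_xyz - res.ca_xyz
        n1 = np.linalg.norm(v1)
        if n1 < 1e-6:
            warnings.warn(f"degenerate backbone at {key}: C == CA; skipped")
            skipped.append(key)
            continue
        e1 = v1 / n1
        u2 = v2 - np.dot(v2, e1) * e1
        n2 = np.linalg.norm(u2)
        if n2 < 1e-6:
            warnings.warn(f"degenerate backbone at {key}: N/CA/C collinear; skipped")
            skipped.append(key)
            continue
        e2 = u2 / n2
        e3 = np.cross(e1, e2)
        rotations.append(np.stack([e1, e2, e3], axis=1))
        translations.append(np.asarray(res.ca_xyz, dtype=float))
        keys.append(key)
    return FrameSet(np.array(rotations).reshape(-1, 3, 3),
                    np.array(translations).reshape(-1, 3), keys, skipped)


def _common_frames_and_ca(query: StructureModel, reference: StructureModel
                          ) -> tuple[FrameSet, FrameSet, np.ndarray, np.ndarray,
                                     list[ResidueKey], np.ndarray]:
    q_keys = query.residue_keys()
    r_keys = reference.residue_keys()
    if q_keys != r_keys:
        raise ValueError(
            "query and reference must share the same residue set and order "
            "(crop them to their common residues first)")
    fq = build_frames(query)
    fr = build_frames(reference)
    valid = [k for k in fq.residue_keys if k in fr.residue_index]
    if len(valid) < 2:
        raise ValueError("fewer than 2 residues with complete backbone frames")
    idx = {k: i for i, k in enumerate(q_keys)}
    keep = np.array([idx[k] for k in valid], dtype=int)
    ca_q = query.ca_coords()[keep]
    ca_r = reference.ca_coords()[keep]
    qi = fq.residue_index
    ri = fr.residue_index
    fq_sel = FrameSet(fq.rotations[[qi[k] for k in valid]],
                      fq.translations[[qi[k] for k in valid]], valid, fq.skipped)
    fr_sel = FrameSet(fr.rotations[[ri[k] for k in valid]],
                      fr.translations[[ri[k] for k in valid]], valid, fr.skipped)
    labels = query.chain_index()[keep]
    return fq_sel, fr_sel, ca_q, ca_r, valid, labels


def aligned_error_matrix(query: StructureModel,
                         reference: StructureModel) -> AEMatrix:
    """Exact aligned-error matrix between a cropped query/reference pair.

    Both models must contain the same residues in the same order.  Residues
    without a complete backbone frame in either structure are excluded from
    both rows and columns (the score normalization shrinks accordingly).
    """
    fq, fr, ca_q, ca_r, keys, labels = _common_frames_and_ca(query, reference)
    # local coordinates of every CA j in every frame i: R_i^T (x_j - t_i)
    loc_q = np.einsum("iab,ija->ijb", fq.rotations,
                      ca_q[None, :, :] - fq.translations[:, None, :])
    loc_r = np.einsum("iab,ija->ijb", fr.rotations,
                      ca_r[None, :, :] - fr.translations[:, None, :])
    e = np.linalg.norm(loc_q - loc_r, axis=2)
    return AEMatrix(e, keys, labels)


def ae_scores(ae: AEMatrix, mode: str = "as_printed") -> AeScores:
    """Aggregate an AE matrix into aeTM / aeiTM / aeRankConf.

    Parameters
    ----------
    ae : aligned-error matrix (rows = aligning residue).
    mode : ``"as_printed"`` evaluates aeiTM with D_i = all residues except
        ``i``; ``"interchain"`` restricts D_i to residues on chains other
        than residue ``i``'s chain (the AlphaFold-multimer ipTM convention).

    Ties in the maximizing residue are broken by the lowest row index.
    """
    e = np.asarray(ae.e, dtype=float)
    n = e.shape[0]
    if n < 2:
        raise ValueError("aeTM/aeiTM need at least 2 residues")

    row_tm = seq_row_sum(tm_weight(e, n)) / n
    i_tm = int(np.argmax(row_tm))
    ae_tm = float(row_tm[i_tm])

    if mode == "as_printed":
        w = tm_weight(e, n - 1)
        np.fill_diagonal(w, 0.0)
        row_itm = seq_row_sum(w) / (n - 1)
    elif mode == "interchain":
        labels = np.asarray(ae.chain_labels)
        other = labels[None, :] != labels[:, None]
        counts = other.sum(axis=1)
        if np.any(counts == 0):
            raise ValueError(
                "interchain aeiTM undefined: some residue has no residues on "
                "other chains (single-chain model?)")
        w = tm_weight(e, counts[:, None])
        row_itm = seq_row_sum(np.where(other, w, 0.0)) / counts
    else:
        raise ValueError(f"unknown aeiTM mode {mode!r}")
    i_itm = int(np.argmax(row_itm))
    ae_itm = float(row_itm[i_itm])

    return AeScores(
        ae_tm=ae_tm,
        ae_itm=ae_itm,
        ae_rank_conf=0.2 * ae_tm + 0.8 * ae_itm,
        argmax_residue_tm=ae.residue_keys[i_tm],
        argmax_residue_itm=ae.residue_keys[i_itm],
    )
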