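"""Predicted-confidence scores derived from PAE matrices.

pTM and ipTM are the expectation counterparts of the oracle aeTM/aeiTM:
the TM-score kernel is applied to the predicted aligned error instead of
the true aligned error, with the expectation taken over the predicted
64-bin error distribution when one is available (bins are represented by
their midpoints, the open-ended last bin by 31.75 A).  With a point PAE
equal to the true AE matrix these scores coincide with aeTM/aeiTM
exactly, since both share the same kernel and aggregation.

Also implemented: the ranking confidence 0.2 pTM + 0.8 ipTM, the ipSAE
interface score (PAE and distance cutoffs, 10 A defaults), pDockQ2
(interface pLDDT x normalized interface PAE through a fitted sigmoid),
and descriptive statistics over the two off-diagonal chain-group blocks
of a PAE matrix (Region1 top-right, Region2 bottom-left).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .frames_ae import seq_row_sum, tm_weight
from .structure_io import (PAE_BIN_MIDPOINTS, ComplexPartition, PaeInput,
                           StructureModel)

__all__ = [
    "ConfidenceScores",
    "RegionStats",
    "IPSAE_CONSTANTS",
    "PDOCKQ2_CONSTANTS",
    "confidence_from_pae",
    "ipsae",
    "pdockq2",
    "pae_region_stats",
]

#: ipSAE conventions: pairs qualify when inter-group, PAE below the PAE
#: cutoff and CA-CA distance below the distance cutoff; d0 is computed from
#: the per-row count of qualifying partners with the TM-score formula.
IPSAE_CONSTANTS = {"pae_cutoff": 10.0, "dist_cutoff": 10.0}

#: pDockQ2 sigmoid constants from its published fit, applied to
#: x = <pLDDT>_interface * <1/(1+(PAE_ij/d0)^2)>_contacts with d0 = 10 A
#: and interface contacts at 8 A CB-CB (CA for glycine).
PDOCKQ2_CONSTANTS = {"L": 1.31, "x0": 84.733, "k": 0.075, "b": 0.005,
                     "d0": 10.0, "contact_cutoff": 8.0}


@dataclass
class ConfidenceScores:
    ptm: float
    iptm: float
    ranking_confidence: float
    ipsae: float | None = None
    pdockq2: float | None = None


@dataclass
class RegionStats:
    region1_mean: float
    region2_mean: float
    row_corr_r1: float
    col_corr_r1: float
    row_corr_r2: float
    col_corr_r2: float
    cross_region_corr: float


def _expected_weight(pae: PaeInput, n: int | np.ndarray) -> np.ndarray:
    """E[f(e_ij, n)] under the PAE: f applied to the point value, or the
    bin-probability-weighted kernel at bin midpoints."""
    if pae.mode == "point":
        return tm_weight(pae.point_matrix, n)
    if np.ndim(n) == 0:
        return pae.bin_probs @ tm_weight(PAE_BIN_MIDPOINTS, n)
    # per-row n: kernel values vary per row
    kern = tm_weight(PAE_BIN_MIDPOINTS[None, :], np.asarray(n)[:, None])
    return np.einsum("ijb,ib->ij", pae.bin_probs, kern)


def confidence_from_pae(pae: PaeInput, chain_labels: np.ndarray,
                        mode: str = "as_printed") -> ConfidenceScores:
    """pTM, ipTM and ranking confidence from a PAE input.

    ``chain_labels`` gives one integer label per residue, in PAE order; it
    determines the interchain restriction when ``mode="interchain"``.  In
    the default ``"as_printed"`` mode ipTM uses D_i = all residues except
    ``i``, matching the oracle aeiTM aggregation.
    """
    labels = np.asarray(chain_labels)
    n = pae.n_res
    if labels.shape[0] != n:
        raise ValueError(f"chain_labels has {labels.shape[0]} entries for a "
                         f"{n}-residue PAE")
    if n < 2:
        raise ValueError("pTM/ipTM need at least 2 residues")

    # sequential row accumulation keeps point-mode results bit-identical to
    # the oracle ae_scores aggregation
    w = _expected_weight(pae, n)
    ptm = float((seq_row_sum(w) / n).max())

    if mode == "as_printed":
        w2 = _expected_weight(pae, n - 1)
        np.fill_diagonal(w2, 0.0)
        iptm = float((seq_row_sum(w2) / (n - 1)).max())
    elif mode == "interchain":
        other = labels[None, :] != labels[:, None]
        counts = other.sum(axis=1)
        if np.any(counts == 0):
            raise ValueError("interchain ipTM undefined for single-chain input")
        w2 = _expected_weight(pae, counts)
        iptm = float((seq_row_sum(np.where(other, w2, 0.0)) / counts).max())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ConfidenceScores(ptm=ptm, iptm=iptm,
                            ranking_confidence=0.2 * ptm + 0.8 * iptm)


def ipsae(pae: PaeInput, distances: np.ndarray, group_labels: np.ndarray,
          pae_cutoff: float = IPSAE_CONSTANTS["pae_cutoff"],
          dist_cutoff: float = IPSAE_CONSTANTS["dist_cutoff"]) -> float:
    """ipSAE interface score.

    Restricted to inter-group residue pairs whose PAE is below
    ``pae_cutoff`` and whose CA-CA distance is below ``dist_cutoff``.  For
    each aligning residue the kernel is summed over qualifying partners
    with d0 computed from their count, and normalized by the number of
    inter-group partners within the distance cutoff (pairs failing the PAE
    cutoff contribute zero, so tightening the PAE cutoff can only lower
    the score).  The maximum over aligning residues is returned; 0 when no
    pair qualifies.
    """
    if pae.mode != "point":
        raise ValueError("ipSAE requires a point-mode PAE")
    m = pae.point_matrix
    labels = np.asarray(group_labels)
    distances = np.asarray(distances, dtype=float)
    if distances.shape != m.shape or labels.shape[0] != m.shape[0]:
        raise ValueError("PAE, distances and labels must agree in size")
    inter = labels[None, :] != labels[:, None]
    near = inter & (distances < dist_cutoff)
    qualifies = near & (m < pae_cutoff)
    q_counts = qualifies.sum(axis=1)
    d_counts = near.sum(axis=1)
    if not np.any(q_counts > 0):
        warnings.warn("no inter-group pair passes the ipSAE cutoffs; score 0")
        return 0.0
    best = 0.0
    for i in np.nonzero(q_counts > 0)[0]:
        sel = qualifies[i]
        best = max(best, float(tm_weight(m[i, sel], q_counts[i]).sum()
                               / d_counts[i]))
    return best


def pdockq2(plddt: np.ndarray, pae: PaeInput, query: StructureModel,
            partition: ComplexPartition) -> float:
    """pDockQ2 interface quality estimate.

    Contacts are inter-group residue pairs within 8 A CB-CB (CA for
    glycine).  The sigmoid input is the mean interface pLDDT multiplied by
    the mean normalized PAE kernel 1/(1+(PAE/10)^2) over the contact pairs.
    Returns 0 when the interface has no contacts.
    """
    if pae.mode != "point":
        raise ValueError("pDockQ2 requires a point-mode PAE")
    plddt = np.asarray(plddt, dtype=float)
    m = pae.point_matrix
    if plddt.shape[0] != m.shape[0] or query.n_residues() != m.shape[0]:
        raise ValueError("pLDDT, PAE and model sizes must agree")

    def cb_or_ca(res):
        atoms = dict(res.heavy_atoms)
        if res.aa != "G" and "CB" in atoms:
            return atoms["CB"]
        return res.ca_xyz

    coords = []
    groups = []
    for chain in query.chains:
        g = 0 if chain.chain_id in partition.antibody_chain_ids else 1
        for res in chain.residues:
            coords.append(cb_or_ca(res))
            groups.append(g)
    coords = np.array(coords)
    groups = np.array(groups)
    d = cdist(coords, coords)
    inter = groups[None, :] != groups[:, None]
    contact = inter & (d <= PDOCKQ2_CONSTANTS["contact_cutoff"])
    if not np.any(contact):
        warnings.warn("no inter-group contacts; pDockQ2 set to 0")
        return 0.0
    iface = np.nonzero(contact.any(axis=1))[0]
    mean_plddt = float(plddt[iface].mean())
    ii, jj = np.nonzero(np.triu(contact))
    d0 = PDOCKQ2_CONSTANTS["d0"]
    mean_kernel = float(np.mean(1.0 / (1.0 + (m[ii, jj] / d0) ** 2)))
    x = mean_plddt * mean_kernel
    c = PDOCKQ2_CONSTANTS
    return float(c["L"] / (1.0 + np.exp(-c["k"] * (x - c["x0"]))) + c["b"])


def _mean_pairwise_corr(vectors: np.ndarray) -> float:
    """Mean pairwise Pearson correlation between the rows of ``vectors``;
    NaN when no pair has variance on both sides."""
    k = vectors.shape[0]
    if k < 2 or vectors.shape[1] < 2:
        return float("nan")
    std = vectors.std(axis=1)
    ok = std > 0
    if ok.sum() < 2:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corr = np.corrcoef(vectors[ok])
    iu = np.triu_indices_from(corr, k=1)
    vals = corr[iu]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def pae_region_stats(pae: PaeInput, group_labels: np.ndarray,
                     region1: str = "top_right") -> RegionStats:
    """Statistics of the two off-diagonal chain-group blocks of a PAE matrix.

    With residues ordered antibody-then-antigen, ``region1="top_right"``
    places Region1 at rows in the first group / columns in the second
    (and Region2 at the transposed block); ``region1="bottom_left"`` swaps
    the naming.  The orientation is configurable because the mapping from
    matrix block to "aligned on antigen" vs "aligned on antibody" depends on
    the producer's row convention.
    """
    if pae.mode != "point":
        raise ValueError("region statistics require a point-mode PAE")
    labels = np.asarray(group_labels)
    m = pae.point_matrix
    if labels.shape[0] != m.shape[0]:
        raise ValueError("labels and PAE size must agree")
    first = labels == labels[0]
    second = ~first
    if not second.any():
        raise ValueError("need two chain groups for region statistics")
    top_right = m[np.ix_(first, second)]
    bottom_left = m[np.ix_(second, first)]
    if region1 == "top_right":
        r1, r2 = top_right, bottom_left
    elif region1 == "bottom_left":
        r1, r2 = bottom_left, top_right
    else:
        raise ValueError(f"unknown region1 orientation {region1!r}")

    flat1 = r1.ravel()
    flat2 = r2.T.ravel()  # transpose aligns shapes with region1
    if flat1.std() > 0 and flat2.std() > 0:
        cross = float(np.corrcoef(flat1, flat2)[0, 1])
    else:
        cross = float("nan")
    return RegionStats(
        region1_mean=float(r1.mean()),
        region2_mean=float(r2.mean()),
        row_corr_r1=_mean_pairwise_corr(r1),
        col_corr_r1=_mean_pairwise_corr(r1.T),
        row_corr_r2=_mean_pairwise_corr(r2),
        col_corr_r2=_mean_pairwise_corr(r2.T),
        cross_region_corr=cross,
    )
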