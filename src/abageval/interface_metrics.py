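"""Geometry-based quality scores.

Kabsch superposition, a TM-score computed by iterative superposition,
interface-residue extraction at a heavy-atom distance cutoff, and DockQ
evaluated on the antibody-antigen interface with the antibody chains
merged into one receptor entity and the antigen chains merged into one
ligand entity, so that each complex yields a single DockQ score.

DockQ follows the published conventions: native contacts are residue
pairs across the interface with any heavy-atom pair within 5 A; the
interface for iRMS is defined at 10 A; LRMS superposes on the receptor
group; and

    DockQ = ( fnat + 1/(1+(iRMS/1.5)^2) + 1/(1+(LRMS/8.5)^2) ) / 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .frames_ae import build_frames, tm_d0, tm_weight
from .structure_io import ComplexPartition, ResidueKey, StructureModel

__all__ = [
    "DockQResult",
    "dockq_from_components",
    "superpose",
    "tm_score",
    "interface_residues",
    "dockq_merged",
]

FNAT_CUTOFF = 5.0      # A, heavy-atom contact defining native contacts
IRMS_CUTOFF = 10.0     # A, heavy-atom cutoff defining the iRMS interface
DOCKQ_D1 = 1.5         # A, iRMS scaling constant
DOCKQ_D2 = 8.5         # A, LRMS scaling constant
BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class DockQResult:
    fnat: float
    fnonnat: float
    irms: float
    lrms: float
    dockq: float
    native_contacts: int


def dockq_from_components(fnat: float, irms: float, lrms: float) -> float:
    """DockQ = (fnat + 1/(1+(iRMS/1.5)^2) + 1/(1+(LRMS/8.5)^2)) / 3."""
    return (fnat
            + 1.0 / (1.0 + (irms / DOCKQ_D1) ** 2)
            + 1.0 / (1.0 + (lrms / DOCKQ_D2) ** 2)) / 3.0


def superpose(mobile: np.ndarray, target: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``
    (Kabsch).  Returns (rotation, translation, rmsd) with a proper rotation
    (det = +1, no reflection); apply as ``x @ R.T + t``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching (N, 3) arrays")
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = tc - rot @ mc
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(((moved - target) ** 2).sum(axis=1).mean()))
    return rot, trans, rmsd


def _rmsd_after_superposition(mobile: np.ndarray, target: np.ndarray) -> float:
    return superpose(mobile, target)[2]


def tm_score(query: StructureModel, reference: StructureModel) -> float:
    """TM-score of a cropped query/reference pair, normalized by the
    reference length.

    The score is maximized over superpositions found by iterative
    refinement from two seed families: contiguous fragments (full length,
    halves, quarters, 4-mers) and the per-residue backbone-frame
    superpositions.  Each seed is refined by repeatedly superposing on the
    residue pairs closer than a distance cutoff until the included set is
    stable; the reported score is max over seeds of
    (1/Lref) sum_j f(d_j, Lref).
    """
    q_keys = query.residue_keys()
    if q_keys != reference.residue_keys():
        raise ValueError("query and reference must be cropped to the same "
                         "residue set and order")
    x = query.ca_coords()
    y = reference.ca_coords()
    n = x.shape[0]
    if n < 3:
        raise ValueError("TM-score needs at least 3 common residues")
    d0 = max(tm_d0(n), 0.5)
    # decreasing inclusion cutoffs: late rounds superpose on only the
    # best-fitting residues, which is what maximizes the TM objective when
    # part of the structure cannot be brought close
    cut_schedule = [max(d0, 8.0), max(d0, 4.5), max(d0, 2.0), max(d0, 1.0),
                    d0]

    def score_from_transform(rot: np.ndarray, trans: np.ndarray) -> float:
        best_local = float(tm_weight(
            np.linalg.norm(x @ rot.T + trans - y, axis=1), n).mean())
        for d_cut in cut_schedule:
            included = None
            for _ in range(20):
                d = np.linalg.norm(x @ rot.T + trans - y, axis=1)
                best_local = max(best_local, float(tm_weight(d, n).mean()))
                new_included = d < d_cut
                if new_included.sum() < 3:
                    # keep the 4 closest pairs so refinement can proceed
                    new_included = np.zeros(n, dtype=bool)
                    new_included[np.argsort(d)[:4]] = True
                if included is not None and np.array_equal(new_included,
                                                           included):
                    break
                included = new_included
                rot, trans, _ = superpose(x[included], y[included])
        return best_local

    best = 0.0
    # fragment seeds
    for frag in {n, max(n // 2, 4), max(n // 4, 4), 4}:
        if frag > n:
            continue
        step = max(frag // 2, 1)
        for start in range(0, n - frag + 1, step):
            sl = slice(start, start + frag)
            rot, trans, _ = superpose(x[sl], y[sl])
            best = max(best, score_from_transform(rot, trans))
    # frame seeds: aligning on residue i's backbone frame is one admissible
    # superposition, which makes the score an upper bound of aeTM
    fq = build_frames(query)
    fr = build_frames(reference)
    common = [k for k in fq.residue_keys if k in fr.residue_index]
    qi, ri = fq.residue_index, fr.residue_index
    for key in common:
        rq, tq = fq.rotations[qi[key]], fq.translations[qi[key]]
        rr, tr = fr.rotations[ri[key]], fr.translations[ri[key]]
        rot = rr @ rq.T
        trans = tr - rot @ tq
        best = max(best, score_from_transform(rot, trans))
    return best


def _heavy_coords(model: StructureModel, chain_ids: set[str]
                  ) -> tuple[np.ndarray, list[ResidueKey]]:
    coords, keys = [], []
    for chain in model.chains:
        if chain.chain_id not in chain_ids:
            continue
        for res in chain.residues:
            key = (chain.chain_id, res.res_number, res.insertion_code)
            for _, xyz in res.heavy_atoms:
                coords.append(xyz)
                keys.append(key)
    return (np.array(coords).reshape(-1, 3), keys)


def interface_residues(model: StructureModel, partition: ComplexPartition,
                       cutoff: float = 12.0) -> set[ResidueKey]:
    """Residues of either group with any heavy atom within ``cutoff`` A of
    the other group (symmetric)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ab_xyz, ab_keys = _heavy_coords(model, set(partition.antibody_chain_ids))
    ag_xyz, ag_keys = _heavy_coords(model, set(partition.antigen_chain_ids))
    if len(ab_xyz) == 0 or len(ag_xyz) == 0:
        return set()
    d = cdist(ab_xyz, ag_xyz)
    hit_ab, hit_ag = np.nonzero(d <= cutoff)
    out: set[ResidueKey] = set()
    out.update(ab_keys[i] for i in hit_ab)
    out.update(ag_keys[j] for j in hit_ag)
    return out


def _residue_contacts(model: StructureModel, partition: ComplexPartition,
                      cutoff: float) -> set[tuple[ResidueKey, ResidueKey]]:
    ab_xyz, ab_keys = _heavy_coords(model, set(partition.antibody_chain_ids))
    ag_xyz, ag_keys = _heavy_coords(model, set(partition.antigen_chain_ids))
    if len(ab_xyz) == 0 or len(ag_xyz) == 0:
        return set()
    d = cdist(ab_xyz, ag_xyz)
    ii, jj = np.nonzero(d <= cutoff)
    return {(ab_keys[i], ag_keys[j]) for i, j in zip(ii, jj)}


def _backbone_for_keys(query: StructureModel, reference: StructureModel,
                       keys: set[ResidueKey]) -> tuple[np.ndarray, np.ndarray]:
    """Matched backbone coordinates for the given residue keys, using the
    backbone atom names present on both sides of each residue."""
    q_pts, r_pts = [], []
    ref_res = {(c.chain_id, r.res_number, r.insertion_code): r
               for c in reference.chains for r in c.residues}
    for chain in query.chains:
        for res in chain.residues:
            key = (chain.chain_id, res.res_number, res.insertion_code)
            if key not in keys or key not in ref_res:
                continue
            q_atoms = dict(res.heavy_atoms)
            r_atoms = dict(ref_res[key].heavy_atoms)
            for name in BACKBONE_ATOMS:
                if name in q_atoms and name in r_atoms:
                    q_pts.append(q_atoms[name])
                    r_pts.append(r_atoms[name])
    return np.array(q_pts).reshape(-1, 3), np.array(r_pts).reshape(-1, 3)


def dockq_merged(query: StructureModel, reference: StructureModel,
                 partition: ComplexPartition) -> DockQResult:
    """DockQ on the antibody-antigen interface with merged chain groups.

    All antibody chains form the receptor entity and all antigen chains the
    ligand entity, so multi-chain antigens contribute a single interface and
    the complex gets one DockQ score.  Contacts and the iRMS interface are
    defined on the reference (native) structure.
    """
    native = _residue_contacts(reference, partition, FNAT_CUTOFF)
    model = _residue_contacts(query, partition, FNAT_CUTOFF)
    if native:
        fnat = len(native & model) / len(native)
    else:
        warnings.warn("no native cross-interface contacts; fnat term set to 0")
        fnat = 0.0
    fnonnat = (len(model - native) / len(model)) if model else 0.0

    iface_keys = interface_residues(reference, partition, IRMS_CUTOFF)
    q_bb, r_bb = _backbone_for_keys(query, reference, iface_keys)
    if len(q_bb) >= 3:
        irms = _rmsd_after_superposition(q_bb, r_bb)
    else:
        warnings.warn("interface too small for iRMS; iRMS term set to 0")
        irms = float("inf")

    all_keys = set(query.residue_keys())
    rec_keys = {k for k in all_keys if k[0] in partition.antibody_chain_ids}
    lig_keys = {k for k in all_keys if k[0] in partition.antigen_chain_ids}
    q_rec, r_rec = _backbone_for_keys(query, reference, rec_keys)
    q_lig, r_lig = _backbone_for_keys(query, reference, lig_keys)
    if len(q_rec) >= 3 and len(q_lig) >= 1:
        rot, trans, _ = superpose(q_rec, r_rec)
        moved = q_lig @ rot.T + trans
        lrms = float(np.sqrt(((moved - r_lig) ** 2).sum(axis=1).mean()))
    else:
        lrms = float("inf")

    dockq = dockq_from_components(fnat, irms, lrms)
    return DockQResult(fnat=fnat, fnonnat=fnonnat, irms=irms, lrms=lrms,
                       dockq=float(dockq), native_contacts=len(native))
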