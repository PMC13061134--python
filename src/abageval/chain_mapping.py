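"""Chain pairing and cropping to the shared residue set.

Predicted models and experimental references rarely contain exactly the
same residues: references have unresolved loops and sometimes extra
chains.  Before any per-residue score can be computed, query chains must
be matched to reference chains and both structures cropped to the
residues present on both sides.

Chain pairing here is sequence-driven: a global alignment (BLOSUM62, gap
open 11 / extend 1) gives a per-chain-pair identity, an optimal
assignment maximizes total identity, and ties between identical
sequences (multi-copy antigens) are broken by C-alpha RMSD after a
whole-complex superposition, then by chain id.  Pairs below 30% identity
are left unpaired; a model whose chains cannot be paired at all scores
near zero downstream, which is the intended treatment of unalignable
predictions.

Cropped structures are emitted with the query's chain ids and residue
numbering on both sides so that residue keys match position-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import linear_sum_assignment

from .structure_io import Chain, Residue, StructureModel

__all__ = [
    "ChainPairing",
    "CroppedPair",
    "MIN_PAIR_IDENTITY",
    "global_alignment",
    "pair_chains",
    "crop_to_common",
    "cropping_report",
]

#: Chain pairs below this global-alignment identity are left unpaired.
MIN_PAIR_IDENTITY = 0.3

#: Coverage (aligned residues / query length) below which a comparison is
#: flagged low-quality; scoring still proceeds.
LOW_COVERAGE_THRESHOLD = 0.9


@dataclass
class ChainPairing:
    pairs: list[tuple[str, str, float]]  # (query_chain, reference_chain, identity)
    unpaired_query: list[str]
    unpaired_reference: list[str]


@dataclass
class CroppedPair:
    query_cropped: StructureModel
    reference_cropped: StructureModel
    aligned_residue_count: int
    coverage: float
    low_quality_flag: bool
    pair_details: list[dict]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def global_alignment(a: str, b: str) -> tuple[list[tuple[int, int]], float]:
    """Globally align two sequences.

    Returns the list of aligned index pairs (positions with a residue on
    both sides) and the identity fraction, defined as exact matches divided
    by the total alignment length including gap columns.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner()
    alignment = aligner.align(a, b)[0]
    blocks_a, blocks_b = alignment.aligned
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((i, j))
            if a[i] == b[j] and a[i] != "X":
                matches += 1
    length = alignment.shape[1]
    return pairs, matches / length


def pair_chains(query: StructureModel, reference: StructureModel) -> ChainPairing:
    """Assign query chains to reference chains by sequence identity.

    The assignment maximizes total identity over chain pairs; identity ties
    (e.g. several copies of the same antigen) are resolved by the aligned
    C-alpha RMSD of each candidate pair after superposing the whole query
    onto the reference, and remaining ties lexicographically by reference
    chain id.
    """
    if not query.chains or not reference.chains:
        raise ValueError("both models must contain at least one chain")
    nq, nr = len(query.chains), len(reference.chains)
    identity = np.zeros((nq, nr))
    aligned_pairs: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for qi, qchain in enumerate(query.chains):
        for rj, rchain in enumerate(reference.chains):
            pairs, ident = global_alignment(qchain.sequence, rchain.sequence)
            identity[qi, rj] = ident
            aligned_pairs[(qi, rj)] = pairs

    # Provisional max-identity assignment -> CA correspondence -> one global
    # superposition; its per-pair RMSD breaks identity ties in a second pass.
    # Only pairs whose identity is the strict maximum of both their row and
    # column anchor the superposition: ambiguous copies must not steer it.
    row0, col0 = linear_sum_assignment(-identity)

    def _unambiguous(qi: int, rj: int) -> bool:
        val = identity[qi, rj]
        row_rivals = np.delete(identity[qi, :], rj)
        col_rivals = np.delete(identity[:, rj], qi)
        return ((row_rivals.size == 0 or val > row_rivals.max() + 1e-9)
                and (col_rivals.size == 0 or val > col_rivals.max() + 1e-9))

    anchors = [(qi, rj) for qi, rj in zip(row0, col0)
               if identity[qi, rj] >= MIN_PAIR_IDENTITY
               and _unambiguous(qi, rj)]
    if not anchors:  # everything ambiguous: anchor on the provisional pairs
        anchors = [(qi, rj) for qi, rj in zip(row0, col0)
                   if identity[qi, rj] >= MIN_PAIR_IDENTITY]
    rmsd = np.zeros_like(identity)
    corr_q, corr_r = [], []
    for qi, rj in anchors:
        for i, j in aligned_pairs[(qi, rj)]:
            corr_q.append(query.chains[qi].residues[i].ca_xyz)
            corr_r.append(reference.chains[rj].residues[j].ca_xyz)
    if len(corr_q) >= 3:
        from .interface_metrics import superpose
        rot, trans, _ = superpose(np.array(corr_q), np.array(corr_r))
        for (qi, rj), pairs in aligned_pairs.items():
            if not pairs:
                rmsd[qi, rj] = 1e3
                continue
            xq = np.array([query.chains[qi].residues[i].ca_xyz for i, _ in pairs])
            xr = np.array([reference.chains[rj].residues[j].ca_xyz for _, j in pairs])
            moved = xq @ rot.T + trans
            rmsd[qi, rj] = float(np.sqrt(((moved - xr) ** 2).sum(axis=1).mean()))

    # identity dominates; RMSD (bounded ~1e3) breaks ties at the 1e-6 level;
    # a per-column epsilon prefers earlier reference chains on exact ties
    lex = np.arange(nr)[None, :] * 1e-12
    cost = -identity * 1e6 + np.minimum(rmsd, 1e3) + lex
    rows, cols = linear_sum_assignment(cost)

    pairs_out: list[tuple[str, str, float]] = []
    used_q, used_r = set(), set()
    for qi, rj in zip(rows, cols):
        if identity[qi, rj] >= MIN_PAIR_IDENTITY:
            pairs_out.append((query.chains[qi].chain_id,
                              reference.chains[rj].chain_id,
                              float(identity[qi, rj])))
            used_q.add(qi)
            used_r.add(rj)
    if not pairs_out:
        warnings.warn(
            f"no chain pair of {query.target_id!r} vs {reference.target_id!r} "
            f"reaches {MIN_PAIR_IDENTITY:.0%} identity; empty pairing")
    return ChainPairing(
        pairs=pairs_out,
        unpaired_query=[c.chain_id for i, c in enumerate(query.chains)
                        if i not in used_q],
        unpaired_reference=[c.chain_id for j, c in enumerate(reference.chains)
                            if j not in used_r],
    )


def _copy_residue(res: Residue, number: int, icode: str) -> Residue:
    return Residue(number, icode, res.aa, np.array(res.ca_xyz),
                   None if res.n_xyz is None else np.array(res.n_xyz),
                   None if res.c_xyz is None else np.array(res.c_xyz),
                   [(n, np.array(x)) for n, x in res.heavy_atoms], res.plddt)


def crop_to_common(query: StructureModel, reference: StructureModel,
                   pairing: ChainPairing) -> CroppedPair:
    """Crop both structures to the residues present on both sides.

    For every paired chain a global sequence alignment is computed and only
    columns with a residue on both sides are kept (aligned columns with a
    substitution are retained: cropping is by presence, not identity).
    Coverage is the number of retained residues divided by the total residue
    count of the *original* query; below 0.9 the pair is flagged
    low-quality but still returned for scoring.
    """
    q_chains: list[Chain] = []
    r_chains: list[Chain] = []
    details = []
    total_aligned = 0
    for q_id, r_id, ident in pairing.pairs:
        qchain = query.get_chain(q_id)
        rchain = reference.get_chain(r_id)
        pairs, _ = global_alignment(qchain.sequence, rchain.sequence)
        q_res, r_res = [], []
        for i, j in pairs:
            qr = qchain.residues[i]
            rr = rchain.residues[j]
            q_res.append(_copy_residue(qr, qr.res_number, qr.insertion_code))
            # reference residues adopt the query numbering so residue keys
            # match position-wise across the pair
            r_res.append(_copy_residue(rr, qr.res_number, qr.insertion_code))
        if q_res:
            q_chains.append(Chain(q_id, q_res))
            r_chains.append(Chain(q_id, r_res))
        total_aligned += len(q_res)
        details.append({"query_chain": q_id, "reference_chain": r_id,
                        "identity": ident, "aligned_residues": len(q_res)})
    n_query = query.n_residues()
    coverage = total_aligned / n_query if n_query else 0.0
    return CroppedPair(
        query_cropped=StructureModel(query.target_id, q_chains,
                                     query.source_format),
        reference_cropped=StructureModel(reference.target_id, r_chains,
                                         reference.source_format),
        aligned_residue_count=total_aligned,
        coverage=coverage,
        low_quality_flag=coverage < LOW_COVERAGE_THRESHOLD,
        pair_details=details,
    )


def cropping_report(cropped: CroppedPair) -> pd.DataFrame:
    """Tabular cropping report: one row per chain pair plus totals."""
    df = pd.DataFrame(cropped.pair_details,
                      columns=["query_chain", "reference_chain", "identity",
                               "aligned_residues"])
    df["coverage"] = cropped.coverage
    df["low_quality_flag"] = cropped.low_quality_flag
    return df
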