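"""Batch scoring workflow.

One function scores a single (query, reference) pair end to end — chain
pairing, cropping to the common residues, merged-interface DockQ,
TM-score, the oracle aligned-error scores and, when a PAE file is
supplied, the predicted-confidence scores — and one function drives it
over a CSV manifest of (target, model, reference, pae, chain roles)
rows, producing the score table the ensemble analyses consume.

Fixture emission lives here too: a seeded generator writing reference
PDBs, decoy models, calibrated PAE JSONs and a manifest, so the whole
pipeline can run from a single command without external data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .chain_mapping import crop_to_common, pair_chains
from .confidence import confidence_from_pae, ipsae, pdockq2
from .frames_ae import aligned_error_matrix, ae_scores, tm_weight
from .interface_metrics import dockq_merged, tm_score
from .structure_io import (ComplexPartition, PaeInput, StructureModel,
                           partition_complex, read_pae, read_structure,
                           write_pae, write_pdb)
from .synthetic import make_decoy, make_toy_complex, synth_pae

__all__ = ["score_pair", "score_manifest", "emit_fixture_set",
           "SCORE_COLUMNS"]

SCORE_COLUMNS = ["target_id", "model_id", "dockq", "fnat", "irms", "lrms",
                 "tm_score", "ae_tm", "ae_itm", "ae_rank_conf", "ptm", "iptm",
                 "ranking_confidence", "ipsae", "pdockq2", "coverage",
                 "low_quality_flag"]


def _subset_pae(pae: PaeInput, indices: np.ndarray) -> PaeInput:
    """Restrict a PAE input to the given residue indices (cropping)."""
    if pae.mode == "point":
        return PaeInput(mode="point",
                        point_matrix=pae.point_matrix[np.ix_(indices, indices)])
    return PaeInput(mode="binned",
                    bin_probs=pae.bin_probs[np.ix_(indices, indices)])


def score_pair(query: StructureModel, reference: StructureModel,
               antibody_ids: list[str], antigen_ids: list[str],
               pae: PaeInput | None = None,
               aeitm_mode: str = "as_printed") -> dict:
    """Score one predicted model against its reference.

    Returns a flat dict of metrics (NaN where a score is unavailable, e.g.
    confidence scores without a PAE).  The PAE, when given, must be indexed
    over the query's residues; it is cropped alongside the structures.
    """
    pairing = pair_chains(query, reference)
    cropped = crop_to_common(query, reference, pairing)
    out: dict = {
        "coverage": cropped.coverage,
        "low_quality_flag": cropped.low_quality_flag,
    }
    qc, rc = cropped.query_cropped, cropped.reference_cropped
    scored_ab = [c for c in qc.chain_ids() if c in antibody_ids]
    scored_ag = [c for c in qc.chain_ids() if c in antigen_ids]
    nan_keys = ["dockq", "fnat", "irms", "lrms", "tm_score", "ae_tm", "ae_itm",
                "ae_rank_conf", "ptm", "iptm", "ranking_confidence", "ipsae",
                "pdockq2"]
    for key in nan_keys:
        out[key] = float("nan")
    if not scored_ab or not scored_ag or qc.n_residues() < 3:
        out["dockq"] = 0.0  # unalignable model: poor by construction
        return out
    partition = partition_complex(qc, scored_ab, scored_ag)

    dq = dockq_merged(qc, rc, partition)
    out.update(dockq=dq.dockq, fnat=dq.fnat, irms=dq.irms, lrms=dq.lrms)
    out["tm_score"] = tm_score(qc, rc)
    ae = aligned_error_matrix(qc, rc)
    sc = ae_scores(ae, mode=aeitm_mode)
    out.update(ae_tm=sc.ae_tm, ae_itm=sc.ae_itm, ae_rank_conf=sc.ae_rank_conf)

    if pae is not None:
        # map cropped query residues back to their original query indices
        orig_index = {k: i for i, k in enumerate(query.residue_keys())}
        idx = np.array([orig_index[k] for k in qc.residue_keys()], dtype=int)
        pae_c = _subset_pae(pae, idx)
        labels = partition.group_labels(qc)
        conf = confidence_from_pae(pae_c, labels, mode=aeitm_mode)
        out.update(ptm=conf.ptm, iptm=conf.iptm,
                   ranking_confidence=conf.ranking_confidence)
        if pae_c.mode == "point":
            ca = qc.ca_coords()
            dists = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=2)
            out["ipsae"] = ipsae(pae_c, dists, labels)
            plddt = qc.plddt_vector()
            if not np.any(np.isnan(plddt)):
                out["pdockq2"] = pdockq2(plddt, pae_c, qc, partition)
    return out


def score_manifest(manifest: pd.DataFrame,
                   base_dir: str | Path = ".") -> pd.DataFrame:
    """Score every row of a manifest.

    Required columns: ``target_id``, ``model_id``, ``model_path``,
    ``reference_path``, ``antibody_chains``, ``antigen_chains`` (comma
    separated); optional ``pae_path``.  Paths are resolved against
    ``base_dir``.  Rows are scored in manifest order.
    """
    base = Path(base_dir)
    required = ["target_id", "model_id", "model_path", "reference_path",
                "antibody_chains", "antigen_chains"]
    missing = [c for c in required if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest lacks columns {missing}")
    ref_cache: dict[str, StructureModel] = {}
    rows = []
    for rec in manifest.itertuples(index=False):
        ref_path = str(rec.reference_path)
        if ref_path not in ref_cache:
            ref_cache[ref_path] = read_structure(base / ref_path)
        query = read_structure(base / str(rec.model_path),
                               b_factor_is_plddt=True)
        pae = None
        if hasattr(rec, "pae_path") and isinstance(rec.pae_path, str) \
                and rec.pae_path:
            pae = read_pae(base / rec.pae_path)
        result = score_pair(query, ref_cache[ref_path],
                            [c for c in str(rec.antibody_chains).split(",") if c],
                            [c for c in str(rec.antigen_chains).split(",") if c],
                            pae=pae)
        result["target_id"] = rec.target_id
        result["model_id"] = rec.model_id
        rows.append(result)
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def emit_fixture_set(out_dir: str | Path, n_targets: int = 3,
                     models_per_target: int = 8, seed: int = 7,
                     pae_noise: float = 2.0, good_fraction: float = 0.3,
                     n_res: tuple[int, int] = (14, 12)) -> Path:
    """Write a synthetic fixture set and return the manifest path.

    Each target is a two-chain toy complex (antibody chain H, antigen
    chain A).  Models are decoys whose antigen group is translated by a
    random direction with magnitude drawn small ("good" models) or large
    ("bad" models), plus mild coordinate jitter; each model gets a point
    PAE synthesized from its true aligned-error matrix with the requested
    noise, and a pLDDT column derived from its true per-residue error.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest_rows = []
    for t in range(n_targets):
        tid = f"T{t:03d}"
        ref = make_toy_complex(list(n_res), geometry="helix", separation=4.5,
                               seed=int(rng.integers(2 ** 31)),
                               chain_ids=["H", "A"], target_id=tid)
        partition = partition_complex(ref, ["H"], ["A"])
        ref_path = out / f"{tid}_ref.pdb"
        write_pdb(ref, ref_path)
        for m in range(models_per_target):
            mid = f"m{m:03d}"
            good = rng.random() < good_fraction
            magnitude = (rng.uniform(0.1, 1.0) if good
                         else rng.uniform(4.0, 20.0))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            decoy = make_decoy(ref, partition,
                               translation=magnitude * direction,
                               jitter_sigma=0.15,
                               seed=int(rng.integers(2 ** 31)))
            decoy.target_id = f"{tid}_{mid}"
            ae = aligned_error_matrix(decoy, ref)
            n = ae.n_res
            plddt = 100.0 * tm_weight(ae.e, n).mean(axis=0)
            for (cid, res), value in zip(decoy.iter_residues(), plddt):
                res.plddt = float(np.clip(value, 0.0, 100.0))
            pae = synth_pae(ae, noise_sigma=pae_noise, mode="point",
                            seed=int(rng.integers(2 ** 31)))
            model_path = out / f"{tid}_{mid}.pdb"
            pae_path = out / f"{tid}_{mid}_pae.json"
            write_pdb(decoy, model_path)
            write_pae(pae, pae_path)
            manifest_rows.append({
                "target_id": tid, "model_id": mid,
                "model_path": model_path.name,
                "reference_path": ref_path.name,
                "pae_path": pae_path.name,
                "antibody_chains": "H", "antigen_chains": "A",
            })
    manifest = pd.DataFrame(manifest_rows)
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path
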