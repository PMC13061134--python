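"""Benchmark-set construction from tabular structure metadata.

Builds an antibody-antigen benchmark from per-structure records by the
date-split / filter / deduplication procedure used for unseen-complex
benchmarks:

1. keep only X-ray or electron-microscopy structures at 3.5 A resolution
   or better;
2. drop antibody-peptide complexes;
3. drop structures missing more than 10% of their residues;
4. drop structures redundant with the pre-cutoff ("before") set — two
   complexes are redundant when the heavy-chain, light-chain AND antigen
   sequence identities all exceed the threshold (80% default; an "any"
   combination rule is available);
5. cluster the survivors by the same redundancy relation (single
   linkage) and keep one representative per cluster: fewest missing
   residues summed over H, L and antigen chains, then the shorter
   antigen sequence, then the lexicographically smallest PDB id.

Sequence identity is global-alignment identity (matches / alignment
length).  Multi-chain antigens are compared chain-by-chain under a
maximum-identity assignment; the antigen identity of a record pair is
the highest identity among the assigned chain pairs.  Every rejection
carries a machine-readable reason code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import linear_sum_assignment

from .chain_mapping import global_alignment

__all__ = [
    "BenchmarkRecord",
    "BenchmarkConfig",
    "sequence_identity",
    "build_benchmark",
    "records_from_csv",
    "records_to_csv",
    "rejections_to_csv",
    "load_config",
]

REASONS = ("MODALITY", "RESOLUTION", "PEPTIDE_ANTIGEN", "MISSING",
           "BEFORE_REDUNDANT", "CLUSTER_DUPLICATE")


@dataclass
class BenchmarkRecord:
    pdb_id: str
    deposit_date: date
    method: str  # xray | em | nmr | other
    resolution: float | None
    h_seq: str
    l_seq: str
    antigen_seqs: list[str]
    missing_fraction: float
    missing_counts: tuple[int, int, int] = (0, 0, 0)  # H, L, antigen totals
    antigen_is_peptide: bool = False

    @property
    def total_missing(self) -> int:
        return int(sum(self.missing_counts))

    @property
    def antigen_length(self) -> int:
        return sum(len(s) for s in self.antigen_seqs)


@dataclass
class BenchmarkConfig:
    identity_threshold: float = 0.80
    max_resolution: float = 3.5
    max_missing_fraction: float = 0.10
    allowed_methods: tuple[str, ...] = ("xray", "em")
    exclude_peptide_antigens: bool = True
    redundancy_combine: str = "all"  # "all": H, L and antigen must all exceed


def load_config(path: str | Path) -> BenchmarkConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = BenchmarkConfig()
    for key, value in data.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config key {key!r}")
        if key == "allowed_methods":
            value = tuple(value)
        setattr(cfg, key, value)
    return cfg


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity: matches / alignment length."""
    if not a or not b:
        raise ValueError("cannot compute identity of an empty sequence")
    _, ident = global_alignment(a, b)
    return ident


def _chain_identity(a: str, b: str) -> float:
    # empty-vs-empty chains (e.g. two nanobodies without light chains)
    # compare as identical; empty-vs-present as fully dissimilar
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    return sequence_identity(a, b)


def _antigen_identity(seqs_a: list[str], seqs_b: list[str]) -> float:
    """Antigen identity under a maximum-identity chain assignment: the
    highest identity among the optimally paired antigen chains."""
    if not seqs_a or not seqs_b:
        return 1.0 if not seqs_a and not seqs_b else 0.0
    ident = np.array([[_chain_identity(a, b) for b in seqs_b] for a in seqs_a])
    rows, cols = linear_sum_assignment(-ident)
    return float(ident[rows, cols].max())


def _is_redundant(a: BenchmarkRecord, b: BenchmarkRecord,
                  cfg: BenchmarkConfig) -> bool:
    thr = cfg.identity_threshold
    idents = (_chain_identity(a.h_seq, b.h_seq),
              _chain_identity(a.l_seq, b.l_seq),
              _antigen_identity(a.antigen_seqs, b.antigen_seqs))
    if cfg.redundancy_combine == "all":
        return all(x > thr for x in idents)
    if cfg.redundancy_combine == "any":
        return any(x > thr for x in idents)
    raise ValueError(f"unknown redundancy_combine {cfg.redundancy_combine!r}")


def _representative(cluster: list[BenchmarkRecord]) -> BenchmarkRecord:
    # fewest missing residues over H+L+antigen, then shorter antigen,
    # then lexicographic pdb id
    return min(cluster, key=lambda r: (r.total_missing, r.antigen_length,
                                       r.pdb_id))


def build_benchmark(records: list[BenchmarkRecord],
                    before: list[BenchmarkRecord],
                    config: BenchmarkConfig | None = None
                    ) -> tuple[list[BenchmarkRecord],
                               list[tuple[BenchmarkRecord, str]]]:
    """Apply the benchmark filters and clustering.

    ``records`` are the candidate (post-cutoff) structures, ``before`` the
    pre-cutoff set used for redundancy removal; the date split itself
    happens upstream.  Returns (kept, rejected) where each rejection is
    (record, reason code).  Deterministic given input order.
    """
    cfg = config or BenchmarkConfig()
    kept: list[BenchmarkRecord] = []
    rejected: list[tuple[BenchmarkRecord, str]] = []

    survivors: list[BenchmarkRecord] = []
    for rec in records:
        if rec.method not in cfg.allowed_methods:
            rejected.append((rec, "MODALITY"))
        elif rec.resolution is None or rec.resolution > cfg.max_resolution:
            rejected.append((rec, "RESOLUTION"))
        elif cfg.exclude_peptide_antigens and rec.antigen_is_peptide:
            rejected.append((rec, "PEPTIDE_ANTIGEN"))
        elif rec.missing_fraction > cfg.max_missing_fraction:
            rejected.append((rec, "MISSING"))
        elif any(_is_redundant(rec, b, cfg) for b in before):
            rejected.append((rec, "BEFORE_REDUNDANT"))
        else:
            survivors.append(rec)

    # single-linkage clustering on the redundancy relation
    survivors = sorted(survivors, key=lambda r: r.pdb_id)
    n = len(survivors)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _is_redundant(survivors[i], survivors[j], cfg):
                parent[find(i)] = find(j)
    clusters: dict[int, list[BenchmarkRecord]] = {}
    for i, rec in enumerate(survivors):
        clusters.setdefault(find(i), []).append(rec)
    for members in clusters.values():
        rep = _representative(members)
        kept.append(rep)
        for rec in members:
            if rec is not rep:
                rejected.append((rec, "CLUSTER_DUPLICATE"))
    kept.sort(key=lambda r: r.pdb_id)
    return kept, rejected


_CSV_COLUMNS = ["pdb_id", "deposit_date", "method", "resolution", "h_seq",
                "l_seq", "antigen_seqs", "missing_fraction", "missing_h",
                "missing_l", "missing_antigen", "antigen_is_peptide"]


def records_from_csv(path: str | Path) -> list[BenchmarkRecord]:
    """Read benchmark records from CSV (antigen chains ';'-separated)."""
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        res = row.resolution
        out.append(BenchmarkRecord(
            pdb_id=str(row.pdb_id),
            deposit_date=date.fromisoformat(str(row.deposit_date)),
            method=str(row.method),
            resolution=None if res in ("", None) else float(res),
            h_seq=str(row.h_seq),
            l_seq=str(row.l_seq),
            antigen_seqs=[s for s in str(row.antigen_seqs).split(";") if s],
            missing_fraction=float(row.missing_fraction),
            missing_counts=(int(row.missing_h), int(row.missing_l),
                            int(row.missing_antigen)),
            antigen_is_peptide=str(row.antigen_is_peptide).lower()
            in ("1", "true", "yes"),
        ))
    return out


def records_to_csv(records: list[BenchmarkRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "pdb_id": r.pdb_id,
            "deposit_date": r.deposit_date.isoformat(),
            "method": r.method,
            "resolution": "" if r.resolution is None else r.resolution,
            "h_seq": r.h_seq,
            "l_seq": r.l_seq,
            "antigen_seqs": ";".join(r.antigen_seqs),
            "missing_fraction": r.missing_fraction,
            "missing_h": r.missing_counts[0],
            "missing_l": r.missing_counts[1],
            "missing_antigen": r.missing_counts[2],
            "antigen_is_peptide": r.antigen_is_peptide,
        })
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def rejections_to_csv(rejected: list[tuple[BenchmarkRecord, str]],
                      path: str | Path) -> None:
    pd.DataFrame([{"pdb_id": r.pdb_id, "reason": reason}
                  for r, reason in rejected]).to_csv(path, index=False)
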