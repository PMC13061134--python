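"""Ensemble-level analyses of scored model sets.

Given a table of per-model scores (one row per (target, model) with a
DockQ value and one or more ranking columns), this module computes:

* bootstrap sampling curves — for growing sample sizes ``k``, draw ``k``
  models per target with replacement, record the DockQ of the best
  (highest DockQ) and of the top-ranked (highest selector) model, average
  over iterations and then over targets.  The gap between the two curves
  is the cost of imperfect ranking;
* an exact-expectation variant of the same curves, obtained from the
  order statistics of sampling with replacement (used to validate the
  bootstrap);
* ensemble diversity in the PconsDock sense: the mean pairwise DockQ
  among a target's models, either over all pairs or over a seeded random
  subset of partners per model;
* a ranking summary: mean DockQ of the top-ranked model per target,
  pooled Spearman correlation R between selector and DockQ, and the mean
  per-target Spearman <R>.

All resampling is seeded and reproducible; selector ties are broken by
the lower model id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "SamplingCurve",
    "RankingSummary",
    "sampling_curve",
    "sampling_curve_exact",
    "pconsdock_diversity",
    "ranking_summary",
]


@dataclass
class SamplingCurve:
    k_values: list[int]
    mean_best_dockq: np.ndarray
    mean_top_ranked_dockq: np.ndarray
    n_iterations: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.k_values,
            "mean_best_dockq": self.mean_best_dockq,
            "mean_top_ranked_dockq": self.mean_top_ranked_dockq,
        })


@dataclass
class RankingSummary:
    mean_top_dockq: float
    overall_r: float
    mean_per_target_r: float
    n_targets: int
    n_targets_excluded: int = 0


def _per_target_arrays(records: pd.DataFrame, selector: str
                       ) -> list[tuple[str, np.ndarray, np.ndarray]]:
    for col in ("target_id", "model_id", "dockq", selector):
        if col not in records.columns:
            raise ValueError(f"score table lacks required column {col!r}")
    if records.duplicated(["target_id", "model_id"]).any():
        raise ValueError("(target_id, model_id) pairs must be unique")
    out = []
    for tid, grp in records.sort_values(["target_id", "model_id"]).groupby(
            "target_id", sort=True):
        out.append((tid, grp["dockq"].to_numpy(dtype=float),
                    grp[selector].to_numpy(dtype=float)))
    return out


def sampling_curve(records: pd.DataFrame, k_values: list[int],
                   n_iter: int = 50, seed: int = 0,
                   selector: str = "ranking_confidence") -> SamplingCurve:
    """Bootstrap best-vs-top-ranked DockQ curves over sample size.

    For each target and each ``k``, ``n_iter`` samples of ``k`` models are
    drawn with replacement; the best model is the sample's DockQ maximum
    and the top-ranked model is the sample's selector maximum (ties to the
    lower model id).  Recorded DockQ values are averaged over iterations,
    then over targets.
    """
    groups = _per_target_arrays(records, selector)
    if not groups:
        raise ValueError("empty score table")
    rng = np.random.default_rng(seed)
    best = np.zeros((len(groups), len(k_values)))
    top = np.zeros((len(groups), len(k_values)))
    for gi, (_, dockq, sel) in enumerate(groups):
        n = len(dockq)
        for ki, k in enumerate(k_values):
            idx = rng.integers(0, n, size=(n_iter, k))
            idx.sort(axis=1)  # ascending model order -> argmax tie = lowest id
            sampled_dockq = dockq[idx]
            best[gi, ki] = sampled_dockq.max(axis=1).mean()
            choice = np.argmax(sel[idx], axis=1)
            top[gi, ki] = sampled_dockq[np.arange(n_iter), choice].mean()
    return SamplingCurve(list(k_values), best.mean(axis=0), top.mean(axis=0),
                         n_iter, seed)


def sampling_curve_exact(records: pd.DataFrame, k_values: list[int],
                         selector: str = "ranking_confidence") -> SamplingCurve:
    """Exact expectations of the bootstrap curves.

    With models sorted by DockQ, P(max of k draws <= m-th value) = (m/n)^k,
    which gives E[best-of-k] in closed form; the top-ranked expectation uses
    the same order statistics under the strict selector order (ties broken
    by lower model id).
    """
    groups = _per_target_arrays(records, selector)
    if not groups:
        raise ValueError("empty score table")
    best = np.zeros((len(groups), len(k_values)))
    top = np.zeros((len(groups), len(k_values)))
    for gi, (_, dockq, sel) in enumerate(groups):
        n = len(dockq)
        m = np.arange(1, n + 1)
        # best: ascending DockQ order
        v = np.sort(dockq)
        # top-ranked: ascending by (selector, reversed model position) so the
        # last element wins every tie-broken comparison
        order = np.lexsort((-np.arange(n), sel))
        w = dockq[order]
        for ki, k in enumerate(k_values):
            p = (m / n) ** k - ((m - 1) / n) ** k
            best[gi, ki] = float(v @ p)
            top[gi, ki] = float(w @ p)
    return SamplingCurve(list(k_values), best.mean(axis=0), top.mean(axis=0),
                         0, None)


def pconsdock_diversity(pairwise: dict[str, pd.DataFrame], n_partners: int = 20,
                        seed: int = 0, mode: str = "sampled"
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Ensemble diversity from per-target pairwise DockQ matrices.

    ``pairwise`` maps target id to a square symmetric DataFrame indexed by
    model id.  In ``sampled`` mode each model is compared with
    ``n_partners`` distinct randomly chosen other models (the published
    procedure); ``full`` uses all pairs.  Returns a per-model table and the
    per-target means (mean of per-model means).
    """
    if mode not in ("sampled", "full"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for tid in sorted(pairwise):
        mat = pairwise[tid]
        ids = list(mat.index)
        m = mat.to_numpy(dtype=float)
        n = len(ids)
        if n < 2:
            raise ValueError(f"target {tid!r} needs >= 2 models")
        use_full = mode == "full"
        if not use_full and n_partners >= n:
            warnings.warn(f"n_partners={n_partners} >= {n} models for "
                          f"{tid!r}; falling back to all pairs")
            use_full = True
        for i, mid in enumerate(ids):
            others = np.delete(np.arange(n), i)
            if not use_full:
                others = rng.choice(others, size=n_partners, replace=False)
            rows.append({"target_id": tid, "model_id": mid,
                         "diversity": float(m[i, others].mean())})
    per_model = pd.DataFrame(rows)
    per_target = per_model.groupby("target_id")["diversity"].mean()
    return per_model, per_target


def ranking_summary(records: pd.DataFrame,
                    selector: str = "ranking_confidence") -> RankingSummary:
    """Mean top-ranked DockQ and Spearman correlations for one selector.

    ``overall_r`` pools every model; ``mean_per_target_r`` averages the
    per-target Spearman, excluding (and counting) targets where either
    variable has zero variance.
    """
    groups = _per_target_arrays(records, selector)
    if not groups:
        raise ValueError("empty score table")
    top_vals = []
    per_target_r = []
    excluded = 0
    all_dockq, all_sel = [], []
    for _, dockq, sel in groups:
        top_vals.append(dockq[int(np.argmax(sel))])
        all_dockq.append(dockq)
        all_sel.append(sel)
        if len(dockq) < 2 or np.ptp(dockq) == 0 or np.ptp(sel) == 0:
            excluded += 1
            continue
        per_target_r.append(spearmanr(sel, dockq).statistic)
    pooled = spearmanr(np.concatenate(all_sel), np.concatenate(all_dockq))
    return RankingSummary(
        mean_top_dockq=float(np.mean(top_vals)),
        overall_r=float(pooled.statistic),
        mean_per_target_r=(float(np.mean(per_target_r)) if per_target_r
                           else float("nan")),
        n_targets=len(groups),
        n_targets_excluded=excluded,
    )
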