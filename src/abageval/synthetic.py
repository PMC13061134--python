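"""Synthetic fixtures: toy complexes, decoys, calibrated PAE inputs and
planted score ensembles.

Every scoring operation in this package can be exercised without
external data: this module builds small multi-chain complexes with ideal
backbone geometry, perturbs them into decoys whose deviation from the
reference is known exactly (a pure translation of the antigen group
implies a cross-chain aligned-error block identically equal to the
translation norm), synthesizes point or binned PAE matrices as the true
aligned error plus truncated Gaussian noise, and generates score tables
whose DockQ distribution and confidence-DockQ rank correlation are
planted via a Gaussian copula.

Backbone geometry uses standard bond lengths and angles (N-CA 1.458 A,
CA-C 1.525 A, C-N 1.329 A) with per-geometry (phi, psi) torsions; all
generators are bit-reproducible given their arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import cos, radians, sin

import numpy as np
import pandas as pd
from scipy.stats import norm

from .frames_ae import AEMatrix
from .structure_io import (Chain, ComplexPartition, PaeInput, Residue,
                           StructureModel)

__all__ = [
    "EnsembleSpec",
    "GEOMETRY_TORSIONS",
    "make_toy_complex",
    "make_decoy",
    "synth_pae",
    "make_ensemble",
    "random_rotation",
]

# internal-coordinate constants (lengths in A, angles in degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.5
OMEGA = 180.0

#: (phi, psi) per chain geometry
GEOMETRY_TORSIONS = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
    "zigzag": (-120.0, 120.0),
}


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position of atom d given internal coordinates relative to a-b-c
    (NeRF extension)."""
    angle = radians(angle_deg)
    torsion = radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * cos(angle),
                        bond * sin(angle) * cos(torsion),
                        bond * sin(angle) * sin(torsion)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_chain_backbone(n_res: int, phi: float, psi: float) -> np.ndarray:
    """(n_res, 3, 3) array of N/CA/C positions for an ideal chain."""
    coords = np.zeros((n_res, 3, 3))
    # first residue placed canonically
    coords[0, 0] = np.array([0.0, 0.0, 0.0])                      # N
    coords[0, 1] = np.array([BOND_N_CA, 0.0, 0.0])                # CA
    ang = radians(ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array(
        [-cos(ang), sin(ang), 0.0])                               # C
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[i - 1]
        n_i = _place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi)
        ca_i = _place_atom(ca_prev, c_prev, n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = _place_atom(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        coords[i] = [n_i, ca_i, c_i]
    return coords


def _residue_from_backbone(number: int, aa: str, n_xyz: np.ndarray,
                           ca_xyz: np.ndarray, c_xyz: np.ndarray) -> Residue:
    heavy = [("N", n_xyz), ("CA", ca_xyz), ("C", c_xyz)]
    # carbonyl O at a fixed torsion: idealized placement, identical on both
    # sides of any comparison, which is all the backbone RMSDs need
    o = _place_atom(n_xyz, ca_xyz, c_xyz, BOND_C_O, ANGLE_CA_C_O, 0.0)
    heavy.append(("O", o))
    if aa != "G":
        cb = _place_atom(c_xyz, n_xyz, ca_xyz, BOND_CA_CB, ANGLE_N_CA_CB, 122.5)
        heavy.append(("CB", cb))
    return Residue(number, "", aa, np.array(ca_xyz), np.array(n_xyz),
                   np.array(c_xyz), [(nm, np.array(x)) for nm, x in heavy],
                   plddt=None)


def make_toy_complex(n_res_per_chain: list[int] | tuple[int, ...],
                     geometry: str = "helix", separation: float = 5.0,
                     seed: int = 0,
                     chain_ids: list[str] | None = None,
                     target_id: str = "toy") -> StructureModel:
    """Multi-chain toy complex with ideal backbone geometry.

    Chains are parallel copies of the same ideal-geometry backbone stacked
    along y with a gap of ``separation`` A between consecutive chains'
    bounding surfaces.  The random sequence of each chain is drawn from the
    seed; coordinates are deterministic.
    """
    if any(n < 4 for n in n_res_per_chain):
        raise ValueError("chains need at least 4 residues")
    if geometry not in GEOMETRY_TORSIONS:
        raise ValueError(f"unknown geometry {geometry!r}; "
                         f"choose from {sorted(GEOMETRY_TORSIONS)}")
    phi, psi = GEOMETRY_TORSIONS[geometry]
    rng = np.random.default_rng(seed)
    ids = chain_ids or [chr(ord("A") + i) for i in range(len(n_res_per_chain))]
    if len(ids) != len(n_res_per_chain):
        raise ValueError("chain_ids length must match n_res_per_chain")
    aa_pool = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    chains = []
    y_top = None
    for cid, n_res in zip(ids, n_res_per_chain):
        bb = _build_chain_backbone(n_res, phi, psi)
        # orient the chain's principal axis along x so parallel stacking in
        # y produces a closest approach equal to the requested separation
        flat = bb.reshape(-1, 3)
        center = flat.mean(axis=0)
        _, _, vt = np.linalg.svd(flat - center)
        axes = vt.T
        if np.linalg.det(axes) < 0:
            axes[:, 2] = -axes[:, 2]
        bb = (flat - center) @ axes
        bb = bb.reshape(n_res, 3, 3)
        seq = rng.choice(aa_pool, size=n_res)
        if y_top is not None:
            shift = y_top + separation - bb[:, :, 1].min()
            bb = bb + np.array([0.0, shift, 0.0])
        y_top = bb[:, :, 1].max()
        residues = []
        for i in range(n_res):
            residues.append(_residue_from_backbone(
                i + 1, str(seq[i]), bb[i, 0], bb[i, 1], bb[i, 2]))
        chains.append(Chain(cid, residues))
    return StructureModel(target_id, chains)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_decoy(reference: StructureModel, partition: ComplexPartition,
               rotation: np.ndarray | None = None,
               translation: np.ndarray | None = None,
               jitter_sigma: float = 0.0, seed: int = 0) -> StructureModel:
    """Decoy with a known rigid displacement of the antigen group.

    The antigen chains are moved by ``x -> R x + t`` and, optionally, all
    atoms receive isotropic Gaussian jitter.  With zero jitter and a pure
    translation the cross-group aligned-error block equals ||t|| exactly.
    """
    rot = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    trans = (np.zeros(3) if translation is None
             else np.asarray(translation, dtype=float))
    decoy = reference.transformed(rot, trans,
                                  chain_ids=sorted(partition.antigen_chain_ids))
    if jitter_sigma > 0:
        rng = np.random.default_rng(seed)
        for chain in decoy.chains:
            for res in chain.residues:
                jittered = [(name, xyz + rng.normal(0.0, jitter_sigma, 3))
                            for name, xyz in res.heavy_atoms]
                res.heavy_atoms = jittered
                by_name = dict(jittered)
                res.ca_xyz = by_name.get("CA", res.ca_xyz)
                res.n_xyz = by_name.get("N", res.n_xyz)
                res.c_xyz = by_name.get("C", res.c_xyz)
    return decoy


def synth_pae(true_ae: AEMatrix | np.ndarray, noise_sigma: float = 0.0,
              mode: str = "point", seed: int = 0) -> PaeInput:
    """Synthetic PAE calibrated on a true aligned-error matrix.

    Point mode adds zero-mean Gaussian noise truncated at zero (PAE is
    non-negative); binned mode places all probability mass in the bin of
    the noised value (values past 31.5 A fall in the open last bin).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    e = true_ae.e if isinstance(true_ae, AEMatrix) else np.asarray(true_ae,
                                                                   dtype=float)
    rng = np.random.default_rng(seed)
    noised = e + (rng.normal(0.0, noise_sigma, e.shape) if noise_sigma > 0
                  else 0.0)
    noised = np.maximum(noised, 0.0)
    np.fill_diagonal(noised, 0.0)
    if mode == "point":
        return PaeInput(mode="point", point_matrix=noised)
    if mode == "binned":
        n = e.shape[0]
        idx = np.minimum((noised / 0.5).astype(int), 63)
        probs = np.zeros((n, n, 64))
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        probs[ii, jj, idx] = 1.0
        return PaeInput(mode="binned", bin_probs=probs)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class EnsembleSpec:
    """Parameters of a planted score ensemble.

    The DockQ marginal is a two-mode logistic-normal mixture (a "good"
    mode and a "bad" mode, echoing ensembles where a minority of samples
    find the right interface), and the confidence column attains the
    requested Spearman correlation with DockQ through a Gaussian copula.
    """

    n_targets: int = 5
    models_per_target: int = 200
    good_fraction: float = 0.10
    good_mode: float = 0.80
    bad_mode: float = 0.05
    good_spread: float = 0.40   # sd in logit space
    bad_spread: float = 0.50
    confidence_dockq_correlation: float = 0.30
    seed: int = 0


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _mixture_quantile(u: np.ndarray, spec: EnsembleSpec) -> np.ndarray:
    """Quantile function of the logit-space Gaussian mixture, by grid
    inversion; strictly monotone, so ranks of u are preserved exactly."""
    mu_b, mu_g = _logit(spec.bad_mode), _logit(spec.good_mode)
    grid = np.linspace(min(mu_b, mu_g) - 8.0, max(mu_b, mu_g) + 8.0, 4001)
    cdf = ((1.0 - spec.good_fraction) * norm.cdf(grid, mu_b, spec.bad_spread)
           + spec.good_fraction * norm.cdf(grid, mu_g, spec.good_spread))
    w = np.interp(u, cdf, grid)
    return 1.0 / (1.0 + np.exp(-w))


def make_ensemble(spec: EnsembleSpec) -> pd.DataFrame:
    """Planted score table: one row per (target, model) with ``dockq`` and
    ``ranking_confidence`` columns.

    The confidence-DockQ Spearman correlation equals the requested value in
    population (Pearson correlation of the Gaussian copula is
    2 sin(pi rho_s / 6)); both marginals are strictly monotone transforms
    of the latent normals, so no rank information is lost.
    """
    rho_s = spec.confidence_dockq_correlation
    if not -1.0 <= rho_s <= 1.0:
        raise ValueError("confidence_dockq_correlation must be in [-1, 1]")
    if not 0.0 <= spec.good_fraction <= 1.0:
        raise ValueError("good_fraction must be in [0, 1]")
    rho_z = 2.0 * np.sin(np.pi * rho_s / 6.0)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for t in range(spec.n_targets):
        z1 = rng.normal(size=spec.models_per_target)
        z2 = rho_z * z1 + np.sqrt(1.0 - rho_z ** 2) * rng.normal(
            size=spec.models_per_target)
        dockq = _mixture_quantile(norm.cdf(z1), spec)
        confidence = norm.cdf(z2)
        for m in range(spec.models_per_target):
            rows.append({
                "target_id": f"T{t:03d}",
                "model_id": f"m{m:04d}",
                "dockq": float(dockq[m]),
                "ranking_confidence": float(confidence[m]),
            })
    return pd.DataFrame(rows)
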