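"""Structure and PAE input/output.

Reads predicted and experimental protein complex structures (PDB / mmCIF)
into a light-weight in-memory model that every scoring module consumes,
reads predicted-aligned-error (PAE) JSON files, and assigns chain roles
(antibody vs antigen) for interface scoring.

Only polymer amino-acid residues are retained; solvent, ligands and
nucleic acids are dropped.  Alternate locations are resolved to the
highest-occupancy atom.  Residues are identified by
``(chain_id, res_number, insertion_code)`` using author numbering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Residue",
    "Chain",
    "StructureModel",
    "ComplexPartition",
    "PaeInput",
    "StructureFormatError",
    "PaeFormatError",
    "read_structure",
    "write_pdb",
    "read_pae",
    "partition_complex",
    "PAE_BIN_EDGES",
    "PAE_BIN_MIDPOINTS",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: PAE distributions are discretized into 64 bins covering 0-31.5 A with a
#: 0.5 A width; the last bin is open-ended and is represented by its lower
#: edge + half a width (31.75 A).
PAE_BIN_EDGES = np.arange(0.0, 32.0, 0.5)
PAE_BIN_MIDPOINTS = PAE_BIN_EDGES + 0.25


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed."""


class PaeFormatError(ValueError):
    """Raised when a PAE payload is malformed."""


@dataclass
class Residue:
    """One amino-acid residue with backbone coordinates.

    ``n_xyz``/``c_xyz`` may be ``None`` when those backbone atoms are
    absent; such residues still participate in contact-based scores
    (via CA / heavy atoms) but carry no backbone frame.
    """

    res_number: int
    insertion_code: str
    aa: str
    ca_xyz: np.ndarray
    n_xyz: np.ndarray | None = None
    c_xyz: np.ndarray | None = None
    heavy_atoms: list[tuple[str, np.ndarray]] = field(default_factory=list)
    plddt: float | None = None

    @property
    def has_frame(self) -> bool:
        return self.n_xyz is not None and self.c_xyz is not None

    @property
    def key_tail(self) -> tuple[int, str]:
        return (self.res_number, self.insertion_code)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


ResidueKey = tuple[str, int, str]


@dataclass
class StructureModel:
    """A parsed complex: ordered chains of ordered residues."""

    target_id: str
    chains: list[Chain]
    source_format: str = "PDB"

    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def get_chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not in model {self.target_id!r}")

    def iter_residues(self) -> Iterator[tuple[str, Residue]]:
        for chain in self.chains:
            for res in chain.residues:
                yield chain.chain_id, res

    def residue_keys(self) -> list[ResidueKey]:
        return [(cid, r.res_number, r.insertion_code)
                for cid, r in self.iter_residues()]

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca_xyz for _, r in self.iter_residues()], dtype=float)

    def chain_index(self) -> np.ndarray:
        """Integer chain label per residue, in residue order."""
        labels = []
        for i, chain in enumerate(self.chains):
            labels.extend([i] * len(chain))
        return np.asarray(labels, dtype=int)

    def plddt_vector(self) -> np.ndarray:
        vals = [r.plddt if r.plddt is not None else np.nan
                for _, r in self.iter_residues()]
        return np.asarray(vals, dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    chain_ids: Sequence[str] | None = None) -> "StructureModel":
        """Return a copy with ``x -> R x + t`` applied to the selected chains
        (all chains when ``chain_ids`` is None)."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        selected = set(chain_ids) if chain_ids is not None else None

        def mv(x: np.ndarray | None) -> np.ndarray | None:
            return None if x is None else rotation @ x + translation

        new_chains = []
        for chain in self.chains:
            if selected is not None and chain.chain_id not in selected:
                new_res = [Residue(r.res_number, r.insertion_code, r.aa,
                                   np.array(r.ca_xyz), None if r.n_xyz is None else np.array(r.n_xyz),
                                   None if r.c_xyz is None else np.array(r.c_xyz),
                                   [(n, np.array(x)) for n, x in r.heavy_atoms],
                                   r.plddt)
                           for r in chain.residues]
            else:
                new_res = [Residue(r.res_number, r.insertion_code, r.aa,
                                   mv(r.ca_xyz), mv(r.n_xyz), mv(r.c_xyz),
                                   [(n, mv(x)) for n, x in r.heavy_atoms],
                                   r.plddt)
                           for r in chain.residues]
            new_chains.append(Chain(chain.chain_id, new_res))
        return StructureModel(self.target_id, new_chains, self.source_format)


@dataclass(frozen=True)
class ComplexPartition:
    """Chain-role assignment: antibody group vs (merged) antigen group."""

    antibody_chain_ids: frozenset[str]
    antigen_chain_ids: frozenset[str]

    def group_of(self, chain_id: str) -> str:
        if chain_id in self.antibody_chain_ids:
            return "antibody"
        if chain_id in self.antigen_chain_ids:
            return "antigen"
        raise KeyError(f"chain {chain_id!r} not in partition")

    def group_labels(self, model: StructureModel) -> np.ndarray:
        """0 for antibody residues, 1 for antigen residues, residue order."""
        out = []
        for chain in model.chains:
            out.extend([0 if chain.chain_id in self.antibody_chain_ids else 1]
                       * len(chain))
        return np.asarray(out, dtype=int)


@dataclass
class PaeInput:
    """Predicted aligned error, either a point matrix or a binned
    distribution over 64 half-Angstrom bins (0 to 31.5 A, last bin open).

    ``pae[i, j]`` is the expected error (A) in residue ``j``'s position when
    prediction and truth are aligned on residue ``i``'s frame.
    """

    mode: str  # "point" | "binned"
    point_matrix: np.ndarray | None = None
    bin_probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("point", "binned"):
            raise PaeFormatError(f"unknown PAE mode {self.mode!r}")
        if (self.point_matrix is None) == (self.bin_probs is None):
            raise PaeFormatError(
                "exactly one of point_matrix / bin_probs must be present")
        if self.point_matrix is not None:
            m = np.asarray(self.point_matrix, dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise PaeFormatError(f"PAE matrix must be square, got {m.shape}")
            if np.any(m < 0):
                raise PaeFormatError("PAE entries must be non-negative")
            self.point_matrix = m
        else:
            p = np.asarray(self.bin_probs, dtype=float)
            if p.ndim != 3 or p.shape[0] != p.shape[1] or p.shape[2] != 64:
                raise PaeFormatError(
                    f"binned PAE must be Nres x Nres x 64, got {p.shape}")
            sums = p.sum(axis=2)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                raise PaeFormatError("bin probabilities must each sum to 1")
            self.bin_probs = p

    @property
    def n_res(self) -> int:
        m = self.point_matrix if self.point_matrix is not None else self.bin_probs
        return m.shape[0]

    def expected_matrix(self) -> np.ndarray:
        """Point matrix, or the expectation of the binned distribution using
        bin midpoints (last bin represented by 31.75 A)."""
        if self.point_matrix is not None:
            return self.point_matrix
        return self.bin_probs @ PAE_BIN_MIDPOINTS


def _one_letter(resname: str) -> str | None:
    """One-letter code for standard amino acids, 'X' for non-standard
    amino acids, None for non-amino-acid residues."""
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return None
    code = info.one_letter_code.upper()
    return code if code in STANDARD_AA else "X"


def _pick_altlocs(residue: gemmi.Residue) -> dict[str, gemmi.Atom]:
    """Resolve alternate locations to the highest-occupancy atom per name."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = chosen.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            chosen[atom.name] = atom
    return chosen


def read_structure(path: str | Path, format: str = "auto", *,
                   target_id: str | None = None,
                   b_factor_is_plddt: bool = False) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    path : file path
    format : ``"auto"`` (detect from content/extension), ``"pdb"`` or
        ``"mmcif"``.
    target_id : identifier for the model; defaults to the file stem.
    b_factor_is_plddt : set True for predicted models whose B-factor column
        stores per-residue pLDDT.  Native B-factors are never interpreted as
        confidence unless the caller asserts this.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt_map = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format.lower()])
    except KeyError:
        raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path} contains no models")
    source_format = "mmCIF" if st.input_format == gemmi.CoorFormat.Mmcif else "PDB"
    st.setup_entities()
    model = st[0]

    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            aa = _one_letter(gres.name)
            if aa is None or gres.is_water():
                continue
            atoms = _pick_altlocs(gres)
            ca = atoms.get("CA")
            if ca is None or ca.element.is_hydrogen:
                continue
            heavy = [(a.name, np.array([a.pos.x, a.pos.y, a.pos.z]))
                     for a in atoms.values() if not a.element.is_hydrogen]

            def coord(name: str) -> np.ndarray | None:
                a = atoms.get(name)
                if a is None:
                    return None
                return np.array([a.pos.x, a.pos.y, a.pos.z])

            residues.append(Residue(
                res_number=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                aa=aa,
                ca_xyz=coord("CA"),
                n_xyz=coord("N"),
                c_xyz=coord("C"),
                heavy_atoms=heavy,
                plddt=float(ca.b_iso) if b_factor_is_plddt else None,
            ))
        if not residues:
            continue
        if not any(r.has_frame for r in residues):
            warnings.warn(
                f"chain {gchain.name!r} has no residue with a complete "
                "N/CA/C backbone; chain dropped")
            continue
        chains.append(Chain(gchain.name, residues))
    if not chains:
        raise StructureFormatError(f"{path}: no polymer chains with backbone")
    return StructureModel(target_id or path.stem, chains, source_format)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a :class:`StructureModel` to a PDB file (backbone + stored
    heavy atoms; pLDDT, when present, goes to the B-factor column)."""
    st = gemmi.Structure()
    st.name = model.target_id
    gm = gemmi.Model("1")
    for chain in model.chains:
        gc = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = _THREE_LETTER.get(res.aa, "UNK")
            gr.seqid = gemmi.SeqId(res.res_number, res.insertion_code or " ")
            names_seen = set()
            for name, xyz in res.heavy_atoms:
                if name in names_seen:
                    continue
                names_seen.add(name)
                atom = gemmi.Atom()
                atom.name = name
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.occ = 1.0
                atom.b_iso = res.plddt if res.plddt is not None else 0.0
                atom.element = gemmi.Element(name[0])
                gr.add_atom(atom)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    doc_path = Path(path)
    if doc_path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(doc_path))
    else:
        st.write_pdb(str(doc_path))


_THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK",
}


def read_pae(path: str | Path) -> PaeInput:
    """Read a PAE JSON file.

    Accepts the common dialects: a dict with key ``predicted_aligned_error``
    or ``pae`` holding a square matrix of Angstrom values (optionally wrapped
    in a one-element list), or a binned payload with key ``bin_probs``
    (Nres x Nres x 64 probabilities).
    """
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, list):
        if len(payload) != 1 or not isinstance(payload[0], dict):
            raise PaeFormatError(f"{path}: unrecognized PAE JSON layout")
        payload = payload[0]
    if not isinstance(payload, dict):
        raise PaeFormatError(f"{path}: unrecognized PAE JSON layout")
    if "bin_probs" in payload:
        return PaeInput(mode="binned", bin_probs=np.asarray(payload["bin_probs"],
                                                            dtype=float))
    for key in ("predicted_aligned_error", "pae"):
        if key in payload:
            matrix = np.asarray(payload[key], dtype=float)
            if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
                raise PaeFormatError(
                    f"{path}: PAE matrix must be square, got {matrix.shape}")
            return PaeInput(mode="point", point_matrix=matrix)
    raise PaeFormatError(
        f"{path}: no 'predicted_aligned_error', 'pae' or 'bin_probs' key")


def write_pae(pae: PaeInput, path: str | Path) -> None:
    """Write a PaeInput back to JSON (inverse of :func:`read_pae`)."""
    if pae.mode == "point":
        payload = {"predicted_aligned_error": pae.point_matrix.tolist()}
    else:
        payload = {"bin_probs": pae.bin_probs.tolist()}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def partition_complex(model: StructureModel, antibody_ids: Sequence[str],
                      antigen_ids: Sequence[str]) -> ComplexPartition:
    """Assign chain roles for interface scoring.

    The two sets must be disjoint and every id must exist in the model.
    Multi-chain antigens are treated downstream as a single merged entity.
    """
    ab = frozenset(antibody_ids)
    ag = frozenset(antigen_ids)
    if not ab or not ag:
        raise ValueError("both antibody and antigen chain sets must be non-empty")
    overlap = ab & ag
    if overlap:
        raise ValueError(f"chains {sorted(overlap)} assigned to both groups")
    known = set(model.chain_ids())
    missing = (ab | ag) - known
    if missing:
        raise KeyError(f"chains {sorted(missing)} not present in model "
                       f"{model.target_id!r}")
    return ComplexPartition(ab, ag)
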