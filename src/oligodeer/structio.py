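"""Structure I/O, residue correspondence, and rigid-body superposition.

Structures are thin wrappers around a :class:`biotite.structure.AtomArray`
(a structure-of-arrays atom container), read from and written to the fixed-
column PDB format. Superposition uses the closed-form Kabsch solution with
an iterative 2-sigma outlier rejection loop, the common protocol for
comparing homologous seven-transmembrane folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial import cKDTree

__all__ = [
    "Structure",
    "ResidueMapping",
    "SuperpositionResult",
    "read_pdb",
    "write_pdb",
    "align_sequences",
    "kabsch",
    "superpose_structures",
    "polar_contacts",
]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class StructureError(ValueError):
    """Raised for malformed or inconsistent structural input."""


@dataclass
class Structure:
    """Atomic model: one biotite AtomArray plus an identifier.

    Residues are addressed by (chain id, author residue number); only
    polymer residues with a CA atom participate in sequence-level analyses.
    HETATM records (waters, ligands, the retinal chromophore) are retained
    but flagged ``hetero``.
    """

    id: str
    atoms: bst.AtomArray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.atoms.coord)):
            raise StructureError(f"{self.id}: non-finite coordinates")

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.atoms.chain_id:
            seen.setdefault(str(c))
        return list(seen)

    def chain(self, chain_id: str) -> "Structure":
        mask = self.atoms.chain_id == chain_id
        if not mask.any():
            raise StructureError(f"{self.id}: no chain {chain_id!r}")
        return Structure(f"{self.id}:{chain_id}", self.atoms[mask])

    def polymer(self) -> "Structure":
        """Amino-acid residues only (drops waters/ligands)."""
        return Structure(self.id, self.atoms[~self.atoms.hetero])

    def residue_ids(self, chain_id: str) -> np.ndarray:
        """Author residue numbers of polymer residues with a CA atom."""
        a = self.atoms
        mask = (a.chain_id == chain_id) & ~a.hetero & (a.atom_name == "CA")
        return a.res_id[mask]

    def sequence(self, chain_id: str) -> str:
        a = self.atoms
        mask = (a.chain_id == chain_id) & ~a.hetero & (a.atom_name == "CA")
        return "".join(_THREE_TO_ONE.get(str(n), "X") for n in a.res_name[mask])

    def atom_coord(self, chain_id: str, res_id: int, atom_name: str) -> np.ndarray:
        a = self.atoms
        mask = (
            (a.chain_id == chain_id)
            & (a.res_id == int(res_id))
            & (a.atom_name == atom_name)
        )
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise StructureError(
                f"{self.id}: no atom {atom_name} in {chain_id}/{res_id}"
            )
        return self.atoms.coord[idx[0]].copy()

    def ca_coords(self, chain_id: str, res_ids=None) -> np.ndarray:
        a = self.atoms
        mask = (a.chain_id == chain_id) & ~a.hetero & (a.atom_name == "CA")
        sub = self.atoms[mask]
        if res_ids is None:
            return sub.coord.copy()
        by_id = {int(r): i for i, r in enumerate(sub.res_id)}
        try:
            rows = [by_id[int(r)] for r in res_ids]
        except KeyError as exc:
            raise StructureError(f"{self.id}: residue {exc} has no CA") from exc
        return sub.coord[rows].copy()

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        out = self.atoms.copy()
        out.coord = self.atoms.coord @ np.asarray(rotation).T + translation
        return Structure(self.id, out)


@dataclass
class ResidueMapping:
    """Ordered one-to-one residue correspondence between two chains.

    ``pairs`` holds ((chain_a, res_a), (chain_b, res_b)) tuples in sequence
    order; injective in both directions by construction from an alignment.
    """

    pairs: list[tuple[tuple[str, int], tuple[str, int]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def identity(cls, chain_a: str, res_ids_a, chain_b: str, res_ids_b) -> "ResidueMapping":
        return cls([
            ((chain_a, int(ra)), (chain_b, int(rb)))
            for ra, rb in zip(res_ids_a, res_ids_b)
        ])


@dataclass
class SuperpositionResult:
    """Optimal rigid transform y ~ R x + t with its RMSD bookkeeping."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs_used: int
    rejected_pairs: list = field(default_factory=list)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def read_pdb(path, model_index: int = 1, altloc_policy: str = "first") -> Structure:
    """Read one model from a PDB file.

    altloc policy "first" keeps a single conformer per atom (the
    highest-occupancy one, ties broken by altloc letter); "occupancy" is an
    alias. Waters and ligands are retained as hetero atoms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if altloc_policy not in ("first", "occupancy"):
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    _validate_coordinate_lines(path)
    pdb = PDBFile.read(str(path))
    try:
        atoms = pdb.get_structure(
            model=model_index, altloc="occupancy", extra_fields=["occupancy"]
        )
    except Exception as exc:  # biotite raises on empty / malformed models
        raise StructureError(f"{path.name}: {exc}") from exc
    if atoms.array_length() == 0:
        raise StructureError(f"{path.name}: model {model_index} is empty")
    return Structure(path.stem, atoms)


def _validate_coordinate_lines(path: Path) -> None:
    n_atom = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(("ATOM  ", "HETATM")):
                n_atom += 1
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except (ValueError, IndexError):
                    raise StructureError(
                        f"{path.name}: malformed coordinate on line {lineno}"
                    ) from None
    if n_atom == 0:
        raise StructureError(f"{path.name}: no ATOM records")


def write_pdb(s: Structure, path) -> None:
    pdb = PDBFile()
    pdb.set_structure(s.atoms)
    pdb.write(str(path))


_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


def align_sequences(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    """Global (Needleman-Wunsch-Gotoh) alignment of two amino-acid sequences.

    BLOSUM62, gap open -10, gap extend -1. Returns aligned non-gap column
    pairs as 0-based sequence indices; wrap into a :class:`ResidueMapping`
    with actual residue numbers via :func:`map_chains`.
    """
    for seq in (seq_a, seq_b):
        if not seq:
            raise ValueError("empty sequence")
        bad = set(seq) - _AA_ALPHABET
        if bad:
            raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def map_chains(a: Structure, chain_a: str, b: Structure, chain_b: str) -> ResidueMapping:
    """Alignment-derived residue correspondence between two chains."""
    idx_pairs = align_sequences(a.sequence(chain_a), b.sequence(chain_b))
    res_a = a.residue_ids(chain_a)
    res_b = b.residue_ids(chain_b)
    return ResidueMapping([
        ((chain_a, int(res_a[i])), (chain_b, int(res_b[j])))
        for i, j in idx_pairs
    ])


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Closed-form least-RMSD rigid superposition of a onto b.

    SVD of the cross-covariance with the determinant sign correction that
    forbids reflections (smallest singular direction flipped if needed).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cb - rot @ ca
    moved = a @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    return SuperpositionResult(rot, trans, rmsd, n)


def superpose_structures(
    mobile: Structure,
    reference: Structure,
    mapping: ResidueMapping,
    atom_set: str = "CA",
    max_cycles: int = 5,
    sigma_cutoff: float = 2.0,
) -> SuperpositionResult:
    """Iterative outlier-rejecting superposition over mapped residues.

    A full Kabsch fit, then pairs whose residual exceeds ``sigma_cutoff``
    standard deviations are dropped and the fit repeated, up to
    ``max_cycles`` cycles or until the retained set is stable.
    """
    if atom_set not in ("CA", "backbone"):
        raise ValueError(f"atom_set must be CA or backbone, got {atom_set!r}")
    if len(mapping) == 0:
        raise ValueError("empty residue mapping")
    names = ("CA",) if atom_set == "CA" else ("N", "CA", "C", "O")
    xa, xb, tags = [], [], []
    for (ch_a, ra), (ch_b, rb) in mapping.pairs:
        try:
            pa = [mobile.atom_coord(ch_a, ra, nm) for nm in names]
            pb = [reference.atom_coord(ch_b, rb, nm) for nm in names]
        except StructureError:
            continue
        xa.append(pa)
        xb.append(pb)
        tags.append(((ch_a, ra), (ch_b, rb)))
    xa = np.asarray(xa, dtype=float)  # (n_pairs, n_names, 3)
    xb = np.asarray(xb, dtype=float)
    keep = np.ones(len(tags), dtype=bool)
    result = None
    for _ in range(max_cycles):
        if keep.sum() < 3:
            raise ValueError("fewer than 3 residue pairs survive rejection")
        result = kabsch(
            xa[keep].reshape(-1, 3), xb[keep].reshape(-1, 3)
        )
        moved = xa @ result.rotation.T + result.translation
        resid = np.sqrt(np.mean(np.sum((moved - xb) ** 2, axis=2), axis=1))
        # absolute floor: residuals below coordinate precision are never
        # outliers, and a perfect fit must not reject anything
        thresh = max(
            resid[keep].mean() + sigma_cutoff * resid[keep].std(), 0.1
        )
        new_keep = keep & (resid <= thresh)
        if new_keep.sum() < 3 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    result.n_pairs_used = int(keep.sum()) * len(names)
    result.rejected_pairs = [t for t, k in zip(tags, keep) if not k]
    # rmsd over the retained pairs only
    moved = xa[keep].reshape(-1, 3) @ result.rotation.T + result.translation
    result.rmsd = float(
        np.sqrt(np.mean(np.sum((moved - xb[keep].reshape(-1, 3)) ** 2, axis=1)))
    )
    return result


def polar_contacts(s: Structure, cutoff: float = 3.5):
    """All N/O--N/O atom pairs from distinct residues within ``cutoff`` (Å).

    Returned sorted by distance as ((chain, res, atom), (chain, res, atom),
    distance) triples; waters count as residues.
    """
    if not 2.0 < cutoff < 6.0:
        raise ValueError("cutoff must lie in (2.0, 6.0) Å")
    a = s.atoms
    mask = np.isin(a.element, ("N", "O"))
    sub = a[mask]
    if sub.array_length() == 0:
        return []
    tree = cKDTree(sub.coord)
    out = []
    for i, j in tree.query_pairs(cutoff):
        if (sub.chain_id[i], sub.res_id[i]) == (sub.chain_id[j], sub.res_id[j]):
            continue
        d = float(np.linalg.norm(sub.coord[i] - sub.coord[j]))
        key_i = (str(sub.chain_id[i]), int(sub.res_id[i]), str(sub.atom_name[i]))
        key_j = (str(sub.chain_id[j]), int(sub.res_id[j]), str(sub.atom_name[j]))
        out.append((key_i, key_j, d))
    out.sort(key=lambda t: t[2])
    return out
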