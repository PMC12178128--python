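"""Protein structure data model and PDB/FASTA input-output.

The in-memory model is deliberately minimal: per-residue coordinates for the
five atoms the template encoding needs (N, CA, C, O, CB), a per-atom presence
mask, and a one-letter sequence. Decoys from heterogeneous sources carry
inconsistent residue numbering, so residues are re-indexed 0..L-1 on read and
metrics align purely by position; the original author numbering is not kept.
"""

from __future__ import annotations

import dataclasses
import io
import os
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

#: Canonical atom order for the per-residue coordinate array.
ATOM_NAMES: tuple[str, ...] = ("N", "CA", "C", "O", "CB")
ATOM_INDEX: dict[str, int] = {name: i for i, name in enumerate(ATOM_NAMES)}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
_ONE_TO_THREE["X"] = "UNK"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class PDBFormatError(ValueError):
    """Raised when the input contains no parsable ATOM records."""


class ChainNotFoundError(KeyError):
    """Raised when the requested chain is absent from the file."""


@dataclasses.dataclass
class ProteinStructure:
    """A single-chain protein backbone (+Cβ) with explicit atom presence.

    Attributes
    ----------
    residue_ids : (L,) int array, strictly increasing within the chain.
    sequence : length-L string over the 20 amino-acid letters plus 'X'.
    coords : (L, 5, 3) float array of positions in Å, atom order
        ``ATOM_NAMES``; absent atoms hold NaN and must never be read.
    atom_mask : (L, 5) bool array, True where the atom is present/resolved.
    chain_id : single chain identifier.
    """

    residue_ids: np.ndarray
    sequence: str
    coords: np.ndarray
    atom_mask: np.ndarray
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        self.atom_mask = np.asarray(self.atom_mask, dtype=bool)
        L = len(self.sequence)
        if self.coords.shape != (L, 5, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} inconsistent with sequence length {L}"
            )
        if self.atom_mask.shape != (L, 5):
            raise ValueError("atom_mask shape inconsistent with sequence length")
        if self.residue_ids.shape != (L,):
            raise ValueError("residue_ids length inconsistent with sequence length")
        if L > 1 and not np.all(np.diff(self.residue_ids) > 0):
            raise ValueError("residue_ids must be strictly increasing")
        if not np.all(np.isfinite(self.coords[self.atom_mask])):
            raise ValueError("present atoms must have finite coordinates")
        bad = set(self.sequence) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValueError(f"sequence contains invalid letters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    # -- convenience accessors ------------------------------------------------

    def atom_coords(self, name: str) -> np.ndarray:
        """(L, 3) coordinates of one atom type; NaN where absent."""
        return self.coords[:, ATOM_INDEX[name], :]

    def atom_present(self, name: str) -> np.ndarray:
        return self.atom_mask[:, ATOM_INDEX[name]]

    @property
    def ca(self) -> np.ndarray:
        return self.atom_coords("CA")

    def copy(self) -> "ProteinStructure":
        return ProteinStructure(
            residue_ids=self.residue_ids.copy(),
            sequence=self.sequence,
            coords=self.coords.copy(),
            atom_mask=self.atom_mask.copy(),
            chain_id=self.chain_id,
        )

    def subset(self, idx: np.ndarray) -> "ProteinStructure":
        """Structure restricted to residue positions ``idx`` (re-indexed)."""
        idx = np.asarray(idx, dtype=int)
        return ProteinStructure(
            residue_ids=np.arange(len(idx)),
            sequence="".join(self.sequence[i] for i in idx),
            coords=self.coords[idx],
            atom_mask=self.atom_mask[idx],
            chain_id=self.chain_id,
        )


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties (and the common all-1.00 case) keep the
    # first atom seen in file order
    best = atoms[0]
    for atom in atoms[1:]:
        if atom.occ > best.occ:
            best = atom
    return best


def read_pdb(text_or_path: str | os.PathLike | io.IOBase,
             chain_selector: str | None = None) -> ProteinStructure:
    """Read one chain of a PDB file into a :class:`ProteinStructure`.

    Parameters
    ----------
    text_or_path : PDB-format text, a path to a ``.pdb`` file, or a text
        stream. Only the first MODEL is read.
    chain_selector : chain identifier; ``None`` selects the first chain that
        contains a CA atom.

    Notes
    -----
    Atoms other than N/CA/C/O/CB are dropped; alternate locations resolve to
    the highest-occupancy conformer (first seen on ties); residues are kept in
    file order with insertion-coded residues folded into the sequential
    numbering; non-standard residues map to ``'X'`` with their backbone kept.
    """
    if isinstance(text_or_path, io.IOBase):
        text = text_or_path.read()
    else:
        s = str(text_or_path)
        if "\n" in s or not os.path.exists(s):
            text = s if "\n" in s else None
            if text is None:
                raise FileNotFoundError(s)
        else:
            text = Path(s).read_text()
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"unparsable PDB input: {exc}") from None
    if len(st) == 0:
        raise PDBFormatError("no models in PDB input")
    model = st[0]

    chains_with_ca = []
    for chain in model:
        if any(res.find_atom("CA", "*") for res in chain):
            chains_with_ca.append(chain.name)
    if not chains_with_ca:
        raise PDBFormatError("no parsable ATOM records with CA atoms")
    if chain_selector is None:
        chain_name = chains_with_ca[0]
    else:
        if chain_selector not in [c.name for c in model]:
            raise ChainNotFoundError(
                f"chain {chain_selector!r} not in {[c.name for c in model]}"
            )
        chain_name = chain_selector
    chain = model[chain_name]

    residues = []
    for res in chain:
        if res.name in ("HOH", "WAT", "DOD"):
            continue
        by_name: dict[str, list[gemmi.Atom]] = {}
        for atom in res:
            if atom.name in ATOM_INDEX:
                by_name.setdefault(atom.name, []).append(atom)
        if not by_name:
            continue
        residues.append((res.name, by_name))
    if not residues:
        raise PDBFormatError(f"chain {chain_name!r} has no backbone atoms")

    L = len(residues)
    coords = np.full((L, 5, 3), np.nan)
    mask = np.zeros((L, 5), dtype=bool)
    seq = []
    for i, (resname, by_name) in enumerate(residues):
        seq.append(_THREE_TO_ONE.get(resname, "X"))
        for name, atoms in by_name.items():
            atom = _pick_altloc(atoms)
            j = ATOM_INDEX[name]
            coords[i, j] = (atom.pos.x, atom.pos.y, atom.pos.z)
            mask[i, j] = True

    return ProteinStructure(
        residue_ids=np.arange(L),
        sequence="".join(seq),
        coords=coords,
        atom_mask=mask,
        chain_id=chain_name,
    )


def write_pdb(structure: ProteinStructure,
              bfactors: Sequence[float] | None = None) -> str:
    """Render a structure as PDB ATOM records (present atoms only).

    ``bfactors`` optionally supplies one per-residue value written into the
    B-factor column — the conventional slot for per-residue confidence.
    """
    if bfactors is not None and len(bfactors) != len(structure):
        raise ValueError("bfactors length must equal structure length")
    lines = []
    serial = 1
    for i in range(len(structure)):
        resname = _ONE_TO_THREE.get(structure.sequence[i], "UNK")
        b = 0.0 if bfactors is None else float(bfactors[i])
        for j, name in enumerate(ATOM_NAMES):
            if not structure.atom_mask[i, j]:
                continue
            x, y, z = structure.coords[i, j]
            element = name[0]
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} {structure.chain_id:1s}"
                f"{i + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
    lines.append(f"TER   {serial:5d}      {_ONE_TO_THREE.get(structure.sequence[-1], 'UNK'):>3s} "
                 f"{structure.chain_id:1s}{len(structure):4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_fasta(text_or_path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file (single- or multi-record) into {id: sequence}."""
    from Bio import SeqIO

    s = str(text_or_path)
    if "\n" in s or s.startswith(">"):
        handle: io.IOBase = io.StringIO(s)
    else:
        handle = open(s)
    with handle:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
    if not records:
        raise ValueError("no FASTA records found")
    return records
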