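"""Sequence-free template encoding of a candidate structure.

A decoy is handed to the predictor as a *template*: a one-hot amino-acid row
per residue (all gap tokens by default, so the decoy's sequence identity is
hidden), a Cβ–Cβ distance matrix, and backbone dihedrals with validity masks.
Side chains beyond Cβ are removed before featurization, and glycines — which
have no Cβ — receive a virtual one built from ideal tetrahedral geometry, so
the distance matrix is defined everywhere the backbone is resolved.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from foldcritic.structure_io import ATOM_INDEX, AMINO_ACIDS, ProteinStructure

#: The 22-token template alphabet: 20 amino acids, unknown, gap. This ordering
#: is the single source of truth inside the package; predictor adapters that
#: need a different internal ordering translate at their boundary.
TEMPLATE_ALPHABET: str = AMINO_ACIDS + "X-"
UNKNOWN_INDEX: int = TEMPLATE_ALPHABET.index("X")
GAP_INDEX: int = TEMPLATE_ALPHABET.index("-")
N_TOKENS: int = len(TEMPLATE_ALPHABET)

# ideal virtual-Cβ internal coordinates (L-amino-acid chirality)
CBETA_BOND_LENGTH = 1.522       # Å, CA–CB
CBETA_BOND_ANGLE = np.deg2rad(110.4)   # N–CA–CB
CBETA_DIHEDRAL = np.deg2rad(122.6)     # C–N–CA–CB torsion


class GeometryError(ValueError):
    """Raised when atom positions are too degenerate to define a frame."""


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Natural-extension placement: position d such that |cd| = bond,
    angle(b, c, d) = angle and dihedral(a, b, c, d) = dihedral."""
    bc = c - b
    nbc = np.linalg.norm(bc)
    ab = b - a
    if nbc < 1e-6 or np.linalg.norm(ab) < 1e-6:
        raise GeometryError("coincident atoms cannot define a frame")
    bc = bc / nbc
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-6:
        raise GeometryError("collinear atoms cannot define a frame")
    n = n / nn
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(angle),
        np.sin(angle) * np.cos(dihedral),
        -np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def virtual_cbeta(n_pos: np.ndarray, ca_pos: np.ndarray, c_pos: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral Cβ position from the backbone frame of one residue.

    Bond length 1.522 Å, angle N–CA–CB 110.4°, dihedral chosen so the Cβ sits
    on the L-amino-acid side of the backbone plane.
    """
    n_pos = np.asarray(n_pos, dtype=float)
    ca_pos = np.asarray(ca_pos, dtype=float)
    c_pos = np.asarray(c_pos, dtype=float)
    if not (np.all(np.isfinite(n_pos)) and np.all(np.isfinite(ca_pos))
            and np.all(np.isfinite(c_pos))):
        raise GeometryError("backbone positions must be finite")
    return _place_atom(c_pos, n_pos, ca_pos,
                       CBETA_BOND_LENGTH, CBETA_BOND_ANGLE, CBETA_DIHEDRAL)


def mask_to_backbone(structure: ProteinStructure) -> ProteinStructure:
    """Reduce a structure to backbone + Cβ, virtualizing missing Cβ atoms.

    Wherever N, CA and C are all present and Cβ is not — glycines in
    particular — an ideal Cβ is constructed with :func:`virtual_cbeta`.
    Experimentally observed Cβ positions are never overwritten. Residues
    lacking a complete N/CA/C frame keep their Cβ absent.
    """
    out = structure.copy()
    i_n, i_ca, i_c, i_cb = (ATOM_INDEX[a] for a in ("N", "CA", "C", "CB"))
    for i in range(len(out)):
        if out.atom_mask[i, i_cb]:
            continue
        if out.atom_mask[i, i_n] and out.atom_mask[i, i_ca] and out.atom_mask[i, i_c]:
            try:
                cb = virtual_cbeta(out.coords[i, i_n], out.coords[i, i_ca],
                                   out.coords[i, i_c])
            except GeometryError:
                continue
            out.coords[i, i_cb] = cb
            out.atom_mask[i, i_cb] = True
    return out


def gap_sequence(length: int) -> np.ndarray:
    """(length, 22) one-hot matrix with every row at the gap token."""
    if length < 1:
        raise ValueError("length must be >= 1")
    onehot = np.zeros((length, N_TOKENS))
    onehot[:, GAP_INDEX] = 1.0
    return onehot


def encode_sequence(sequence: str) -> np.ndarray:
    """(L, 22) one-hot encoding of an amino-acid string ('X' allowed)."""
    onehot = np.zeros((len(sequence), N_TOKENS))
    for i, letter in enumerate(sequence):
        onehot[i, TEMPLATE_ALPHABET.index(letter)] = 1.0
    return onehot


def decode_onehot(onehot: np.ndarray) -> str:
    return "".join(TEMPLATE_ALPHABET[j] for j in np.argmax(onehot, axis=1))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle (rad) of four points, IUPAC sign convention."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    return float(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))


@dataclasses.dataclass
class TemplateFeatures:
    """The predictor-facing template encoding.

    Attributes
    ----------
    aatype_onehot : (L, 22) one-hot rows over :data:`TEMPLATE_ALPHABET`.
    cbeta_distance_matrix : (L, L) Cβ–Cβ distances in Å; NaN where invalid.
    pair_mask : (L, L) bool, True where both residues contribute a valid Cβ
        (or CA under the fallback).
    torsions : (L, 3, 2) backbone dihedrals φ, ψ, ω as (sin, cos) pairs.
    torsion_mask : (L, 3) bool; False at termini and wherever a defining
        atom is absent. Side-chain torsion slots are not carried at all:
        side chains were removed, so the encoding marks them invalid by
        construction.
    atom_mask : (L, 5) atom presence copied from the featurized structure.
    """

    aatype_onehot: np.ndarray
    cbeta_distance_matrix: np.ndarray
    pair_mask: np.ndarray
    torsions: np.ndarray
    torsion_mask: np.ndarray
    atom_mask: np.ndarray
    #: The structure the features were computed from, when available. Not part
    #: of the predictor-facing encoding and never serialized; mock predictors
    #: use it to return the template as their output structure.
    source_structure: ProteinStructure | None = None

    def __len__(self) -> int:
        return self.aatype_onehot.shape[0]

    def validate(self) -> None:
        L = len(self)
        assert self.aatype_onehot.shape == (L, N_TOKENS)
        np.testing.assert_allclose(self.aatype_onehot.sum(axis=1), 1.0)
        assert self.cbeta_distance_matrix.shape == (L, L)
        d = self.cbeta_distance_matrix
        valid = self.pair_mask
        assert np.allclose(d[valid], d.T[valid])
        assert np.all(np.abs(np.diag(d)[np.diag(valid)]) < 1e-9)
        norm = np.sum(self.torsions ** 2, axis=-1)
        assert np.all(np.abs(norm[self.torsion_mask] - 1.0) < 1e-9)

    # -- flat-container serialization ----------------------------------------

    _FIELDS = ("aatype_onehot", "cbeta_distance_matrix", "pair_mask",
               "torsions", "torsion_mask", "atom_mask")

    def save(self, directory: str | Path) -> None:
        """Write per-field ``.npy`` arrays plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"length": len(self), "alphabet": TEMPLATE_ALPHABET, "fields": {}}
        for name in self._FIELDS:
            arr = getattr(self, name)
            np.save(directory / f"{name}.npy", arr)
            manifest["fields"][name] = {"shape": list(arr.shape), "dtype": str(arr.dtype)}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "TemplateFeatures":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        if manifest["alphabet"] != TEMPLATE_ALPHABET:
            raise ValueError("template alphabet mismatch")
        arrays = {name: np.load(directory / f"{name}.npy") for name in cls._FIELDS}
        return cls(**arrays)


def featurize_template(structure: ProteinStructure, sequence_mode: str = "gap",
                       ca_fallback: bool = False) -> TemplateFeatures:
    """Encode a backbone-reduced structure as template features.

    ``sequence_mode='gap'`` (the default) hides the decoy's amino-acid
    identity behind gap tokens; ``'native'`` exposes the real sequence — the
    control that reproduces sequence-identity-induced overconfidence in
    predictors. ``ca_fallback`` substitutes CA for residues whose Cβ cannot
    be virtualized instead of flagging their pairs invalid.
    """
    if sequence_mode not in ("gap", "native"):
        raise ValueError("sequence_mode must be 'gap' or 'native'")
    st = structure
    L = len(st)
    i_n, i_ca, i_c, i_cb = (ATOM_INDEX[a] for a in ("N", "CA", "C", "CB"))

    point_ok = st.atom_mask[:, i_cb].copy()
    points = st.coords[:, i_cb].copy()
    if ca_fallback:
        fallback = ~point_ok & st.atom_mask[:, i_ca]
        points[fallback] = st.coords[fallback, i_ca]
        point_ok |= fallback
    if point_ok.sum() < 2:
        raise ValueError("need at least 2 residues with a usable Cβ/CA point")

    pair_mask = point_ok[:, None] & point_ok[None, :]
    dmat = np.full((L, L), np.nan)
    safe = np.where(point_ok[:, None], points, 0.0)
    dists = np.linalg.norm(safe[:, None, :] - safe[None, :, :], axis=-1)
    dmat[pair_mask] = dists[pair_mask]

    if sequence_mode == "gap":
        aatype = gap_sequence(L)
    else:
        aatype = encode_sequence(st.sequence)

    torsions = np.zeros((L, 3, 2))
    torsion_mask = np.zeros((L, 3), dtype=bool)
    has = st.atom_mask

    def _coord(i: int, j: int) -> np.ndarray:
        return st.coords[i, j]

    for i in range(L):
        # phi_i: C(i-1) - N(i) - CA(i) - C(i)
        if i > 0 and has[i - 1, i_c] and has[i, i_n] and has[i, i_ca] and has[i, i_c]:
            ang = dihedral(_coord(i - 1, i_c), _coord(i, i_n), _coord(i, i_ca),
                           _coord(i, i_c))
            torsions[i, 0] = (np.sin(ang), np.cos(ang))
            torsion_mask[i, 0] = True
        # psi_i: N(i) - CA(i) - C(i) - N(i+1)
        if i < L - 1 and has[i, i_n] and has[i, i_ca] and has[i, i_c] and has[i + 1, i_n]:
            ang = dihedral(_coord(i, i_n), _coord(i, i_ca), _coord(i, i_c),
                           _coord(i + 1, i_n))
            torsions[i, 1] = (np.sin(ang), np.cos(ang))
            torsion_mask[i, 1] = True
        # omega_i: peptide bond preceding residue i: CA(i-1) - C(i-1) - N(i) - CA(i)
        if i > 0 and has[i - 1, i_ca] and has[i - 1, i_c] and has[i, i_n] and has[i, i_ca]:
            ang = dihedral(_coord(i - 1, i_ca), _coord(i - 1, i_c), _coord(i, i_n),
                           _coord(i, i_ca))
            torsions[i, 2] = (np.sin(ang), np.cos(ang))
            torsion_mask[i, 2] = True

    return TemplateFeatures(
        aatype_onehot=aatype,
        cbeta_distance_matrix=dmat,
        pair_mask=pair_mask,
        torsions=torsions,
        torsion_mask=torsion_mask,
        atom_mask=st.atom_mask.copy(),
        source_structure=st,
    )
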