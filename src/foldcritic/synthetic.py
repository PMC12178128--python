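"""Toy natives and decoy ladders with known quality.

The decoy-ranking protocol needs, for testing, a native structure plus a set
of candidate structures spanning a wide quality range — a desk-scale stand-in
for large public decoy sets. Natives are idealized backbones built in torsion
space with standard bond geometry; decoys are generated by perturbing the
native at a ladder of noise scales, so each decoy's true quality is known by
construction and decreases (stochastically) with its rung's noise level.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from foldcritic.rng import stable_seed
from foldcritic.structure_io import AMINO_ACIDS, ATOM_INDEX, ProteinStructure
from foldcritic.template_features import GeometryError, _place_atom, dihedral, virtual_cbeta

# ideal backbone internal coordinates (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

HELIX_PHI, HELIX_PSI = -57.0, -47.0
SHEET_PHI, SHEET_PSI = -120.0, 130.0

TOPOLOGIES = ("helix", "helix_hairpin", "random_compact")


class GenerationError(RuntimeError):
    """Raised when self-avoiding sampling fails within its retry budget."""


def build_backbone(phi: np.ndarray, psi: np.ndarray, omega: np.ndarray,
                   sequence: str) -> ProteinStructure:
    """Build an all-backbone structure from torsions (degrees) by chain
    extension with ideal bond lengths and angles. ``phi[0]`` and ``omega[0]``
    are unused (undefined at the N terminus), ``psi[-1]`` is used only to
    place the final carbonyl oxygen."""
    L = len(sequence)
    phi = np.deg2rad(np.asarray(phi, dtype=float))
    psi = np.deg2rad(np.asarray(psi, dtype=float))
    omega = np.deg2rad(np.asarray(omega, dtype=float))
    if not (len(phi) == len(psi) == len(omega) == L):
        raise ValueError("torsion arrays must match sequence length")

    coords = np.full((L, 5, 3), np.nan)
    i_n, i_ca, i_c, i_o, i_cb = (ATOM_INDEX[a] for a in ("N", "CA", "C", "O", "CB"))

    # first residue in a canonical local frame
    ang = np.deg2rad(ANGLE_N_CA_C)
    coords[0, i_n] = (0.0, 0.0, 0.0)
    coords[0, i_ca] = (BOND_N_CA, 0.0, 0.0)
    coords[0, i_c] = coords[0, i_ca] + BOND_CA_C * np.array(
        [-np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, L):
        n_prev, ca_prev, c_prev = coords[i - 1, i_n], coords[i - 1, i_ca], coords[i - 1, i_c]
        coords[i, i_n] = _place_atom(n_prev, ca_prev, c_prev, BOND_C_N,
                                     np.deg2rad(ANGLE_CA_C_N), psi[i - 1])
        coords[i, i_ca] = _place_atom(ca_prev, c_prev, coords[i, i_n], BOND_N_CA,
                                      np.deg2rad(ANGLE_C_N_CA), omega[i])
        coords[i, i_c] = _place_atom(c_prev, coords[i, i_n], coords[i, i_ca], BOND_CA_C,
                                     np.deg2rad(ANGLE_N_CA_C), phi[i])

    for i in range(L):
        # carbonyl O is anti to the next amide nitrogen (psi + pi)
        coords[i, i_o] = _place_atom(coords[i, i_n], coords[i, i_ca], coords[i, i_c],
                                     BOND_C_O, np.deg2rad(ANGLE_CA_C_O), psi[i] + np.pi)
        coords[i, i_cb] = virtual_cbeta(coords[i, i_n], coords[i, i_ca], coords[i, i_c])

    mask = np.ones((L, 5), dtype=bool)
    return ProteinStructure(residue_ids=np.arange(L), sequence=sequence,
                            coords=coords, atom_mask=mask, chain_id="A")


def measure_torsions(structure: ProteinStructure) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(phi, psi, omega) in degrees from coordinates; undefined entries hold
    the idealized defaults so the arrays can be fed back to build_backbone."""
    L = len(structure)
    i_n, i_ca, i_c = (ATOM_INDEX[a] for a in ("N", "CA", "C"))
    co = structure.coords
    phi = np.full(L, HELIX_PHI)
    psi = np.full(L, HELIX_PSI)
    omega = np.full(L, 180.0)
    for i in range(L):
        if i > 0:
            phi[i] = np.rad2deg(dihedral(co[i - 1, i_c], co[i, i_n], co[i, i_ca], co[i, i_c]))
            omega[i] = np.rad2deg(dihedral(co[i - 1, i_ca], co[i - 1, i_c], co[i, i_n],
                                           co[i, i_ca]))
        if i < L - 1:
            psi[i] = np.rad2deg(dihedral(co[i, i_n], co[i, i_ca], co[i, i_c],
                                         co[i + 1, i_n]))
    return phi, psi, omega


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _nonneighbor_min_dist_ok(ca: np.ndarray, new_idx: int, cutoff: float = 3.5) -> bool:
    if new_idx < 2:
        return True
    d = np.linalg.norm(ca[: new_idx - 1] - ca[new_idx], axis=1)
    return bool(np.all(d >= cutoff))


def make_toy_native(length: int, topology: str = "helix", seed: int = 0) -> ProteinStructure:
    """Build an idealized native structure.

    topology:
      - ``helix``: a single α-helix (φ = −57°, ψ = −47°, ω = 180°).
      - ``helix_hairpin``: two helices joined by a short turn.
      - ``random_compact``: torsion-space self-avoiding sampling over
        helix/sheet basins with CA–CA clash rejection at 3.5 Å.

    Deterministic per (length, topology, seed).
    """
    if length < 8:
        raise ValueError("length must be >= 8")
    if topology not in TOPOLOGIES:
        raise ValueError(f"topology must be one of {TOPOLOGIES}")
    rng = np.random.default_rng(stable_seed("native", topology, length, seed))
    sequence = _random_sequence(length, rng)

    if topology == "helix":
        phi = np.full(length, HELIX_PHI)
        psi = np.full(length, HELIX_PSI)
        omega = np.full(length, 180.0)
        return build_backbone(phi, psi, omega, sequence)

    if topology == "helix_hairpin":
        phi = np.full(length, HELIX_PHI)
        psi = np.full(length, HELIX_PSI)
        omega = np.full(length, 180.0)
        turn = [( -60.0, 140.0), (75.0, 10.0), (-90.0, 0.0), (-75.0, 140.0)]
        mid = length // 2 - len(turn) // 2
        for k, (tphi, tpsi) in enumerate(turn):
            if 0 < mid + k < length:
                phi[mid + k] = tphi
                psi[mid + k] = tpsi
        return build_backbone(phi, psi, omega, sequence)

    # random_compact: grow residue by residue, resampling torsions on clash
    basins = [(HELIX_PHI, HELIX_PSI, 8.0), (SHEET_PHI, SHEET_PSI, 12.0),
              (-75.0, 150.0, 10.0)]
    max_restarts = 40
    for _ in range(max_restarts):
        phi = np.full(length, HELIX_PHI)
        psi = np.full(length, HELIX_PSI)
        omega = np.full(length, 180.0)
        st = build_backbone(phi[:2], psi[:2], omega[:2], sequence[:2])
        ca = np.zeros((length, 3))
        ca[:2] = st.ca
        ok = True
        for i in range(2, length):
            placed = False
            for _attempt in range(60):
                c_phi, c_psi, width = basins[rng.integers(len(basins))]
                phi[i] = c_phi + rng.normal(0.0, width)
                psi[i - 1] = c_psi + rng.normal(0.0, width)
                st = build_backbone(phi[: i + 1], psi[: i + 1], omega[: i + 1],
                                    sequence[: i + 1])
                ca[i] = st.ca[i]
                if _nonneighbor_min_dist_ok(ca, i):
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return build_backbone(phi, psi, omega, sequence)
    raise GenerationError("self-avoiding sampling failed within the retry budget")


def perturb_structure(structure: ProteinStructure, sigma: float,
                      mode: str = "cartesian_smooth", seed: int = 0,
                      smooth_window: int = 5) -> ProteinStructure:
    """Degrade a structure by a controlled amount of noise.

    ``cartesian_smooth`` adds per-residue Gaussian displacements (std
    ``sigma`` Å per coordinate) smoothed along the chain with a flat window,
    so local bond geometry degrades gracefully with sigma rather than being
    destroyed outright. ``torsion`` jitters φ/ψ by Gaussian(0, sigma degrees)
    and rebuilds the chain with ideal geometry. Cβ atoms are re-virtualized
    from the perturbed backbone in both modes. Deterministic per seed.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if mode not in ("cartesian_smooth", "torsion"):
        raise ValueError("mode must be 'cartesian_smooth' or 'torsion'")
    rng = np.random.default_rng(stable_seed("perturb", mode, seed))
    out = structure.copy()
    if sigma == 0:
        return out
    L = len(out)
    i_n, i_ca, i_c, i_cb = (ATOM_INDEX[a] for a in ("N", "CA", "C", "CB"))

    if mode == "cartesian_smooth":
        noise = rng.normal(0.0, 1.0, size=(L, 3))
        w = smooth_window
        kernel = np.ones(w) / w
        pad = w // 2
        padded = np.pad(noise, ((pad, pad), (0, 0)), mode="edge")
        smoothed = np.empty_like(noise)
        for k in range(3):
            smoothed[:, k] = np.convolve(padded[:, k], kernel, mode="valid")[:L]
        # restore unit variance lost to averaging, then scale to sigma
        smoothed *= sigma / np.sqrt(np.sum(kernel ** 2))
        out.coords = out.coords + smoothed[:, None, :]
    else:
        phi, psi, omega = measure_torsions(out)
        phi = phi + rng.normal(0.0, sigma, size=L)
        psi = psi + rng.normal(0.0, sigma, size=L)
        rebuilt = build_backbone(phi, psi, omega, out.sequence)
        out.coords = rebuilt.coords
        out.atom_mask = np.ones((L, 5), dtype=bool)

    for i in range(L):
        if out.atom_mask[i, i_n] and out.atom_mask[i, i_ca] and out.atom_mask[i, i_c]:
            try:
                out.coords[i, i_cb] = virtual_cbeta(out.coords[i, i_n],
                                                    out.coords[i, i_ca],
                                                    out.coords[i, i_c])
                out.atom_mask[i, i_cb] = True
            except GeometryError:
                out.atom_mask[i, i_cb] = False
                out.coords[i, i_cb] = np.nan
    return out


@dataclasses.dataclass
class DecoyLadderSpec:
    """Recipe for a decoy set of known, graded quality."""

    native_length: int = 40
    sigmas: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 2.0)
    n_per_sigma: int = 10
    mode: str = "cartesian_smooth"
    seed: int = 0
    topology: str = "helix_hairpin"

    def __post_init__(self) -> None:
        sig = tuple(float(s) for s in self.sigmas)
        if any(s < 0 for s in sig):
            raise ValueError("sigmas must be >= 0")
        if list(sig) != sorted(set(sig)):
            raise ValueError("sigmas must be strictly increasing")
        if self.n_per_sigma < 1:
            raise ValueError("n_per_sigma must be >= 1")
        self.sigmas = sig


def make_decoy_ladder(spec: DecoyLadderSpec,
                      native: ProteinStructure | None = None,
                      ) -> tuple[ProteinStructure, list[tuple[str, ProteinStructure, float]]]:
    """Generate (native, decoys) where decoys is a list of
    ``(decoy_id, structure, sigma)``. Each decoy gets an independent sub-seed
    derived from (spec.seed, rung, index); the σ = 0 rung reproduces the
    unperturbed native."""
    if native is None:
        native = make_toy_native(spec.native_length, spec.topology, spec.seed)
    decoys = []
    for rung, sigma in enumerate(spec.sigmas):
        for j in range(spec.n_per_sigma):
            sub = stable_seed(spec.seed, rung, j)
            decoy = perturb_structure(native, sigma, spec.mode, seed=sub)
            decoy_id = f"decoy_r{rung}_s{sigma:g}_{j:03d}"
            decoys.append((decoy_id, decoy, sigma))
    return native, decoys
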