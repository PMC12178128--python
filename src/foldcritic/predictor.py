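"""The structure-predictor contract and desk-scale mock implementations.

Every downstream protocol — decoy scoring, ranking, generator–discriminator
search, sequence design — talks to a :class:`Predictor`: give it a target
sequence and (optionally) template features, get back a predicted structure,
per-residue pLDDT, a global pTM and a distogram. Two mocks make the whole
pipeline runnable without network weights:

* :class:`GeometryMockPredictor` scores templates by backbone plausibility
  (virtual CA–CA bond-length regularity and steric clashes) — a crude,
  sequence-blind stand-in for a learned energy that still ranks noisy decoys
  correctly.
* :class:`OracleMockPredictor` holds a hidden native structure and emits
  confidences equal to the true quality of the template (pLDDT from lDDT,
  pTM from TM-score) — the pipeline-correctness oracle.

Planted-signal mocks (:class:`PlantedDesignMock`,
:class:`PlantedGeneratorMock`) hide a target sequence and respond more
confidently the closer the query gets to it; they give the optimization loops
a recoverable signal with a known answer.
"""

from __future__ import annotations

import abc
import dataclasses

import numpy as np

from foldcritic.metrics import lddt, tm_score
from foldcritic.rng import stable_seed
from foldcritic.structure_io import AMINO_ACIDS, ProteinStructure
from foldcritic.synthetic import make_toy_native, perturb_structure
from foldcritic.template_features import TemplateFeatures, mask_to_backbone

IDEAL_CA_CA = 3.8   # Å, trans-peptide virtual bond
CLASH_CUTOFF = 3.5  # Å


class CapabilityError(RuntimeError):
    """A predictor was asked for something it cannot provide."""


# -- distogram bin layout -----------------------------------------------------
# Default: 64 bins, first edge 2.3125 Å, last edge 21.6875 Å, final bin open.

N_BINS = 64
FIRST_EDGE = 2.3125
LAST_EDGE = 21.6875


def distogram_bin_edges(n_bins: int = N_BINS, first: float = FIRST_EDGE,
                        last: float = LAST_EDGE) -> np.ndarray:
    """The n_bins − 1 internal edges; bin 0 is (−inf, first), the final bin
    is [last, inf)."""
    return np.linspace(first, last, n_bins - 1)


def distance_to_bin(distances: np.ndarray, edges: np.ndarray | None = None) -> np.ndarray:
    if edges is None:
        edges = distogram_bin_edges()
    return np.digitize(np.asarray(distances, dtype=float), edges)


def bin_centers(edges: np.ndarray | None = None) -> np.ndarray:
    """Representative distance per bin (outer bins use the adjacent edge
    offset by half a step)."""
    if edges is None:
        edges = distogram_bin_edges()
    step = edges[1] - edges[0]
    inner = (edges[:-1] + edges[1:]) / 2
    return np.concatenate([[edges[0] - step / 2], inner, [edges[-1] + step / 2]])


@dataclasses.dataclass
class PredictorOutput:
    """What a predictor returns for one query."""

    structure: ProteinStructure
    plddt_per_residue: np.ndarray
    ptm: float
    distogram: np.ndarray           # (L, L, B), rows normalized
    num_recycles_used: int = 1

    def validate(self) -> None:
        L = len(self.structure)
        assert self.plddt_per_residue.shape == (L,)
        assert np.all((self.plddt_per_residue >= 0) & (self.plddt_per_residue <= 100))
        assert 0.0 <= self.ptm <= 1.0
        assert self.distogram.shape[:2] == (L, L)
        sums = self.distogram.sum(axis=-1)
        assert np.all(np.abs(sums - 1.0) < 1e-6)

    @property
    def plddt_mean(self) -> float:
        return float(np.mean(self.plddt_per_residue))


class Predictor(abc.ABC):
    """Contract: deterministic given (inputs, seed); output satisfies the
    :class:`PredictorOutput` invariants and preserves the target length."""

    name: str = "predictor"

    @abc.abstractmethod
    def predict(self, target_sequence: str, template: TemplateFeatures | None = None,
                num_recycles: int = 1, seed: int = 0) -> PredictorOutput:
        ...

    def _check_inputs(self, target_sequence: str,
                      template: TemplateFeatures | None) -> None:
        bad = set(target_sequence) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValueError(f"invalid sequence letters: {sorted(bad)}")
        if template is not None and len(template) != len(target_sequence):
            raise ValueError(
                f"template length {len(template)} != sequence length {len(target_sequence)}"
            )


def _template_structure(template: TemplateFeatures) -> ProteinStructure:
    st = getattr(template, "source_structure", None)
    if st is None:
        raise CapabilityError(
            "mock predictors need template features carrying their source "
            "structure (produce them with featurize_template)"
        )
    return st


def geometry_mock_confidence(structure: ProteinStructure) -> tuple[np.ndarray, float]:
    """Backbone-plausibility confidence: per-residue
    p_i = 100 exp(−(dev_i / 0.5)²) with dev_i the mean |CA–CA − 3.8 Å| over
    the residue's virtual bonds, multiplied by (1 − clash fraction) where a
    clash is a non-neighbor (|i − j| > 2) CA pair closer than 3.5 Å; pTM is a
    rescaled logistic of the mean p."""
    ca = structure.ca
    present = structure.atom_present("CA")
    L = len(structure)
    dev = np.zeros(L)
    counts = np.zeros(L)
    for i in range(L - 1):
        if present[i] and present[i + 1]:
            d = np.linalg.norm(ca[i + 1] - ca[i])
            e = abs(d - IDEAL_CA_CA)
            dev[i] += e
            dev[i + 1] += e
            counts[i] += 1
            counts[i + 1] += 1
    mean_dev = np.where(counts > 0, dev / np.maximum(counts, 1), 0.0)
    p = 100.0 * np.exp(-((mean_dev / 0.5) ** 2))

    # clash penalty over non-neighbor pairs
    idx = np.flatnonzero(present)
    n_pairs = 0
    n_clash = 0
    if len(idx) > 3:
        x = ca[idx]
        dm = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
        sep = np.abs(idx[:, None] - idx[None, :])
        sel = sep > 2
        n_pairs = int(sel.sum()) // 2
        n_clash = int(((dm < CLASH_CUTOFF) & sel).sum()) // 2
    clash_frac = n_clash / n_pairs if n_pairs else 0.0
    p = p * (1.0 - clash_frac)

    x = float(np.mean(p)) / 100.0
    k = 8.0
    lo = 1.0 / (1.0 + np.exp(k / 2))
    hi = 1.0 / (1.0 + np.exp(-k / 2))
    raw = 1.0 / (1.0 + np.exp(-k * (x - 0.5)))
    ptm = float((raw - lo) / (hi - lo))
    return p, min(1.0, max(0.0, ptm))


def _gaussian_distogram(structure: ProteinStructure, width: float,
                        edges: np.ndarray | None = None) -> np.ndarray:
    """Rows are Gaussians over bin centers around the structure's Cβ
    distances; pairs without a valid Cβ get a uniform row."""
    if edges is None:
        edges = distogram_bin_edges()
    centers = bin_centers(edges)
    bb = mask_to_backbone(structure)
    cb = bb.atom_coords("CB")
    ok = bb.atom_present("CB")
    L = len(structure)
    B = len(centers)
    safe = np.where(ok[:, None], cb, 0.0)
    dm = np.linalg.norm(safe[:, None, :] - safe[None, :, :], axis=-1)
    logits = -((centers[None, None, :] - dm[:, :, None]) ** 2) / (2 * width ** 2)
    dist = np.exp(logits - logits.max(axis=-1, keepdims=True))
    dist /= dist.sum(axis=-1, keepdims=True)
    invalid = ~(ok[:, None] & ok[None, :])
    dist[invalid] = 1.0 / B
    return dist


class GeometryMockPredictor(Predictor):
    """Scores a template by backbone plausibility; no learned weights.

    With a template, the output structure is the template itself (no
    refinement — this isolates scoring-pipeline correctness). Without one, a
    sequence-seeded jittered helix stands in for a de-novo guess, so the
    candidate depends deterministically on the input sequence.
    """

    name = "geometry-mock"

    def __init__(self, distogram_base_width: float = 0.4,
                 distogram_extra_width: float = 4.0):
        self.base_width = distogram_base_width
        self.extra_width = distogram_extra_width

    def predict(self, target_sequence: str, template: TemplateFeatures | None = None,
                num_recycles: int = 1, seed: int = 0) -> PredictorOutput:
        self._check_inputs(target_sequence, template)
        if template is not None:
            structure = _template_structure(template).copy()
        else:
            helix = make_toy_native(max(len(target_sequence), 8), "helix",
                                    seed=stable_seed("geomock", seed))
            structure = perturb_structure(
                helix, 0.3, "cartesian_smooth",
                seed=stable_seed("geomock-jitter", target_sequence, seed))
        plddt, ptm = geometry_mock_confidence(structure)
        width = self.base_width + self.extra_width * (1.0 - float(np.mean(plddt)) / 100.0)
        distogram = _gaussian_distogram(structure, width)
        return PredictorOutput(structure=structure, plddt_per_residue=plddt,
                               ptm=ptm, distogram=distogram,
                               num_recycles_used=num_recycles)


class OracleMockPredictor(Predictor):
    """Holds a hidden native; confidences equal the template's true quality.

    pLDDT is 100 × the per-residue lDDT of the template against the native,
    pTM its TM-score, and the distogram puts probability one on the bin of
    each native Cβ distance. Requires a template.
    """

    name = "oracle-mock"

    def __init__(self, hidden_native: ProteinStructure):
        self._native = mask_to_backbone(hidden_native)
        self._edges = distogram_bin_edges()
        self._native_distogram: np.ndarray | None = None

    def _make_native_distogram(self) -> np.ndarray:
        cb = self._native.atom_coords("CB")
        ok = self._native.atom_present("CB")
        L = len(self._native)
        safe = np.where(ok[:, None], cb, 0.0)
        dm = np.linalg.norm(safe[:, None, :] - safe[None, :, :], axis=-1)
        bins = distance_to_bin(dm, self._edges)
        dist = np.zeros((L, L, N_BINS))
        ii, jj = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
        dist[ii, jj, bins] = 1.0
        invalid = ~(ok[:, None] & ok[None, :])
        dist[invalid] = 1.0 / N_BINS
        return dist

    def predict(self, target_sequence: str, template: TemplateFeatures | None = None,
                num_recycles: int = 1, seed: int = 0) -> PredictorOutput:
        self._check_inputs(target_sequence, template)
        if template is None:
            raise CapabilityError("the oracle mock requires a template")
        structure = _template_structure(template).copy()
        if len(structure) != len(self._native):
            raise ValueError("template length does not match the hidden native")
        global_lddt, per_res = lddt(structure, self._native)
        per_res = np.where(np.isnan(per_res), global_lddt, per_res)
        plddt = 100.0 * np.clip(per_res, 0.0, 1.0)
        ptm = tm_score(structure, self._native)
        if self._native_distogram is None:
            self._native_distogram = self._make_native_distogram()
        return PredictorOutput(structure=structure, plddt_per_residue=plddt,
                               ptm=ptm, distogram=self._native_distogram,
                               num_recycles_used=num_recycles)


def oracle_mock(hidden_native: ProteinStructure) -> OracleMockPredictor:
    """Construct the pipeline-correctness oracle around a hidden native."""
    return OracleMockPredictor(hidden_native)


def _match_fraction(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(x == y for x, y in zip(a[:n], b[:n])) / n


class PlantedDesignMock(Predictor):
    """Synthetic design landscape: the distogram sharpens around the template
    distances as the query sequence approaches a hidden target sequence.

    The distogram width shrinks strictly with the match fraction m, so the
    cross-entropy against the template distances strictly decreases with every
    correctly recovered position — a hill-climbable landscape whose optimum is
    the hidden sequence.
    """

    name = "planted-design-mock"

    def __init__(self, hidden_sequence: str, min_width: float = 0.25,
                 max_width: float = 3.0):
        self._hidden = hidden_sequence
        self.min_width = min_width
        self.max_width = max_width

    def predict(self, target_sequence: str, template: TemplateFeatures | None = None,
                num_recycles: int = 1, seed: int = 0) -> PredictorOutput:
        self._check_inputs(target_sequence, template)
        if template is None:
            raise CapabilityError("the planted design mock requires a template")
        structure = _template_structure(template).copy()
        m = _match_fraction(target_sequence, self._hidden)
        width = self.max_width + (self.min_width - self.max_width) * m
        distogram = _gaussian_distogram(structure, width)
        plddt = np.full(len(structure), 50.0 + 50.0 * m)
        return PredictorOutput(structure=structure, plddt_per_residue=plddt,
                               ptm=0.5 + 0.5 * m, distogram=distogram,
                               num_recycles_used=num_recycles)


class PlantedGeneratorMock(Predictor):
    """Synthetic generator: emits the hidden native perturbed by noise whose
    scale shrinks as the input sequence approaches a planted key sequence.

    The noise realization is deterministic per (sequence, seed), so the
    generator–discriminator search sees a reproducible but rugged landscape.
    """

    name = "planted-generator-mock"

    def __init__(self, hidden_native: ProteinStructure, key_sequence: str,
                 sigma_max: float = 3.0, sigma_min: float = 0.25):
        self._native = hidden_native
        self._key = key_sequence
        self.sigma_max = sigma_max
        self.sigma_min = sigma_min

    def predict(self, target_sequence: str, template: TemplateFeatures | None = None,
                num_recycles: int = 1, seed: int = 0) -> PredictorOutput:
        self._check_inputs(target_sequence, template)
        m = _match_fraction(target_sequence, self._key)
        sigma = self.sigma_max + (self.sigma_min - self.sigma_max) * m
        structure = perturb_structure(
            self._native, sigma, "cartesian_smooth",
            seed=stable_seed("planted-gen", target_sequence, seed))
        plddt, ptm = geometry_mock_confidence(structure)
        distogram = _gaussian_distogram(structure, 1.0)
        return PredictorOutput(structure=structure, plddt_per_residue=plddt,
                               ptm=ptm, distogram=distogram,
                               num_recycles_used=num_recycles)


class AlphaFoldAdapter(Predictor):
    """Contract stub for driving a real AlphaFold installation.

    The adapter's responsibilities, when backed by a working installation:
    translate :data:`~foldcritic.template_features.TEMPLATE_ALPHABET` one-hot
    rows into the network's internal residue-type ordering, pack the Cβ
    distance matrix and torsion channels into the template stack (a single
    template), run the selected model with the configured number of recycling
    iterations (default 1), and pass through pLDDT, pTM and the distogram
    head unchanged. Which pTM variant of the weights to use is a
    configuration choice (``model_name``); no default is endorsed.

    This class only defines the contract; constructing it without the
    optional runtime raises :class:`CapabilityError`.
    """

    name = "alphafold-adapter"

    def __init__(self, model_name: str = "model_1", num_recycles: int = 1):
        self.model_name = model_name
        self.num_recycles = num_recycles
        try:
            import alphafold  # noqa: F401
        except ImportError as exc:
            raise CapabilityError(
                "the AlphaFold runtime is not installed; use a mock predictor"
            ) from exc

    def predict(self, target_sequence: str, template: TemplateFeatures | None = None,
                num_recycles: int = 1, seed: int = 0) -> PredictorOutput:
        raise CapabilityError("AlphaFold adapter is a contract stub")


PREDICTOR_REGISTRY = {
    "geometry-mock": GeometryMockPredictor,
    "alphafold-adapter": AlphaFoldAdapter,
}
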