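"""The composite confidence score and the per-decoy scoring protocol.

A decoy is judged by querying the predictor with the target sequence and the
decoy's sequence-free template features, then multiplying three factors:

    composite = (mean pLDDT / 100) × pTM × TM(decoy, predicted structure)

The pLDDT and pTM factors express the predictor's confidence in its output;
the TM factor discounts confidence the predictor spent on an output that
drifted away from the decoy actually being scored, so the product remains an
estimate of *the decoy's* quality.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from foldcritic.metrics import gdt_ts, tm_score
from foldcritic.predictor import Predictor, PredictorOutput
from foldcritic.structure_io import ProteinStructure
from foldcritic.template_features import featurize_template, mask_to_backbone


@dataclasses.dataclass
class ScoringConfig:
    """Protocol knobs for scoring a decoy.

    sequence_mode : 'gap' hides the decoy sequence behind gap tokens (the
        default protocol); 'native' supplies the decoy's real sequence — the
        control that demonstrates sequence-identity-induced overconfidence.
    num_recycles : recycling iterations requested from the predictor.
    plddt_aggregation : how per-residue pLDDT collapses to the scalar factor;
        'mean' is the community convention.
    """

    sequence_mode: str = "gap"
    num_recycles: int = 1
    plddt_aggregation: str = "mean"
    ca_fallback: bool = False
    seed: int = 0


@dataclasses.dataclass
class DecoyRecord:
    """One decoy's scored identity; ``composite`` always equals the product
    of its three logged factors."""

    decoy_id: str
    composite: float
    plddt_mean: float
    ptm: float
    tm_decoy_vs_output: float
    true_tm: float | None = None
    true_gdt_ts: float | None = None

    def __post_init__(self) -> None:
        expected = (self.plddt_mean / 100.0) * self.ptm * self.tm_decoy_vs_output
        if abs(self.composite - expected) > 1e-9:
            raise ValueError("composite does not equal the product of its factors")


def _aggregate_plddt(plddt: np.ndarray, how: str) -> float:
    if how == "mean":
        return float(np.mean(plddt))
    if how == "median":
        return float(np.median(plddt))
    raise ValueError(f"unknown plddt aggregation {how!r}")


def composite_score(output: PredictorOutput, decoy: ProteinStructure,
                    plddt_aggregation: str = "mean") -> tuple[float, dict[str, float]]:
    """Composite confidence of a predictor output for a given decoy.

    Returns ``(composite, factors)`` where factors holds the three terms
    separately. TM is normalized by the decoy/target length.
    """
    if len(output.structure) != len(decoy):
        raise ValueError("decoy and predictor output must have equal length")
    plddt = _aggregate_plddt(output.plddt_per_residue, plddt_aggregation)
    tm = tm_score(decoy, output.structure, normalize_length=len(decoy))
    factors = {"plddt_mean": plddt, "ptm": float(output.ptm),
               "tm_decoy_vs_output": tm}
    return (plddt / 100.0) * output.ptm * tm, factors


def score_decoy(predictor: Predictor, target_sequence: str,
                decoy: ProteinStructure, native: ProteinStructure | None = None,
                config: ScoringConfig | None = None,
                decoy_id: str = "decoy") -> DecoyRecord:
    """Run the full scoring protocol for one decoy.

    Stages: reduce the decoy to backbone + (virtual) Cβ, featurize it as a
    sequence-free template, query the predictor with the target sequence, and
    combine the confidence outputs into the composite score. When a native
    structure is supplied the record also carries the decoy's true TM-score
    and GDT_TS. Stage failures are re-raised labeled with the decoy id.
    """
    config = config or ScoringConfig()
    if len(decoy) != len(target_sequence):
        raise ValueError(
            f"{decoy_id}: decoy length {len(decoy)} != sequence length {len(target_sequence)}"
        )
    try:
        backbone = mask_to_backbone(decoy)
        features = featurize_template(backbone, sequence_mode=config.sequence_mode,
                                      ca_fallback=config.ca_fallback)
    except Exception as exc:
        raise type(exc)(f"{decoy_id}: featurization failed: {exc}") from exc
    try:
        output = predictor.predict(target_sequence, features,
                                   num_recycles=config.num_recycles,
                                   seed=config.seed)
    except Exception as exc:
        raise type(exc)(f"{decoy_id}: prediction failed: {exc}") from exc
    composite, factors = composite_score(output, backbone,
                                         plddt_aggregation=config.plddt_aggregation)
    true_tm = true_gdt = None
    if native is not None:
        true_tm = tm_score(backbone, native)
        true_gdt = gdt_ts(backbone, native)
    return DecoyRecord(decoy_id=decoy_id, composite=composite,
                       plddt_mean=factors["plddt_mean"], ptm=factors["ptm"],
                       tm_decoy_vs_output=factors["tm_decoy_vs_output"],
                       true_tm=true_tm, true_gdt_ts=true_gdt)
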