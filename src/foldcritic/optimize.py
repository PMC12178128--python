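"""Optimization loops over the predictor contract.

Two application protocols share the same machinery:

* **Fixed-backbone sequence design** — the desired backbone goes in as a
  sequence-free template, and the input sequence is optimized to minimize the
  categorical cross-entropy between the predictor's distogram and the
  template's Cβ distances. The cross-entropy is a surrogate for the composite
  confidence: when the predictor is unsure, its distance distributions widen
  and the cross-entropy grows, so minimizing it also concentrates confidence —
  without differentiating through the TM-score's iterative alignment.
* **Structure prediction by generator–discriminator search** — a generator
  predictor maps a mutable input sequence to a candidate structure; the
  candidate is featurized as a gap-sequence template and handed to a
  discriminator predictor, whose composite confidence is the search objective.

Both default to a discrete hill-climb (mutate, evaluate, keep on strict
improvement), which needs nothing from the predictor beyond the base
contract. A gradient engine is defined at the interface level only: it
requires the predictor to expose ``objective_gradient(sequence_logits, ...)``,
a capability only a differentiable network adapter can provide.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from foldcritic.predictor import (
    CapabilityError,
    Predictor,
    distance_to_bin,
    distogram_bin_edges,
)
from foldcritic.rng import stable_seed
from foldcritic.scoring import composite_score
from foldcritic.structure_io import AMINO_ACIDS, ProteinStructure
from foldcritic.template_features import encode_sequence, featurize_template, mask_to_backbone

PROB_FLOOR = 1e-12


def distogram_cross_entropy(distogram: np.ndarray, target_cbeta_distances: np.ndarray,
                            pair_mask: np.ndarray | None = None,
                            bin_edges: np.ndarray | None = None) -> float:
    """Mean categorical cross-entropy of a distogram against target distances.

    Each target distance is assigned to its bin (the open final bin catches
    everything beyond the last edge); the loss is the mean of
    −log p(target bin) over masked pairs, with probabilities floored at 1e−12.
    """
    distogram = np.asarray(distogram, dtype=float)
    target = np.asarray(target_cbeta_distances, dtype=float)
    L = target.shape[0]
    if distogram.shape[:2] != (L, L):
        raise ValueError("distogram and target distance matrix disagree in size")
    if pair_mask is None:
        pair_mask = np.isfinite(target)
    pair_mask = np.asarray(pair_mask, dtype=bool) & np.isfinite(target)
    if not pair_mask.any():
        raise ValueError("no valid pairs to score")
    if bin_edges is None:
        bin_edges = distogram_bin_edges(distogram.shape[-1])
    bins = distance_to_bin(target[pair_mask], bin_edges)
    probs = distogram[pair_mask, bins]
    return float(np.mean(-np.log(np.maximum(probs, PROB_FLOOR))))


@dataclasses.dataclass
class DesignState:
    """Snapshot of a design trajectory; ``best_loss`` never increases."""

    sequence_logits: np.ndarray
    step: int
    best_loss: float
    best_sequence: str
    rng_seed: int


@dataclasses.dataclass
class OptimizeConfig:
    """Shared knobs for the hill-climb engines.

    steps : proposal budget (0 evaluates the starting point only).
    k_mutations : positions mutated per proposal.
    engine : 'hill_climb' or 'gradient' (gradient requires a predictor
        capability and is adapter-only).
    flat_patience : consecutive no-change proposals before the landscape is
        declared flat and the search stops early.
    """

    steps: int = 1000
    k_mutations: int = 1
    engine: str = "hill_climb"
    num_recycles: int = 1
    seed: int = 0
    flat_patience: int = 30
    initial_sequence: str | None = None


@dataclasses.dataclass
class DesignResult:
    best_sequence: str
    best_loss: float
    trajectory: list[DesignState]
    flat_landscape: bool
    steps_run: int


@dataclasses.dataclass
class SearchResult:
    best_structure: ProteinStructure
    best_objective: float
    objective_trajectory: list[float]
    best_trajectory: list[float]
    steps_run: int


def _mutate(sequence: str, k: int, rng: np.random.Generator) -> str:
    seq = list(sequence)
    positions = rng.choice(len(seq), size=min(k, len(seq)), replace=False)
    for pos in positions:
        seq[pos] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
    return "".join(seq)


def _check_engine(predictor: Predictor, config: OptimizeConfig) -> None:
    if config.engine == "hill_climb":
        return
    if config.engine == "gradient":
        if not hasattr(predictor, "objective_gradient"):
            raise CapabilityError(
                "gradient engine requires a predictor exposing objective_gradient"
            )
        raise CapabilityError("gradient engine is adapter-only and not wired here")
    raise ValueError(f"unknown engine {config.engine!r}")


def design_sequence(predictor: Predictor, target_backbone: ProteinStructure,
                    config: OptimizeConfig | None = None) -> DesignResult:
    """Fixed-backbone sequence design by distogram cross-entropy descent.

    The backbone is featurized once (gap tokens, side chains masked); every
    proposed sequence is evaluated by querying the predictor with the fixed
    template and scoring its distogram against the template's Cβ distances.
    The best sequence seen is kept; acceptance requires strict improvement.
    If the first ``flat_patience`` proposals all leave the loss unchanged the
    landscape is flat (the predictor's distogram ignores the sequence) and
    the search reports that instead of spinning.
    """
    config = config or OptimizeConfig()
    _check_engine(predictor, config)
    frame_ok = target_backbone.atom_mask[:, :3].all(axis=1)
    if frame_ok.mean() < 0.9:
        raise ValueError("target backbone needs N, CA, C for >= 90% of residues")
    backbone = mask_to_backbone(target_backbone)
    template = featurize_template(backbone, sequence_mode="gap")
    target_d = template.cbeta_distance_matrix
    sep = np.abs(np.arange(len(backbone))[:, None] - np.arange(len(backbone))[None, :])
    pair_mask = template.pair_mask & (sep >= 1)

    rng = np.random.default_rng(stable_seed("design", config.seed))
    L = len(backbone)
    if config.initial_sequence is not None:
        seq = config.initial_sequence
        if len(seq) != L:
            raise ValueError("initial_sequence length must match the backbone")
    else:
        seq = "".join(AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=L))

    def evaluate(s: str) -> float:
        out = predictor.predict(s, template, num_recycles=config.num_recycles,
                                seed=config.seed)
        return distogram_cross_entropy(out.distogram, target_d, pair_mask)

    best_loss = evaluate(seq)
    best_seq = seq
    trajectory = [DesignState(encode_sequence(seq)[:, :20], 0, best_loss, seq,
                              config.seed)]
    unchanged = 0
    flat = False
    step = 0
    for step in range(1, config.steps + 1):
        proposal = _mutate(best_seq, config.k_mutations, rng)
        loss = evaluate(proposal)
        if loss < best_loss:
            best_loss = loss
            best_seq = proposal
            unchanged = 0
        elif abs(loss - best_loss) < 1e-12:
            unchanged += 1
        else:
            unchanged = 0
        trajectory.append(DesignState(encode_sequence(best_seq)[:, :20], step,
                                      best_loss, best_seq, config.seed))
        if unchanged >= config.flat_patience and step == unchanged:
            # every proposal so far left the loss identical: flat landscape
            flat = True
            break
    return DesignResult(best_sequence=best_seq, best_loss=best_loss,
                        trajectory=trajectory, flat_landscape=flat,
                        steps_run=step)


def fold_by_search(generator_predictor: Predictor, discriminator_predictor: Predictor,
                   target_sequence: str,
                   config: OptimizeConfig | None = None) -> SearchResult:
    """Structure prediction by generator–discriminator search.

    A mutable generator input sequence (initialized to the target sequence)
    is hill-climbed: the generator predicts a candidate structure from it
    (no template), the candidate is featurized as a gap-sequence template,
    and the discriminator's composite confidence for the target sequence
    given that template is the objective. With ``steps = 0`` the result is
    the single-pass baseline.
    """
    config = config or OptimizeConfig()
    _check_engine(discriminator_predictor, config)
    rng = np.random.default_rng(stable_seed("fold-search", config.seed))

    def evaluate(gen_input: str, step: int) -> tuple[float, ProteinStructure]:
        try:
            cand = generator_predictor.predict(
                gen_input, None, num_recycles=config.num_recycles,
                seed=config.seed).structure
            cand_bb = mask_to_backbone(cand)
            template = featurize_template(cand_bb, sequence_mode="gap")
            out = discriminator_predictor.predict(
                target_sequence, template, num_recycles=config.num_recycles,
                seed=config.seed)
            objective, _ = composite_score(out, cand_bb)
        except CapabilityError as exc:
            raise CapabilityError(f"step {step}: {exc}") from exc
        return objective, cand

    gen_input = target_sequence
    best_objective, best_structure = evaluate(gen_input, 0)
    objective_traj = [best_objective]
    best_traj = [best_objective]
    best_input = gen_input
    step = 0
    for step in range(1, config.steps + 1):
        proposal = _mutate(best_input, config.k_mutations, rng)
        objective, cand = evaluate(proposal, step)
        objective_traj.append(objective)
        if objective > best_objective:
            best_objective = objective
            best_structure = cand
            best_input = proposal
        best_traj.append(best_objective)
    return SearchResult(best_structure=best_structure, best_objective=best_objective,
                        objective_trajectory=objective_traj, best_trajectory=best_traj,
                        steps_run=step)
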