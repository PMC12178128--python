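"""Decoy ranking and the evaluation statistics of the EMA task.

Per target: rank decoys by composite confidence, report the Spearman rank
correlation between confidence and true TM-score, the quality of the top-1
pick, and the top-1 GDT_TS loss (the gap between the best available decoy and
the one the method chose). Across methods: the CASP-style comparison — mean
loss and mean per-target Z-score over targets whose best decoy clears
GDT_TS 0.4.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from foldcritic.metrics import spearman
from foldcritic.scoring import DecoyRecord


@dataclasses.dataclass
class RankingReport:
    """Evaluation of one target's decoy ranking."""

    target_id: str
    spearman_composite_vs_tm: float
    top1_decoy_id: str
    top1_true_tm: float
    top1_gdt_loss: float
    n_decoys: int


def rank_decoys(records: Sequence[DecoyRecord]) -> list[str]:
    """Decoy ids in descending composite order; ties break lexicographically
    by id, so the ranking is deterministic under input permutation."""
    if not records:
        raise ValueError("need at least one record")
    ordered = sorted(records, key=lambda r: (-r.composite, r.decoy_id))
    return [r.decoy_id for r in ordered]


def evaluate_target(records: Sequence[DecoyRecord],
                    target_id: str = "target") -> RankingReport:
    """Fill a :class:`RankingReport` from truth-bearing records."""
    if not records:
        raise ValueError("need at least one record")
    if any(r.true_tm is None or r.true_gdt_ts is None for r in records):
        raise ValueError("every record needs true_tm and true_gdt_ts")
    top_id = rank_decoys(records)[0]
    by_id = {r.decoy_id: r for r in records}
    top = by_id[top_id]
    best_gdt = max(r.true_gdt_ts for r in records)
    composites = [r.composite for r in records]
    tms = [r.true_tm for r in records]
    try:
        rho = spearman(composites, tms)
    except ValueError:
        rho = float("nan")
    return RankingReport(
        target_id=target_id,
        spearman_composite_vs_tm=rho,
        top1_decoy_id=top_id,
        top1_true_tm=top.true_tm,
        top1_gdt_loss=best_gdt - top.true_gdt_ts,
        n_decoys=len(records),
    )


def random_baseline_loss(records: Sequence[DecoyRecord]) -> float:
    """Expected top-1 GDT_TS loss of a uniformly random ranking: the mean
    loss over decoys."""
    best = max(r.true_gdt_ts for r in records)
    return float(np.mean([best - r.true_gdt_ts for r in records]))


def ema_evaluation(per_method_losses: Mapping[str, Mapping[str, float]],
                   per_target_best_gdt: Mapping[str, float],
                   gdt_filter: float = 0.4,
                   ) -> tuple[dict[str, float], dict[str, float]]:
    """CASP-style multi-method comparison of top-1 GDT_TS losses.

    Targets whose best decoy has GDT_TS <= ``gdt_filter`` are dropped. On each
    surviving target the Z-score of method m is (mean(loss) − loss_m) / sd
    with the sample (n−1) standard deviation — signed so that a lower loss
    gives a higher Z. Returns (mean loss per method, mean Z per method).
    """
    methods = sorted(per_method_losses)
    if not methods:
        raise ValueError("need at least one method")
    targets = sorted(per_target_best_gdt)
    surviving = [t for t in targets if per_target_best_gdt[t] > gdt_filter]
    if not surviving:
        raise ValueError(f"no target passes the best-GDT_TS > {gdt_filter} filter")

    z_acc: dict[str, list[float]] = {m: [] for m in methods}
    loss_acc: dict[str, list[float]] = {m: [] for m in methods}
    for t in surviving:
        losses = []
        for m in methods:
            if t not in per_method_losses[m]:
                raise ValueError(f"method {m!r} has no loss for target {t!r}")
            losses.append(per_method_losses[m][t])
        losses = np.asarray(losses, dtype=float)
        if len(methods) < 2:
            raise ValueError("Z-scores need at least 2 methods per target")
        sd = float(np.std(losses, ddof=1))
        if sd == 0:
            raise ValueError(f"degenerate Z on target {t!r}: all losses equal")
        z = (losses.mean() - losses) / sd
        for m, lm, zm in zip(methods, losses, z):
            loss_acc[m].append(float(lm))
            z_acc[m].append(float(zm))
    mean_loss = {m: float(np.mean(loss_acc[m])) for m in methods}
    mean_z = {m: float(np.mean(z_acc[m])) for m in methods}
    return mean_loss, mean_z


def bootstrap_ci_mean(values: Sequence[float], n_resamples: int = 10_000,
                      alpha: float = 0.05, seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of the mean."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_resamples, len(values)))
    means = values[idx].mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
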