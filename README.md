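# foldcritic

Estimation of protein model accuracy (EMA) by **template injection**: a
candidate 3D structure ("decoy") for a target sequence is encoded as a
*sequence-free template* — gap tokens in place of its amino acids, a Cβ–Cβ
distance matrix, backbone torsions, side chains stripped to Cβ — and handed to
a structure predictor together with the target sequence. The predictor's
confidence outputs then track how plausible the decoy geometry is for that
sequence, with no multiple-sequence alignment or coevolutionary input at all.
Decoys are ranked by the **composite confidence score**

```
composite = (mean pLDDT / 100) · pTM · TM(decoy, predicted structure)
```

where pLDDT and pTM are the predictor's per-residue and global confidence
estimates and the TM-score factor discounts confidence the predictor spent on
an output that drifted away from the decoy being scored.

The package is for structural bioinformaticians who want to rank decoy sets,
benchmark EMA statistics (per-target Spearman, top-1 GDT_TS loss, CASP-style
Z-scores), or run the two application loops built on the same machinery:

* **fixed-backbone sequence design** — optimize the input sequence to minimize
  the categorical cross-entropy between the predictor's distogram and the
  target backbone's Cβ distances;
* **structure prediction by generator–discriminator search** — one predictor
  proposes candidate structures from a mutable input sequence, a second scores
  them through template injection.

The predictor is a pluggable contract. A real AlphaFold adapter is specified
but optional; two shipped mock predictors (a backbone-plausibility
*geometry mock* and a hidden-native *oracle mock*) plus a synthetic decoy
generator make every stage runnable and testable on a laptop with no weights,
no GPU and no network.

Native implementations of TM-score, GDT_TS (fixed-frame and search modes),
CA-lDDT, Kabsch superposition and Spearman correlation are included; all
metrics assume positional residue correspondence (decoy and reference share
the target sequence).

## Worked example

Generate a toy native with a 50-decoy ladder of known quality, score it with
the geometry mock, and evaluate the ranking:

```bash
foldcritic make-decoys --length 40 --topology helix_hairpin \
    --sigmas 0,0.25,0.5,1,2 --n-per-sigma 10 --seed 1 --out data/
foldcritic score --fasta data/target.fasta --decoys data/decoys \
    --native data/native.pdb --predictor geometry-mock --out scores.tsv
foldcritic evaluate scores.tsv --out report.json
```

`report.json` then contains (numbers from this exact command sequence):

```json
{
  "per_target": [
    {
      "target_id": "scores",
      "spearman_composite_vs_tm": 0.9764762826718296,
      "top1_decoy_id": "decoy_r0_s0_000",
      "top1_true_tm": 1.0,
      "top1_gdt_loss": 0.0,
      "n_decoys": 50
    }
  ],
  "aggregate": {
    "n_targets": 1,
    "mean_spearman": 0.9764762826718296,
    "mean_top1_gdt_loss": 0.0,
    "mean_top1_true_tm": 1.0
  }
}
```

The composite score correlates strongly with true decoy quality
(Spearman 0.98 against TM-score over the 50 decoys) and the top-ranked decoy
is the unperturbed native (top-1 GDT_TS loss 0), i.e. the mock-backed
protocol recovers the quality ordering the noise ladder was built with.
`foldcritic compare model.pdb native.pdb` prints TM-score, GDT_TS, lDDT and
CA-RMSD for any pair; `foldcritic design` and `foldcritic fold-search` run
the two optimization protocols.

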