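# Methods

## The scoring model

A decoy structure for a target sequence is evaluated by handing it to a
structure predictor as a *template* while withholding its amino-acid
identity. The template channels are: a one-hot sequence made entirely of gap
tokens (so the predictor cannot read the decoy's residue identities), the
Cβ–Cβ distance matrix, backbone dihedrals (φ, ψ, ω) as (sin, cos) pairs with
validity masks, and an atom-presence mask. Side chains beyond Cβ are removed
before featurization; glycines and any residue with an unresolved Cβ but a
complete N/CA/C frame receive a *virtual* Cβ constructed from ideal internal
coordinates (bond 1.522 Å, angle N–CA–CB 110.4°, torsion C–N–CA–CB +122.6°,
the L-chirality side of the backbone plane). Withholding the sequence
matters: supplying the decoy's real sequence makes predictors overconfident
when it matches the target, and `sequence_mode="native"` exists precisely to
reproduce that control.

The decoy's score is the product of three factors: the mean per-residue
pLDDT (scaled to [0, 1]), the global pTM, and the TM-score between the decoy
and the predictor's output structure. The predictor's confidences describe
its *output*; the TM factor transfers them back to the decoy whenever the
output drifts. pLDDT is aggregated as the unweighted mean over residues (the
community convention; a config knob offers the median), and the TM factor is
normalized by the decoy/target length.

## Metrics

* **Kabsch superposition** — SVD solution with the determinant correction;
  always a proper rotation.
* **TM-score** — `(1/L_norm) Σ 1/(1+(d_i/d0)²)` maximized over rigid
  superpositions, `d0 = 1.24·(L_norm−15)^⅓ − 1.8` floored at 0.5 Å.
  Normalization defaults to the reference length (penalizing incomplete
  decoys); residue correspondence is positional over residues with CA in
  both structures. The mobile frame is first canonicalized by the global
  Kabsch fit, making the score rigid-motion invariant by construction. The
  maximization then seeds superpositions from contiguous fragments, iterates
  include/refit cycles until the included set fixes, and polishes the best
  transforms (L-BFGS-B with a batched central-difference gradient, then
  Nelder–Mead). Chains of ≤ 20 residues get denser search — all windows,
  several selection cutoffs, and at ≤ 12 residues all residue triples plus
  roll-swept transforms that exactly align each residue pair: with the d0
  floor active the objective is rugged and multi-modal, and a basin can
  anchor on a residue pair rather than on any contiguous fragment. The
  extra effort is what makes the search agree with a brute-force
  rotation-grid oracle on short chains. At realistic chain lengths the
  standard seeding converges in a few refits.
* **GDT_TS** — mean over {1, 2, 4, 8} Å of the maximal fraction of CA atoms
  within threshold. Search mode seeds from the global Kabsch fit plus every
  contiguous 3–7-residue window (solved as one batched SVD) and iterates
  within-threshold refits from the two dozen most promising seeds — a
  documented deterministic heuristic, not the full LGA program. A fixed-frame
  mode (`superpose=False`) skips the search entirely and is exactly
  hand-checkable.
* **CA-lDDT** — superposition-free; reference CA pairs within 15 Å and
  |i−j| ≥ 2, thresholds {0.5, 1, 2, 4} Å; per-residue scores average over a
  residue's pairs, the global score averages over residues with ≥ 1 pair.
* **Spearman** — mid-rank Pearson (average ranks on ties); undefined and an
  error on constant input.

## Ranking statistics

Per target: rank decoys by composite (ties broken lexicographically by decoy
id for determinism), report Spearman(composite, true TM), the top-1 pick's
quality, and top-1 GDT_TS loss = best available GDT_TS − GDT_TS of the pick.
Across methods: targets whose best decoy has GDT_TS ≤ 0.4 are dropped, then
per-target Z-scores over methods use the sample (n−1) standard deviation,
signed so lower loss ⇒ higher Z. This is deliberately simpler than the full
CASP assessor protocol (no iterative outlier trimming, no floor at −2) and
is flagged as such. GDT_TS lives on [0, 1] internally. Bootstrap confidence
intervals are percentile bootstrap, 10 000 resamples, fixed seed.

## Predictor contract and mocks

`predict(target_sequence, template_features_or_none, num_recycles, seed)`
must return a predicted structure of target length, per-residue pLDDT in
[0, 100], pTM in [0, 1], and a row-normalized distogram, deterministically
given (inputs, seed). The default distogram layout mirrors the common
64-bin binning (first edge 2.3125 Å, last edge 21.6875 Å, open final bin)
and is configurable.

* **GeometryMock** scores backbone plausibility:
  `p_i = 100·exp(−(dev_i/0.5)²)` with `dev_i` the mean |CA–CA − 3.8 Å| over a
  residue's virtual bonds, multiplied by (1 − clash fraction) over
  non-neighbor pairs closer than 3.5 Å; pTM is a rescaled logistic of the
  mean. Its distogram is a Gaussian over bin centers around the template
  distances whose width grows as confidence falls.
* **OracleMock** holds a hidden native and emits the template's *true*
  quality (pLDDT from per-residue lDDT, pTM from TM-score, one-hot distogram
  at native Cβ distance bins). It isolates pipeline correctness: any ranking
  failure with the oracle is a bug, not a modelling limitation.
* **Planted mocks** give the optimizers a recoverable signal: the design
  mock's distogram width shrinks strictly with the fraction of positions
  matching a hidden sequence; the generator mock emits the native perturbed
  with noise that shrinks as the input sequence approaches a planted key.

Mocks return the template itself as the output structure (no refinement), so
the TM(decoy, output) factor is 1 by construction there; this is accounted
for in the oracle-based end-to-end checks. Template features carry a
non-serialized reference to their source structure for exactly this purpose.
A real-predictor adapter is specified as a contract (alphabet translation,
template packing, recycle count, model selection, pass-through confidences)
but is not functional without the external runtime.

## Synthetic data

`make_toy_native` builds idealized backbones in torsion space (helix at
φ = −57°, ψ = −47°, ω = 180°; a helix–turn–helix hairpin; or a self-avoiding
sampler over helix/sheet basins with a 3.5 Å CA clash cutoff) with standard
bond geometry, and a random 20-letter sequence per seed. `perturb_structure`
degrades a native either by chain-smoothed Cartesian noise (per-residue
Gaussian displacements averaged over a 5-residue window, rescaled so the
per-residue displacement std equals σ) or by Gaussian φ/ψ jitter (σ in
degrees) with rebuilding; Cβ is re-virtualized in both modes. Smoothing is
essential: unsmoothed i.i.d. noise destroys bond geometry at almost no
TM-score cost, which would decouple local-plausibility signals from global
quality in a way real decoys do not.

Default ladder: length-40 natives, σ ∈ {0, 0.25, 0.5, 1, 2} Å, 10 decoys per
rung, topologies cycled — 50 decoys per target spanning TM ≈ 0.4–1.0, a
desk-scale stand-in for public decoy sets with thousands of decoys per
native. Sub-seeds derive from a stable BLAKE2 hash of (spec seed, rung,
index), so regeneration is byte-identical regardless of order. What the
generator does *not* emulate: physically realistic decoy diversity (fragment
assembly, energy-minimized traps), side-chain packing, register shifts.
Passing the mock-backed tests therefore demonstrates pipeline and statistic
correctness, not predictive performance of any real network on real decoys.

## Optimization protocols

Both applications are hill-climbs over the predictor contract: mutate
(1 position per step by default, uniform position and residue proposals),
evaluate, accept on strict improvement, fully reproducible given (config,
seed). Design minimizes the distogram cross-entropy against the fixed
template distances (pairs with |i−j| ≥ 1 and valid Cβ on both sides;
probabilities floored at 1e−12); the cross-entropy serves as a surrogate for
the composite score because an unconfident predictor spreads its distance
distributions and pays for it in cross-entropy, and it avoids
differentiating the TM-score's iterative alignment. If every early proposal
leaves the loss bit-identical (30 consecutive by default) the landscape is
flat — the predictor's distogram ignores the sequence, as with the oracle
mock — and the search reports that instead of spinning. The
generator–discriminator search keeps a mutable generator input sequence
(initialized to the target), folds it without a template, re-featurizes the
candidate as a gap template, and maximizes the discriminator's composite
score. A gradient engine is defined at the interface level only
(`objective_gradient` capability); the discrete climb is what runs here.
Step budgets (2000 for design on 30 residues, 60 for the search experiments)
are the package's defaults for the planted-signal studies; all knobs sit in
`OptimizeConfig`.

## Numerical choices and limitations

* Absent atoms hold NaN and are excluded by masks everywhere; metrics never
  read them.
* Distance-matrix entries for residues without a usable Cβ are flagged
  invalid rather than silently substituted with CA (an explicit
  `ca_fallback` flag enables the substitution).
* ω is assigned to the peptide bond *preceding* each residue; the first
  residue's ω (and φ) and the last residue's ψ are masked.
* The 22-token template alphabet (20 amino acids + unknown + gap) is defined
  in exactly one place; adapters translate at their boundary.
* GDT search refits only the most promising seeds per threshold; in rare
  borderline cases this can sit a residue below an exhaustive refit of all
  windows. TM-score search is matched against a brute-force rotation-grid
  oracle on short chains; the grid step (9°) is chosen finer than the basin
  width of the d0-floored objective so the oracle's candidate set covers
  every basin, and on the tested noise range (per-coordinate σ up to 3 Å)
  the two independent searches agree to machine precision.
* The composite score is calibrated to nothing: it is a ranking statistic,
  not an energy in physical units.
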