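# Methods

## The sequence-coupled model

The predictor assumes that the residues flanking a hydroxylation site carry
first-order, direction-dependent dependencies: the identity of the residue
at position −k is informative through its conditional distribution given
the residue one step closer to the center, and symmetrically downstream.
Two sets of tables — marginals for positions ±1, conditionals
p(R₋ₖ | R₋ₖ₊₁) and p(R₊ₖ | R₊ₖ₋₁) for 2 ≤ k ≤ ξ — are estimated by plain
relative frequency, separately on the positive (true-site) and negative
windows. A window is encoded as the per-position difference of the two
classes' probabilities looked up at the residue pairs actually present,
giving a 2ξ-vector in [−1, 1]²ξ; a random forest then separates the
classes in that feature space, scoring by the fraction of trees voting
positive.

The encoding is deliberately asymmetric around the center (conditioning
always points toward it): the immediate neighbors are modelled
unconditionally because the residue between them and the center is always
the fixed target residue.

The dummy residue `X` (terminal padding) participates as an ordinary 21st
symbol in all tables. Any non-standard letter in input sequences (B, J, O,
U, Z, `*`, gaps) is normalized to `X` rather than rejected, since `X`
already exists as the padding symbol.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| ξ (window half-width) | 10 | window length 2ξ+1 = 21; the value found most effective in the original study |
| smoothing | none | unseen conditioning contexts have probability 0; `laplace(α)` adds α to every pair count |
| n_trees | 100 | forest size; vote fractions stabilize as it grows |
| max_features | sqrt | split-candidate rule, the common RF convention |
| class_weighting | none | imbalanced benchmarks are left imbalanced, which yields the characteristic high-Sp / lower-Sn profile |
| threshold | 0.5 | vote fraction for calling a site; sweep it to trace the ROC |

The forest hyperparameters of the original predictor were never published;
these defaults are the field's conventions and all are exposed.

## Evaluation protocols

Metrics are computed in the miss-count formulation (README); its MCC is
algebraically identical to the textbook Matthews coefficient, which the
test suite checks property-based to 1e−12. When every prediction falls in
one class the MCC denominator vanishes; the coefficient is then reported as
0 with a warning (standard convention). ROC curves sweep the threshold over
all distinct vote fractions; the trapezoidal AUC equals the Mann–Whitney
concordance statistic with ties counted one half (cross-checked against an
all-pairs oracle).

The jackknife exists in two flavors because published descriptions of such
pipelines rarely state whether the probability tables were refit inside
each fold:

* `strict` (default) — tables *and* forest are refit on the n−1 training
  samples of every fold; no information about the held-out sample leaks
  into its features.
* `paper-style` — tables are fitted once on the full dataset, only the
  forest is refit per fold. This is the reproduction mode for the original
  publication's protocol and is mildly optimistic.

k-fold splits are stratified by label and reproducible from a seed; k equal
to the dataset size reproduces the jackknife folds exactly.

## The synthetic generator

The generator emulates precisely the statistical structure the model
assumes — nothing more. Windows are produced by per-class Markov chains
running outward from the center, matching the conditioning direction of the
encoder, so parameter recovery is well-posed: fitting tables on generated
windows converges to the generating tables. `coupling_strength` c
interpolates entry-wise between one shared table set (c = 0, classes
indistinguishable) and independently sampled class tables (c = 1); windows
at intermediate c carry intermediate signal, and pipeline AUC is
non-decreasing in c (tested).

Design choices, fixed once at design time:

* **Flank sub-alphabet.** Conditional tables live on a small subset
  (default 4) of the 19 non-target residues. At benchmark sizes of a few
  thousand windows, a frequency estimate of a 20×20 conditional table
  simply cannot reach uniform max-abs accuracy of a few hundredths — the
  worst-case entry error scales like √(log m / n) over m table cells — so a
  compact support is what makes recovery identifiable at realistic n. The
  default was calibrated (support 4, log-normal sharpness 2.0, Sinkhorn
  balancing) so that at c = 1 a 200-window benchmark is nearly separable
  (jackknife Acc ≈ 0.99) while fitted tables at 5,000 windows/class match
  the truth within 0.05 max-abs.
* **Uniform ±1 marginals, doubly stochastic conditionals.** Both classes
  share the identical (uniform) single-residue composition at every flank
  position; they differ *only* through nearest-neighbor coupling — exactly
  the effect the encoder measures. A side effect: a ξ = 1 window carries no
  signal at all, which makes window-size experiments sharp.
* **Non-overlapping sites.** Candidate centers are planted with spacing
  ≥ 2ξ+1 and flanks are redrawn whole, so windows never overlap and no
  target residue appears in a flank; every target occurrence in a generated
  protein is a planted candidate.

What the generator does **not** emulate: real collagen motifs (Gly-X-Y
repeats, proline-rich contexts), realistic amino-acid composition,
overlapping or clustered sites, annotation noise. Tests passing on this
generator therefore demonstrate that the pipeline recovers the statistical
structure it assumes, not that the trained models transfer to real
proteomes — that requires the experimentally derived benchmarks.

A caveat worth knowing: the benchmark screening step (duplicate and
self-conflict removal) removes high-probability windows preferentially on
low-entropy synthetic data. Frequency-recovery experiments therefore fit on
raw extracted windows; screened datasets are used for classification
experiments, where the slight pruning is harmless. For the same reason the
window-size sweep experiment uses a wider flank alphabet (10 letters) so
that 3-mer windows survive screening.

## Numerical and degenerate-input choices

* Unseen conditioning context (zero denominator): probability 0, mirroring
  a pure frequency derivation; optional Laplace smoothing for users who
  prefer positive mass.
* Duplicate screening keeps the first occurrence in input order; a
  self-conflict window is removed from both subsets, all copies.
* Window length is always 2ξ+1; feature order is −ξ…−1, +1…+ξ.
* Benchmarks whose screening empties a subset raise an error (the model
  cannot be fitted).
* Training windows must share one center residue; scoring windows with any
  other center raises a self-consistency error, and batch prediction
  verifies the bundle/target match before touching the output file.
* Coupling models serialize to a text format with `%.17g` floats
  (write→read round-trip exact); full prediction bundles (including the
  fitted forest) use joblib.
* Problem sizes in the test suite (e.g. 5,000 windows/class for recovery,
  400 windows for null calibration, 200 for separability) are the package's
  statistical calibration points: large enough for the bounds they check,
  small enough to run as ordinary unit tests.

## Known limitations

* The exact random-forest hyperparameters, decision threshold and fold
  protocol of the original published predictor are unknown, so its exact
  headline numbers (HyP Acc 96.58 %, MCC 0.89; HyL Acc 97.08 %, MCC 0.86)
  are not expected to be reproduced digit-for-digit; the `paper-style`
  protocol exists to attempt it when the original benchmark files are
  available, and the qualitative profile (high Acc, Sp ≫ Sn on imbalanced
  data) is reproduced on synthetic benchmarks of the same shape.
* Only first-order (nearest-neighbor) coupling is modelled; higher-order
  dependencies and other feature modes (functional-domain, GO, PSSM) are
  out of scope.
* Zero-probability features under `smoothing="none"` make the encoding of
  rare contexts uninformative rather than extreme; this is intentional but
  means very small training sets benefit from Laplace smoothing.
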