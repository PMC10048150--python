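# Methods

## Problem and model

`synthdiff` predicts whether a DNA sequence is EASY or HARD to synthesize
de novo. Synthesis difficulty is driven by sequence determinants —
extreme or fluctuating GC content, direct/tandem/inverted repeats,
stable hairpins, homopolymer tracts, weakly annealing (low-Tm) regions —
so the method is: characterize a sequence by a fixed 426-value
descriptor, reduce the descriptor to an informative subset, and train a
weighted ensemble of classical classifiers on labeled examples. HARD is
the positive class throughout: it is the rarer, actionable outcome.

The modeling surface follows the Model/Results convention:
`SynthesisDifficultyModel(matrix, labels)` binds the classifier
specification to data; `fit()` returns `SynthesisDifficultyResults`
carrying the deployable `ModelBundle` (ensemble + frozen normalizer +
selected-feature manifest), held-out metrics, permutation importance,
partial dependence and a `summary()` table.

## The 426-feature descriptor

Eleven groups, sizes fixed at 84/22/40/112/15/8/3/7/20/114/1
(composition, ANF, EIIP, k-mer, repeat, GC, Tm, structure, specific,
restriction, length). The group totals and the individually named
features (`dGC`, `GC_short_l`, `GC_long_l`, `Tm_low`, `site_ApaI`,
`length`) are the method's published shape; the internal inventory of
each group is this package's pinned, versioned definition (manifest
version 1.0), chosen once and shipped with the package. Divergence from
any other implementation of the same inventory is possible and is
exactly why trained bundles record the manifest version and refuse to
score across versions.

Key numerical choices:

- **Windows.** All window features slide by 1 bp. GC windows are 20 bp
  (low < 40%, high > 60%) and 100 bp (low < 30%, high > 70%); the 30%
  bound for long windows is the published screening threshold, the
  20 bp bounds are conventional synthesis-screening values. `dGC` is the
  max−min GC fraction over 100 bp windows. A sequence shorter than a
  window contributes a single whole-sequence window.
- **Tm.** Nearest-neighbor thermodynamics with the unified parameter
  set (Biopython `Tm_NN` defaults) at 50 mM Na⁺ and 250 nM per strand,
  recorded in the manifest. `Tm_low`/`Tm_high` are extremes over 20 bp
  windows; `Tm_global` is the whole-sequence duplex Tm. Note that the
  whole-sequence Tm of a long duplex is *not* bounded by its 20-mer
  window Tms — entropy and the salt correction scale differently with
  length — so no envelope relation between the three is assumed or
  tested beyond `Tm_low ≤ Tm_high`.
- **Hairpins.** Exact reverse-complement stems of ≥ 6 bp closing a loop
  of 3–48 bp. Each physical stem-loop is recorded once per pairing
  center: a placement whose loop could pair-shrink within range is
  attributed to the smaller loop. "Strong" hairpins have stems ≥ 10 bp.
  Detection is combinatorial by design; it finds exact-match stems, not
  minimum-free-energy structures.
- **EIIP spectra.** Bases map to electron-ion interaction potentials
  (A 0.1260, C 0.1340, G 0.0806, T 0.1335); the mean-removed signal's
  periodogram power is aggregated into 38 equal bins over (0, 0.5] and
  normalized to sum to 1 (all-zero for a constant signal).
- **Restriction sites.** 114 enzymes with unambiguous recognition
  sites, one enzyme per distinct site, ApaI (GGGCCC) mandatory.
  Non-palindromic sites are counted on both strands by scanning the
  site and its reverse complement on the forward strand; palindromic
  sites count once per position. Overlapping matches count.
- **Repeats.** The group pins 15 statistics: longest direct repeat,
  duplicated 10/20-mer counts and 10-mer coverage, longest tandem
  repeat (unit ≥ 2 bp, ≥ 2 copies), longest inverted-repeat stem and
  the count of stems ≥ 10 bp, longest even-length reverse-complement
  palindrome, per-base and overall longest homopolymer runs, longest
  dinucleotide tandem, and the count of homopolymer runs ≥ 5 bp.
- **Normalization.** Per-feature min–max scaling fit on *training data
  only* and frozen into the bundle; constant features map to 0; unseen
  values are not clipped. Fitting on the full dataset would leak test
  information into the scaler, so the leak-free variant is used even
  though it can place test values outside [0, 1].
- **Short sequences.** The full descriptor needs ≥ 40 bp (the spectral
  group's floor). Between 40 and 100 bp extraction proceeds with a
  warning and single-window fallbacks.

## Feature reduction

Three methods, composed cheapest-first (variance → correlation → GA),
each stage filtering the previous stage's survivors:

- **Variance filter**: keep features with sample variance ≥ cutoff
  (0.01/0.02/0.03/0.04) on the normalized matrix.
- **Correlation filter**: keep features with |point-biserial
  correlation| with the HARD=1 label ≥ cutoff (0.1/0.15/0.2/0.3);
  constant features are dropped. Label correlation (not pairwise
  redundancy pruning) is the interpretation used.
- **Genetic algorithm**: binary-mask chromosomes, population 50,
  tournament size 3, one-point crossover p = 0.8, per-bit mutation
  1/n_features, elitism 1; "rounds" count fitness evaluations (10,000
  or 100,000 in the grid). Fitness is the mean stratified 3-fold
  cross-validated F1 of a reference learner on the masked features,
  minus a parsimony penalty of 10⁻⁴ per kept feature. The default
  reference learner is Gaussian naive Bayes: its O(n·d) fit is what
  makes 10⁴–10⁵ evaluations tractable on a desk machine, and its
  feature-independence assumption is harmless for scoring masks. Any
  scikit-learn classifier factory can be injected through `GAConfig`
  (e.g. a random forest) when evaluation budgets allow.

The experiment grid enumerates 74 configurations — 10 single-method
(4 correlation + 4 variance + 2 GA), 32 two-method (16 corr×var + 8
corr×GA + 8 var×GA), 32 three-method (4×4×2) — and `run_experiments`
scores each one by repeated train/evaluate cycles, reporting mean/std of
F1, MCC and Cohen's kappa. Ties among configurations are resolved by
higher mean F1, then fewer features, then grid order.

## Training protocol

- **Split**: 3:1 train/test with a fixed seed (default 0); 1076 items
  split 807/269. The split is fixed across repeat evaluations; only the
  model-search seed varies.
- **Budgeted search**: candidates are drawn round-robin from an
  8-family portfolio (random forest, extremely randomized trees,
  AdaBoost stumps, Gaussian/Bernoulli naive Bayes, decision tree,
  k-nearest neighbors, linear SVM with a logistic squash of the margin,
  linear discriminant analysis) with seeded hyperparameters, fitted on
  an inner 75% of the training data and scored by F1 on the inner
  validation fold. The budget is dual-denominated: an iteration cap
  (deterministic, used everywhere in tests) and an optional wall-clock
  limit (production convenience; wall-clock runs are not reproducible).
- **Ensembling**: greedy forward selection with replacement on the
  validation fold (Caruana-style); ensemble weights are selection
  counts normalized to 1. Prediction is the weight-averaged HARD
  probability; the decision threshold is 0.5 with ties called HARD.
- **Repeat protocol**: n (default 10) independent search seeds on the
  fixed split; per-metric mean, std, min, max are reported.
- **Diagnostics**: permutation importance is the mean F1 decrease over
  n independent permutations of one feature column; partial dependence
  overwrites a column with grid values spanning its observed range and
  averages predicted probabilities.

## Synthetic data

The generator emulates the *structure* of a synthesis-outcome dataset:
i.i.d. background at a target GC content, with planted elements
(low/high-GC patches, direct/tandem/inverted repeats, homopolymers,
motifs) written over non-overlapping spans. Labels come from a
`DifficultyRule` applied to the planted ground truth — HARD if the
sequence carries a sufficiently long GC patch, repeat, homopolymer, or
at least one hairpin — with optional independent label noise drawn from
a separate random stream, so the noise rate does not perturb the
sequences themselves.

Default study conditions used by the acceptance pipeline: 400 sequences
of 500 bp at 50% background GC, balanced classes, noise 0. HARD
sequences carry one determinant drawn uniformly from {low-GC patch of
100–139 bp at 8% GC, direct repeat of 20–29 bp, hairpin with stem
12–17 bp}, with a 30% chance of an additional A₂₀₋₂₅ homopolymer.

What passing on synthetic data does and does not show: it demonstrates
that the pipeline recovers a known, planted mapping from sequence
determinants to labels end to end (extraction, normalization,
selection, ensembling, prediction). It does not certify performance on
real synthesis-outcome data, where determinants are correlated, labels
are noisy, backgrounds are not i.i.d., and the difficulty boundary is
not a clean threshold rule.

## Design choices made where the design was open

- The automated model search is a *contract* (seeded, budgeted portfolio
  search + greedy ensembling), not a dependency on an AutoML product.
- The repeat protocol re-runs the model search only; the split stays
  fixed, matching the fixed-seed split convention.
- Permutation importance uses F1 as its score.
- Degenerate metric denominators (no positives anywhere, an empty
  confusion marginal, chance agreement 1) evaluate to 0 with a warning
  rather than raising, so repeated evaluation never aborts on a trivial
  fold.
- Validation policy defaults to strict (any non-ACGT base is an error);
  `strip_ambiguous` removes IUPAC ambiguity codes with a warning.
  Error positions are reported 1-based; internal arithmetic is 0-based
  half-open.

## Problem sizes

The test suite and the acceptance script run at desk scale by choice:
400-sequence synthetic datasets, 12–16 search iterations per fit,
10-repeat protocols, GA budgets of 10,000 evaluations (the grid's
100,000-round cells are exercised with capped budgets in smoke runs and
at full budget only through the CLI). Oracle-equivalence checks cover
100 random sequences of 200–1000 bp per run.

## Known limitations

- Hairpin and repeat detection are exact-match combinatorics, not
  thermodynamic folding; near-complementary stems are invisible.
- The 426-feature inventory beyond the published group sizes and named
  features is this package's own pinned definition; numbers produced on
  top of it are not comparable feature-by-feature with other
  implementations of the same method shape.
- The GA's reference learner trades fidelity for speed; a mask that is
  optimal for naive Bayes need not be optimal for the final ensemble.
- Wall-clock budgets are supported but not reproducible; use iteration
  caps where determinism matters.
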