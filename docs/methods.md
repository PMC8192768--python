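# Methods

## Model and procedure

The package treats light-chain toxicity as a property of the *difference*
between a mature λ light chain (LC) and its germline precursor, not of the
raw sequence. The pipeline is:

1. **Alignment.** Needleman–Wunsch global alignment of the LC to its
   assigned germline with linear gap penalties (match +1, mismatch −1,
   gap −2). These defaults matter little — an LC aligned to its own
   germline is near-identity — and are configurable. Traceback ties are
   broken deterministically (match/mismatch over gap-in-LC over
   gap-in-germline), so the first optimal alignment is reproducible. The
   inner dynamic-programming loop is JIT-compiled with numba when
   available, with an identical pure-Python fallback.
2. **Numbering.** Kabat–Chothia labels transfer from the germline to
   aligned LC residues; LC insertions receive the preceding label plus
   the next insertion letter (30 → 30A → 30B, error past Z). The label
   universe (germline reference ∪ dataset insertions) is renumbered
   progressively to contiguous integers 1..N. The universe is *derived*,
   not hard-coded: the bundled synthetic reference yields N = 111; a
   full λ reference reproducing the classic scheme yields 125.
3. **Encoding (`S_mut`).** Per position: `X` if LC equals germline, the
   LC residue if mutated, a missing token if the LC does not cover a
   germline position (V-region-only sequences). Encode∘decode is an
   identity over covered positions, and `n_sm` equals the Hamming
   distance — both are tested properties.
4. **Positional statistics.** Per position, the 2×2 table
   (tox_M, tox_NM, nox_M, nox_NM) gives the sample odds ratio
   (cross-product), a two-sided Fisher exact p (point-probability
   convention, matching R's `fisher.test`), and a 95% CI. Positions are
   partitioned at α = 0.05 by OR direction. No multiple-testing
   correction by default (a Benjamini–Hochberg helper is a config
   option); the screen is descriptive, the classifier does the inference.
5. **Features.** AMP: one categorical column per position. MAP/DAP:
   token pairs `t_i-t_j` at monomeric/dimeric Cβ contacts (< 7.5 Å,
   strict; glycine falls back to Cα; altlocs resolved by occupancy then
   alphabetically). GLVJ: the germline rearrangement string. Values stay
   categorical; one-hot expansion happens only inside the ML harness and
   importances map back to named levels (`49-A`, `56X-59X`).
6. **Learning.** Stratified k-fold CV (default 10) with per-fold SMOTE
   when enabled, over 7 family subsets × 4 algorithms × ±SMOTE = 56
   configurations. Metrics from pooled out-of-fold tox-probabilities;
   the operating point maximizes the Youden index over unique score
   cutpoints (ties: higher sensitivity, then lower threshold).
7. **Ranking and reversion.** Information gain (base-2) of the class
   label given each value-level feature; levels below 0.01 bits are
   removed. Reversion scores each SM of a toxic sequence by the best
   general rank among features containing its position, and restores
   germline residues greedily, re-encoding and re-predicting after each
   step, until the prediction flips.

## Design choices where the design was open

- **Classifier backends.** The four learners are scikit-learn
  equivalents of the classic nominal-attribute setup: Bernoulli naive
  Bayes on one-hot features, L2 logistic regression, a pruned CART tree
  (`min_samples_leaf=2`), and a 100-tree random forest. Parity targets
  are the grid structure, CV protocol and metric definitions — not any
  other toolkit's exact defaults.
- **Categorical SMOTE.** Interpolating nominal features is meaningless,
  so synthetic minority samples take each feature's majority value among
  the k = 5 Hamming-nearest minority neighbours of a random seed row
  (ties: lexicographically smallest). Oversampling happens strictly
  inside each training fold; the implementation exposes donor ids so the
  no-leakage property is asserted by id-tracking in tests.
- **Missing coverage.** In per-position count tables an uncovered
  position counts as *not mutated* (an unobserved residue is taken as
  germline); a config switch excludes such sequences from the table
  instead. In feature vectors the missing token is its own category —
  no imputation of germline identity.
- **Zero cells.** The odds ratio is reported literally (0 or +inf); the
  CI uses the Haldane–Anscombe 0.5-corrected Woolf interval so it stays
  finite. The Fisher p needs no correction.
- **Dimeric self-pairs.** A position may contact its own two-fold
  symmetric mate across the interface; such (i, i) pairs are allowed in
  the dimeric set.
- **Reversion rank.** When an SM participates in several ranked
  features, the best (smallest) general rank wins, ties by position; a
  family-restricted mode can be emulated by filtering the ranking before
  calling `greedy_revert`.
- **Information-gain placement.** For reporting/ranking the IG is
  computed once on the full labelled matrix; classifiers built from
  ranked features for performance claims are cross-validated on top, so
  the incremental-feature trajectories should be read as descriptive of
  the ranking, not as unbiased generalisation estimates.

## The synthetic generator

`SimSpec` defaults describe the study conditions the package is
exercised under: 428 toxic / 647 non-toxic sequences (the scale of the
collection the method targets), background SM rate 0.03 per position
(~3 substitutions per ~110-residue variable domain), uniform germline
usage over a bundled set of three hand-written synthetic λ-like
germlines (two with CDR insertion labels, so progressive renumbering is
exercised). Planted effects set (position, amino acid) with
class-conditional probabilities; planted p_tox = 0.39 vs p_nox = 0.05 on
the 0.03 background corresponds to a per-position mutation odds ratio of
about 8, the effect size used in the parameter-recovery tests
(n = 500/group, 20 seeds). The toy structure generator places residues
on a 10 Å grid and moves designated pairs inside the 7.5 Å cutoff,
verifying by construction that no undesignated pair comes closer than
9 Å.

What the generator does *not* emulate: hypermutation hotspots and
transition bias, clonal lineage structure, CDR3 length variation,
germline-correlated mutation patterns, and any real structural coupling
between positions. Passing tests therefore demonstrate that the
pipeline's statistics and learners recover planted signal of realistic
magnitude from data of realistic shape — not that any particular AUC
will be attained on clinical repertoires.

## Numerical conventions

- Two-sided Fisher p: sum of hypergeometric point probabilities ≤ the
  observed table's (with a 1 + 1e−9 relative guard in the enumeration
  oracle used by tests).
- Welch t-test for mutation-count (PDSM) comparisons; two constant equal
  groups return (0, 1) by convention.
- Undefined metrics (zero denominators) are reported as missing, never
  as 0.
- AUC is the rank statistic over pooled out-of-fold scores; constant
  scores give 0.5.
- All randomised stages (fold shuffling, SMOTE, relabeling, generation)
  are driven by explicit integer seeds and log them.

## Problem sizes in the shipped checks

The test-suite simulations use 150–500 sequences per class and 5–20
seeds per property; the acceptance script's null control uses 400
sequences × 10 seeds. These sizes were chosen so each check has clear
statistical resolution for the property it asserts (3σ binomial bands,
±0.05 AUC tolerance) while remaining quick to re-run.

## Known limitations

- Germline assignment is taken as input (or nearest-identity fallback,
  logged); there is no nucleotide-level V/J calling.
- κ-isotype references, mmCIF structures and constant regions are out of
  scope.
- The exact historical insertion-label inventory producing a 125-position
  universe is not bundled; the scheme is reconstructed from whatever
  reference is loaded.
- Reported performance on synthetic data does not transfer to clinical
  sequence collections without retraining on real repertoires.
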