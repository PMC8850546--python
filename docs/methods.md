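# Methods

## Problem and model

`phosfuse` predicts which serine residues of a protein are phosphorylated
from sequence context alone. Every serine is a candidate site; the
experimentally annotated ones are positives and the remaining serines in the
same proteins are negatives. Each candidate is represented by the
`2w + 1`-residue peptide window centered on it (default `w = 12`, window
size 25), padded with the terminal-gap symbol `O` when the window runs past
a protein terminus, so the window alphabet has 21 letters
(`ACDEFGHIKLMNPQRSTVWYO`). Windows whose flanks contain ambiguity codes
(B, J, X, Z, U) are excluded with a warning, because the 21-symbol encoders
are not defined for them.

Three encoders turn a window into numbers:

* **CKSAAP** — for each gap `k = 0..kmax` (default 5), the count of every
  ordered letter pair `(a, b)` with `k` residues between them, divided by
  the number of k-spaced slots `N_tal(k) = L - k - 1` (L = 25). The
  normalizer is chosen so each 441-pair block sums to exactly 1, which the
  tests assert. The center serine participates in pair counting; the padded
  `O` runs do too (pairs such as `OO` encode terminal proximity).
  Dimension: 441 × 6 = 2646.
* **Binary** — one-hot encoding of each of the 2w flanking positions over
  the 21 letters. The center is skipped because it is constant `S`.
  Dimension: 21 × 24 = 504.
* **AAC** — relative frequency of the 20 standard residues over the flanks
  only; `O` is excluded from numerator and denominator. A window whose
  flanks are entirely padding gets an all-zero vector with a warning.
  Dimension: 20.

Features are ranked per scheme by the two-group Kruskal–Wallis H statistic
(mid-rank tie correction, chi-square p with 1 df) and the top N retained:
1500/2646 for CKSAAP, 400/504 for binary; AAC passes through unselected.
With two groups KW is the Wilcoxon rank-sum test up to the chi-square
approximation; it is implemented directly by rank arithmetic and
cross-checked in the tests against an independent library implementation.
Ties in H break toward the lower column index, so rankings are reproducible
and nested (top-n2 ⊆ top-n1 for n2 ≤ n1).

One classifier is trained per scheme — Random Forest with 500 trees by
default; AdaBoost with 100 stumps and an RBF SVM are alternative families —
and the three probability-like scores are fused as

    score = w1·f(CKSAAP) + w2·f(Binary) + w3·f(AAC),  w1 + w2 + w3 = 1,

with weights proportional to each scheme's standalone performance. The
standalone metric is internal 3-fold stratified CV AUC by default
(training-set performance and manual weights are config options; the choice
between CV and training performance was genuinely open, and CV was chosen
because training-set AUC of a 500-tree forest saturates near 1 and would
flatten the weights). SVM decision values are mapped to [0, 1] by Platt
(sigmoid) calibration so the convex combination is well defined across
families.

## Operating point and evaluation

Class imbalance is handled by ratio-controlled negative subsampling:
all positives are kept and `ratio × n1` negatives are drawn uniformly
without replacement (default ratio 1:2). Train/test splitting is at the
protein level so no protein contributes windows to both sides; the test
count is `floor(n × fraction)`.

The decision threshold is fixed by a false-positive-rate cap (default
0.20): the smallest threshold whose empirical FPR does not exceed the cap,
which maximizes TPR subject to it. Predicted positive means
`score > threshold` (strict), and tied scores are grouped all-or-none so
the cap is never exceeded — a conservative operating point. Reported
metrics are TPR, TNR, FPR, FNR, ACC, MCR and MCC from the confusion
counts, plus trapezoid AUC and the partial AUC over FPR ∈ [0, cap].
pAUC is reported **unnormalized** (its maximum is the cap itself, e.g.
0.20); a normalized variant can be derived by dividing by the cap.

Cross-validation uses stratified k = 5 folds (each fold preserves the
positive:negative ratio). The entire pipeline — feature selection, backend
training, weight derivation — is refit on the training folds of every
split, so no information from the held-out fold leaks into selection. The
null-calibration test (shuffled labels must give CV AUC within 3 SE of 0.5)
doubles as the leakage guard: with 3150 candidate features per window,
selecting on the full set before splitting would inflate null AUC well
above chance.

## Synthetic data generator

The generator produces annotated proteomes so every stage is testable
without external downloads. Defaults (the study conditions used by the
acceptance script): 300 proteins, lengths uniform in 200–600, serines
planted at rate 0.08 per residue on top of a uniform 20-letter background
(total serine density ≈ 0.13), 10% of serines positive (≈ 1000–1600
positive windows), three positional enrichments at probability 0.35 against
a 0.05 background (R at −3, P at +1, D at +2 — loosely shaped after
basophilic, proline-directed and acidic kinase motifs), and two k-spaced
pair injections (`KK` at gap 1, `ED` at gap 3) at probability 0.50 each.
The two signal types are planted separately so ablations can attribute
performance to the right encoder; the effect sizes are calibrated so the
fused 5-fold CV AUC sits near 0.90 — a realistic regime for this kind of
predictor — without claiming equivalence to any real proteome.

Semantics worth knowing when interpreting tests:

* At an enriched offset of a positive site the residue is the enriched
  letter with exactly the configured probability (otherwise it is redrawn
  from the background excluding that letter and S), so empirical
  frequencies converge to the configured values.
* Pair injections are applied before positional enrichment, so a site's
  own positional draw has priority at a contested offset. Overlapping
  windows still interfere: an injected pair is visible in the windows of
  neighboring serines, and a later positive site can overwrite an earlier
  site's flank. These effects shrink observed effect sizes by a few
  percent and are why frequency-convergence tests carry a small slack term.
* The generator does not emulate realistic proteome composition, kinase
  families, sequence redundancy, or evolutionary correlation between
  sites. Passing tests demonstrate that the pipeline recovers planted
  signal of the kinds the encoders target — not field performance on real
  phosphoproteomes.

## Numerical choices and edge cases

* A feature constant across all windows gets H = 0, p = 1 (not an error).
* A performance of exactly 0 for any scheme makes weight derivation fail
  loudly rather than silently dropping the scheme.
* `threshold_at_fpr` enumerates distinct scores plus a sentinel below the
  minimum; cap = 1.0 therefore returns a threshold below all scores
  (TPR = 1), and pAUC at cap 1.0 equals AUC exactly.
* MCC with an empty margin (degenerate confusion table) is reported as 0.
* All randomness flows through seeded NumPy generators; the same seed
  reproduces FASTA, site tables, model files and scores bit-for-bit.

## Problem sizes used by the test suite and acceptance script

The acceptance computations run the default 300-protein corpus for the
planted-signal CV (≈ 4600 windows after 1:2 subsampling) and a 60-protein
corpus for the shuffled-label null CV; oracle comparisons use 1000 random
windows (CKSAAP), 200 random score sets (AUC vs Mann–Whitney) and 100
small cases (KW vs an independent implementation). These sizes were chosen
to give stable stochastic estimates at desk scale.

## Known limitations

* Only serine sites are modeled (no threonine/tyrosine, no kinase-specific
  typing).
* Redundancy reduction beyond exact-duplicate removal is the caller's
  upstream responsibility (e.g. 30%-identity clustering with an external
  tool).
* The fused score is a convex combination, so it can sit slightly below
  the best single backend when one scheme dominates; fusion helps most
  when schemes carry complementary signal.
* The two-sample-logo module reports per-cell uncorrected p-values at
  alpha = 0.05 by design (a descriptive display, not simultaneous
  inference); the normal-approximate two-proportion test is inaccurate for
  very rare residues in small groups.
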