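# Methods

## Problem setting

Many human introns carry functional elements (miRNAs, snoRNAs, transcription
factor binding sites), yet intronic sequence is poorly conserved, so sequence
similarity cannot find them. What *is* conserved for functional introns is
their **position** relative to the coding sequence across deep evolutionary
time: they are lost more slowly, originate earlier, and sit closer to the CDS
start. `intronfun` turns these evolutionary signatures into a classifier.

A crucial asymmetry governs the labels. An intron annotated as functional
almost certainly is; an intron with no annotation may simply not have been
studied. Labels are therefore *one-sided noisy*: the model never treats
"unannotated" as a clean negative.

## Ternary patterns

For one set of orthologous transcripts, aligned CDS positions are encoded per
species as 1 (last nucleotide of a non-terminal exon — an intron starts
immediately downstream), 0 (any other coding nucleotide) or 2 (gap or missing
ortholog). Each alignment column containing a 1 is a presence–absence
*pattern*. Columns are filtered in order: (i) fraction of 2s ≥ 0.45 (over all
species) dropped; (ii) no 1 dropped; (iii) human entry ≠ 1 dropped (function
is only assessed on human introns). Identical vectors collapse into *unique
patterns* carrying multiplicity and all occurrence metadata. A unique pattern
is labeled functional when every occurrence carries an element tag,
non-functional when none does, partial otherwise; partial patterns are
excluded from training and scored afterwards.

Coordinates: on-disk interval formats are 0-based half-open (BED convention);
the internal POSITION is the 1-based count of human non-gap CDS nucleotides
from the CDS start through the junction-marking nucleotide inclusive. The
junction TSV input assumes coordinates on a common, already-aligned CDS axis;
producing alignments is outside this package's scope.

## The 13 features

Per unique pattern: `LOG_LIKE` (pattern log-likelihood under a gain/loss
Markov model, below), `ONES_KNOWN` (fraction of 1s among non-missing
entries), `SANKOFF_G1L3` and `SANKOFF_G3L1` (minimal parsimony cost with
loss = 3×gain and gain = 3×loss respectively), six clade indicators
(`IN_AMPHIBIAN`, `IN_FISH`, `IN_BIRD`, `IN_FUNGI`, `IN_PLANT`, `IN_PROTIST`:
1 iff some member of the group carries the intron), `LCA_AGE` (age in MY of
the MRCA of intron-bearing species — the single origin under Dollo
parsimony), `MED_POSITION` and `MED_REL_POSITION` (medians over occurrences
of the human CDS offset, absolute and relative).

Numerical conventions:

- **Sankoff**: tips with value 2 are ambiguous (either state at zero cost),
  the standard treatment; both root states are free (only gain/loss events
  are costed). The dynamic program is validated against exhaustive
  enumeration over all ancestral assignments on random small trees.
- **Median** of an even count is the mean of the two middle values.
- **Standardization**: continuous features are z-scored on the training
  table, binary indicators left as 0/1; the parameters are stored in the
  model JSON so prediction reuses the exact transform.

### Gain/loss model behind LOG_LIKE

`LOG_LIKE` asks "how typical is this pattern's evolutionary history?". It is
computed under a deliberately simple, fully reproducible surrogate for
branch-heterogeneous intron-evolution models: a homogeneous two-state
continuous-time Markov chain (gain rate γ, loss rate λ, both per MY) with a
free root distribution (π₀, π₁), shared by all branches. The three
parameters are fit by maximum likelihood over the whole pattern collection
(multiplicity-weighted by default), using L-BFGS-B on (log γ, log λ,
logit π₁) with multiple starts; pattern likelihoods use the pruning
algorithm with per-node renormalization against underflow, and missing tips
contribute likelihood 1 in both states. Branch-specific rates and rate
classes are out of scope; the feature's semantics survive the
simplification, but absolute LOG_LIKE values are not comparable to
heterogeneous-rate implementations.

## The noisy-label logistic model

The probability that pattern x is truly functional (hidden y = 1) is
logistic, with the offset entering the exponent with a plus sign:

    p(y=1 | x; ω) = 1 / (1 + exp(−ωᵀx + ω₀))

so the logit is ωᵀx − ω₀ (this sign convention is deliberately preserved and
pinned by tests so it cannot silently flip). The observed label z relates to
y through θᵢⱼ = p(z=j | y=i) with the structural constraints θ₀₁ = 0,
θ₀₀ = 1; the only free noise parameter is θ₁₁ = p(z=1 | y=1) — the fraction
of truly functional patterns that are annotated.

Training maximizes the observed-data log-likelihood
l(ω, θ) = Σₜ log Σᵢ θ(i, zₜ) p(yₜ=i | xₜ) by EM:

- **E-step**: responsibilities c_t1 = p(yₜ=1 | zₜ, xₜ). One-sided noise
  forces c_t1 = 1 when zₜ = 1; for zₜ = 0,
  c_t1 = (1−θ₁₁)p / (1−θ₁₁p).
- **M-step**: θ₁₁ = Σₜ c_t1 1{zₜ=1} / Σₜ c_t1 in closed form; ω maximizes
  the responsibility-weighted logistic objective (concave) by Newton's
  method with step-halving, falling back to gradient ascent with the
  configured learning rate τ if the Hessian solve fails.

Convergence: absolute improvement of the observed log-likelihood < 1e-8, up
to 2,000 iterations (near the θ₁₁ boundary EM's improvement decays
geometrically and needs on the order of 10³ iterations at n = 5,000).
Initialization: ω from a plain logistic fit of z on x; θ₁₁ uniform in
(0.05, 0.95) per restart; 100 restarts by default, reporting
mean/STD/coefficient-of-variation of every parameter across restarts as the
robustness diagnostic. Training uses unique patterns unweighted by
multiplicity (a flag enables weighting).

**Classification**: the default thresholds the observed-label marginal
θ₁₁·p(y=1|x) > T (T = 0.5), exactly as the model equation for p(z=1|x)
reads; ties are non-functional. Because θ₁₁·p ≤ θ₁₁, this rule predicts
nothing functional when θ₁₁ ≤ T — a real consequence of reading the rule
literally — so `classify(..., on_true_label=True)` exposes thresholding the
hidden-label probability p(y=1|x) instead. Both scores are always written to
the predictions table.

**Derived quantities**: θ₁₁ itself, and
P₁₀ = p(y=1 | z=0) = mean over z=0 patterns of (1−θ₁₁)p / (1−θ₁₁p) — the
estimated fraction of annotated-non-functional patterns that are actually
functional.

Identifiability caveat: with few positives and flexible features the
likelihood can be maximized at θ₁₁ = 1 by separating the positives (the
classic failure mode of positive-unlabeled learning). Reliable θ₁₁ recovery
needs enough positives and features under which p(y=1|x) approaches 1 for
some patterns; the recovery checks in the test suite use n = 5,000.

## Fisher-discriminant view

Features are standardized, projected onto the top seven principal
components, and a Fisher direction w ∝ S_W⁻¹(m₁ − m₀) is computed between
functional- and non-functional-labeled patterns (partial patterns are
projected but excluded from w). The second axis is the leading principal
direction of the data after removing the w component, so the two axes are
orthogonal in PC space. If S_W is singular it is ridge-regularized with
ε = 1e-6 × trace/dim. Signs are fixed deterministically: the functional mean
is positive on x; the y-axis loading of largest magnitude is positive.

## Feature-contribution battery

1. **Mutual information** (bits) between each feature and the predicted
   labels, plug-in estimate with 0·log 0 = 0; continuous features are
   discretized into 10 equal-frequency bins (binary features used as-is).
   Predictions here threshold p(y=1|x), since thresholding θ₁₁·p is
   degenerate whenever θ₁₁ ≤ T.
2. **Leave-one-out distance**: Performance(F) = Σₚ (Pr_F(p) − Pr₀(p))² where
   Pr₀ are full-feature predictions and Pr_F predictions after retraining on
   F; larger = the omitted feature mattered more.
3. **Single-feature distance**: same quantity for each feature alone;
   smaller = stronger alone.
4. **Sequential remove-two-add-one selection**: each iteration removes the
   pair of kept features whose joint removal raises Performance least, then
   re-admits the feature from the entire rejected set (including features
   rejected in earlier iterations) whose return lowers Performance most —
   one net removal per iteration until a single feature survives (13
   features → 12 iterations). Pair search is exhaustive; subset
   performances are cached.

All retrainings share one initialization scheme and seed (so distances
reflect feature sets, not restart luck) and are capped at 10 restarts,
tolerance 1e-6 and 300 EM iterations. The caps matter: feature subsets with
no signal sit on a likelihood ridge where only the product θ₁₁·p is
identifiable — predictions stabilize quickly while (θ₁₁, ω) drift — so the
battery accepts the best restart without requiring formal convergence.

## Supporting statistics

- Group comparisons: two-sided equal-variance t-test and Mann–Whitney U,
  Bonferroni-adjusted (p × n_tests, capped at 1). Zero pooled variance:
  only U is reported.
- Enrichment: upper-tail hypergeometric P(X ≥ k) for the count of
  predicted-functional patterns in a group.
- Repositioning permutation test: under the null that an element is equally
  likely to sit anywhere inside any intron of its transcript, the element
  (length preserved) is placed uniformly over all start positions where it
  fits wholly inside a single intron; boundary-spanning placements are
  invalid. Since only the hosting intron matters for the statistic, the
  implementation draws the intron directly with probability proportional to
  its count of valid starts — the exact marginal of that null. Reported per
  transcript: the fraction of placements landing in the actual host intron
  or one closer to the CDS start; the summary reports the share of
  transcripts with fraction ≥ 0.95.

## Synthetic data generator

The generator emulates the statistical structure of the real data at the
defaults that define the package's study conditions: 10% of patterns truly
functional; θ₁₁ = 0.2 (roughly one functional intron in five annotated);
functional introns evolve with loss rate 2×10⁻⁴/MY, root presence 0.8 and
CDS offsets exponential with mean 300 nt; non-functional introns with loss
rate 2×10⁻³/MY, root presence 0.5 and uniform offsets; both classes gain at
6×10⁻⁴/MY; 20% of non-human species entries missing; CDS lengths log-normal
around 1,500 nt. These contrasts match the *direction* of the differences
between functional and non-functional patterns (lower loss, older origin,
5′-biased positions), not any particular magnitudes.

Presence/absence evolves down the dated 28-species fixture tree (any
ultrametric tree is accepted) under each class's two-state chain; patterns
are conditioned on human presence by rejection, with class membership drawn
first so the functional fraction stays at its nominal value. For the
collapsed unique patterns, the true label is the majority class of the draws
that produced the vector (ties functional) and label noise is applied at the
unique-pattern level — the unit the classifier trains on. The
architecture-level generator instead tags each occurrence independently,
which produces partial patterns through the ordinary labeling rule, and
emits the junction TSV / element BED / truth TSV trio the pipeline reads.

What the simulation does **not** capture: real alignments (and their
errors), branch-heterogeneous rates, correlated introns within a gene,
gene-specific covariates, element-type-specific positional preferences, and
the real data's class imbalance at pattern granularity. Passing tests show
the machinery is correct under its assumptions, not that real-data accuracy
matches any published figure.

The fixture tree ships with approximate, rounded divergence times in MY and
the topology commonly accepted for these 28 species; it is a test fixture,
not a dated phylogeny of record. The default clade map follows the grouping
the clade features were defined over (the "amphibian" group contains both
*Xenopus tropicalis* and *Anolis carolinensis*); it is overridable by TSV.

## Problem sizes used by the tests and the acceptance script

Parsimony/pruning oracle checks use exhaustive enumeration on trees of 2–6
leaves (hundreds of random cases); EM-vs-direct-optimizer agreement uses
n ≤ 200 with 2 features; θ₁₁/P₁₀ recovery uses n = 5,000 over
θ₁₁ ∈ {0.1, 0.2, 0.5} with 20 seeded runs and 3 restarts; the importance
battery uses 20 planted-signal runs at n = 600 with 5 features and 4
restarts; the end-to-end pipeline recovery uses 5,000 simulated patterns on
the 28-species tree. These sizes were chosen as the smallest at which the
statistical guarantees are comfortably resolvable.

## Known limitations

- The gain/loss model is homogeneous; LOG_LIKE values are not comparable to
  branch-heterogeneous implementations.
- θ₁₁ is only identifiable when some patterns reach high p(y=1|x); on small
  or weakly informative data the fit may collapse to θ₁₁ = 1.
- The literal θ₁₁·p > T rule predicts nothing functional when θ₁₁ ≤ T; use
  `on_true_label=True` when that is not the intended reading.
- MRCA queries treat polytomies as-is; no polytomy resolution or tree
  inference is attempted.
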