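# Methods

## Model and assumptions

The method turns enzyme–substrate prediction into binary classification of
*molecule pairs*. The underlying assumption is metric: substrates of the
same enzyme occupy nearby regions of physico-chemical descriptor space, so
the element-wise difference of two substrates' descriptor vectors carries
the information "same enzyme or not". Concretely:

- Training instances are all n(n−1)/2 unordered pairs of known substrates.
  A pair is positive when the two molecules share at least one enzyme
  (multi-enzyme substrates are allowed); self-pairs are never generated.
- The feature vector of a pair is the element-wise **absolute** difference
  of the two z-scored descriptor rows. The sign of a pairwise subtraction
  is meaningless for an unordered pair; the absolute value makes the
  feature symmetric and encodes the intended geometry directly (small
  difference ⇒ likely same enzyme, which is why informative difference
  features correlate *negatively* with the label).
- No class rebalancing is applied. Real reaction tables are extremely
  imbalanced (positives well under 1% of pairs) and the method is designed
  to operate under that imbalance; its consequences surface as low
  sensitivity/PPV at high specificity, which is why MCC rather than
  accuracy drives threshold selection.

The pairwise scorer is ordinary least squares of the 0/1 label on the
selected features. A linear model on |Δx| is deliberately simple: its
continuous output orders pairs for AUC, it is deterministic and cheap at
the scale of millions of pairs, and it was the best-performing of the four
learner families considered (naïve Bayes, random forest and a small MLP
remain available as plug-ins behind the same interface).

## Normalization

Descriptor columns are z-scored with the **population** (divide-by-n)
standard deviation, fitted on the training substrate matrix only and
stored with the model; query rows are mapped through the stored parameters
and never trigger a refit. Normalizing *before* subtraction (rather than
normalizing the difference features) keeps query-time application simple
and leak-free: a query molecule needs only its own descriptor row.
Zero-variance columns are dropped. Columns containing missing values in
the training matrix are likewise dropped (with a logged count) rather than
imputed — conservative, and it keeps the correlation statistic
well-defined. Both drops are recorded in the normalization parameters.

## Feature ranking

Relevance of feature x to label y is the point-biserial correlation

    r_pb = (M1 − M0)/s_n · sqrt(n1·n0/n²)

with s_n the population standard deviation — algebraically the Pearson
correlation of x with the 0/1 label, which the test suite asserts to
1e-12. Conventions chosen where the formula is silent:

- zero-variance features and single-class labels give r_pb = 0, routing
  constants to exclusion instead of erroring;
- features with |r_pb| below a floor (default 0.01) are excluded outright;
- ties in |r_pb| break lexicographically by descriptor name, making the
  ranking deterministic;
- the default number of retained features is 500, the configuration at
  which the linear model performed best in the original feature sweep.

## Score integration

For a query q and an enzyme with substrates s_1..s_m, the pairwise model
produces individual scores s_i = f(|x_q − x_{s_i}|), clipped to [0, 1]
(the linear predictor is unbounded; clipping keeps integrated scores
comparable with the decision threshold). The weighted integrator is

    p = s̄ + [ Σ_{s_i ≥ s̄} (s_i − s̄) ] · sqrt( Σ_i f(s_i − s̄) / k ),
    f(d) = d² if s_i ≥ s̄ else 0,    k = #{ i : s_i ≥ s̄ },

clipped to [0, 1]. Two readings of the defining sum are possible; the sum
over *above-mean* scores is used because the full signed sum is
identically zero (it would collapse the integrator to the mean), and k
counts scores at or above the mean *inclusive of ties*, since a strict
count would be zero for constant lists. Under these conventions the
canonical worked values hold exactly: {0,1} → 0.75, {0.5,0.5} → 0.5, and
{0,1,1,1} = 0.9375 > {0,0.2,0.5,1} = 0.6915, so a skewed score
distribution outranks a flat one. Guaranteed properties (property-tested):
p ≥ s̄ always, p = s̄ for constant lists, mean ≤ weighted ≤ 1,
noisy-or ≥ max, and permutation invariance of all four integrators.

The decision rule is inclusive: the enzyme is predicted to react when
p ≥ threshold (default 0.75). If the query is itself a known substrate it
is removed from every enzyme's reference list before scoring, so
prediction for training molecules is leave-one-out by construction.

## Cross-validation protocol

Folds are assigned at the **enzyme** level (sorted, seeded shuffle,
round-robin deal; fold sizes differ by at most one). For fold i:

- test enzymes T_i = the fold's enzymes; held-out substrates S_i = the
  substrates catalyzed *only* by enzymes in T_i;
- normalization, feature ranking and the pair model are fitted on pairs
  among substrates outside S_i, with positive labels defined only by
  enzymes outside T_i;
- evaluation instances are (q, e) for every e ∈ T_i and every substrate q
  of e's fold, scored against e's substrates excluding q and labeled by
  whether (e, q) is a real reaction;
- instances whose reference list is empty are skipped; a fold with no
  positive instance is skipped with a warning; if every fold is skipped
  the run fails loudly.

AUC is computed on the instances pooled across folds (a single AUC per
configuration, the stabler convention), with per-fold AUCs reported as
detail and a pooled pair-level AUC over the individual (query, substrate)
scores exposed as a diagnostic. The no-leakage property is enforced by
test instrumentation: deleting the held-out substrate rows from the input
matrix leaves the fitted fold model bit-identical.

With only two enzymes this protocol is degenerate — a training half
containing a single enzyme yields all-positive pairs — so meaningful
cross-validation needs at least two enzymes per training split; the
smallest smoke configuration used in the tests is four enzymes in two
folds.

## Synthetic data

The generator reproduces the geometry the method assumes, nothing more.
Each enzyme receives a Gaussian center (spread `between_enzyme_sd`) in the
signal subspace of descriptor space; each substrate is its enzyme's center
plus Gaussian noise (`within_enzyme_sd`); a fraction of substrates
(default 5%) also belongs to a second enzyme and averages the two centers;
a fraction of columns (default 20%) is pure noise; background molecules
(descriptor rows with no reactions) serve as negative queries. Defaults —
10 enzymes with 4–6 substrates each, 50 descriptors, spread ratio 10 for
the `separated` preset — keep within-enzyme pairs visibly tighter than
between-enzyme pairs while leaving positives a small minority of pairs,
mirroring the imbalance regime of real reaction tables at a desk-scale
size chosen so the full leave-enzyme-out pipeline runs in seconds. The
`hard` preset halves the separation (ratio 2); the `null` preset keeps the
`separated` geometry but randomly permutes substrate identities in the
reaction table, severing labels from geometry so any correct pipeline
scores at chance.

What the generator does **not** emulate: real descriptor distributions
(heavy tails, discreteness, block correlations between descriptor
families), chemistry-level constraints, or database artifacts such as
mislabeled transporter "enzymes". Passing tests on synthetic data
therefore demonstrate correctness of the machinery and recoverability of
cluster structure under the model's own assumption — not predictive
performance on real reaction databases, which depends on how well real
substrates actually cluster.

## Numerical choices

- OLS is solved via a minimum-norm least-squares factorization; a
  rank-deficient design logs a warning and proceeds with the minimum-norm
  solution rather than failing. Refits are bit-stable.
- Population (1/n) variance everywhere a standard deviation appears.
- AUC is the Mann–Whitney rank statistic with ties counted 1/2.
- Confusion metrics with a zero denominator are reported as 0 and flagged;
  MCC with any zero factor is 0.
- The threshold grid is 0.00–1.00 inclusive with step 0.05; the best
  threshold is the lowest argmax of MCC.
- All randomness (fold shuffling, simulation, stochastic learners) flows
  from explicit integer seeds; the linear learner accepts and ignores one.

## Problem sizes

Synthetic evaluations default to 10 enzymes × 5 substrates and 50
descriptors (1225 pairs per fit), with 5 folds and 40 features in the
cross-validated checks — large enough that pooled AUC estimates are stable
across seeds while the entire suite runs in seconds.

## Known limitations

- Descriptor computation from SMILES uses the installed RDKit 1-D/2-D
  descriptor set (~210 columns); models trained on another descriptor
  dialect (e.g. PaDEL's 1444) must be queried with descriptor rows from
  that same dialect.
- Identifier namespaces are opaque: reconciling substrate identifiers
  across databases is the caller's responsibility.
- Only the linear learner serializes to the JSON model format.
- Integrated scores are threshold-comparable but are not calibrated
  probabilities.
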