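# Methods

## Model

The package aggregates a base predictor's scores on a focal sequence and
its orthologs into a single log-likelihood-ratio score. The species tree
is rerooted at the focal species, so the focal label *Y* sits at the root
and the joint likelihood of the score vector factorizes into a root
marginal `P[s_1|Y]` and one conditional `P[s_c|s_p,Y]` per parent→child
edge. The aggregated score is

    score = log P[s_1|Y=1]/P[s_1|Y=0]
          + α · Σ_edges log P[s_c|s_p,Y=1]/P[s_c|s_p,Y=0],

natural log throughout (the >0 decision rule and all rank-based metrics
are base-invariant; the choice only fixes reported magnitudes). The class
prior is uniform by default and cancels from the ratio; a user-supplied
prior adds `log P1/P0` as a constant.

Assumptions: scores on child and parent sequences are conditionally
dependent only along tree edges given *Y* (a Markov process on the tree);
the base predictor's score distribution is stable across species; the
label of the focal sequence is the quantity of interest, not the
orthologs' own (unobserved) labels.

### Estimation

Scores are discretized by rounding to the first decimal place: bins
0–10, plus bin 11 for missing orthologs. Ties round half away from zero
(0.25 → bin 3); any consistent rule would do, this one is fixed for
reproducibility. Out-of-range scores are clipped with a warning, since
sigmoid-output predictors only violate [0, 1] by float artifacts.

Tables are empirical bin counts with a pseudocount ε:

    P[s_1=b | Y=y]      = (#{i: s_1^i=b, l(i)=y} + ε) / (#{i: l(i)=y} + 12ε)
    P[s_c=b | s_p=b', Y=y] = (#{i: s_c^i=b, s_p^i=b', l(i)=y} + ε)
                             / (#{i: s_p^i=b', l(i)=y} + 12ε)

Each edge gets its own table — never pooled across edges — so the edge's
evolutionary distance enters implicitly: a long branch simply shows
weaker parent–child coupling in its counts. ε > 0 is required; it keeps
every probability strictly positive and every 12-bin distribution a
proper multinomial (asserted after every fit). An empty training set
yields all-uniform tables (score 0 everywhere) with a warning.

### Missing data

At fit time a missing score is counted in bin 11, populating the
missing-value bin. At predict time any term whose score is missing is
skipped (contributes 0) — this includes the root term when the focal
score is missing. The alternative reading, pushing missing scores
through the tables as bin 11, is available via `missing="bin"`
(CLI: `--missing-at-predict use-bin`); the default was chosen because it
makes a species with no data exactly inert, which is the safer contract
when missingness correlates with alignment quality rather than function.

### Parameters

- **ε (pseudocount), default 1.** Larger values shrink all tables toward
  uniform and all scores toward 0; the standard grid for tuning is
  [0.01, 0.1, 1, 10].
- **α (branch weight), default 0.1, dimensionless.** Balances ortholog
  against focal evidence; with ~20 contributing edges the branch sum has
  roughly ten times the root term's scale, so α ≈ 0.1 equalizes them
  a priori. The standard tuning grid is [0.001 … 1000].
  `select_hyperparameters` grid-searches (ε, α) by AUPR on a validation
  split; `fit` itself never searches.
- Exact-zero scores classify as 0 (strict inequality in the decision
  rule).

## Baselines

**Stacking (PhyloStackNN-style):** an MLP over the raw per-species score
vector, architecture from {(32,), (100,), (64, 32)} and L2 penalty from
{0.1, 1, 10}, selected by mean 10-fold cross-validated AUPR and refitted
on the full training set. Missing inputs are imputed with 0.5, the
uninformative midpoint of a sigmoid output. Fold membership is a hash of
(seed, example id) and rows are canonicalized by id before fitting, so
the selected configuration and predictions are invariant to input row
order. **Mean-of-scores:** the unweighted average of non-missing scores.
**Focal-only:** the base predictor's focal score as-is.

## Evaluation

AUPR is the step-wise average precision (ties grouped as blocks; backed
by scikit-learn's estimator, cross-checked in the tests against an
exhaustive top-k threshold scan). Recall at FDR *f* is the recall at the
most permissive cutoff whose empirical FDR (1 − precision) is ≤ *f*, 0
if none qualifies; "FDR" here is a PR-curve quantity, no multiple-testing
correction. Branch informativeness of an edge is the mean per-example
edge LLR term (unweighted by α) over positives minus that over
negatives, counting only examples where the edge contributed; it should
be computed on held-out data — in-sample, per-class overfitting of the
tables inflates even uninformative edges to visibly positive values.
With no missing data, α times the summed informativeness plus the
root-term class difference reconstructs the mean score difference
between classes exactly (tested).

## Synthetic data generator

Each example draws a label *Y*; the focal/root latent state is set to
*Y*; the binary functional state propagates down the rerooted tree,
flipping along a branch of length *e* with probability 1 − exp(−μ·e)
(two-state symmetric Markov process, the weakest structure under which
the model's factorization assumptions hold). Each node's score is drawn
from a beta distribution conditional on its state — defaults
Beta(3.5, 1.5) / Beta(1.5, 3.5), means ≈ 0.7 / 0.3, overlap adjustable to
tune base-predictor strength — and non-focal cells are masked missing
completely at random. Per-branch flip probabilities can be overridden
(scalar, or a {child: p} mapping); 0.5 makes a branch's descendant state
an independent fair coin, i.e. carries no signal.

What it does *not* emulate: sequence content, motifs or alignments;
ortholog absence correlated with function; species-specific predictor
calibration drift; correlated turnover of neighboring sites. Passing
tests therefore demonstrate correctness of the estimator and the
qualitative value of phylogenetic aggregation under the model's own
assumptions — not performance on real ChIP-/CLIP-derived data.

### The bundled demo regime

The demo uses a 12-leaf mammal-like tree (branch lengths of magnitudes
typical for mammal phylogenies), n = 5000 examples split 60/20/20
(stratified), positive fraction 0.3, turnover rate μ = 0.3, 15%
missingness, a deliberately weak focal emission (Beta(1.5, 1)/Beta(1, 1.5),
focal-only AUPR ≈ 0.5) and full turnover (flip 0.5) on the ten branches
outside the primate clade. The mixed regime is deliberate: when every
species is equally informative, the plain mean of scores is already
near-optimal and tables estimated from a few thousand examples cannot
beat it; heterogeneous conservation is both the biologically motivated
setting (binding-site turnover) and the one where tree-aware weighting
pays. The demo keeps ε = 1 and tunes α on the validation split over the
standard grid, mirroring how α is chosen in practice. Problem sizes
(n = 5000, 12 leaves, 10 null seeds) were chosen so the full
demo-plus-null sweep completes in well under a minute on one CPU.

## Numerical choices and edge cases

- Unnamed internal Newick nodes get deterministic names
  `_internal_<preorder-index>`, so tables stay keyed stably across fit,
  serialization and predict. Duplicate names are rejected.
- Missing branch lengths default to 0 with a warning (the numeric length
  is never used directly by the estimator).
- Rerooting at a leaf makes it a degree-1 root; if the old root is left
  with degree 2 it is suppressed and its two branch lengths summed, so
  no artifactual edge splits a single lineage. Polytomies are allowed.
- Grid searches break ties toward the earlier grid entry; model
  serialization is versioned JSON at full float precision.

## Known limitations

Per-edge 12×12×2 tables are data-hungry: with only a few thousand
training examples their estimation variance can cost a few AUPR points
against simpler combiners when informativeness is homogeneous (the model
wins asymptotically; verified in simulation). The multinomial treats
bins as unordered, ignoring score smoothness — a beta or ordinal model
would pool strength across adjacent bins. Missingness is assumed
ignorable. The simulator's conservation process is symmetric and
memoryless; real turnover is lineage- and element-specific.
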