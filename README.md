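# phylopgm

Phylogenetically informed aggregation of ortholog prediction scores for
regulatory-function classification.

## The problem

Sequence-based predictors of transcription-factor binding sites (TFBS) and
RNA-binding-protein (RBP) targets emit a score in [0, 1] for a genomic
window, and they suffer from high false-positive rates. Because regulatory
function tends to be conserved, the same predictor applied to the
*orthologous* sequences of other species — and to reconstructed ancestral
sequences — carries independent evidence about the focal (human) sequence's
label. This package aggregates that evidence with a probabilistic graphical
model on the species phylogeny, for people who already have a base
predictor and a multiple-genome alignment and want better rankings without
retraining anything.

## The model

Let the species tree ψ be rerooted so the focal species is the root, let
`s_i` be the base predictor's score on node *i*'s sequence, and let *Y* be
the focal label (1 = binding site). The joint score likelihood factorizes
along the edges:

    P[s_1, …, s_n | Y] = P[s_1 | Y] · ∏_{(p,c) ∈ edges(ψ)} P[s_c | s_p, Y]

and the aggregated score is the log-likelihood ratio, with a weight α
balancing ortholog against focal evidence:

    score = log( P[s_1|Y=1] / P[s_1|Y=0] )
          + α · Σ_{(p,c)} log( P[s_c|s_p,Y=1] / P[s_c|s_p,Y=0] )

An example is called a binding site iff score > 0. Every distribution is a
12-bin multinomial — scores rounded to one decimal (bins 0–10) plus a bin
for missing orthologs — estimated from labeled training examples with a
pseudocount ε (default 1), one conditional table per edge, so each edge's
evolutionary distance enters implicitly through its own table. Missing
scores contribute nothing to the sum at predict time.

The package also provides a tree-agnostic stacking baseline (an MLP over
the raw score vector, grid-searched by 10-fold cross-validated AUPR),
ranking metrics (AUPR, recall at an empirical FDR threshold), a per-branch
informativeness diagnostic, and a synthetic ortholog-score simulator in
which a binary functional state evolves along the tree as a two-state
Markov process and scores are emitted from state-conditional beta
distributions.

## Worked example

```bash
python examples/03_demo_benchmark.py
```

runs simulate → fit → predict → evaluate on the bundled 12-leaf mammal
tree: 5000 examples, a deliberately weak base predictor on human,
informative orthologs across the primates, and binding-site turnover (no
signal) outside the primate clade. It prints:

```
selected hyper-parameters: {'epsilon': 1.0, 'alpha': 1.0}
test examples: 1000

test AUPR (higher is better):
  phylopgm        0.9962
  mean_of_scores  0.9879
  focal_only      0.4839

recall at 10% FDR: aggregation 0.997 vs focal alone 0.013
```

The weak base predictor alone ranks poorly (AUPR 0.48); averaging ortholog
scores helps but is diluted by the uninformative turnover clades; the
tree-aware aggregation learns per-branch likelihood ratios that down-weight
those lineages and ranks best. At a strict 10% false discovery rate it
recovers essentially all binding sites where the base predictor finds
almost none. `examples/04_branch_informativeness.py` shows the per-edge
diagnostic: every primate edge separates the classes (informativeness
+1.35 to +2.70) while every turnover edge sits within noise of zero
(|informativeness| ≤ 0.14).

Other examples: `01_reroot_tree.py` (rerooting invariants),
`02_fit_and_score.py` (score decomposition per example),
`05_stacking_baseline.py` (the tree-agnostic MLP baseline).

The same workflow is available as a CLI:

```bash
phylopgm simulate --tree tree.nwk --focal human --n 5000 --seed 7 --out-prefix sim
phylopgm fit --tree tree.nwk --focal human --train sim.train.tsv --out model.json
phylopgm predict --model model.json --scores sim.test.tsv --out preds.tsv
phylopgm evaluate --predictions preds.tsv --labels sim.test.tsv --out report.json
phylopgm demo --seed 7
```

Score tables are TSV: an `example_id` column, one column per tree node
(species or ancestor), empty/`NA` cells for missing orthologs, and an
optional 0/1 `label` column.

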