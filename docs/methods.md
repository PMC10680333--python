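# Methods

## Problem and model

Workflow platforms such as Galaxy represent an analysis as a directed
acyclic graph (DAG) whose nodes are tools.  While a user builds a workflow,
a recommender should predict which tools can extend the current tool or
tool sequence.  `flowrec` frames this as multi-class, multi-label sequence
classification: for a prefix of tools $x_1, \dots, x_t$, predict the set of
tools observed to follow that prefix anywhere in a training corpus.

The pipeline is:

1. **Mining.**  Each workflow DAG is decomposed into its maximal linear
   tool sequences — every simple path from an in-degree-0 tool to an
   out-degree-0 tool with at least two tools.  Non-tool steps (data
   inputs) are removed from parsed workflow files with their edges
   contracted, because the model reasons over tools only.  Duplicate edges
   are collapsed (recommendations are set-valued).
2. **Sample derivation.**  Every proper prefix of every sequence becomes
   one sample; its label set is the union over the corpus of the tools
   that immediately follow the prefix.  Prefixes longer than the model
   window N keep their most recent N tools *before* deduplication, so
   long contexts sharing a recent suffix merge.  N = 25; the longest
   sequences run to 28 tools, and the most recent context drives the next
   choice.
3. **Encoding.**  Tools map to integers 1..V assigned by descending corpus
   frequency (lexicographic tie-break); 0 is the padding index.  Prefixes
   are left-padded, so the most recent tool always occupies the final
   position; labels are multi-hot vectors of length V+1 whose index 0 is
   never set.
4. **Training.**  Adam (learning rate 0.001) minimises element-wise binary
   cross-entropy over the sigmoid outputs; the unused padding column is
   excluded from the loss so an always-zero target cannot dilute it.  The
   default budget is 35,000 iterations at batch size 512 with an 80/20
   train/test split; dropout 0.2 everywhere.
5. **Recommendation.**  Sigmoid scores are ranked (descending score,
   ascending index on ties), the padding slot is never recommended,
   deprecated tools are filtered, and survivors are re-ranked by last-year
   usage (ties by score, then name).

## Architectures

All four models share the embedding → representation → 128-unit hidden →
sigmoid output shape and differ in the representation block:

| model | representation | trainable parameters (V = 2354, N = 25) |
|---|---|---|
| transformer | 1 encoder block: 4-head self-attention (head dim 128), residual + layer norm, 2×128 feed-forward, residual + layer norm; final-position pooling | 922,291 |
| rnn | two stacked 128-unit GRU layers (reset-after biases), last state | — (see below) |
| cnn | 128-filter 16×3 valid conv on the (25, 128) embedding plane, relu, 2×2 max-pool (floor), flatten | 5,772,723 |
| dnn | flatten, two 128-unit relu dense layers | 1,031,603 |

Conventions that these counts pin down:

* the transformer and RNN embed V+1 rows (tools plus padding); the CNN and
  DNN embed V+2 rows (one extra reserved row, e.g. out-of-vocabulary) —
  the only combination consistent with all three counts above;
* per-head attention dimension is 128, so the total projection width is
  512 — smaller head sizes cannot reproduce 922,291;
* exactly one encoder block with two layer normalisations.

The commonly printed RNN figure of 241,063 parameters is not reproducible
from a 2,354-tool vocabulary under any standard GRU convention (it implies
a vocabulary of roughly 167 tools); the RNN here is built exactly as
described and its count follows the closed form
`3(d·u + u² + 2u)` per layer, but no specific total is asserted for it.

Choices the architecture description leaves open, fixed here:

* **Positional encoding** is a learned embedding (N × d_model), added to
  the token embedding.
* **Pooling** takes the representation at the final (most recent)
  position; with left-padding this is always a real tool.  Flattening or
  averaging would also be consistent with the parameter count of the
  pooled-path layers; final-position pooling mirrors the recency focus of
  next-tool recommendation.
* **Dropout placement**: after the embedding sum, after the attention
  output, after the feed-forward block, and after the hidden dense layer.
* **Attention masking**: padded key positions are masked out before the
  softmax, so each attention row is a probability distribution over the
  real tools; a fully padded input degenerates to an unmasked softmax so
  the forward pass stays finite.

## Numerical core

The models run on a small reverse-mode automatic-differentiation engine
(`flowrec.nn`) over float64 NumPy arrays.  Gradients of every operation are
validated against central differences (tolerance 1e-6) in the test suite,
and the framework-reported parameter counts are checked against the closed
forms for 20 random configurations per run.  All randomness flows through
`numpy.random.Generator` seeded from a single run seed, so forward passes,
training histories and written containers are bit-reproducible.  Backward
closures never reference their own output node, so spent computation
graphs free by reference counting; a training loop allocates no garbage
cycles.

## Frequency-balanced batches

Tool usage in real corpora is heavily skewed (common text tools appear
five orders of magnitude more often than specialist tools).  Batches are
therefore sampled by label-frequency quartile: each tool's label frequency
(number of samples containing it as a label) places it into one of four
bins split at the 25/50/75 percentiles; each batch slot first picks a bin
uniformly among bins that have eligible samples, then a sample whose label
set touches that bin, uniformly with replacement.  A tool exactly on a
percentile boundary stays in the lower bin so the rarest quartile is never
empty by construction.  Sampling is with replacement because the iteration
budget times the batch size exceeds any realistic corpus.

## Evaluation

`precision@k = |top-k(scores) ∩ labels| / k`, ranked by descending score
with ascending-index tie-break.  The default policy sets k to the size of
the sample's label set; a fixed-k mode (e.g. k = 20) is also available.
The infrequent-tool report restricts the test set to samples whose label
set intersects the rarest quartile bin ("any" semantics; an "all" mode is
exposed).  Model usage time is the median over repeats of the bundle
reconstruction time plus the median one-prediction time; the reported
total is the sum of the two medians, which keeps the additivity
`total = reconstruction + prediction` exact while staying robust to
warm-up outliers.

## Synthetic corpus generator

Real corpora cannot be redistributed, so every stage is exercised against
a generator with known ground truth.  A *tool grammar* is a layered DAG:
tools are spread over L layers (every layer non-empty) and each non-final
tool receives up to `branching_factor` successors in the next layer.
Layering makes acyclicity structural.  Tool frequency weights follow
`rank^(-skew)` over a randomly permuted ranking, giving a max/min weight
ratio of `n_tools^skew` (the default skew of 1.5 over tens of tools mirrors
the orders-of-magnitude spread of real tool usage).

Workflows are weighted random walks from a start tool (layer 0), with
lengths drawn from a shifted negative binomial truncated to [2, 28] and
calibrated so the median is 15 — the published corpus profile.  Branch
duplication then attaches, independently with probability `branch_prob`
(default 0.25), each unused grammar successor of each interior chain node
as an extra leaf edge, which is what makes one prefix map to several
labels.  At `branch_prob = 1` every workflow exposes the full successor
set of each interior tool, so corpus-derived label sets equal the
grammar's ground truth exactly.

What the generator does **not** emulate: tool parameters and datatypes,
correlated co-occurrence of tool suites, non-stationary usage over time,
and real tool-name semantics.  Tests passing on synthetic corpora
demonstrate the pipeline's correctness and the models' capacity to recover
a deterministic successor structure — not the headline accuracy achievable
on a production workflow corpus.

## Desk-scale reference experiment

The full-scale experiment (2,354 tools, 500,000 samples, 35,000 iterations)
needs the production corpus and days of compute.  The package instead ships
a desk-scale mirror (`flowrec.training.run_reference_experiment`): a
48-tool grammar over 10 layers (branching 2, skew 1.5), 800 workflows of
lengths 2–10 (median 6) with full branch coverage, and 32-wide models
(4 heads × 32 for the transformer) trained for 2,000 iterations at batch
size 64.  Because labels are saturated, the mapping is exactly learnable;
the converged transformer reaches mean test precision@k above 0.95 and the
matched DNN lands at or below it, mirroring the full-scale ordering.
These sizes were chosen once as the smallest task on which convergence is
clean and reproducible.

## Known limitations

* Duplicate tools within one workflow collapse to a single graph node;
  self-loops arising from repeated tools are dropped rather than modelled.
* Path enumeration is exponential in pathological DAGs (it is linear in
  the tree-like workflows the generator produces and real corpora mostly
  contain).
* Datatype-compatibility filtering is represented only by the externally
  supplied deprecated/invalid tool list; inferring compatibility would
  need the platform's tool registry.
* The engine is CPU-only float64 NumPy; it is meant for correctness and
  desk-scale experiments, not production-scale training throughput.
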