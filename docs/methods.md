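# Methods

## Overview

`topogen` trains a conditional autoregressive language model over
amino-acid tokens to generate small protein sequences that fold into a
requested secondary-structure topology (e.g. `HHH`, a three-helix
bundle; `EHEE`, a strand–helix–strand–strand fold).  Training has two
stages:

1. **Pretraining** by maximum likelihood on a labelled sequence corpus.
2. **Fine-tuning** by policy-gradient reinforcement learning against a
   reward that combines a real/fake discriminator with a stability
   scorer, updated adversarially.

Everything is exercisable at desk scale through a synthetic sequence
world whose secondary structure and stability are deterministic
functions of the sequence, so every stage of the pipeline has an
independent oracle.

## Conditional language model

A training example is the composite token stream `x = [t; a]`: one or
more topology-label tokens `t` prepended to the residue sequence `a`,
with a sequence-end mark appended.  Two label schemes exist: one
lowercase letter per topology (`i` ↔ `HHH`, `j` ↔ `HHHH`, further keys
taking the next free letters; capacity 18), or the delimited form
`<hhh>` in which `<`, `>` and each lowercase structure letter are
separate tokens.  The model factorizes

    p_θ(x) = Π_i p_θ(x_i | x_<i)

and only residue tokens and the end mark are ever predicted: label and
pad tokens are masked out of the output layer (their probability is
exactly zero), and pad positions are excluded from the loss.  The
padded layout reserves `max_len` slots (default 80) for residues plus
the end mark, with label tokens prepended on top of that budget; a
record therefore needs `len(residues) + 1 <= max_len`.

The training loss is the dataset mean of the per-sequence mean
negative log-likelihood over predicted positions,

    L(D) = -(1/|D|) Σ_k (1/n^k) Σ_i log p_θ(x_i^k | x_<i^k),

where `n^k` counts predicted positions only (residues + end).  Counting
the same positions in the numerator and the normalizer keeps the
per-position average meaningful under masking.

Two backends satisfy one next-token-distribution contract
(normalization to 1 within 1e-6; causality; hard masking):

* **Transformer decoder** (primary): pre-norm architecture, default 5
  layers × 8 heads with per-head q/k/v dimension 32 (so
  `d_model = 8 × 32 = 256` by standard head concatenation), feed-forward
  512, sinusoidal positions (learned positions available).
* **LSTM** (control): default 10 layers × 1024 units with carried cell
  state.

Weights are truncated-normal initialized (±2 σ, σ = 0.02),
seed-controlled.  Because no GPU framework is assumed, the models run
on a small in-package reverse-mode autodiff engine over NumPy arrays
(`topogen.autodiff`); a finite-difference gradient check in the test
suite validates backpropagation through both backends to 1e-4 relative
error.  Sampling uses a separate pure-NumPy incremental decoding path
(per-layer key/value cache for the transformer, carried state for the
LSTM) that is bit-identical to the training forward pass; the parity is
asserted in the tests.

Generation starts from the label tokens and samples token by token
(multinomial at temperature 1.0 by default; greedy argmax mode is
exposed separately and is rejected by the RL machinery, whose estimator
is only valid for stochastic draws).  Generation stops at the end mark
or after `max_len` residues; truncated sequences are flagged, and the
self-terminated fraction is reported by the CLI.

## Fine-tuning: adversarial reinforcement learning

Each fine-tuning epoch runs a three-step loop on a single-topology
dataset:

1. the generator samples a batch of sequences for the target label;
2. a discriminator `D` (residue embedding → window-5 convolutional
   encoder → masked mean-pool → MLP → sigmoid) takes one training round
   on fine-tuning-set sequences vs. the fresh samples (balanced 1:1,
   binary cross-entropy, 5 Adam steps by default, fake set resampled
   every epoch);
3. each sample is scored by `D(x) ∈ [0,1]` and a stability scorer
   `P(x)`, combined into the reward

       thresholded:          R(x) = λ1·D(x)  if P(x) ≥ 1.0 else λ2·D(x)
       product:              R(x) = P(x)·D(x)
       discriminator-only:   R(x) = D(x)

   with defaults λ1 = 1.2, λ2 = 0.6, threshold 1.0 (a score exactly at
   the threshold counts as stable).  The two ablation modes reproduce
   the "multiply the scores" and "discriminator only" reward variants;
   with λ1 = λ2 the thresholded reward provably ignores stability.

The policy-gradient (REINFORCE) step treats the partial sequence as the
state and the next residue as the action.  The surrogate loss is

    -mean_k (R_k − b) Σ_i log p_θ(token_i | prefix)

summed over predicted positions; `b` is a running-mean reward baseline
(variance reduction; on by default, disable to match the plain
estimator, which is what the unbiasedness test exercises).  Rewards are
sequence-level and applied uniformly to all positions — per-token
credit assignment is deliberately out of scope.  The generator and the
discriminator are never updated in the same optimizer step.

Defaults follow the full-scale recipe: 50 epochs × 150 sequences, Adam
at 1e-6 peak with linear warm-up (10% of steps) and cosine annealing to
a 1% floor; the checkpoint with the lowest mean negative reward
(highest mean reward, earliest epoch on ties) is selected.  The
schedule's closed form is tested at the warm-up boundary and the cosine
midpoint.

**Central correctness property.**  On a fully enumerable toy space
(residue length ≤ 2) the Monte-Carlo gradient from 10,000 sampler draws
is compared coordinate-wise with the exact gradient
`Σ_x p(x) R(x) ∇log p(x)`.  Because ~800 coordinates are tested
jointly, the acceptance test asserts the multiplicity-aware reading of
"within 3 standard errors": at most 1% of coordinates beyond 3 SE
(the chance rate is ~0.27%) and none beyond 5 SE.

## Stability scorers

`StabilityScorer` is a contract: any deterministic callable from a
residue string to a finite float.  Implementations:

* **Toy trainable scorer** — residue embedding → window-5 conv encoder
  → masked mean-pool → linear head, trained by MSE on (sequence, score)
  pairs; held-out Pearson r is recorded (≥ 0.95 on the synthetic
  fine-tuning set).  This stands in for a large pretrained
  encoder + MLP stability predictor, at desk scale.
* **Synthetic oracle** — the world's own stability function (below).
* **Score table** — precomputed scores keyed by sequence.

RL optimizes the *learned* toy scorer while the synthetic oracle
arbitrates evaluation, so the fine-tuning test is not circular.

## Topology derivation from DSSP

Real-data mode consumes classic fixed-column DSSP text.  The structure
code is the first character of the summary column (blank → `C`);
chain-break rows (`!`) and chain-id changes split chains;
disulfide-bridge cysteines (lowercase letters) are normalized to `C`.
The topology string scans the per-residue codes left to right: maximal
runs of `H` of length ≥ 3 emit `H`, maximal runs of `E` of length ≥ 2
emit `E`, and every other code (`G`, `I`, `T`, `S`, `B`, coil) is a
separator.  Only true α-helix and strand codes count — a 3₁₀-helix is
not a helix element.  The minimum run lengths are configurable and
echoed in output metadata; the defaults encode the judgement that a
single stray assignment should not create a topology element.  A
regular-expression oracle re-derives the topology independently in the
tests (1000 random code strings).

Records whose topology has no vocabulary label are routed to a reject
list with reasons.  An optional pre-filter keeps records whose
structure-agreement score (e.g. a TM-score between a predicted and a
reference structure, supplied by the user) strictly exceeds a threshold,
default 0.9.

## Synthetic world

The world partitions the 20 residues into helix-formers (`AELMQKR`),
strand-formers (`VIYWFT`) and loop-formers (`GPSNDHC`) — a 7/6/7 split
loosely mirroring real propensities so emitted FASTA looks
protein-like; tests depend only on the partition's existence.  A
sequence is built as alternating loop/element segments (loops flank and
separate elements) with lengths drawn uniformly: helix 9–14, strand
6–9, loop 6–9.  Each position draws from its segment's class with
probability `1 − ε` (default ε = 0.1) and uniformly from the other
classes otherwise.

*Structure oracle.*  Per-residue class codes smoothed by a centred
majority window of 7 (ties keep the centre's class, then the fixed
order H, E, C).  The window and the segment minima are jointly sized so
that isolated and paired noise residues are smoothed away rather than
splitting an element or spawning a spurious strand: at ε = 0.1, ≥ 95%
of draws (measured ~97%) still collapse to their generating topology
under the default minimum-run settings, and at ε = 0 the recovery is
exact.  These two requirements are what fixed the window at 7 and the
loop minimum at 6: a window of 3 leaves adjacent same-class noise pairs
as spurious two-residue strands, and short loops are overwhelmed by a
single helix-former.

*Stability oracle.*  Let `c` be the fraction of positions whose own
class is a (tied-)majority of the *other* residues in a window of 5
around it (leave-one-out; ties favour the position's own class).
Excluding the centre residue matters: a residue only counts as
consistent when its neighbours define the structure it fits into,
rather than the sequence trivially agreeing with itself.  The score is
the affine calibration

    P(x) = 1 + (c − c₀) / (1 − c₀),   c₀ = 0.87,

so a noise-free construction (`c = 1`) scores exactly 2.0 for any
centre, `c₀ = 0.5` recovers plain doubled consistency `2c`, and the
default centre — the median consistency of the ε = 0.1 generating
regime — places the 1.0 stable/unstable threshold at the dataset
median.  Consequences, all measured: ~55% of a generated dataset is
stable; a faithfully imitating generator starts near 50% stable,
leaving fine-tuning genuine headroom; uniform-random sequences
(`c ≈ 0.42`) score ≈ −2.5 and are firmly unstable.  Without the
calibration the threshold is vacuous (random sequences would score
1.58) and no stable-fraction improvement would be observable.

Both oracles are pure functions of the residues, so they serve as the
evaluation module's structure source and as a StabilityScorer without
circularity.

*What the world does not emulate:* real protein energetics, long-range
residue contacts, backbone-library sequence statistics, or any
length/composition biases of real mini-protein libraries.  Passing
tests demonstrate that the training machinery optimizes what it is
pointed at — not that generated sequences would fold in the laboratory.

## Evaluation

* **Topology proportion** — fraction of sequences whose derived
  topology equals the target exactly, with structure strings from DSSP
  files (real mode) or the synthetic oracle.
* **Stability statistics** — stable fraction (score ≥ 1.0) and mean
  score under any scorer.
* **Identity** — global Needleman–Wunsch alignment (match +1,
  mismatch 0, linear gap −1; configurable), identity = matches /
  alignment length, computed by Biopython's pairwise aligner.  The
  argument pair is canonicalized (sorted) before aligning so ties among
  co-optimal alignments cannot break symmetry.  This is a deterministic
  proxy for BLAST-style local identity, adequate for same-length
  mini-proteins but not numerically interchangeable with it.
  `max_identity` scans a reference set (first-occurrence tie-break).
* **Clustering** — greedy centroid assignment: sequences sorted
  lexicographically (making counts order-independent), each joining the
  first centroid at identity ≥ threshold (default 0.5) or founding a
  new cluster.  The cluster count is the diversity index.
* **Report** — aggregates the above into JSON/TSV; absent inputs leave
  fields `None` (never fabricated); a column is reserved for externally
  computed structure-similarity (TM-like) scores, which the package
  does not compute.

## Desk-scale study conditions

The reproducible study in `topogen.study` (used by the acceptance
script and the heavyweight tests) fixes:

| quantity | value |
| --- | --- |
| dataset | 1000 HHH + 1000 EHEE, ε = 0.1, lengths 57–66 |
| model | transformer, 2 layers × 4 heads × head-dim 16, ff 128 |
| pretraining | 10 epochs, batch 64, Adam 1e-3, clip 1.0 |
| toy scorer | window 5, 1500 steps at 3e-3, 20% holdout |
| discriminator | 200 steps at 1e-3 (sanity check), 5 steps/epoch in RL |
| fine-tuning | 30 epochs × 100 sequences, Adam peak 3e-4, thresholded reward λ1 = 1.2, λ2 = 0.6 |
| evaluation | 500 samples per condition, temperature 1.0 |

The 57–66 length band is the feasible overlap of both topologies'
segment layouts.  The desk transformer and the 3e-4 RL rate are the
package's CPU-scale operating point; the full-scale defaults (5 × 8 ×
32 / ff 512; RL at 1e-6 over 50 × 150) remain the configuration
defaults and are what a GPU-scale run would use.  All seeds derive from
a single study seed; two runs with the same seed are bit-identical.

## Numerical choices and edge cases

* Hard masking uses an additive −1e30 in logit space; probabilities of
  masked tokens underflow to exactly zero, and a zero-probability token
  inside `sequence_log_prob` returns −∞ with a warning rather than
  raising.
* Sequences that hit the residue budget are truncated without an end
  mark; their probability mass is accounted as such, which is why the
  enumeration test's total sampling-outcome mass sums to 1.
* NLL batches are padded to the batch's own width; trailing pad columns
  are provably inert (causality + loss masking).
* Gradient clipping at global norm 1.0; Adam with bias correction;
  float64 throughout (determinism and gradient-check headroom outweigh
  the ~2× speed of float32 at these sizes).
* Checkpoints are a JSON sidecar (architecture + vocabulary + seed)
  plus an NPZ of weights; a load round-trip reproduces next-token
  distributions bit-identically.
* Empty inputs, mixed-topology fine-tuning sets, unknown residues,
  non-finite scores, greedy samples fed to the policy gradient, and
  missing per-record scores all raise typed exceptions
  (`topogen.errors`).

## Known limitations

* The identity metric is global, not local; BLAST-style identities on
  sequences of very different lengths will differ.
* The stability scorers are sequence-level surrogates; no structure
  prediction, energy function, or molecular dynamics is performed, and
  externally computed structure scores enter only as optional inputs.
* The LSTM control backend at its full default size (10 × 1024) is
  impractical on one CPU; it exists to satisfy the shared contract and
  is exercised at small sizes.
* Fine-tuning optimizes a learned scorer; if that scorer generalizes
  badly the reward can be gamed.  The study guards this by reporting
  the scorer's held-out correlation and by evaluating with the
  independent oracle.
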