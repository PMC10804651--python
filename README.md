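# topogen

Topology-conditioned generation of small protein sequences with an
autoregressive language model, fine-tuned by adversarial reinforcement
learning for stability.

## The problem

De novo mini-protein design often starts from a target *topology* — the
ordered pattern of secondary-structure elements, e.g. `HHH` for a
three-helix bundle or `EHEE` for a strand–helix–strand–strand fold.
Sequence databases carry almost no such structural annotation, so
general protein language models cannot be steered toward a fold.
`topogen` trains a conditional autoregressive model in which a topology
tag `t` is prepended to the amino-acid sequence `a`, forming the
composite stream `x = [t; a]`; the model learns
`p_θ(x) = Π_i p_θ(x_i | x_<i)` by minimizing the masked negative
log-likelihood

```
L(D) = -(1/|D|) Σ_k (1/n^k) Σ_i log p_θ(x_i^k | x_<i^k)
```

over predicted positions (residues and the end mark only).  Sampling
from the trained model with a chosen tag yields sequences biased toward
that fold.  A second stage sharpens *stability*: a REINFORCE
policy-gradient loop maximizes the reward

```
R(x) = λ1·D(x)  if P(x) ≥ 1.0      (stable branch,  λ1 = 1.2)
R(x) = λ2·D(x)  otherwise          (unstable branch, λ2 = 0.6)
```

where `D(x)` is an adversarially trained real/fake discriminator and
`P(x)` a stability scorer (scores ≥ 1.0 denote "stable"); product and
discriminator-only reward variants cover the ablations.  The backbone
is a transformer decoder (an LSTM control backend shares the same
next-token contract), implemented on a small in-package NumPy autodiff
engine so the whole pipeline runs on one CPU.

A fully specified *synthetic sequence world* — residue classes,
segment grammar, a deterministic secondary-structure oracle and a
calibrated stability oracle — makes every stage testable end to end
without external data.  Real-data mode consumes classic DSSP output
for topology labelling instead.

## Worked example

```
$ topogen synth --mix HHH=1000,EHEE=1000 --seed 1 --length-range 57,66 --out data/
wrote 2000 records to data

$ topogen pretrain --fasta data/dataset.fasta --out-dir run/ \
    --preset desk --epochs 10 --seed 2
final NLL 2.4266; checkpoints in run/

$ topogen generate --checkpoint run/final --label HHH --n 200 \
    --length 79 --seed 3 --out gen.fasta
wrote 200 sequences; self-terminated fraction 1.000

$ topogen evaluate --fasta gen.fasta --target HHH \
    --world data/world.json --out report.json
{
  "n_sequences": 200,
  "target_topology": "HHH",
  "topology_proportion": 0.93,
  "stable_proportion": 0.555,
  "mean_stability": 1.0012332349552517,
  "n_clusters": 200,
  ...
}
```

Reading the numbers: after a ten-epoch desk-scale pretraining on 2000
sequences (~3 CPU-minutes), 93% of `HHH`-conditioned samples collapse
to exactly the `HHH` topology under the world's structure oracle (a
uniform-random baseline achieves well under 2%), 55.5% clear the 1.0
stability threshold — about the training data's own stable fraction, as
expected for a likelihood-trained imitator — and all 200 samples fall
into distinct clusters at 50% identity, i.e. the model is not
memorizing.  Fine-tuning (`topogen finetune --reward thresholded
--lambda1 1.2 --lambda2 0.6 ...`) then pushes the stable fraction up;
the study run below nearly doubles it.

## Package layout

| module | contents |
| --- | --- |
| `topogen.vocab`, `topogen.sequences` | token vocabulary (single-letter and `<xxx>` label schemes), encoding/padding, labelled FASTA I/O |
| `topogen.dssp` | classic DSSP parsing, topology-string derivation, dataset labelling, score pre-filter |
| `topogen.autodiff` | reverse-mode autodiff over NumPy, Adam, gradient clipping |
| `topogen.models` | transformer / LSTM generators, sampling (KV-cache decoding), log-probabilities, random baseline, checkpoints |
| `topogen.pretrain` | masked NLL loss and the pretraining loop |
| `topogen.finetune` | reward modes, discriminator, toy stability scorer, LR schedule, REINFORCE, fine-tuning loop |
| `topogen.evaluation` | topology proportion, stability stats, pairwise/max identity, greedy clustering, reports |
| `topogen.synthetic` | the synthetic world: generator, structure oracle, stability oracle, dataset builder |
| `topogen.study` | the fixed desk-scale study used by the acceptance script |
| `topogen.cli` | `topogen synth / label / pretrain / generate / finetune / evaluate / random-baseline` |

See `docs/methods.md` for the model, the reward, the synthetic world's
calibration, and the package's numerical choices and limitations.
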