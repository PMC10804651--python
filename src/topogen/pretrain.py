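"""Maximum-likelihood pretraining of the generator.

The loss is the dataset-mean of per-sequence mean negative
log-likelihood over *predicted* positions only: residue tokens and the
end mark count toward both the sum and the normalizer, while label and
pad positions are excluded.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Adam, Tensor, clip_global_norm
from .errors import TopogenError
from .models import GeneratorModel, token_log_probs
from .sequences import LabeledSequence, SequenceDataset, encode_batch


@dataclass
class PretrainConfig:
    epochs: int = 5
    batch_size: int = 64
    lr: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    clip_norm: float = 1.0
    max_len: int = 80
    seed: int = 0
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.lr <= 0:
            raise TopogenError("epochs, batch_size must be >= 1 and lr > 0")


@dataclass
class EpochRecord:
    epoch: int
    mean_nll: float
    seconds: float
    checkpoint: str | None = None


@dataclass
class TrainingHistory:
    epochs: list[EpochRecord] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch\tmean_nll\tseconds\tcheckpoint\n")
            for r in self.epochs:
                fh.write(f"{r.epoch}\t{r.mean_nll!r}\t{r.seconds:.2f}\t{r.checkpoint or ''}\n")

    def mean_nlls(self) -> list[float]:
        return [r.mean_nll for r in self.epochs]


def nll_loss(model: GeneratorModel, batch: list[LabeledSequence],
             max_len: int | None = None) -> Tensor:
    """Mean over sequences of per-predicted-position mean negative log-prob."""
    if not batch:
        raise TopogenError("empty batch")
    if max_len is not None:
        longest = max(len(r.residues) for r in batch)
        if longest + 1 > max_len:
            raise TopogenError(f"batch contains {longest} residues; max_len={max_len}")
    # right-pad only to the batch's own width; trailing pad columns are inert
    ids, _ = encode_batch(batch, model.vocab, None)
    logp, _, predicted = token_log_probs(model, ids)
    pmask = Tensor(predicted.astype(np.float64))
    counts = predicted.sum(axis=1).astype(np.float64)
    if (counts == 0).any():
        raise TopogenError("a sequence has no predicted positions")
    per_seq = (logp * pmask).sum(axis=1) * Tensor(1.0 / counts)
    return -per_seq.mean()


def pretrain(
    model: GeneratorModel,
    dataset: SequenceDataset,
    config: PretrainConfig | None = None,
) -> tuple[GeneratorModel, TrainingHistory]:
    """Minimize the NLL with Adam; fully reproducible from ``config.seed``."""
    config = config or PretrainConfig()
    unknown = set(dataset.labels()) - set(model.vocab.label_keys)
    if unknown:
        raise TopogenError(f"dataset labels not in vocabulary: {sorted(unknown)}")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.lr, betas=config.betas)
    history = TrainingHistory()
    ckpt_dir = Path(config.checkpoint_dir) if config.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)
    best = np.inf
    records = list(dataset.records)
    for epoch in range(1, config.epochs + 1):
        t0 = time.time()
        order = rng.permutation(len(records))
        total, weight = 0.0, 0
        for lo in range(0, len(records), config.batch_size):
            batch = [records[i] for i in order[lo: lo + config.batch_size]]
            loss = nll_loss(model, batch, max_len=config.max_len)
            val = loss.item()
            if not np.isfinite(val):
                raise TopogenError(f"training diverged (NLL={val}) at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            clip_global_norm(model.parameters(), config.clip_norm)
            opt.step()
            total += val * len(batch)
            weight += len(batch)
        mean_nll = total / weight
        ckpt_path = None
        if ckpt_dir:
            if mean_nll < best:
                model.save(ckpt_dir / "best")
            model.save(ckpt_dir / "final")
            ckpt_path = str(ckpt_dir / "final")
        best = min(best, mean_nll)
        history.epochs.append(
            EpochRecord(epoch=epoch, mean_nll=mean_nll,
                        seconds=time.time() - t0, checkpoint=ckpt_path)
        )
    return model, history
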