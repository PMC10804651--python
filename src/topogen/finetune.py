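"""Adversarial + reinforcement-learning fine-tuning.

Each epoch runs the three-step loop: (1) the generator samples a batch
of sequences for the target topology; (2) a real/fake discriminator is
trained on fine-tuning-set sequences vs. the fresh samples; (3) every
sample is scored by the discriminator D(x) and a stability scorer P(x),
combined into a reward

    thresholded:          R = lambda1 * D   if P >= threshold else  lambda2 * D
    product ("OriScale"): R = P * D
    discriminator_only:   R = D

and a REINFORCE policy-gradient step maximizes the expected reward,
with an optional running-mean baseline for variance reduction.  The
best checkpoint is the epoch with the highest mean reward (lowest mean
negative reward), earliest epoch on ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor, clip_global_norm
from .errors import ContractError, ScorerError, TopogenError
from .models import GeneratorModel, SampledSequence, sample_sequences, token_log_probs
from .sequences import SequenceDataset
from .vocab import AA_ALPHABET

# A stability scorer is any deterministic callable residues -> finite float.
StabilityScorer = Callable[[str], float]


# -- reward -----------------------------------------------------------------

REWARD_MODES = ("thresholded", "product", "discriminator_only")


@dataclass
class RewardConfig:
    mode: str = "thresholded"
    lambda1: float = 1.2
    lambda2: float = 0.6
    threshold: float = 1.0

    def __post_init__(self):
        if self.mode not in REWARD_MODES:
            raise TopogenError(f"unknown reward mode {self.mode!r}")
        if self.lambda1 < 0 or self.lambda2 < 0 or not np.isfinite(self.threshold):
            raise TopogenError("lambda1, lambda2 must be >= 0 and threshold finite")


@dataclass
class RewardBreakdown:
    d_score: float
    p_score: float
    reward: float
    stable: bool


def reward(d_score: float, p_score: float, cfg: RewardConfig) -> RewardBreakdown:
    """Combine discriminator and stability scores; P == threshold is stable."""
    if not (np.isfinite(d_score) and np.isfinite(p_score)):
        raise TopogenError("reward inputs must be finite")
    if not 0.0 <= d_score <= 1.0:
        raise TopogenError(f"discriminator score {d_score} outside [0, 1]")
    stable = p_score >= cfg.threshold
    if cfg.mode == "thresholded":
        r = (cfg.lambda1 if stable else cfg.lambda2) * d_score
    elif cfg.mode == "product":
        r = p_score * d_score
    else:
        r = d_score
    return RewardBreakdown(d_score=d_score, p_score=p_score, reward=r, stable=stable)


# -- sequence encoders (shared by discriminator and toy scorer) -------------


class _ConvEncoder:
    """Embedding + windowed convolution + masked mean-pool, on residue tokens."""

    def __init__(self, embed_dim: int, hidden_dim: int, window: int,
                 rng: np.random.Generator):
        self.window = window
        self.embed_dim = embed_dim
        self.hidden_dim = hidden_dim
        n_aa = len(AA_ALPHABET)
        std = 0.1
        self.params: dict[str, Tensor] = {
            "emb": Tensor(rng.normal(0, std, (n_aa, embed_dim)), requires_grad=True),
            "w_conv": Tensor(
                rng.normal(0, std, (window * embed_dim, hidden_dim)), requires_grad=True
            ),
            "b_conv": Tensor(np.zeros(hidden_dim), requires_grad=True),
        }
        self._aa_index = {c: i for i, c in enumerate(AA_ALPHABET)}

    def encode_ids(self, sequences: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        w = self.window
        width = max(max(len(s) for s in sequences), w)
        ids = np.zeros((len(sequences), width), dtype=np.int64)
        mask = np.zeros((len(sequences), width))
        for i, s in enumerate(sequences):
            for j, c in enumerate(s):
                try:
                    ids[i, j] = self._aa_index[c]
                except KeyError as exc:
                    raise ScorerError(f"non-canonical residue {c!r}") from exc
            mask[i, : len(s)] = 1.0
        return ids, mask

    def forward(self, sequences: Sequence[str]) -> Tensor:
        """Pooled feature vector per sequence, shape (B, hidden_dim)."""
        ids, mask = self.encode_ids(sequences)
        B, T = ids.shape
        w = self.window
        emb = ad.embedding(self.params["emb"], ids)  # (B, T, E)
        n_win = T - w + 1
        windows = [emb[:, k: k + n_win, :] for k in range(w)]
        stacked_data = [win for win in windows]
        cat = _concat_last(stacked_data)  # (B, n_win, w*E)
        h = (cat @ self.params["w_conv"] + self.params["b_conv"]).relu()
        # a window is valid when fully inside the unpadded sequence
        valid = np.ones((B, n_win))
        for k in range(w):
            valid *= mask[:, k: k + n_win]
        vm = Tensor(valid[:, :, None])
        denom = Tensor(np.maximum(valid.sum(axis=1), 1.0)[:, None])
        return (h * vm).sum(axis=1) / denom

    def parameters(self) -> list[Tensor]:
        return [self.params[k] for k in sorted(self.params)]


def _concat_last(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the last axis via stack + reshape-free interleave."""
    # stack to (B, n, k, E) then reshape to (B, n, k*E)
    st = ad.stack(tensors, axis=2)
    B, n, k, E = st.shape
    return st.reshape(B, n, k * E)


class Discriminator:
    """Real-vs-generated sequence classifier with output in [0, 1]."""

    def __init__(self, embed_dim: int = 16, hidden_dim: int = 64, window: int = 5,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.encoder = _ConvEncoder(embed_dim, hidden_dim, window, rng)
        self.params = {
            "w_h": Tensor(rng.normal(0, 0.1, (hidden_dim, hidden_dim)), requires_grad=True),
            "b_h": Tensor(np.zeros(hidden_dim), requires_grad=True),
            "w_o": Tensor(rng.normal(0, 0.1, (hidden_dim, 1)), requires_grad=True),
            "b_o": Tensor(np.zeros(1), requires_grad=True),
        }

    def forward(self, sequences: Sequence[str]) -> Tensor:
        pooled = self.encoder.forward(sequences)
        h = (pooled @ self.params["w_h"] + self.params["b_h"]).relu()
        return (h @ self.params["w_o"] + self.params["b_o"])[:, 0].sigmoid()

    def scores(self, sequences: Sequence[str]) -> np.ndarray:
        return self.forward(sequences).data

    def parameters(self) -> list[Tensor]:
        return self.encoder.parameters() + [self.params[k] for k in sorted(self.params)]


def train_discriminator(
    disc: Discriminator,
    real: Sequence[str],
    fake: Sequence[str],
    steps: int = 200,
    lr: float = 1e-3,
    batch_size: int = 64,
    holdout_frac: float = 0.2,
    rng: np.random.Generator | int | None = None,
) -> tuple[Discriminator, dict]:
    """Binary cross-entropy training on balanced real/fake batches."""
    if not real or not fake:
        raise TopogenError("both real and fake sets must be non-empty")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    real, fake = list(real), list(fake)

    def _n_hold(n: int) -> int:
        if holdout_frac <= 0 or n <= 4:
            return 0
        return max(1, int(n * holdout_frac))

    n_hr, n_hf = _n_hold(len(real)), _n_hold(len(fake))
    hold_real, train_real = real[:n_hr], real[n_hr:] or real
    hold_fake, train_fake = fake[:n_hf], fake[n_hf:] or fake
    opt = Adam(disc.parameters(), lr=lr)
    half = max(1, batch_size // 2)
    last_loss = np.nan
    for _ in range(steps):
        ri = rng.integers(0, len(train_real), size=half)
        fi = rng.integers(0, len(train_fake), size=half)
        seqs = [train_real[i] for i in ri] + [train_fake[i] for i in fi]
        y = np.concatenate([np.ones(half), np.zeros(half)])
        p = disc.forward(seqs)
        eps = 1e-9
        loss = -(
            Tensor(y) * (p + eps).log() + Tensor(1.0 - y) * (1.0 - p + eps).log()
        ).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        last_loss = loss.item()
    metrics: dict = {"final_loss": last_loss}
    if hold_real or hold_fake:
        hp = disc.scores(hold_real + hold_fake)
        hy = np.concatenate([np.ones(len(hold_real)), np.zeros(len(hold_fake))])
        metrics["holdout_accuracy"] = float(((hp >= 0.5) == hy).mean())
    return disc, metrics


# -- toy stability scorer ---------------------------------------------------


class ToyStabilityScorer:
    """Trainable sequence-to-stability regressor (conv encoder + linear head)."""

    def __init__(self, embed_dim: int = 8, hidden_dim: int = 64, window: int = 5,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.encoder = _ConvEncoder(embed_dim, hidden_dim, window, rng)
        self.params = {
            "w_o": Tensor(rng.normal(0, 0.1, (hidden_dim, 1)), requires_grad=True),
            "b_o": Tensor(np.zeros(1), requires_grad=True),
        }
        self.metrics: dict = {}

    def forward(self, sequences: Sequence[str]) -> Tensor:
        pooled = self.encoder.forward(sequences)
        return (pooled @ self.params["w_o"] + self.params["b_o"])[:, 0]

    def predict(self, sequences: Sequence[str]) -> np.ndarray:
        return self.forward(sequences).data

    def __call__(self, residues: str) -> float:
        return float(self.predict([residues])[0])

    def parameters(self) -> list[Tensor]:
        return self.encoder.parameters() + [self.params[k] for k in sorted(self.params)]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"enc.{k}": v.data for k, v in self.encoder.params.items()}
        arrays.update({f"head.{k}": v.data for k, v in self.params.items()})
        arrays["shape"] = np.array(
            [self.encoder.embed_dim, self.encoder.hidden_dim, self.encoder.window]
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ToyStabilityScorer":
        with np.load(path) as npz:
            e, h, w = (int(v) for v in npz["shape"])
            scorer = cls(embed_dim=e, hidden_dim=h, window=w)
            for k in scorer.encoder.params:
                scorer.encoder.params[k].data = npz[f"enc.{k}"].astype(np.float64)
            for k in scorer.params:
                scorer.params[k].data = npz[f"head.{k}"].astype(np.float64)
        return scorer


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def train_toy_stability_scorer(
    sequences: Sequence[str],
    targets: Sequence[float],
    steps: int = 1500,
    lr: float = 3e-3,
    batch_size: int = 64,
    holdout_frac: float = 0.2,
    seed: int = 0,
    scorer: ToyStabilityScorer | None = None,
) -> ToyStabilityScorer:
    """Fit the toy regressor; held-out Pearson r lands in ``scorer.metrics``."""
    sequences = list(sequences)
    targets = np.asarray(targets, dtype=np.float64)
    if len(sequences) < 100:
        raise TopogenError("at least 100 labelled examples are required")
    if len(sequences) != len(targets):
        raise TopogenError("one target per sequence is required")
    if np.ptp(targets) == 0:
        raise TopogenError("degenerate constant targets")
    rng = np.random.default_rng(seed)
    scorer = scorer or ToyStabilityScorer(seed=seed)
    n_hold = max(1, int(len(sequences) * holdout_frac))
    hold_x, hold_y = sequences[:n_hold], targets[:n_hold]
    train_x, train_y = sequences[n_hold:], targets[n_hold:]
    opt = Adam(scorer.parameters(), lr=lr)
    for _ in range(steps):
        idx = rng.integers(0, len(train_x), size=min(batch_size, len(train_x)))
        pred = scorer.forward([train_x[i] for i in idx])
        err = pred - Tensor(train_y[idx])
        loss = (err * err).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
    hold_pred = scorer.predict(hold_x)
    scorer.metrics = {
        "holdout_pearson_r": _pearson(hold_pred, hold_y),
        "holdout_rmse": float(np.sqrt(((hold_pred - hold_y) ** 2).mean())),
        "n_train": len(train_x),
        "n_holdout": n_hold,
    }
    return scorer


class SyntheticOracleScorer:
    """Adapter exposing the synthetic world's stability oracle as a scorer."""

    def __init__(self, world):
        from .synthetic import synthetic_stability

        self._world = world
        self._fn = synthetic_stability

    def __call__(self, residues: str) -> float:
        return self._fn(self._world, residues)


class TableScorer:
    """Scorer backed by a precomputed ``sequence -> score`` table."""

    def __init__(self, table: dict[str, float]):
        self.table = dict(table)

    def __call__(self, residues: str) -> float:
        try:
            return self.table[residues]
        except KeyError as exc:
            raise ScorerError(f"no precomputed score for sequence {residues[:12]}...") from exc


# -- learning-rate schedule -------------------------------------------------


@dataclass
class ScheduleConfig:
    peak_lr: float
    warmup_steps: int
    cosine_period: int
    floor_lr: float = 0.0


def lr_schedule(step: int, cfg: ScheduleConfig) -> float:
    """Linear warm-up to ``peak_lr`` then cosine decay to ``floor_lr``.

    step 0 -> 0; step == warmup_steps -> peak; midpoint of the cosine phase
    -> (peak + floor) / 2; beyond warmup + period -> floor.
    """
    if step < 0:
        raise TopogenError("step must be >= 0")
    if cfg.warmup_steps > 0 and step <= cfg.warmup_steps:
        return cfg.peak_lr * step / cfg.warmup_steps
    t = step - cfg.warmup_steps
    if t >= cfg.cosine_period:
        return cfg.floor_lr
    span = cfg.peak_lr - cfg.floor_lr
    return cfg.floor_lr + 0.5 * span * (1.0 + math.cos(math.pi * t / cfg.cosine_period))


# -- policy gradient --------------------------------------------------------


class RunningMeanBaseline:
    """Cumulative mean of observed rewards; reads 0 until first update."""

    def __init__(self, enabled: bool = True):
        self.enabled = enabled
        self.total = 0.0
        self.count = 0

    @property
    def value(self) -> float:
        if not self.enabled or self.count == 0:
            return 0.0
        return self.total / self.count

    def update(self, rewards: Sequence[float]) -> None:
        if self.enabled:
            self.total += float(np.sum(rewards))
            self.count += len(rewards)


def policy_gradient_step(
    model: GeneratorModel,
    samples: Sequence[SampledSequence],
    rewards: Sequence[RewardBreakdown],
    baseline: RunningMeanBaseline,
    optimizer: Adam,
    clip_norm: float = 1.0,
    update_baseline: bool = True,
) -> dict:
    """One REINFORCE update from stochastically sampled sequences.

    Surrogate loss: -mean_k (R_k - b) * sum_i log p_theta(token_i | prefix),
    summed over predicted positions (residues + end mark when the sample
    self-terminated).  Greedy samples are rejected: the estimator is only
    valid for draws from the model's own distribution.
    """
    if not samples:
        raise TopogenError("no samples")
    if any(s.mode != "stochastic" for s in samples):
        raise ContractError("policy gradient requires stochastically sampled sequences")
    if len(samples) != len(rewards):
        raise TopogenError("one reward per sample is required")
    vocab = model.vocab
    b = baseline.value
    r = np.array([rb.reward for rb in rewards])
    adv = r - b
    width = max(len(s.residues) + 1 for s in samples)
    label_len = len(vocab.label_token_ids(samples[0].label))
    rows = []
    for s in samples:
        ids = vocab.label_token_ids(s.label) + [vocab.id_of(c) for c in s.residues]
        if s.self_terminated:
            ids.append(vocab.end_id)
        rows.append(ids + [vocab.pad_id] * (label_len + width - len(ids)))
    ids = np.array(rows, dtype=np.int64)
    logp, _, predicted = token_log_probs(model, ids)
    seq_logp = (logp * Tensor(predicted.astype(np.float64))).sum(axis=1)
    loss = -(Tensor(adv) * seq_logp).mean()
    optimizer.zero_grad()
    loss.backward()
    clip_global_norm(model.parameters(), clip_norm)
    optimizer.step()
    if update_baseline:
        baseline.update(r)
    return {
        "mean_reward": float(r.mean()),
        "surrogate_loss": loss.item(),
        "baseline": b,
    }


# -- fine-tuning loop -------------------------------------------------------


@dataclass
class FinetuneConfig:
    epochs: int = 50
    sequences_per_epoch: int = 150
    lr: float = 1e-6
    warmup_frac: float = 0.1
    cosine_floor_frac: float = 0.01
    disc_steps: int = 5
    disc_lr: float = 1e-3
    baseline: bool = True
    max_len: int = 80
    temperature: float = 1.0
    clip_norm: float = 1.0
    seed: int = 0
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.epochs < 1 or self.sequences_per_epoch < 1 or self.lr <= 0:
            raise TopogenError("epochs, sequences_per_epoch >= 1 and lr > 0 required")

    def schedule(self) -> ScheduleConfig:
        total = self.epochs  # one policy-gradient step per epoch
        warmup = max(1, round(self.warmup_frac * total))
        return ScheduleConfig(
            peak_lr=self.lr,
            warmup_steps=warmup,
            cosine_period=max(1, total - warmup),
            floor_lr=self.cosine_floor_frac * self.lr,
        )


@dataclass
class FinetuneEpoch:
    epoch: int
    mean_reward: float
    mean_d: float
    mean_p: float
    stable_fraction: float
    loss: float  # negative mean reward, the checkpoint-selection quantity
    lr: float
    disc_accuracy: float | None = None


@dataclass
class FinetuneHistory:
    epochs: list[FinetuneEpoch] = field(default_factory=list)
    best_epoch: int | None = None

    def to_tsv(self, path: str | Path) -> None:
        cols = ["epoch", "mean_reward", "mean_d", "mean_p",
                "stable_fraction", "loss", "lr", "disc_accuracy"]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for e in self.epochs:
                fh.write("\t".join(repr(getattr(e, c)) for c in cols) + "\n")


def finetune(
    model: GeneratorModel,
    dataset: SequenceDataset,
    scorer: StabilityScorer,
    cfg: FinetuneConfig | None = None,
    reward_cfg: RewardConfig | None = None,
    discriminator: Discriminator | None = None,
) -> tuple[GeneratorModel, FinetuneHistory, dict[str, np.ndarray]]:
    """Adversarial RL fine-tuning on a single-topology dataset.

    Returns the (last-epoch) model, the per-epoch history, and the
    parameter arrays of the best checkpoint (highest mean reward,
    earliest epoch among ties).  The discriminator and generator are
    never updated in the same optimizer step.
    """
    cfg = cfg or FinetuneConfig()
    reward_cfg = reward_cfg or RewardConfig()
    labels = dataset.labels()
    if len(labels) != 1:
        raise TopogenError(f"fine-tuning dataset must carry one topology, got {labels}")
    label = labels[0]
    if label not in model.vocab.label_keys:
        raise TopogenError(f"label {label!r} not in model vocabulary")
    rng = np.random.default_rng(cfg.seed)
    disc = discriminator or Discriminator(seed=int(rng.integers(2 ** 31)))
    opt = Adam(model.parameters(), lr=cfg.lr)
    sched = cfg.schedule()
    baseline = RunningMeanBaseline(enabled=cfg.baseline)
    real_pool = [r.residues for r in dataset.records]
    history = FinetuneHistory()
    best_reward = -np.inf
    best_state = model.state_arrays()
    best_epoch = 0
    ckpt_dir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)
    for epoch in range(1, cfg.epochs + 1):
        # (1) sample fresh sequences from the generator
        samples = sample_sequences(
            model, label, cfg.sequences_per_epoch, max_len=cfg.max_len - 1,
            mode="stochastic", temperature=cfg.temperature, rng=rng,
        )
        fake = [s.residues for s in samples if s.residues]
        if not fake:
            raise TopogenError("generator produced only empty sequences")
        # (2) one discriminator round on real vs freshly sampled
        disc, disc_metrics = train_discriminator(
            disc, real_pool, fake, steps=cfg.disc_steps, lr=cfg.disc_lr,
            rng=rng, holdout_frac=0.0,
        )
        # (3) score, build rewards, policy-gradient update
        kept = [s for s in samples if s.residues]
        d_scores = disc.scores([s.residues for s in kept])
        breakdowns = []
        for s, d in zip(kept, d_scores):
            try:
                p = float(scorer(s.residues))
            except Exception as exc:
                raise ScorerError(
                    f"stability scorer failed on sampled sequence "
                    f"{s.residues[:12]}...: {exc}"
                ) from exc
            if not np.isfinite(p):
                raise ScorerError("stability scorer returned a non-finite value")
            breakdowns.append(reward(float(d), p, reward_cfg))
        opt.lr = lr_schedule(epoch, sched)
        pg = policy_gradient_step(
            model, kept, breakdowns, baseline, opt, clip_norm=cfg.clip_norm
        )
        rec = FinetuneEpoch(
            epoch=epoch,
            mean_reward=pg["mean_reward"],
            mean_d=float(np.mean([b.d_score for b in breakdowns])),
            mean_p=float(np.mean([b.p_score for b in breakdowns])),
            stable_fraction=float(np.mean([b.stable for b in breakdowns])),
            loss=-pg["mean_reward"],
            lr=opt.lr,
            disc_accuracy=disc_metrics.get("holdout_accuracy"),
        )
        history.epochs.append(rec)
        if rec.mean_reward > best_reward:
            best_reward = rec.mean_reward
            best_state = model.state_arrays()
            best_epoch = epoch
            if ckpt_dir:
                model.save(ckpt_dir / "best")
        if ckpt_dir:
            model.save(ckpt_dir / "final")
            FinetuneHistory(history.epochs).to_tsv(ckpt_dir / "history.tsv")
    history.best_epoch = best_epoch
    return model, history, best_state
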