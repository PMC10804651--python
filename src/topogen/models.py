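"""Conditional autoregressive sequence generators.

Two backends share one contract — given a token prefix beginning with a
topology label stream, produce a probability distribution over the next
token in which pad and label tokens are masked to exactly zero:

* a pre-norm transformer decoder (default: 5 layers, 8 heads, per-head
  q/k/v dimension 32 so d_model = 256, feed-forward 512, sinusoidal or
  learned positions), and
* an LSTM stack (default: 10 layers x 1024 units) as a control model.

Both are intentionally small enough to train on a CPU; ``desk()``
presets shrink them further for test-scale experiments.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ContractError, TopogenError
from .sequences import LabeledSequence, decode
from .vocab import AA_ALPHABET, Vocabulary

NEG_MASK = -1.0e30  # additive log-space mask; exp() underflows to exactly 0


@dataclass
class TransformerConfig:
    backend: str = "transformer"
    n_layers: int = 5
    n_heads: int = 8
    head_dim: int = 32
    ff_dim: int = 512
    max_positions: int = 128
    positional: str = "sinusoidal"  # or "learned"

    @property
    def d_model(self) -> int:
        return self.n_heads * self.head_dim

    @classmethod
    def desk(cls) -> "TransformerConfig":
        """Desk-scale preset for CPU-minute experiments."""
        return cls(n_layers=2, n_heads=4, head_dim=16, ff_dim=128)


@dataclass
class LSTMConfig:
    backend: str = "lstm"
    n_layers: int = 10
    hidden_dim: int = 1024
    embed_dim: int = 128

    @classmethod
    def desk(cls) -> "LSTMConfig":
        return cls(n_layers=1, hidden_dim=64, embed_dim=32)


def _config_from_dict(d: dict):
    d = dict(d)
    backend = d.get("backend", "transformer")
    return TransformerConfig(**d) if backend == "transformer" else LSTMConfig(**d)


def _trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated normal at +-2 std, by resampling."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2 * std
    return x


def _sinusoidal_table(n_pos: int, d: int) -> np.ndarray:
    pos = np.arange(n_pos)[:, None]
    i = np.arange(d // 2)[None, :]
    angles = pos / np.power(10000.0, 2 * i / d)
    table = np.zeros((n_pos, d))
    table[:, 0::2] = np.sin(angles)
    table[:, 1::2] = np.cos(angles)
    return table


class GeneratorModel:
    """Label-conditioned next-token model over the composite stream [t; a; end]."""

    def __init__(
        self,
        vocab: Vocabulary,
        config: TransformerConfig | LSTMConfig | None = None,
        seed: int = 0,
    ):
        self.vocab = vocab
        self.config = config or TransformerConfig()
        self.seed = seed
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(seed))
        # output-layer mask: only residues and the end mark are generatable
        mask = np.full(vocab.size, NEG_MASK)
        mask[list(vocab.generatable_ids)] = 0.0
        self._out_mask = mask

    # -- parameters ---------------------------------------------------------

    def _add(self, name: str, value: np.ndarray) -> None:
        self.params[name] = Tensor(value, requires_grad=True)

    def _init_params(self, rng: np.random.Generator) -> None:
        V = self.vocab.size
        cfg = self.config
        if cfg.backend == "transformer":
            D = cfg.d_model
            self._add("tok_emb", _trunc_normal(rng, (V, D)))
            if cfg.positional == "learned":
                self._add("pos_emb", _trunc_normal(rng, (cfg.max_positions, D)))
            else:
                self._pos_table = _sinusoidal_table(cfg.max_positions, D)
            for l in range(cfg.n_layers):
                for w in ("wq", "wk", "wv", "wo"):
                    self._add(f"l{l}.{w}", _trunc_normal(rng, (D, D)))
                self._add(f"l{l}.ln1_g", np.ones(D))
                self._add(f"l{l}.ln1_b", np.zeros(D))
                self._add(f"l{l}.ln2_g", np.ones(D))
                self._add(f"l{l}.ln2_b", np.zeros(D))
                self._add(f"l{l}.w1", _trunc_normal(rng, (D, cfg.ff_dim)))
                self._add(f"l{l}.b1", np.zeros(cfg.ff_dim))
                self._add(f"l{l}.w2", _trunc_normal(rng, (cfg.ff_dim, D)))
                self._add(f"l{l}.b2", np.zeros(D))
            self._add("lnf_g", np.ones(D))
            self._add("lnf_b", np.zeros(D))
            self._add("w_out", _trunc_normal(rng, (D, V)))
            self._add("b_out", np.zeros(V))
        elif cfg.backend == "lstm":
            E, H = cfg.embed_dim, cfg.hidden_dim
            self._add("tok_emb", _trunc_normal(rng, (V, E)))
            for l in range(cfg.n_layers):
                in_dim = E if l == 0 else H
                self._add(f"l{l}.w_ih", _trunc_normal(rng, (in_dim, 4 * H)))
                self._add(f"l{l}.w_hh", _trunc_normal(rng, (H, 4 * H)))
                self._add(f"l{l}.b", np.zeros(4 * H))
            self._add("w_out", _trunc_normal(rng, (H, V)))
            self._add("b_out", np.zeros(V))
        else:
            raise TopogenError(f"unknown backend {cfg.backend!r}")

    def parameters(self) -> list[Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = np.array(v, dtype=np.float64)

    # -- forward ------------------------------------------------------------

    def forward(self, ids: np.ndarray) -> Tensor:
        """Masked logits of shape (B, T, V) for an int token matrix (B, T)."""
        ids = np.asarray(ids, dtype=np.int64)
        if ids.ndim == 1:
            ids = ids[None, :]
        if self.config.backend == "transformer":
            logits = self._forward_transformer(ids)
        else:
            logits = self._forward_lstm(ids)
        return logits + Tensor(self._out_mask)

    @staticmethod
    def _layer_norm(x: Tensor, g: Tensor, b: Tensor, eps: float = 1e-5) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + eps).sqrt() * g + b

    def _forward_transformer(self, ids: np.ndarray) -> Tensor:
        cfg = self.config
        B, T = ids.shape
        if T > cfg.max_positions:
            raise TopogenError(f"sequence length {T} exceeds max_positions")
        p = self.params
        x = ad.embedding(p["tok_emb"], ids)
        if cfg.positional == "learned":
            x = x + p["pos_emb"][:T]
        else:
            x = x + Tensor(self._pos_table[:T])
        causal = np.triu(np.full((T, T), NEG_MASK), k=1)
        scale = 1.0 / np.sqrt(cfg.head_dim)
        H, Dh = cfg.n_heads, cfg.head_dim
        for l in range(cfg.n_layers):
            h = self._layer_norm(x, p[f"l{l}.ln1_g"], p[f"l{l}.ln1_b"])
            q = (h @ p[f"l{l}.wq"]).reshape(B, T, H, Dh).transpose((0, 2, 1, 3))
            k = (h @ p[f"l{l}.wk"]).reshape(B, T, H, Dh).transpose((0, 2, 1, 3))
            v = (h @ p[f"l{l}.wv"]).reshape(B, T, H, Dh).transpose((0, 2, 1, 3))
            att = (q @ k.swapaxes(-1, -2)) * scale + Tensor(causal)
            att = ad.softmax(att, axis=-1)
            ctx = (att @ v).transpose((0, 2, 1, 3)).reshape(B, T, H * Dh)
            x = x + ctx @ p[f"l{l}.wo"]
            h2 = self._layer_norm(x, p[f"l{l}.ln2_g"], p[f"l{l}.ln2_b"])
            x = x + (h2 @ p[f"l{l}.w1"] + p[f"l{l}.b1"]).relu() @ p[f"l{l}.w2"] + p[f"l{l}.b2"]
        x = self._layer_norm(x, p["lnf_g"], p["lnf_b"])
        return x @ p["w_out"] + p["b_out"]

    def _forward_lstm(self, ids: np.ndarray) -> Tensor:
        cfg = self.config
        B, T = ids.shape
        p = self.params
        x = ad.embedding(p["tok_emb"], ids)
        Hd = cfg.hidden_dim
        layer_in = [x[:, t, :] for t in range(T)]
        for l in range(cfg.n_layers):
            h = Tensor(np.zeros((B, Hd)))
            c = Tensor(np.zeros((B, Hd)))
            outs = []
            w_ih, w_hh, b = p[f"l{l}.w_ih"], p[f"l{l}.w_hh"], p[f"l{l}.b"]
            for t in range(T):
                gates = layer_in[t] @ w_ih + h @ w_hh + b
                i_g = gates[:, 0:Hd].sigmoid()
                f_g = gates[:, Hd:2 * Hd].sigmoid()
                g_g = gates[:, 2 * Hd:3 * Hd].tanh()
                o_g = gates[:, 3 * Hd:4 * Hd].sigmoid()
                c = f_g * c + i_g * g_g
                h = o_g * c.tanh()
                outs.append(h)
            layer_in = outs
        stacked = ad.stack(layer_in, axis=1)  # (B, T, H)
        return stacked @ p["w_out"] + p["b_out"]

    # -- incremental inference (pure NumPy, no autodiff graph) ---------------

    def init_state(self, batch_size: int, max_len: int) -> dict:
        """Allocate per-sequence decoding state (KV cache / recurrent state)."""
        cfg = self.config
        if cfg.backend == "transformer":
            H, Dh = cfg.n_heads, cfg.head_dim
            return {
                "t": 0,
                "k": [np.zeros((batch_size, H, max_len, Dh)) for _ in range(cfg.n_layers)],
                "v": [np.zeros((batch_size, H, max_len, Dh)) for _ in range(cfg.n_layers)],
            }
        Hd = cfg.hidden_dim
        return {
            "h": [np.zeros((batch_size, Hd)) for _ in range(cfg.n_layers)],
            "c": [np.zeros((batch_size, Hd)) for _ in range(cfg.n_layers)],
        }

    @staticmethod
    def _ln_np(x: np.ndarray, g: np.ndarray, b: np.ndarray, eps: float = 1e-5) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / np.sqrt(var + eps) * g + b

    def step_logits(self, state: dict, tokens: np.ndarray) -> np.ndarray:
        """Advance one position with token ids (B,); returns masked logits (B, V).

        Numerically identical to ``forward(...)[:, -1, :]`` on the same prefix.
        """
        p = {k: t.data for k, t in self.params.items()}
        cfg = self.config
        tokens = np.asarray(tokens, dtype=np.int64)
        B = tokens.shape[0]
        if cfg.backend == "transformer":
            t = state["t"]
            H, Dh = cfg.n_heads, cfg.head_dim
            x = p["tok_emb"][tokens]
            if cfg.positional == "learned":
                x = x + p["pos_emb"][t]
            else:
                x = x + self._pos_table[t]
            scale = 1.0 / np.sqrt(Dh)
            for l in range(cfg.n_layers):
                h = self._ln_np(x, p[f"l{l}.ln1_g"], p[f"l{l}.ln1_b"])
                q = (h @ p[f"l{l}.wq"]).reshape(B, H, Dh)
                state["k"][l][:, :, t, :] = (h @ p[f"l{l}.wk"]).reshape(B, H, Dh)
                state["v"][l][:, :, t, :] = (h @ p[f"l{l}.wv"]).reshape(B, H, Dh)
                K = state["k"][l][:, :, : t + 1, :]
                V = state["v"][l][:, :, : t + 1, :]
                att = np.einsum("bhd,bhtd->bht", q, K) * scale
                att = att - att.max(axis=-1, keepdims=True)
                att = np.exp(att)
                att /= att.sum(axis=-1, keepdims=True)
                ctx = np.einsum("bht,bhtd->bhd", att, V).reshape(B, H * Dh)
                x = x + ctx @ p[f"l{l}.wo"]
                h2 = self._ln_np(x, p[f"l{l}.ln2_g"], p[f"l{l}.ln2_b"])
                x = x + np.maximum(h2 @ p[f"l{l}.w1"] + p[f"l{l}.b1"], 0.0) @ p[f"l{l}.w2"] + p[f"l{l}.b2"]
            state["t"] = t + 1
            x = self._ln_np(x, p["lnf_g"], p["lnf_b"])
        else:
            Hd = cfg.hidden_dim
            x = p["tok_emb"][tokens]
            for l in range(cfg.n_layers):
                gates = x @ p[f"l{l}.w_ih"] + state["h"][l] @ p[f"l{l}.w_hh"] + p[f"l{l}.b"]
                i_g = 1.0 / (1.0 + np.exp(-gates[:, 0:Hd]))
                f_g = 1.0 / (1.0 + np.exp(-gates[:, Hd:2 * Hd]))
                g_g = np.tanh(gates[:, 2 * Hd:3 * Hd])
                o_g = 1.0 / (1.0 + np.exp(-gates[:, 3 * Hd:4 * Hd]))
                state["c"][l] = f_g * state["c"][l] + i_g * g_g
                state["h"][l] = o_g * np.tanh(state["c"][l])
                x = state["h"][l]
        return x @ p["w_out"] + p["b_out"] + self._out_mask

    # -- inference ----------------------------------------------------------

    def next_token_distribution(self, prefix: list[int] | np.ndarray) -> np.ndarray:
        """Probability vector over the vocabulary for the next position."""
        prefix = [int(i) for i in np.asarray(prefix).ravel()]
        self._validate_prefix(prefix)
        logits = self.forward(np.array([prefix])).data[0, -1]
        return _masked_softmax(logits)

    def _validate_prefix(self, prefix: list[int]) -> None:
        if not prefix:
            raise ContractError("prefix must start with a label token stream")
        if self.vocab.pad_id in prefix:
            raise ContractError("prefix must not contain pad tokens")
        if self.vocab.end_id in prefix:
            raise ContractError("prefix already ended")
        aa = set(self.vocab.amino_acid_ids)
        m = 0
        while m < len(prefix) and prefix[m] not in aa:
            m += 1
        self.vocab.key_of_label_ids(prefix[:m])  # raises if not a valid label stream

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Self-describing checkpoint: JSON config+vocab sidecar and NPZ weights."""
        path = Path(path)
        meta = {
            "config": asdict(self.config),
            "vocab": self.vocab.to_dict(),
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")
        np.savez(path.with_suffix(".npz"), **{k: v.data for k, v in self.params.items()})

    @classmethod
    def load(cls, path: str | Path) -> "GeneratorModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        vocab = Vocabulary.from_dict(meta["vocab"])
        model = cls(vocab, _config_from_dict(meta["config"]), seed=meta.get("seed", 0))
        with np.load(path.with_suffix(".npz")) as npz:
            model.load_state_arrays({k: npz[k] for k in npz.files})
        return model


def _masked_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


@dataclass
class SampledSequence:
    """A generated record plus the bookkeeping RL training needs."""

    label: str
    residues: str
    self_terminated: bool
    mode: str
    id: str | None = None

    def as_labeled(self) -> LabeledSequence:
        return LabeledSequence(label=self.label, residues=self.residues, id=self.id)


def sample_sequences(
    model: GeneratorModel,
    label: str,
    n: int,
    max_len: int = 60,
    mode: str = "stochastic",
    temperature: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> list[SampledSequence]:
    """Draw ``n`` sequences conditioned on ``label``, batched.

    Generation stops per-sequence at the end mark or after ``max_len``
    residues.  ``mode='greedy'`` takes the argmax and is deterministic
    regardless of the seed.
    """
    if mode not in ("stochastic", "greedy"):
        raise TopogenError(f"unknown sampling mode {mode!r}")
    if temperature <= 0:
        raise TopogenError("temperature must be > 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    vocab = model.vocab
    prefix = vocab.label_token_ids(label)
    ids = np.tile(np.array(prefix, dtype=np.int64), (n, 1))
    done = np.zeros(n, dtype=bool)
    terminated = np.zeros(n, dtype=bool)
    state = model.init_state(n, len(prefix) + max_len)
    logits = None
    for tok in prefix:
        logits = model.step_logits(state, np.full(n, tok, dtype=np.int64))
    for _ in range(max_len):
        if mode == "greedy":
            nxt = logits.argmax(axis=1)
        else:
            z = logits / temperature
            z = z - z.max(axis=1, keepdims=True)
            probs = np.exp(z)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(n)
            nxt = (probs.cumsum(axis=1) > u[:, None]).argmax(axis=1)
        nxt = np.where(done, vocab.pad_id, nxt)
        just_ended = (~done) & (nxt == vocab.end_id)
        terminated |= just_ended
        done |= just_ended
        ids = np.concatenate([ids, nxt[:, None]], axis=1)
        if done.all():
            break
        # pad steps for finished rows keep the cache aligned; their logits are unused
        feed = np.where(done, vocab.end_id, nxt)
        logits = model.step_logits(state, feed.astype(np.int64))
    out = []
    for row, term in zip(ids, terminated):
        seq = decode(row, vocab)
        out.append(
            SampledSequence(
                label=seq.label,
                residues=seq.residues,
                self_terminated=bool(term),
                mode=mode,
            )
        )
    return out


def sample_sequence(
    model: GeneratorModel,
    label: str,
    max_len: int = 60,
    mode: str = "stochastic",
    temperature: float = 1.0,
    rng_seed: int | np.random.Generator | None = None,
) -> LabeledSequence:
    return sample_sequences(
        model, label, 1, max_len=max_len, mode=mode,
        temperature=temperature, rng=rng_seed,
    )[0].as_labeled()


def token_log_probs(model: GeneratorModel, ids: np.ndarray) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Per-position log-probabilities of the observed next tokens.

    Returns ``(logp, targets, predicted_mask)`` where ``logp`` has shape
    (B, T-1); ``predicted_mask`` selects positions whose target token is a
    residue or the end mark — label and pad targets are excluded, matching
    the convention that only amino acids (and termination) are predicted.
    """
    ids = np.asarray(ids, dtype=np.int64)
    logits = model.forward(ids)
    lsm = ad.log_softmax(logits[:, :-1, :], axis=-1)
    targets = ids[:, 1:]
    logp = ad.gather_last(lsm, targets)
    predicted = np.isin(targets, np.array(model.vocab.generatable_ids))
    return logp, targets, predicted


def sequence_log_prob(model: GeneratorModel, seq: LabeledSequence,
                      include_end: bool = True) -> float:
    """Log-probability summed over residue tokens (and the end mark).

    A zero-probability token under the hard output mask yields ``-inf``
    with a warning.
    """
    vocab = model.vocab
    ids = vocab.label_token_ids(seq.label) + [vocab.id_of(c) for c in seq.residues]
    if include_end:
        ids = ids + [vocab.end_id]
    logp, _, predicted = token_log_probs(model, np.array([ids]))
    vals = logp.data[0][predicted[0]]
    if (vals <= NEG_MASK / 2).any():
        warnings.warn("sequence contains a zero-probability token under the output mask")
        return float("-inf")
    return float(vals.sum())


def random_baseline(
    n: int, length: int = 60, rng_seed: int | np.random.Generator | None = None
) -> list[str]:
    """Uniform i.i.d. residues from the 20-letter pool; no label conditioning."""
    if n < 1 or length < 1:
        raise TopogenError("n and length must be >= 1")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    alphabet = np.array(list(AA_ALPHABET))
    draws = rng.integers(0, len(alphabet), size=(n, length))
    return ["".join(alphabet[row]) for row in draws]
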