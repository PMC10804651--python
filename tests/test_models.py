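"""Next-token-distribution contract, sampling and log-probabilities."""

import numpy as np
import pytest
from scipy import stats

import topogen as tg
from topogen.errors import ContractError, TopogenError
from conftest import make_uniform_model


@pytest.fixture(params=["transformer", "lstm"])
def model(request, tiny_transformer, tiny_lstm):
    return tiny_transformer if request.param == "transformer" else tiny_lstm


def test_distribution_is_normalized_and_masked(model, vocab):
    prefix = vocab.label_token_ids("HHH") + [vocab.id_of(c) for c in "ACD"]
    dist = model.next_token_distribution(prefix)
    assert dist.shape == (vocab.size,)
    assert dist.min() >= 0.0
    assert abs(dist.sum() - 1.0) < 1e-6
    assert dist[vocab.pad_id] == 0.0
    for key in vocab.label_keys:
        for i in vocab.label_token_ids(key):
            assert dist[i] == 0.0


def test_causality_future_edits_do_not_leak(model, vocab):
    """The distribution at position i depends only on tokens before i."""
    base = vocab.label_token_ids("HHH") + [vocab.id_of(c) for c in "ACDEF"]
    edited = list(base)
    edited[-1] = vocab.id_of("W")
    logits_a = model.forward(np.array([base])).data[0]
    logits_b = model.forward(np.array([edited])).data[0]
    # logits strictly before the edited position are identical
    np.testing.assert_allclose(logits_a[:-1], logits_b[:-1], atol=1e-12)


def test_prefix_contract_violations(model, vocab):
    with pytest.raises(ContractError):
        model.next_token_distribution([])
    with pytest.raises(ContractError):
        model.next_token_distribution(vocab.label_token_ids("HHH") + [vocab.end_id])
    with pytest.raises(ContractError):
        model.next_token_distribution(vocab.label_token_ids("HHH") + [vocab.pad_id])


def test_greedy_sampling_ignores_seed(model):
    a = tg.sample_sequences(model, "HHH", 3, max_len=12, mode="greedy", rng=1)
    b = tg.sample_sequences(model, "HHH", 3, max_len=12, mode="greedy", rng=999)
    assert [s.residues for s in a] == [s.residues for s in b]


def test_stochastic_sampling_reproducible_and_capped(model):
    a = tg.sample_sequences(model, "HHH", 20, max_len=5, rng=3)
    b = tg.sample_sequences(model, "HHH", 20, max_len=5, rng=3)
    assert [s.residues for s in a] == [s.residues for s in b]
    assert all(len(s.residues) <= 5 for s in a)
    assert all(s.label == "HHH" for s in a)


def test_sampled_frequencies_match_model_distribution(vocab):
    """First-token frequencies over 10,000 draws agree with the model (chi-square)."""
    model = tg.GeneratorModel(
        vocab, tg.TransformerConfig(n_layers=1, n_heads=2, head_dim=4, ff_dim=8),
        seed=5,
    )
    expected = model.next_token_distribution(vocab.label_token_ids("HHH"))
    samples = tg.sample_sequences(model, "HHH", 10_000, max_len=1, rng=0)
    counts = np.zeros(vocab.size)
    for s in samples:
        tok = vocab.id_of(s.residues) if s.residues else vocab.end_id
        counts[tok] += 1
    keep = expected > 0
    chi = stats.chisquare(counts[keep], expected[keep] * 10_000)
    assert chi.pvalue > 0.01


def test_uniform_model_log_prob_closed_form(vocab):
    """All-zero weights give the uniform distribution over 20 residues + end."""
    model = make_uniform_model(vocab)
    seq = tg.LabeledSequence("HHH", "ACDEFGHIKL")  # 10 residues + end = 11 tokens
    lp = tg.sequence_log_prob(model, seq)
    assert lp == pytest.approx(11 * np.log(1 / 21), rel=1e-9)


def test_sequence_log_prob_matches_chain_rule(model, vocab):
    """sequence_log_prob equals step-by-step evaluation via the distribution API."""
    seq = tg.LabeledSequence("EHEE", "MKVW")
    ids = vocab.label_token_ids("EHEE") + [vocab.id_of(c) for c in "MKVW"]
    total = 0.0
    for i in range(len(vocab.label_token_ids("EHEE")), len(ids) + 1):
        dist = model.next_token_distribution(ids[:i])
        nxt = ids[i] if i < len(ids) else vocab.end_id
        total += np.log(dist[nxt])
    assert tg.sequence_log_prob(model, seq) == pytest.approx(total, abs=1e-9)


def test_model_overfits_single_sequence_to_argmax():
    vocab = tg.build_vocabulary(["HHH"])
    cfg = tg.TransformerConfig(n_layers=1, n_heads=2, head_dim=8, ff_dim=32)
    model = tg.GeneratorModel(vocab, cfg, seed=2)
    target = tg.LabeledSequence("HHH", "MKELAAQW")
    ds = tg.SequenceDataset([target])
    model, _ = tg.pretrain(
        model, ds, tg.PretrainConfig(epochs=250, batch_size=1, lr=3e-3, seed=0)
    )
    out = tg.sample_sequences(model, "HHH", 1, max_len=20, mode="greedy")[0]
    assert out.residues == target.residues
    assert out.self_terminated


def test_save_load_round_trip_is_bit_identical(model, vocab, tmp_path):
    model.save(tmp_path / "ckpt")
    back = tg.GeneratorModel.load(tmp_path / "ckpt")
    prefix = vocab.label_token_ids("HHH") + [vocab.id_of("A")]
    a = model.next_token_distribution(prefix)
    b = back.next_token_distribution(prefix)
    assert np.array_equal(a, b)
    assert back.config == model.config


def test_incremental_decoding_matches_full_forward(model, vocab):
    ids = np.array([vocab.label_token_ids("HHH") + [vocab.id_of(c) for c in "ACDEFMK"]])
    full = model.forward(ids).data[:, -1, :]
    state = model.init_state(1, ids.shape[1])
    inc = None
    for t in range(ids.shape[1]):
        inc = model.step_logits(state, ids[:, t])
    np.testing.assert_allclose(full, inc, atol=1e-10)


def test_random_baseline_properties():
    seqs = tg.random_baseline(5000, 60, rng_seed=4)
    assert len(seqs) == 5000
    assert all(len(s) == 60 for s in seqs)
    assert seqs == tg.random_baseline(5000, 60, rng_seed=4)
    counts = np.zeros(20)
    index = {c: i for i, c in enumerate(tg.AA_ALPHABET)}
    for s in seqs[:200]:
        for c in s:
            counts[index[c]] += 1
    chi = stats.chisquare(counts)
    assert chi.pvalue > 0.01
    with pytest.raises(TopogenError):
        tg.random_baseline(0, 60)
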