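"""Reward formula, LR schedule, discriminator, scorer and policy gradient."""

import numpy as np
import pytest

import topogen as tg
from topogen.autodiff import Adam
from topogen.errors import ContractError, ScorerError, TopogenError
from topogen.finetune import RunningMeanBaseline, policy_gradient_step
from topogen.models import SampledSequence


# -- reward -----------------------------------------------------------------


def _reference_reward(d, p, mode, l1, l2, thr):
    if mode == "thresholded":
        return (l1 if p >= thr else l2) * d
    if mode == "product":
        return p * d
    return d


@pytest.mark.parametrize(
    "d,p,mode,expected",
    [
        (0.5, 1.3, "thresholded", 0.6),   # stable branch: 1.2 * 0.5
        (0.5, 1.0, "thresholded", 0.6),   # P == threshold uses the stable branch
        (0.5, 0.9, "thresholded", 0.3),   # unstable branch: 0.6 * 0.5
        (0.5, 0.9, "product", 0.45),
        (0.5, 0.9, "discriminator_only", 0.5),
    ],
)
def test_reward_fixed_cases(d, p, mode, expected):
    out = tg.reward(d, p, tg.RewardConfig(mode=mode))
    assert out.reward == pytest.approx(expected, abs=1e-12)
    assert out.stable == (p >= 1.0)


def test_reward_matches_reference_on_random_tuples():
    rng = np.random.default_rng(17)
    for _ in range(1000):
        d = float(rng.random())
        p = float(rng.normal(1.0, 0.6))
        l1, l2 = float(rng.random() * 2), float(rng.random() * 2)
        thr = float(rng.normal(1.0, 0.2))
        mode = ["thresholded", "product", "discriminator_only"][int(rng.integers(3))]
        cfg = tg.RewardConfig(mode=mode, lambda1=l1, lambda2=l2, threshold=thr)
        assert tg.reward(d, p, cfg).reward == pytest.approx(
            _reference_reward(d, p, mode, l1, l2, thr), abs=1e-12
        )


def test_equal_lambdas_make_reward_stability_blind():
    cfg = tg.RewardConfig(lambda1=0.8, lambda2=0.8)
    for p in (0.1, 0.99, 1.0, 1.7):
        assert tg.reward(0.4, p, cfg).reward == pytest.approx(0.32)


def test_reward_validates_inputs():
    with pytest.raises(TopogenError):
        tg.reward(1.5, 1.0, tg.RewardConfig())
    with pytest.raises(TopogenError):
        tg.reward(float("nan"), 1.0, tg.RewardConfig())


# -- learning-rate schedule -------------------------------------------------


def test_lr_schedule_closed_forms():
    cfg = tg.ScheduleConfig(peak_lr=1e-3, warmup_steps=10, cosine_period=100,
                            floor_lr=1e-5)
    assert tg.lr_schedule(0, cfg) == 0.0
    assert tg.lr_schedule(10, cfg) == pytest.approx(1e-3)
    mid = tg.lr_schedule(10 + 50, cfg)
    assert mid == pytest.approx((1e-3 + 1e-5) / 2, rel=1e-12)
    assert tg.lr_schedule(10 + 100, cfg) == pytest.approx(1e-5)
    assert tg.lr_schedule(10_000, cfg) == pytest.approx(1e-5)


def test_lr_schedule_continuous_at_junction():
    cfg = tg.ScheduleConfig(peak_lr=2e-4, warmup_steps=7, cosine_period=31,
                            floor_lr=2e-6)
    left = tg.lr_schedule(7, cfg)
    right = tg.lr_schedule(8, cfg)
    assert left == pytest.approx(2e-4)
    assert abs(right - left) < (2e-4 - 2e-6) * (np.pi / 31)  # bounded by max slope


# -- discriminator ----------------------------------------------------------


def test_discriminator_separates_structured_from_random(synthetic_hhh):
    disc = tg.Discriminator(seed=1)
    fake = tg.random_baseline(300, 60, 2)
    disc, metrics = tg.train_discriminator(
        disc, synthetic_hhh, fake, steps=200, rng=3
    )
    assert metrics["holdout_accuracy"] >= 0.9
    scores = disc.scores(synthetic_hhh[:20] + fake[:20])
    assert scores.min() >= 0.0 and scores.max() <= 1.0


def test_discriminator_chance_level_when_classes_identical(synthetic_hhh):
    disc = tg.Discriminator(seed=4)
    same = synthetic_hhh[:120]
    disc, metrics = tg.train_discriminator(disc, same, same, steps=60, rng=5)
    assert abs(metrics["holdout_accuracy"] - 0.5) <= 0.2


def test_discriminator_requires_both_classes():
    with pytest.raises(TopogenError):
        tg.train_discriminator(tg.Discriminator(), [], ["ACDE"], steps=1)


# -- toy stability scorer ---------------------------------------------------


def test_toy_scorer_validation_errors():
    seqs = ["ACDEFGHIKL"] * 150
    with pytest.raises(TopogenError):
        tg.train_toy_stability_scorer(seqs[:50], [1.0] * 50)
    with pytest.raises(TopogenError):
        tg.train_toy_stability_scorer(seqs, [1.0] * 150)  # constant targets


def test_toy_scorer_deterministic_and_finite(world):
    rng = np.random.default_rng(2)
    seqs, targets = [], []
    for _ in range(150):
        rec = tg.sample_synthetic_sequence(world, "HHH", rng)
        seqs.append(rec.residues)
        targets.append(rec.stability)
    scorer = tg.train_toy_stability_scorer(seqs, targets, steps=50, seed=1)
    arbitrary = "ACDEFGHIKLMNPQRSTVWY" * 2
    a, b = scorer(arbitrary), scorer(arbitrary)
    assert a == b and np.isfinite(a)


def test_table_scorer_missing_sequence():
    scorer = tg.TableScorer({"ACDE": 1.5})
    assert scorer("ACDE") == 1.5
    with pytest.raises(ScorerError):
        scorer("MMMM")


# -- policy gradient --------------------------------------------------------


def _stub_samples(vocab, residues_list):
    return [
        SampledSequence(label="HHH", residues=r, self_terminated=True,
                        mode="stochastic")
        for r in residues_list
    ]


def test_constant_reward_at_baseline_leaves_parameters_unchanged(vocab):
    model = tg.GeneratorModel(
        vocab, tg.TransformerConfig(n_layers=1, n_heads=2, head_dim=4, ff_dim=8),
        seed=3,
    )
    before = {k: v.data.copy() for k, v in model.params.items()}
    samples = _stub_samples(vocab, ["ACD", "MKV"])
    rewards = [tg.reward(0.5, 1.2, tg.RewardConfig()) for _ in samples]
    baseline = RunningMeanBaseline()
    baseline.update([rewards[0].reward])  # baseline equals the constant reward
    opt = Adam(model.parameters(), lr=1e-2)
    policy_gradient_step(model, samples, rewards, baseline, opt)
    for k, v in model.params.items():
        assert np.array_equal(before[k], v.data), k


def test_greedy_samples_rejected(vocab, tiny_transformer):
    greedy = [SampledSequence(label="HHH", residues="ACD", self_terminated=True,
                              mode="greedy")]
    rewards = [tg.reward(0.5, 1.2, tg.RewardConfig())]
    opt = Adam(tiny_transformer.parameters(), lr=1e-3)
    with pytest.raises(ContractError):
        policy_gradient_step(tiny_transformer, greedy, rewards,
                             RunningMeanBaseline(), opt)


def test_single_rewarded_sequence_probability_increases(vocab):
    """Reward 1 for one target sequence, 0 otherwise: its probability rises."""
    model = tg.GeneratorModel(
        vocab, tg.TransformerConfig(n_layers=1, n_heads=2, head_dim=4, ff_dim=8),
        seed=9,
    )
    target = "A"
    prefix = vocab.label_token_ids("HHH")
    before = model.next_token_distribution(prefix)[vocab.id_of(target)]
    opt = Adam(model.parameters(), lr=5e-3)
    baseline = RunningMeanBaseline(enabled=False)
    rng = np.random.default_rng(0)
    for _ in range(50):
        samples = tg.sample_sequences(model, "HHH", 32, max_len=1, rng=rng)
        rewards = [
            tg.reward(1.0 if s.residues == target else 0.0, 0.0,
                      tg.RewardConfig(mode="discriminator_only"))
            for s in samples
        ]
        policy_gradient_step(model, samples, rewards, baseline, opt)
    after = model.next_token_distribution(prefix)[vocab.id_of(target)]
    assert after > before


def test_finetune_history_deterministic_and_best_checkpoint(world):
    ds, scores = tg.build_synthetic_dataset(
        world, {"HHH": 30}, seed=21, length_range=(57, 62)
    )
    vocab = tg.build_vocabulary(["HHH"])
    scorer = tg.SyntheticOracleScorer(world)

    def run():
        m = tg.GeneratorModel(
            vocab, tg.TransformerConfig(n_layers=1, n_heads=2, head_dim=4, ff_dim=16),
            seed=2,
        )
        cfg = tg.FinetuneConfig(epochs=3, sequences_per_epoch=12, lr=1e-3,
                                max_len=80, seed=5, disc_steps=2)
        return tg.finetune(m, ds, scorer, cfg, tg.RewardConfig())

    _, h1, best1 = run()
    _, h2, best2 = run()
    assert [e.mean_reward for e in h1.epochs] == [e.mean_reward for e in h2.epochs]
    rewards = [e.mean_reward for e in h1.epochs]
    assert h1.best_epoch == int(np.argmax(rewards)) + 1
    for k in best1:
        assert np.array_equal(best1[k], best2[k])


def test_finetune_requires_single_topology(world, tiny_transformer):
    ds, _ = tg.build_synthetic_dataset(
        world, {"HHH": 3, "EHEE": 3}, seed=1, length_range=(57, 62)
    )
    with pytest.raises(TopogenError):
        tg.finetune(tiny_transformer, ds, lambda s: 1.0,
                    tg.FinetuneConfig(epochs=1, sequences_per_epoch=4))


def test_finetune_aborts_on_scorer_failure(world):
    ds, _ = tg.build_synthetic_dataset(world, {"HHH": 5}, seed=2,
                                       length_range=(57, 62))
    vocab = tg.build_vocabulary(["HHH"])
    m = tg.GeneratorModel(
        vocab, tg.TransformerConfig(n_layers=1, n_heads=2, head_dim=4, ff_dim=8),
        seed=1,
    )

    def bad_scorer(s):
        raise ValueError("boom")

    with pytest.raises(ScorerError):
        tg.finetune(m, ds, bad_scorer,
                    tg.FinetuneConfig(epochs=1, sequences_per_epoch=4, lr=1e-3))
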