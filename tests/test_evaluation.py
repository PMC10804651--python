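"""Identity, clustering, topology/stability statistics and the report."""

import itertools

import numpy as np
import pytest

import topogen as tg
from topogen.errors import ScorerError, TopogenError


# -- brute-force alignment oracle -------------------------------------------


def enumerate_alignments(a, b):
    """All global alignments as (score, matches, length), match+1/mis 0/gap -1."""
    out = []

    def rec(i, j, score, matches, length):
        if i == len(a) and j == len(b):
            out.append((score, matches, length))
            return
        if i < len(a) and j < len(b):
            hit = a[i] == b[j]
            rec(i + 1, j + 1, score + (1 if hit else 0),
                matches + (1 if hit else 0), length + 1)
        if i < len(a):
            rec(i + 1, j, score - 1, matches, length + 1)
        if j < len(b):
            rec(i, j + 1, score - 1, matches, length + 1)

    rec(0, 0, 0, 0, 0)
    return out


def test_pairwise_identity_fixed_cases():
    assert tg.pairwise_identity("ACGTACGT", "ACGTACGT") == 1.0
    assert tg.pairwise_identity("AAAA", "CCCC") == 0.0
    assert tg.pairwise_identity("ACGTACGT", "ACGAACGT") == pytest.approx(7 / 8)


def test_pairwise_identity_agrees_with_enumeration_oracle():
    rng = np.random.default_rng(3)
    alphabet = list("ACGT")
    for _ in range(40):
        a = "".join(rng.choice(alphabet, size=rng.integers(1, 7)))
        b = "".join(rng.choice(alphabet, size=rng.integers(1, 7)))
        alignments = enumerate_alignments(a, b)
        best = max(s for s, _, _ in alignments)
        valid = {m / ln for s, m, ln in alignments if s == best}
        assert tg.pairwise_identity(a, b) in valid


def test_pairwise_identity_symmetric_and_identity_iff_equal():
    rng = np.random.default_rng(8)
    aas = list(tg.AA_ALPHABET)
    for _ in range(50):
        a = "".join(rng.choice(aas, size=rng.integers(1, 12)))
        b = "".join(rng.choice(aas, size=rng.integers(1, 12)))
        ab = tg.pairwise_identity(a, b)
        assert ab == tg.pairwise_identity(b, a)
        assert 0.0 <= ab <= 1.0
        if ab == 1.0:
            assert a == b
    with pytest.raises(TopogenError):
        tg.pairwise_identity("", "ACD")


def test_max_identity_matches_exhaustive_scan():
    rng = np.random.default_rng(5)
    aas = list(tg.AA_ALPHABET)
    reference = ["".join(rng.choice(aas, size=10)) for _ in range(20)]
    ref_ds = tg.SequenceDataset(
        [tg.LabeledSequence("HHH", s, id=f"r{i}") for i, s in enumerate(reference)]
    )
    for _ in range(100):
        q = "".join(rng.choice(aas, size=rng.integers(6, 14)))
        best, best_id = tg.max_identity(q, ref_ds)
        scan = [tg.pairwise_identity(q, r) for r in reference]
        assert best == max(scan)
        assert best_id == f"r{int(np.argmax(scan))}"  # first-occurrence tie-break


def test_max_identity_degenerate_cases():
    ds = tg.SequenceDataset([tg.LabeledSequence("HHH", "MKEL", id="only")])
    assert tg.max_identity("MKEL", ds) == (1.0, "only")
    assert tg.max_identity("MKEW", ds)[0] == tg.pairwise_identity("MKEW", "MKEL")
    with pytest.raises(TopogenError):
        tg.max_identity("MKEL", tg.SequenceDataset([]))


def test_greedy_cluster_fixed_cases():
    assignment, n = tg.greedy_cluster(["AAAA"] * 5, 0.5)
    assert n == 1
    distinct = ["AAAAAAAA", "CCCCCCCC", "DDDDDDDD"]
    _, n = tg.greedy_cluster(distinct, 1.0)
    assert n == 3
    with pytest.raises(TopogenError):
        tg.greedy_cluster(["AAA"], 0.0)


def test_greedy_cluster_members_verify_threshold_post_hoc():
    rng = np.random.default_rng(11)
    base = "MKELAAQWGHDNST"
    seqs = []
    for _ in range(30):
        s = list(base)
        for _ in range(rng.integers(0, 6)):
            s[rng.integers(len(s))] = tg.AA_ALPHABET[rng.integers(20)]
        seqs.append("".join(s))
    assignment, n = tg.greedy_cluster(seqs, 0.7)
    centroids = {}
    for s in sorted(set(seqs)):  # replay: first member of each cluster founded it
        ci = assignment[s]
        centroids.setdefault(ci, s)
    for s, ci in assignment.items():
        assert tg.pairwise_identity(s, centroids[ci]) >= 0.7 or s == centroids[ci]
    assert n == len(centroids) <= len(set(seqs))


def test_greedy_cluster_count_monotone_in_threshold():
    rng = np.random.default_rng(13)
    aas = list(tg.AA_ALPHABET)
    seqs = ["".join(rng.choice(aas, size=12)) for _ in range(25)]
    counts = [tg.greedy_cluster(seqs, t)[1] for t in (0.3, 0.5, 0.7, 0.9)]
    assert counts == sorted(counts)


def test_greedy_cluster_order_independent():
    rng = np.random.default_rng(17)
    aas = list(tg.AA_ALPHABET)
    seqs = ["".join(rng.choice(aas, size=10)) for _ in range(15)]
    shuffled = list(seqs)
    rng.shuffle(shuffled)
    assert tg.greedy_cluster(seqs, 0.5) == tg.greedy_cluster(shuffled, 0.5)


def test_topology_proportion_with_oracle(world):
    rng = np.random.default_rng(2)
    clean = [tg.sample_synthetic_sequence(world, "HHH", rng, noise=0.0).residues
             for _ in range(25)]
    oracle = lambda s: tg.ss_oracle(world, s)  # noqa: E731
    assert tg.topology_proportion(clean, oracle, "HHH") == 1.0
    with pytest.raises(TopogenError):
        tg.topology_proportion([], oracle, "HHH")


def test_topology_proportion_missing_ss_listed():
    with pytest.raises(TopogenError, match="missing SS"):
        tg.topology_proportion(["MKEL"], {}, "HHH")


def test_stability_stats_hand_computed():
    table = {"A" * 4: 1.2, "C" * 4: 0.8}
    frac, mean = tg.stability_stats(list(table), tg.TableScorer(table))
    assert (frac, mean) == (0.5, pytest.approx(1.0))
    # >= semantics: a score exactly at the threshold counts as stable
    frac, _ = tg.stability_stats(["MM"], lambda s: 1.0)
    assert frac == 1.0
    with pytest.raises(TopogenError):
        tg.stability_stats([], lambda s: 1.0)
    with pytest.raises(ScorerError):
        tg.stability_stats(["MM"], tg.TableScorer({}))


def test_report_round_trip_and_consistency(tmp_path, world):
    rng = np.random.default_rng(4)
    seqs = [tg.sample_synthetic_sequence(world, "HHH", rng).residues
            for _ in range(12)]
    oracle = lambda s: tg.ss_oracle(world, s)  # noqa: E731
    scorer = tg.SyntheticOracleScorer(world)
    report = tg.build_report(
        seqs, target="HHH", ss_source=oracle, scorer=scorer,
        reference=seqs[:4], cluster_threshold=0.5,
    )
    assert report.n_sequences == 12
    assert report.topology_proportion == tg.topology_proportion(seqs, oracle, "HHH")
    assert report.stable_proportion == tg.stability_stats(seqs, scorer)[0]
    assert report.max_id_mean == pytest.approx(
        float(np.mean([tg.max_identity(s, seqs[:4])[0] for s in seqs]))
    )
    path = tmp_path / "report.json"
    report.to_json(path)
    back = tg.EvaluationReport.from_json(path)
    assert back == report
    report.to_tsv(tmp_path / "report.tsv")
    assert (tmp_path / "report.tsv").read_text().startswith("n_sequences\t12")


def test_report_marks_absent_inputs_as_none(world):
    report = tg.build_report(["MKEL", "MKEW"], cluster=False)
    assert report.topology_proportion is None
    assert report.stable_proportion is None
    assert report.n_clusters is None
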