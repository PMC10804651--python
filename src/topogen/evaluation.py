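"""Sequence-level evaluation: topology fidelity, stability, diversity.

Identity between two sequences is computed from a global
Needleman-Wunsch alignment (match +1, mismatch 0, linear gap -1 by
default) as matches / alignment length.  This is a deterministic,
dependency-light proxy for BLAST-style local identity — adequate for
same-length mini-proteins but not numerically interchangeable with it.
Clustering is greedy centroid assignment (MMseqs2-like): sequences are
sorted lexicographically (so counts do not depend on input order), and
each joins the first centroid it matches at or above the identity
threshold, else founds a new cluster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from Bio import Align

from .dssp import topology_from_ss, DEFAULT_MIN_E_RUN, DEFAULT_MIN_H_RUN
from .errors import ScorerError, TopogenError
from .sequences import SequenceDataset


def _make_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def pairwise_identity(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> float:
    """Global-alignment identity in [0, 1].

    Symmetric by construction: the argument pair is canonicalized before
    aligning, so ties among co-optimal alignments cannot break symmetry.
    """
    if not a or not b:
        raise TopogenError("sequences must be non-empty")
    if a == b:
        return 1.0
    x, y = sorted((a, b))
    aligner = _make_aligner(match, mismatch, gap)
    aln = aligner.align(x, y)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def max_identity(
    seq: str, reference: SequenceDataset | Sequence[str], **align_kwargs
) -> tuple[float, str | None]:
    """Maximum identity of ``seq`` against a reference set (first-hit ties)."""
    if isinstance(reference, SequenceDataset):
        pairs = [(r.id or str(i), r.residues) for i, r in enumerate(reference)]
    else:
        pairs = [(str(i), s) for i, s in enumerate(reference)]
    if not pairs:
        raise TopogenError("reference set must be non-empty")
    best, best_id = -1.0, None
    for rid, ref in pairs:
        ident = pairwise_identity(seq, ref, **align_kwargs)
        if ident > best:
            best, best_id = ident, rid
    return best, best_id


def greedy_cluster(
    sequences: Sequence[str], identity_threshold: float = 0.5, **align_kwargs
) -> tuple[dict[str, int], int]:
    """Greedy centroid clustering; returns (assignment, cluster count)."""
    if not 0.0 < identity_threshold <= 1.0:
        raise TopogenError("identity threshold must lie in (0, 1]")
    assignment: dict[str, int] = {}
    centroids: list[str] = []
    for s in sorted(set(sequences)):
        placed = False
        for ci, c in enumerate(centroids):
            if pairwise_identity(s, c, **align_kwargs) >= identity_threshold:
                assignment[s] = ci
                placed = True
                break
        if not placed:
            assignment[s] = len(centroids)
            centroids.append(s)
    return assignment, len(centroids)


def topology_proportion(
    sequences: Sequence[str],
    ss_source: Callable[[str], str] | dict[str, str],
    target: str,
    min_h_run: int = DEFAULT_MIN_H_RUN,
    min_e_run: int = DEFAULT_MIN_E_RUN,
) -> float:
    """Fraction of sequences whose derived topology equals ``target`` exactly.

    ``ss_source`` maps residues to a secondary-structure string — either a
    callable (e.g. the synthetic world's oracle) or a precomputed dict
    keyed by sequence (e.g. read from DSSP files).
    """
    if not sequences:
        raise TopogenError("empty input")
    missing = []
    hits = 0
    for s in sequences:
        if callable(ss_source):
            ss = ss_source(s)
        else:
            ss = ss_source.get(s)
            if ss is None:
                missing.append(s[:12] + "...")
                continue
        if topology_from_ss(ss, min_h_run, min_e_run) == target:
            hits += 1
    if missing:
        raise TopogenError(f"missing SS strings for: {missing}")
    return hits / len(sequences)


def stability_stats(
    sequences: Sequence[str],
    scorer: Callable[[str], float],
    threshold: float = 1.0,
) -> tuple[float, float]:
    """(fraction with score >= threshold, arithmetic mean score)."""
    if not sequences:
        raise TopogenError("empty input")
    scores = []
    for s in sequences:
        try:
            scores.append(float(scorer(s)))
        except Exception as exc:
            raise ScorerError(f"scorer failed on {s[:12]}...: {exc}") from exc
    scores = np.asarray(scores)
    return float((scores >= threshold).mean()), float(scores.mean())


@dataclass
class EvaluationReport:
    n_sequences: int
    target_topology: str | None = None
    topology_proportion: float | None = None
    stable_proportion: float | None = None
    mean_stability: float | None = None
    max_id_mean: float | None = None
    max_id_median: float | None = None
    max_id_p90: float | None = None
    n_clusters: int | None = None
    cluster_threshold: float | None = None
    tm_scores: dict | None = None  # reserved for externally computed values
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "EvaluationReport":
        return cls(**json.loads(Path(path).read_text()))

    def to_tsv(self, path: str | Path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            for k, v in d.items():
                if isinstance(v, dict):
                    v = json.dumps(v)
                fh.write(f"{k}\t{v}\n")


def build_report(
    sequences: Sequence[str],
    target: str | None = None,
    ss_source: Callable[[str], str] | dict[str, str] | None = None,
    scorer: Callable[[str], float] | None = None,
    reference: SequenceDataset | Sequence[str] | None = None,
    stability_threshold: float = 1.0,
    cluster_threshold: float = 0.5,
    min_h_run: int = DEFAULT_MIN_H_RUN,
    min_e_run: int = DEFAULT_MIN_E_RUN,
    cluster: bool = True,
) -> EvaluationReport:
    """Aggregate all evaluation statistics; absent inputs leave fields None."""
    sequences = [s for s in sequences]
    if not sequences:
        raise TopogenError("empty input")
    report = EvaluationReport(
        n_sequences=len(sequences),
        target_topology=target,
        config={
            "stability_threshold": stability_threshold,
            "cluster_threshold": cluster_threshold,
            "min_h_run": min_h_run,
            "min_e_run": min_e_run,
        },
    )
    if target is not None and ss_source is not None:
        report.topology_proportion = topology_proportion(
            sequences, ss_source, target, min_h_run, min_e_run
        )
    if scorer is not None:
        report.stable_proportion, report.mean_stability = stability_stats(
            sequences, scorer, stability_threshold
        )
    if reference is not None:
        ids = np.array([max_identity(s, reference)[0] for s in sequences])
        report.max_id_mean = float(ids.mean())
        report.max_id_median = float(np.median(ids))
        report.max_id_p90 = float(np.percentile(ids, 90))
    if cluster:
        _, report.n_clusters = greedy_cluster(sequences, cluster_threshold)
        report.cluster_threshold = cluster_threshold
    return report
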