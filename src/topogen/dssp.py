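"""Topology derivation from DSSP secondary-structure assignments.

The topology of a chain is the ordered pattern of its qualifying
secondary-structure elements: maximal runs of ``H`` (alpha-helix) of
length >= ``min_h_run`` emit an ``H``, maximal runs of ``E`` (strand)
of length >= ``min_e_run`` emit an ``E``.  Every other DSSP code —
``G`` (3-10 helix), ``I`` (pi helix), ``T`` (turn), ``S`` (bend),
``B`` (isolated bridge) and blank/``C`` coil — acts purely as a
separator.  ``"CCHHHHHCCCHHHHHCCHHHHHCC"`` with minimum runs (3, 2)
therefore collapses to ``"HHH"``, a three-helix bundle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import AlignmentError, DsspParseError, TopogenError
from .sequences import LabeledSequence, SequenceDataset
from .vocab import Vocabulary

DSSP_CODES = set("HEGTISBC")
DEFAULT_MIN_H_RUN = 3
DEFAULT_MIN_E_RUN = 2


@dataclass
class DsspChain:
    chain_id: str
    residues: str
    ss: str


def parse_dssp(text: str) -> list[DsspChain]:
    """Parse classic (fixed-column) DSSP output into per-chain SS strings.

    The structure code is the first character of the summary column
    (column 17, 1-based); blanks map to ``C``.  Chain-break rows
    (``!`` in the amino-acid column) split chains, as do changes of
    the chain identifier column.
    """
    lines = text.splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("#") and "RESIDUE" in line and "AA" in line:
            start = i + 1
            break
    if start is None:
        raise DsspParseError("missing residue table header ('#  RESIDUE AA ...')")

    chains: list[DsspChain] = []
    cur_id, cur_res, cur_ss = None, [], []

    def flush():
        nonlocal cur_id, cur_res, cur_ss
        if cur_res:
            chains.append(DsspChain(cur_id or "", "".join(cur_res), "".join(cur_ss)))
        cur_id, cur_res, cur_ss = None, [], []

    for line in lines[start:]:
        if len(line) < 14 or not line[:10].strip():
            continue
        aa = line[13]
        if aa == "!":
            flush()
            continue
        chain = line[11].strip()
        if cur_res and chain != cur_id:
            flush()
        cur_id = chain
        # disulfide-bonded cysteines appear as lowercase letters
        cur_res.append("C" if aa.islower() else aa)
        code = line[16] if len(line) > 16 else " "
        code = "C" if code == " " else code
        if code not in DSSP_CODES:
            raise DsspParseError(f"unknown structure code {code!r}")
        cur_ss.append(code)
    flush()
    if not chains:
        raise DsspParseError("no residue rows found")
    return chains


def parse_dssp_file(path: str | Path) -> list[DsspChain]:
    return parse_dssp(Path(path).read_text())


def topology_from_ss(
    ss: str,
    min_h_run: int = DEFAULT_MIN_H_RUN,
    min_e_run: int = DEFAULT_MIN_E_RUN,
) -> str:
    """Collapse a per-residue SS string to its H/E element pattern."""
    if min_h_run < 1 or min_e_run < 1:
        raise TopogenError("minimum run lengths must be >= 1")
    bad = set(ss) - DSSP_CODES
    if bad:
        raise TopogenError(f"invalid SS codes: {''.join(sorted(bad))}")
    out = []
    i = 0
    n = len(ss)
    while i < n:
        c = ss[i]
        j = i
        while j < n and ss[j] == c:
            j += 1
        run = j - i
        if c == "H" and run >= min_h_run:
            out.append("H")
        elif c == "E" and run >= min_e_run:
            out.append("E")
        i = j
    return "".join(out)


def label_dataset(
    sequences: list[tuple[str, str]],
    ss_strings: list[str],
    vocab: Vocabulary,
    min_h_run: int = DEFAULT_MIN_H_RUN,
    min_e_run: int = DEFAULT_MIN_E_RUN,
) -> tuple[SequenceDataset, list[tuple[str, str]]]:
    """Tag ``(id, residues)`` pairs with topology derived from their SS strings.

    Returns the labelled dataset plus a reject list of ``(id, reason)`` for
    records whose topology has no vocabulary label (or is empty).
    """
    if len(sequences) != len(ss_strings):
        raise AlignmentError("one SS string per sequence is required")
    records: list[LabeledSequence] = []
    rejects: list[tuple[str, str]] = []
    known = set(vocab.label_keys)
    for (rid, residues), ss in zip(sequences, ss_strings):
        if len(residues) != len(ss):
            raise AlignmentError(
                f"record {rid}: sequence length {len(residues)} != SS length {len(ss)}"
            )
        topo = topology_from_ss(ss, min_h_run, min_e_run)
        if not topo:
            rejects.append((rid, "empty topology"))
        elif topo not in known:
            rejects.append((rid, f"topology {topo} not in vocabulary"))
        else:
            records.append(LabeledSequence(label=topo, residues=residues, id=rid))
    ds = SequenceDataset(
        records,
        metadata={"min_h_run": min_h_run, "min_e_run": min_e_run},
    )
    return ds, rejects


def prefilter_by_score(
    dataset: SequenceDataset,
    scores: dict[str, float],
    threshold: float = 0.9,
) -> SequenceDataset:
    """Keep records whose structure-agreement score strictly exceeds ``threshold``.

    ``scores`` maps record id to a TM-score-like value in [0, 1]; records are
    retained when score > threshold (default 0.9).
    """
    kept = []
    for rec in dataset:
        if rec.id not in scores:
            raise TopogenError(f"missing score for record {rec.id}")
        if scores[rec.id] > threshold:
            kept.append(rec)
    return SequenceDataset(
        kept, metadata={**dataset.metadata, "score_threshold": threshold}
    )
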