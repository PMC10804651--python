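r"""Labelled sequence records, token encoding/padding, and FASTA I/O.

The padded token layout for a record with label stream ``t`` is::

    [t_1 .. t_m | r_1 .. r_k  end  pad .. pad]
                  \------------ max_len ------/

i.e. ``max_len`` (default 80) budgets the residue positions plus the
end mark, and the label tokens are prepended on top of that budget.
A record therefore needs ``len(residues) + 1 <= max_len``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .errors import AlphabetError, FastaParseError, LengthError, MissingTopologyError
from .vocab import AA_ALPHABET, Vocabulary

DEFAULT_MAX_LEN = 80

_AA_SET = set(AA_ALPHABET)


@dataclass
class LabeledSequence:
    """A topology key plus an amino-acid sequence."""

    label: str
    residues: str
    id: str | None = None

    def __post_init__(self):
        bad = sorted(set(self.residues) - _AA_SET)
        if bad:
            raise AlphabetError(
                f"record {self.id or '<anon>'}: residues outside the 20-letter "
                f"alphabet: {''.join(bad)}"
            )


@dataclass
class SequenceDataset:
    records: list[LabeledSequence]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def labels(self) -> list[str]:
        return sorted({r.label for r in self.records})

    def subset_by_label(self, label: str) -> "SequenceDataset":
        return SequenceDataset(
            [r for r in self.records if r.label == label],
            metadata={**self.metadata, "subset_label": label},
        )


def encode(
    seq: LabeledSequence, vocab: Vocabulary, max_len: int = DEFAULT_MAX_LEN
) -> tuple[np.ndarray, np.ndarray]:
    """Encode to token ids plus a mask of non-pad positions.

    Raises :class:`LengthError` when residues + end mark exceed ``max_len``.
    """
    if len(seq.residues) + 1 > max_len:
        raise LengthError(
            f"record {seq.id or '<anon>'}: {len(seq.residues)} residues + end mark "
            f"exceed max_len={max_len}"
        )
    label_ids = vocab.label_token_ids(seq.label)
    try:
        res_ids = [vocab.id_of(c) for c in seq.residues]
    except KeyError as exc:  # pragma: no cover - caught at construction
        raise AlphabetError(str(exc)) from exc
    body = res_ids + [vocab.end_id]
    ids = np.array(
        label_ids + body + [vocab.pad_id] * (max_len - len(body)), dtype=np.int64
    )
    mask = (ids != vocab.pad_id).astype(np.int64)
    return ids, mask


def decode(ids: np.ndarray, vocab: Vocabulary) -> LabeledSequence:
    """Inverse of :func:`encode`; tolerates missing end mark (truncated sample)."""
    ids = [int(i) for i in np.asarray(ids)]
    # split off the label stream
    aa_ids = set(vocab.amino_acid_ids)
    m = 0
    while m < len(ids) and ids[m] not in aa_ids and ids[m] != vocab.end_id:
        m += 1
    label = vocab.key_of_label_ids(ids[:m])
    residues = []
    for i in ids[m:]:
        if i == vocab.end_id or i == vocab.pad_id:
            break
        residues.append(vocab.token_of(i))
    return LabeledSequence(label=label, residues="".join(residues))


def encode_batch(
    records: list[LabeledSequence], vocab: Vocabulary, max_len: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stack encodings of same-label-length records, right-padded to a shared width.

    ``max_len=None`` uses the smallest budget that fits the batch.
    """
    if max_len is None:
        max_len = max(len(r.residues) for r in records) + 1
    rows = [encode(r, vocab, max_len) for r in records]
    prefix_lens = {len(vocab.label_token_ids(r.label)) for r in records}
    if len(prefix_lens) != 1:
        raise LengthError("encode_batch requires a uniform label prefix length")
    ids = np.stack([r[0] for r in rows])
    mask = np.stack([r[1] for r in rows])
    return ids, mask


# -- FASTA ------------------------------------------------------------------


def read_labeled_fasta(path: str | Path) -> SequenceDataset:
    """Read FASTA whose description lines carry ``topology=<KEY>``.

    Records missing the key are rejected collectively via
    :class:`MissingTopologyError` listing their ids.
    """
    path = Path(path)
    _precheck_fasta(path)
    records: list[LabeledSequence] = []
    missing: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        key = None
        for tokenish in rec.description.split():
            if tokenish.startswith("topology="):
                key = tokenish.split("=", 1)[1]
                break
        if key is None:
            missing.append(rec.id)
            continue
        records.append(LabeledSequence(label=key, residues=str(rec.seq), id=rec.id))
    if missing:
        raise MissingTopologyError(missing)
    return SequenceDataset(records, metadata={"source": str(path)})


def write_labeled_fasta(dataset: SequenceDataset, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for i, rec in enumerate(dataset.records):
            rid = rec.id or f"seq{i:05d}"
            fh.write(f">{rid} topology={rec.label}\n{rec.residues}\n")


def _precheck_fasta(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError("expected a '>' header line", line=lineno)
            return
    raise FastaParseError("empty FASTA file", line=0)
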