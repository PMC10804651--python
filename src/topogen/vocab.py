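"""Token vocabulary for label-tagged protein sequences.

A composite training sequence is ``x = [t; a]``: one or more topology
label tokens ``t`` prepended to the amino-acid sequence ``a``, with a
"sequence end" mark appended.  Two labelling schemes are supported:

* ``single_letter`` — each topology key gets one lowercase letter,
  with the conventional assignments ``HHH -> 'i'`` and ``HHHH -> 'j'``
  fixed first when those keys are present; remaining keys take the next
  unused letters from ``i..z`` in input order (capacity 18).
* ``delimited_multi`` — the key itself, lowercased, wrapped in ``<``
  and ``>`` which are tokens of their own (e.g. ``<hhh>``), so the
  model sees one token per secondary-structure element.

Only the 20 canonical residues and the end mark are ever generatable;
pad and label tokens are masked out of the output layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import CapacityError, TopogenError

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
PAD_GLYPH = "_"
END_GLYPH = "\\"

SINGLE_LETTER = "single_letter"
DELIMITED_MULTI = "delimited_multi"

_RESERVED = {"HHH": "i", "HHHH": "j"}
_LETTER_POOL = "ijklmnopqrstuvwxyz"  # 18 letters


def _validate_key(key: str) -> None:
    if not key or any(c not in "HE" for c in key):
        raise TopogenError(f"topology key must be a non-empty string over H/E: {key!r}")


@dataclass(frozen=True)
class Vocabulary:
    """Immutable token table: pad, end, 20 residues, then label tokens."""

    scheme: str
    label_keys: tuple[str, ...]
    label_streams: dict[str, tuple[str, ...]] = field(compare=False)
    tokens: tuple[str, ...] = field(compare=False)

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise TopogenError("vocabulary tokens must be distinct")

    # -- id helpers ---------------------------------------------------------

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def end_id(self) -> int:
        return 1

    @property
    def size(self) -> int:
        return len(self.tokens)

    def id_of(self, token: str) -> int:
        try:
            return self._index[token]
        except AttributeError:
            object.__setattr__(self, "_index", {t: i for i, t in enumerate(self.tokens)})
            return self._index[token]

    def token_of(self, idx: int) -> str:
        return self.tokens[idx]

    @property
    def amino_acid_ids(self) -> tuple[int, ...]:
        return tuple(range(2, 22))

    @property
    def generatable_ids(self) -> tuple[int, ...]:
        """Token ids the model may emit: the 20 residues plus the end mark."""
        return (self.end_id,) + self.amino_acid_ids

    def label_token_ids(self, key: str) -> list[int]:
        if key not in self.label_streams:
            raise TopogenError(f"topology key {key!r} not in vocabulary")
        return [self.id_of(t) for t in self.label_streams[key]]

    def key_of_label_ids(self, ids) -> str:
        stream = tuple(self.token_of(i) for i in ids)
        for key, s in self.label_streams.items():
            if s == stream:
                return key
        raise TopogenError(f"no topology key for label token stream {stream!r}")

    def label_prefix_length(self, key: str) -> int:
        return len(self.label_streams[key])

    # -- serialization ------------------------------------------------------

    def to_table_text(self) -> str:
        """Plain-text token table: one ``index<TAB>token<TAB>role`` row per token."""
        roles = {0: "pad", 1: "end"}
        for i in self.amino_acid_ids:
            roles[i] = "aa"
        lines = [f"# scheme={self.scheme}", f"# keys={','.join(self.label_keys)}"]
        for i, tok in enumerate(self.tokens):
            lines.append(f"{i}\t{tok}\t{roles.get(i, 'label')}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_table_text(cls, text: str) -> "Vocabulary":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        scheme = lines[0].split("=", 1)[1]
        keys = tuple(k for k in lines[1].split("=", 1)[1].split(",") if k)
        return build_vocabulary(list(keys), scheme)

    def to_dict(self) -> dict:
        return {"scheme": self.scheme, "label_keys": list(self.label_keys)}

    @classmethod
    def from_dict(cls, d: dict) -> "Vocabulary":
        return build_vocabulary(list(d["label_keys"]), d["scheme"])


def build_vocabulary(topology_keys: list[str], scheme: str = SINGLE_LETTER) -> Vocabulary:
    """Deterministically assign label tokens to topology keys."""
    if not topology_keys:
        raise TopogenError("at least one topology key is required")
    seen = set()
    keys: list[str] = []
    for k in topology_keys:
        _validate_key(k)
        if k not in seen:
            seen.add(k)
            keys.append(k)

    base = [PAD_GLYPH, END_GLYPH] + list(AA_ALPHABET)

    if scheme == SINGLE_LETTER:
        if len(keys) > len(_LETTER_POOL):
            raise CapacityError(
                f"single_letter scheme supports at most {len(_LETTER_POOL)} topology keys"
            )
        assignment: dict[str, str] = {
            k: v for k, v in _RESERVED.items() if k in keys
        }
        used = set(assignment.values())
        pool = (c for c in _LETTER_POOL if c not in used)
        for k in keys:
            if k not in assignment:
                assignment[k] = next(pool)
        streams = {k: (assignment[k],) for k in keys}
        label_tokens = [assignment[k] for k in keys]
    elif scheme == DELIMITED_MULTI:
        streams = {k: ("<",) + tuple(k.lower()) + (">",) for k in keys}
        letters = sorted({c for k in keys for c in k.lower()})
        label_tokens = ["<", ">"] + letters
    else:
        raise TopogenError(f"unknown labelling scheme {scheme!r}")

    return Vocabulary(
        scheme=scheme,
        label_keys=tuple(keys),
        label_streams=streams,
        tokens=tuple(base + label_tokens),
    )
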