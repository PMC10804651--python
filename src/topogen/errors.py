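"""Exception hierarchy."""


class TopogenError(Exception):
    """Base class for all package-specific errors."""


class CapacityError(TopogenError):
    """Label alphabet exhausted for the requested scheme."""


class AlphabetError(TopogenError):
    """Residue outside the 20-letter amino-acid alphabet."""


class LengthError(TopogenError):
    """Sequence does not fit the padded token budget."""


class FastaParseError(TopogenError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message} (line {line})" if line is not None else message)


class MissingTopologyError(TopogenError):
    """FASTA records lacking a ``topology=`` description key."""

    def __init__(self, record_ids):
        self.record_ids = list(record_ids)
        super().__init__(
            "records missing topology= description key: " + ", ".join(self.record_ids)
        )


class DsspParseError(TopogenError):
    """Classic DSSP output could not be parsed."""


class AlignmentError(TopogenError):
    """Sequence and secondary-structure string lengths disagree."""


class ContractError(TopogenError):
    """A caller violated an interface contract (e.g. sampling mode)."""


class ScorerError(TopogenError):
    """A stability scorer failed on a sequence."""
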