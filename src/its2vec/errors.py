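"""Exception hierarchy for the its2vec pipeline."""


class Its2vecError(Exception):
    """Base class for all errors raised by this package."""


class HeaderFormatError(Its2vecError):
    """A FASTA header does not match the expected dialect layout."""


class FastaError(Its2vecError):
    """A FASTA record is structurally invalid (e.g. empty sequence)."""


class ConsistencyError(Its2vecError):
    """An internal invariant of the dataset pipeline was violated."""


class ModelFormatError(Its2vecError):
    """A persisted model file is missing, corrupted, or of the wrong version."""
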