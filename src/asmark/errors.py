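"""Exception hierarchy for the asmark pipeline."""


class AsmarkError(Exception):
    """Base class for all pipeline errors."""


class FormatError(AsmarkError):
    """Malformed input file (FASTA/GFF3/VCF/TSV)."""


class AlphabetError(FormatError):
    """Sequence contains a character outside the allowed alphabet."""


class ModelError(AsmarkError):
    """Gene model violates a structural invariant."""


class ReferenceError_(AsmarkError):
    """A record refers to an unknown chromosome or position."""


class ConsistencyError(AsmarkError):
    """Two inputs disagree about the shared reference."""


class CapacityError(AsmarkError):
    """A simulation design cannot be satisfied on the given genome."""


class DesignError(AsmarkError):
    """A primer design constraint cannot be met."""


class UsageError(AsmarkError):
    """An operation was called with arguments outside its contract."""
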