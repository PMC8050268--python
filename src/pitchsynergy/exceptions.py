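"""Exception hierarchy for the pitchsynergy pipeline."""


class PitchSynergyError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(PitchSynergyError, ValueError):
    """A scenario or pipeline configuration value is out of range."""


class WindowError(PitchSynergyError, ValueError):
    """The analysis window does not fit inside a recording."""


class DataError(PitchSynergyError, ValueError):
    """Input samples are non-finite or otherwise unusable."""


class AssemblyError(PitchSynergyError, ValueError):
    """Per-trial envelopes cannot be stacked into a tensor."""


class DegenerateChannelError(PitchSynergyError, ValueError):
    """A muscle channel is constant and cannot be min-max normalized."""


class ConstraintError(PitchSynergyError, ValueError):
    """Nonnegativity or rank constraints of the CP model are violated."""


class DegenerateInputError(PitchSynergyError, ValueError):
    """An operation received input with no usable variance or norm."""


class IncompleteGridError(PitchSynergyError, ValueError):
    """A long-format tensor file does not cover the full muscle x frame x trial grid."""


class SchemaVersionError(PitchSynergyError, ValueError):
    """A serialized file declares an unsupported schema version."""
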