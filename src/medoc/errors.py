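"""Exception hierarchy for the medoc package."""


class MedocError(Exception):
    """Base class for all package-specific errors."""


class SequenceError(MedocError):
    """Invalid sequence input (unknown residue, empty record, bad state vector)."""


class DatabaseError(MedocError):
    """Invalid or incomplete context free-energy database."""


class EngineError(MedocError):
    """Invalid request to the partition-function engine."""
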