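"""Exception hierarchy for the scoring pipeline."""


class RnpScoreError(Exception):
    """Base class for all pipeline errors."""


class ParseError(RnpScoreError):
    """Coordinate file could not be read or interpreted."""


class CompositionError(RnpScoreError):
    """Structure lacks a protein or an RNA component."""


class TypingError(RnpScoreError):
    """An atom has no entry in the typing table under the fail policy."""


class FrameError(RnpScoreError):
    """A residue/nucleotide is missing one of the frame anchor atoms."""


class DegeneracyError(RnpScoreError):
    """Anchor geometry is collinear/coincident; no frame can be built."""


class EmptyInputError(RnpScoreError):
    """No featurizable units (or no decoys/reports) were provided."""


class PairingError(RnpScoreError):
    """Coordinate lists cannot be put in 1:1 atom correspondence."""


class UndefinedMetricError(RnpScoreError):
    """The requested metric is undefined (e.g. empty native interface)."""


class QuotaError(RnpScoreError):
    """A decoy RMSD bin quota could not be satisfied."""


class ScoringShapeError(RnpScoreError):
    """Checkpoint configuration does not match the input tensor shapes."""


class DivergenceError(RnpScoreError):
    """Training loss became non-finite."""

    def __init__(self, message, last_checkpoint=None):
        super().__init__(message)
        self.last_checkpoint = last_checkpoint


class TraceError(RnpScoreError):
    """Shape trace failed (non-divisible dimensions)."""
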