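"""Exception hierarchy for the gridqsar pipeline."""


class GridQSARError(Exception):
    """Base class for all gridqsar errors."""


class ParseError(GridQSARError):
    """A structure or table file could not be parsed."""


class TopologyMismatchError(GridQSARError):
    """Conformations within one file disagree on atom count or order."""


class MissingParameterError(GridQSARError):
    """An atom could not be resolved in the parameter table (strict policy)."""


class AlignmentError(GridQSARError):
    """Superposition is impossible (too few or degenerate points)."""


class GridSpecError(GridQSARError):
    """An inconsistent grid specification (non-integral edge/spacing)."""


class IncompatibleTensorError(GridQSARError):
    """Descriptor tensors built on different grids or probe sets."""


class FitError(GridQSARError):
    """A regression fit is impossible (degenerate X or constant y)."""


class StageError(GridQSARError):
    """A protocol stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
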