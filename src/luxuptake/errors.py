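"""Exception hierarchy for the luxuptake pipeline."""


class LuxuptakeError(Exception):
    """Base class for all pipeline errors."""


class InvalidConfigError(LuxuptakeError):
    """A synthetic-data or pipeline configuration violates its invariants."""


class InvalidFragmentError(LuxuptakeError):
    """A fragment set contains duplicates or substring-nested sequences."""


class MissingLengthError(LuxuptakeError):
    """Genes in a count matrix have no length annotation."""

    def __init__(self, genes):
        self.genes = list(genes)
        super().__init__(
            f"no length annotation for {len(self.genes)} gene(s): "
            + ", ".join(map(str, self.genes[:10]))
            + ("..." if len(self.genes) > 10 else "")
        )


class InvalidSampleError(LuxuptakeError):
    """A sample has a non-positive total read count."""


class MissingCellError(LuxuptakeError):
    """A line x day cell has no replicates."""


class InsufficientReplicatesError(LuxuptakeError):
    """A contrast side has fewer than two replicates."""


class ParseError(LuxuptakeError):
    """A table could not be parsed; carries the offending line number."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class DomainError(LuxuptakeError):
    """A rate-calculator input is outside its mathematical domain."""


class StageError(LuxuptakeError):
    """A pipeline stage failed; names the stage."""

    def __init__(self, stage, cause):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
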