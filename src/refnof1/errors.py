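"""Exception hierarchy with stable exit codes for the command-line layer."""


class RefNof1Error(Exception):
    """Base class; ``exit_code`` is used verbatim by the CLI."""

    exit_code = 1
    error_class = "error"


class ValidationError(RefNof1Error):
    """Malformed or out-of-range input data (counts, p-values, tables)."""

    exit_code = 3
    error_class = "validation-error"


class DesignError(RefNof1Error):
    """Invalid sample->condition design (wrong number of levels, mismatches)."""

    exit_code = 4
    error_class = "design-error"


class ConfigurationError(RefNof1Error):
    """Inconsistent run configuration (overlapping windows, too few methods)."""

    exit_code = 5
    error_class = "configuration-error"


class CapabilityError(RefNof1Error):
    """A caller's requirements (e.g. replicate minimum) are not met."""

    exit_code = 6
    error_class = "capability-error"


class SizingError(RefNof1Error):
    """Hold-out plan requests more samples than the design provides."""

    exit_code = 7
    error_class = "sizing-error"


class BiasGuardError(RefNof1Error):
    """The prediction method contributes to the reference standard.

    Scoring a method against a consensus it helped build replicates that
    method's systematic artefacts (isomorphic evaluation) and is refused.
    """

    exit_code = 8
    error_class = "bias-guard-error"
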