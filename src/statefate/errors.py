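"""Exception hierarchy shared by all pipeline stages."""


class StatefateError(Exception):
    """Base class for all statefate errors."""


class FormatError(StatefateError):
    """A file's contents do not match the declared format (e.g. non-integer counts)."""


class ValidationError(StatefateError):
    """An in-memory object violates one of its invariants."""


class EmptyResultError(StatefateError):
    """An operation produced an empty result where a nonempty one is required."""


class PreconditionError(StatefateError):
    """An operation's documented precondition does not hold."""


class ConvergenceError(StatefateError):
    """The iterative loop failed to converge or lost its gene subspace."""


class ConflictError(StatefateError):
    """Contradictory local binarization calls for a gene."""


class FeasibilityError(StatefateError):
    """The fixed-point inequality system is infeasible."""


class SamplingError(StatefateError):
    """The LP sampler exhausted its retries."""


class ResourceError(StatefateError):
    """A resource limit (retries, support cap) was exceeded."""
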