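"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`CTDenoiseError`, so callers can catch the package's own failures
without swallowing genuine bugs.
"""


class CTDenoiseError(Exception):
    """Base class for all errors raised by ctdenoise."""


class ParameterError(CTDenoiseError, ValueError):
    """A parameter value violates its documented constraint."""


class ContractError(CTDenoiseError, ValueError):
    """Inputs violate an operation's contract (shape mismatch, index bound, ...)."""
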