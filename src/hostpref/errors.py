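"""Typed errors raised on malformed or inconsistent input tables."""


class HostprefError(Exception):
    """Base class for all package errors."""


class ValidationError(HostprefError):
    """An input table violates a structural invariant (the message names the record)."""


class StateError(HostprefError):
    """An operation was applied to data in the wrong state (e.g. raw vs rarefied)."""


class ConvergenceError(HostprefError):
    """A sampler or diagnostic could not produce a usable result."""
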