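"""Exception hierarchy for uterosim.

All errors raised by the library derive from :class:`UterosimError`, so that
callers (and the CLI) can catch one type and print a one-line diagnostic.
"""


class UterosimError(Exception):
    """Base class for all uterosim errors."""


class ConfigurationError(UterosimError):
    """A parameter set violates a model invariant (e.g. non-positive tau)."""


class InputError(UterosimError, ValueError):
    """Invalid user-supplied input (negative concentration, bad trace...)."""


class IntegrationError(UterosimError):
    """The ODE solver failed or produced non-finite derivatives."""


class FitError(UterosimError):
    """Parameter fitting could not be started (ill-posed problem)."""
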