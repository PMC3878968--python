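"""Exception hierarchy used across the package.

The CLI maps :class:`InputError` to exit code 2 and
:class:`BudgetExceededError` to exit code 3.
"""


class OrdaltError(Exception):
    """Base class for all package-specific errors."""


class InputError(OrdaltError, ValueError):
    """Malformed user input: bad file contents, invalid arguments."""


class BudgetExceededError(OrdaltError, RuntimeError):
    """A computation would exceed its configured enumeration budget."""


class DegenerateVarianceError(OrdaltError, RuntimeError):
    """The null variance of a statistic is not positive for this design."""
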