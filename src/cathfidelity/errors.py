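"""Exception hierarchy for cathfidelity.

All package errors derive from :class:`CathFidelityError` so callers can
catch everything from one base; the subclasses distinguish bad parameters,
mathematical domain violations, numerical blow-ups and signal-processing
failures.
"""


class CathFidelityError(Exception):
    """Base class for all cathfidelity errors."""


class ParameterError(CathFidelityError, ValueError):
    """A parameter is missing, non-finite or outside its admissible range.

    The message names the offending field.
    """


class DomainError(CathFidelityError, ValueError):
    """Input outside the mathematical domain of a closed-form operation."""


class DimensionalError(CathFidelityError):
    """A configured algebraic grouping fails the unit-dimension audit."""


class StabilityError(CathFidelityError, RuntimeError):
    """The explicit solver violated its CFL bound or produced non-finite fields."""


class DetectionError(CathFidelityError, RuntimeError):
    """A waveform feature (upstroke foot, cycle, ...) could not be located."""


class DegenerateSignalError(CathFidelityError, ValueError):
    """The signal is constant (or otherwise degenerate) where variation is required."""


class FormatError(CathFidelityError, ValueError):
    """A file does not conform to the documented CSV/config dialect."""
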