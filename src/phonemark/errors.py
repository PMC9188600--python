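"""Exception hierarchy for the phonemark pipeline.

Every anticipated failure mode raises a subclass of :class:`PhonemarkError`
so callers (and the CLI) can distinguish bad arguments from bad signals.
"""


class PhonemarkError(Exception):
    """Base class for all phonemark errors."""


class InvalidArgumentError(PhonemarkError, ValueError):
    """A parameter violates a precondition (non-positive length, bad band edges...)."""


class TooShortError(PhonemarkError):
    """Recording shorter than the requested analysis duration."""


class UnvoicedSignalError(PhonemarkError):
    """No periodic (voiced) structure found in the signal."""


class InsufficientCyclesError(PhonemarkError):
    """Fewer glottal cycles than a perturbation measure needs."""


class InvalidCycleError(PhonemarkError):
    """A glottal cycle with a degenerate (zero/negative) amplitude."""


class DegenerateSignalError(PhonemarkError):
    """Harmonicity undefined: no frame yielded a usable autocorrelation peak."""


class InsufficientFramesError(PhonemarkError):
    """Fewer analysis frames than a contour statistic needs."""


class FormantFailureError(PhonemarkError):
    """Formant tracking failed on a majority of frames."""


class DegenerateSampleError(PhonemarkError, ValueError):
    """A statistical sample with zero variance where spread is required."""


class InsufficientClassError(PhonemarkError):
    """A class has too few samples for the requested neighborhood size."""
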