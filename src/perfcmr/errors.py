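"""Exception hierarchy for perfcmr.

All package errors derive from :class:`PerfcmrError` so callers can catch
everything with one clause; most also derive from ``ValueError`` because they
signal invalid inputs.
"""


class PerfcmrError(Exception):
    """Base class for all perfcmr errors."""


class InvalidCurveError(PerfcmrError, ValueError):
    """A signal-intensity time curve violates its structural invariants."""


class NoEnhancementError(PerfcmrError, ValueError):
    """No frame of the LV curve satisfies the contrast-arrival criterion."""


class InconsistentInputError(PerfcmrError, ValueError):
    """Mutually inconsistent inputs, e.g. an arrival time after the peak."""


class DegenerateReferenceError(PerfcmrError, ValueError):
    """A nonpositive LV reference value makes a relative parameter undefined."""


class UndefinedTestError(PerfcmrError, ValueError):
    """A statistical test is undefined for the given sample (e.g. all-zero
    paired differences)."""


class NoNativeReferenceError(PerfcmrError, ValueError):
    """A patient has no analyzable native territory to pair grafts against."""


class CurveParseError(PerfcmrError, ValueError):
    """A curve table failed validation; the message names the offending row."""


class InvalidSpecError(PerfcmrError, ValueError):
    """A simulation specification is internally inconsistent."""
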