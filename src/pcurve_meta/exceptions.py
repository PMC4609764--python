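"""Exception hierarchy for pcurve_meta.

All package errors derive from :class:`PCurveMetaError` so callers can catch
one base class; most also derive from :class:`ValueError` since they signal
invalid inputs.
"""


class PCurveMetaError(Exception):
    """Base class for all pcurve_meta errors."""


class ConfigurationError(PCurveMetaError, ValueError):
    """A configuration object violates its invariants.

    The message names the offending field.
    """


class DegenerateVarianceError(PCurveMetaError, ValueError):
    """Both arms of a study report zero variance; no effect-size inference
    is possible."""


class EmptyPCurveError(PCurveMetaError, ValueError):
    """No study survives the significance (and directionality) filter, so
    the p-curve tests are undefined."""


class StudyParseError(PCurveMetaError, ValueError):
    """A study-summary CSV failed validation; the message carries the
    1-based data row number where parsing stopped."""
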