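"""Exception hierarchy.

All package errors derive from :class:`SurnameBiasError` so callers can
catch everything from one base; the subclasses mirror the distinct failure
contracts of the data model (format vs validation), the sampling strategies
(empty selection, oversized request) and the statistics (undefined on the
given input).
"""


class SurnameBiasError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SurnameBiasError):
    """A file or table does not have the expected layout (e.g. no surname column)."""


class ValidationError(SurnameBiasError, ValueError):
    """Data violates a repertoire invariant (non-positive count, empty surname...)."""


class RuleError(SurnameBiasError, ValueError):
    """A lemmatization rule is malformed (e.g. empty canonical form)."""


class EmptySelectionError(SurnameBiasError):
    """A sampling strategy produced no units (e.g. disjoint supports)."""


class SampleSizeError(SurnameBiasError, ValueError):
    """A requested sample size exceeds the available units."""


class UndefinedStatisticError(SurnameBiasError):
    """A statistic is undefined on the given input (empty selection, N < 2...)."""


class ConfigurationError(SurnameBiasError, ValueError):
    """A simulation or pipeline configuration is inconsistent."""
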