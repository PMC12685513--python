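"""Exception hierarchy.

Every declared failure mode raises a subclass of :class:`DpcScreenError`
so callers (and the CLI) can distinguish pipeline errors from bugs.
"""


class DpcScreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DpcScreenError):
    """Invalid plate layout, missing reference wells, bad run config."""


class LabelingError(DpcScreenError):
    """A (dose, time) pair falls outside the labeling anchor table."""


class TrainingError(DpcScreenError):
    """Classifier training preconditions violated (e.g. missing class)."""


class NotFittedError(DpcScreenError):
    """Inference requested from an untrained classifier handle."""


class QcError(DpcScreenError):
    """Plate quality control is undefined (e.g. equal group means)."""


class StatisticsError(DpcScreenError):
    """Too few observations for the requested statistic."""


class AssemblyError(DpcScreenError):
    """Temporality-matrix assembly impossible (no cells at any time)."""


class InvalidWellError(DpcScreenError):
    """A well cannot yield a readout (e.g. zero cells at time zero)."""


class MissingDataError(DpcScreenError):
    """A compound has no classified fields or no measured readout."""


class ImageIOError(DpcScreenError):
    """A field image file is missing, truncated or inconsistent."""
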