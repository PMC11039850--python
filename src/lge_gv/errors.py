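"""Exception hierarchy shared across the pipeline."""


class LgeGvError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(LgeGvError, ValueError):
    """A configuration value violates its documented invariant."""


class SchemaError(LgeGvError, ValueError):
    """An input table is missing a mandatory column."""


class EmptyInputError(LgeGvError, ValueError):
    """An operation received no usable rows/readings."""


class InsufficientDataError(LgeGvError, ValueError):
    """Too few readings/pairs/days for the requested statistic."""


class DomainError(LgeGvError, ValueError):
    """A value lies outside the mathematical domain of a transform."""


class UndefinedResultError(LgeGvError, ValueError):
    """The requested quantity is undefined for this input (e.g. 0 events)."""


class DegenerateInputError(LgeGvError, ValueError):
    """Clustering input lacks the required diversity."""


class SingularDesignError(LgeGvError, ValueError):
    """Regression design matrix is (near-)singular."""
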