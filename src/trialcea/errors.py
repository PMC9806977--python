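"""Exception hierarchy used across the package."""


class TrialCeaError(Exception):
    """Base class for package errors."""


class ConfigurationError(TrialCeaError):
    """A config value is missing, inconsistent, or out of range."""


class ValidationError(TrialCeaError, ValueError):
    """Input data violate a documented precondition."""


class UnpricedCategoryError(ConfigurationError):
    """A service-use category has no entry in the unit-cost table."""

    def __init__(self, category: str):
        self.category = category
        super().__init__(f"no unit cost for service category {category!r}")


class QuadrantStraddleError(TrialCeaError):
    """Bootstrap replicates straddle delta_effect = 0.

    Ratio percentiles are not order-meaningful across CE-plane quadrants;
    use the acceptability curve (``ceac``) instead.
    """
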