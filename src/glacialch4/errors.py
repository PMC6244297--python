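"""Exception types shared across modules."""


class GlacialCH4Error(ValueError):
    """Base class for domain errors raised by this package."""


class ValidityError(GlacialCH4Error):
    """An input lies outside the validity window of a physical model."""


class DataQualityError(GlacialCH4Error):
    """A measurement is inconsistent beyond the configured tolerance."""


class MissingBackgroundError(GlacialCH4Error):
    """No t = 0 background reading; supply the configured ambient default."""


class InconsistencyError(GlacialCH4Error):
    """Inputs are mutually inconsistent (e.g. alpha = 1 with enrichment)."""


class AmbiguityError(GlacialCH4Error):
    """Overlapping source fields both contain the sample point."""
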