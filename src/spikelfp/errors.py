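"""Exception types shared across the package."""


class SpikeLfpError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SpikeLfpError):
    """A synthesis or analysis configuration is invalid (bad band edges,
    fractions summing past one, non-finite rate bounds, ...)."""


class NonCanonicalWaveformError(SpikeLfpError):
    """A snippet has no positive deflection after its trough, so the
    trough-to-peak duration is undefined and the unit is left unclassified."""


class UndefinedMetricError(SpikeLfpError):
    """Too few spikes/intervals for the requested statistic."""


class AdmissibilityError(SpikeLfpError):
    """A unit fails a sampling criterion (e.g. fewer than 40 spikes for
    circular statistics, too few analysis windows for coherence)."""


class SessionValidationError(SpikeLfpError):
    """A stored session bundle is inconsistent with its manifest."""
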