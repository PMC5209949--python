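"""Typed errors raised by nbmix."""


class NBMixError(ValueError):
    """Base class for nbmix input/domain errors."""


class DomainError(NBMixError):
    """A parameter is outside its mathematical domain (e.g. mu <= 0)."""


class DegenerateFeatureError(NBMixError):
    """The count response carries no usable information (all zero, or a
    single positive count); such features are refused rather than fitted."""


class RankDeficientError(NBMixError):
    """The fixed-effect design matrix is not of full column rank."""


class AlignmentError(NBMixError):
    """Sample metadata does not align one-to-one with the count matrix."""
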