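"""Exception hierarchy for hsileaf."""


class HsiLeafError(Exception):
    """Base class for all hsileaf errors."""


class MetadataError(HsiLeafError):
    """Required metadata (e.g. a wavelength table) is missing or inconsistent."""


class FormatError(HsiLeafError):
    """On-disk data does not match its declared shape or layout."""


class EmptySelectionError(HsiLeafError):
    """A spectral window or band selection retained zero bands."""


class EmptyROIError(HsiLeafError):
    """A leaf mask or pixel predicate selected no pixels."""


class StratificationError(HsiLeafError):
    """A class has too few tiles to be split into train and test."""


class ConstructionError(HsiLeafError):
    """A built network does not reproduce the declared stage-output shapes."""
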