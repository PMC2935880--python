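"""Exception hierarchy for gwaspower.

All package-specific errors derive from :class:`GwasPowerError` so callers
can catch one base class at pipeline boundaries.
"""


class GwasPowerError(Exception):
    """Base class for all gwaspower errors."""


class ParseError(GwasPowerError):
    """A malformed input file; the message names the offending line."""


class ValidationError(GwasPowerError):
    """Data violates a table invariant (e.g. a frequency outside [0, 1])."""


class PanelMappingError(GwasPowerError):
    """A VCF sample is missing from the sample-to-panel map."""


class InsufficientSampleError(GwasPowerError):
    """A panel has fewer samples than the requested number of founders."""


class MissingPanelError(GwasPowerError):
    """A scenario references a panel absent from the frequency table."""


class ConfigError(GwasPowerError):
    """Invalid scenario or panel configuration."""


class AlignmentError(GwasPowerError):
    """Two per-SNP inputs do not share the same SNP set."""


class AlleleMismatchError(GwasPowerError):
    """A declared risk allele matches neither allele of the table record."""
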