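"""Exception hierarchy.

Every error raised on a user-facing path derives from :class:`HaplostarError`
so the CLI can map failures to a named error class and a nonzero exit status.
"""


class HaplostarError(Exception):
    """Base class for all package errors."""


class ParseError(HaplostarError):
    """A file could not be tokenized (ragged row, malformed allele pair, ...).

    Messages always carry the 1-based file row number where available.
    """


class ValidationError(HaplostarError):
    """A file parsed but violates a content contract (duplicate IDs,
    negative copy number, unknown function label, ...)."""


class FormatError(HaplostarError):
    """An interchange file (PHASE dialect) does not match the expected
    structure."""


class ConfigError(HaplostarError):
    """A configuration input (phenotype thresholds, run options) is invalid."""


class ResolutionExplosionError(HaplostarError):
    """A sample's phase-resolution space exceeds the configured cap."""
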