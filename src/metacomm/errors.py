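"""Exception hierarchy shared across modules."""


class MetacommError(Exception):
    """Base class for all metacomm errors."""


class FormatError(MetacommError):
    """A file does not conform to the expected dialect (columns, shapes)."""


class DataError(MetacommError):
    """Values violate a data contract (negatives, duplicates, mismatches)."""


class ReferentialIntegrityError(DataError):
    """A foreign key does not resolve within the knowledgebase."""


class ConfigError(MetacommError):
    """An analysis configuration value is out of range."""
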