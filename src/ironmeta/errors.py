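"""Exception hierarchy shared across the pipeline stages."""


class IronmetaError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(IronmetaError):
    """A tabular input file is malformed (wrong column count, bad numeric field)."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += f"{path}"
        if line is not None:
            prefix += f", line {line}"
        super().__init__(f"{prefix}: {message}" if prefix else message)


class ValidationError(IronmetaError):
    """Input values violate a documented invariant (vocabulary, duplicates, ranges)."""


class TaxonomyStructureError(IronmetaError):
    """The taxonomy table does not form a single rooted tree (cycle, extra root, orphan)."""


class UnknownTaxonError(IronmetaError):
    """A hit references a taxon identifier absent from the taxonomy tree."""


class NormalizationError(IronmetaError):
    """A sample cannot be normalized (all marker aggregates zero, non-positive median)."""


class ConfigError(IronmetaError):
    """A pipeline configuration is missing a required key or names an unreadable file."""
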