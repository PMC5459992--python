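"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration field is outside its documented domain."""


class DegenerateCohortError(ValueError):
    """A cohort cannot be scored (zero variance, too few animals)."""


class FormatError(ValueError):
    """An input file violates its format contract."""


class DomainError(ValueError):
    """An operation was called outside its mathematical domain."""
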