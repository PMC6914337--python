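"""Exception taxonomy shared across the pipeline."""


class SilamqError(Exception):
    """Base class for all package-raised errors."""


class FormatError(SilamqError):
    """A file could not be parsed as the expected format."""


class ValidationError(SilamqError):
    """Input contents violate a documented contract."""
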