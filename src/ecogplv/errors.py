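"""Exception hierarchy shared by all pipeline stages."""


class EcogPlvError(Exception):
    """Base class for all package errors."""


class FormatError(EcogPlvError, ValueError):
    """A file is missing, unreadable, or not in the documented format."""


class IntegrityError(EcogPlvError, ValueError):
    """File contents are parseable but internally inconsistent
    (e.g. declared shape does not match the data on disk, or
    event onsets are not strictly increasing)."""


class ConfigError(EcogPlvError, ValueError):
    """A configuration value violates its documented constraints."""
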