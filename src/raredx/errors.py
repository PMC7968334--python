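"""Exception hierarchy shared across the toolkit."""


class RaredxError(Exception):
    """Base class for all toolkit errors."""


class FormatError(RaredxError):
    """An input file violates its format contract."""


class StructuralError(RaredxError):
    """Input parses but is internally inconsistent (e.g. unknown parent id)."""


class PairingError(RaredxError):
    """Sample ids in a record cannot be matched to the pedigree."""


class ConfigError(RaredxError):
    """A configuration file is invalid."""


class EmptyStoreError(RaredxError):
    """The observation store has no loaded cases."""
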