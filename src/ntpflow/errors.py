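"""Exception hierarchy shared by all ntpflow modules."""


class NtpflowError(Exception):
    """Base class for all package-specific errors."""


class InputError(NtpflowError):
    """A file could not be read or parsed."""


class EmptyStructureError(InputError):
    """A structure file yielded zero atoms."""


class TopologyError(NtpflowError):
    """Frame/structure atom layouts are incompatible."""


class SelectionError(NtpflowError):
    """A residue selection could not be resolved as required."""


class ConfigError(NtpflowError):
    """A configuration (region map, model spec) is inconsistent."""


class SpecError(NtpflowError):
    """A synthetic-data specification is invalid."""
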