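"""Exception hierarchy shared across the package."""


class MirselectError(Exception):
    """Base class for all package-specific errors."""


class AlphabetError(MirselectError, ValueError):
    """A sequence contains characters outside its declared alphabet."""


class LengthError(MirselectError, ValueError):
    """A sequence is too short (or of inconsistent length) for the operation."""


class ConfigurationError(MirselectError, ValueError):
    """An option value is outside its permitted domain."""


class InsufficientDataError(MirselectError, ValueError):
    """A statistical routine received an empty or one-sided sample."""


class NoInformationError(MirselectError, ValueError):
    """A paired test received data carrying no information (all ties)."""


class DegenerateDesignError(MirselectError, ValueError):
    """A factorial design has too few levels or an empty cell structure."""


class CapacityError(MirselectError, ValueError):
    """A simulation request does not fit in the sequence space provided."""
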