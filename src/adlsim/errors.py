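"""Exception types shared across the package."""


class AdlsimError(Exception):
    """Base class for all package errors."""


class LayoutError(AdlsimError, ValueError):
    """Invalid layout file or layout contents (unknown place type, bad coordinates...)."""


class ProfileError(AdlsimError, ValueError):
    """Invalid resident profile (negative duration, D exceeding T, bad override...)."""


class ConfigurationError(AdlsimError, ValueError):
    """A run configuration that cannot produce a simulation (non-positive awake time...)."""


class ContractError(AdlsimError, ValueError):
    """An operation was called outside its contract (non-performable AS, negative dt...)."""
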