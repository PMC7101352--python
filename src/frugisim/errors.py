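"""Typed exceptions raised across the package."""


class FrugisimError(Exception):
    """Base class for all package errors."""


class NetworkFormatError(FrugisimError, ValueError):
    """A network file or matrix violates the interaction-network contract."""


class TraitError(FrugisimError, ValueError):
    """A trait table is missing or violates required trait information."""


class DomainError(FrugisimError, ValueError):
    """A numeric argument is outside the domain of an allometric function."""


class ConfigError(FrugisimError, ValueError):
    """A configuration value violates its contract."""
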