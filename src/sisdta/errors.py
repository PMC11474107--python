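"""Exception hierarchy shared across the package."""


class SisdtaError(Exception):
    """Base class for all package errors."""


class InputError(SisdtaError):
    """Malformed or inconsistent user-supplied data (bad SMILES, missing ids, shape mismatch)."""


class ConfigError(SisdtaError):
    """Invalid configuration value (negative length, unknown kernel, latent >= input)."""


class DomainError(SisdtaError):
    """Mathematically undefined request (empty source set, zero row sum, constant vector)."""
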