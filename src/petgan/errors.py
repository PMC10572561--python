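"""Exception hierarchy; the CLI maps these onto exit codes."""


class PetganError(Exception):
    """Base class for package errors."""
    exit_code = 1


class ConfigError(PetganError):
    """Invalid specification, configuration or argument."""
    exit_code = 2


class DataError(PetganError):
    """Missing, malformed or inconsistent data."""
    exit_code = 3


class DivergenceError(PetganError):
    """Training produced non-finite losses."""
    exit_code = 4
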