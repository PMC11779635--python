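"""Exception hierarchy shared across the package."""


class MatrikinError(Exception):
    """Base class for package errors."""


class ConfigError(MatrikinError):
    """Invalid configuration value or unknown key."""


class DataFormatError(MatrikinError):
    """Malformed input file; carries the offending path/line where known."""


class SimulationFailure(MatrikinError):
    """A stochastic simulation could not produce a valid outcome.

    Raised e.g. when every lineage of a pedigree goes extinct before the
    requested depth, or a deme loses one sex entirely too many times.
    Retriable: re-running with a different seed may succeed.
    """
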