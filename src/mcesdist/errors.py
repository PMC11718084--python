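"""Exception types shared across the package."""


class MCESError(Exception):
    """Base class for all package errors."""


class InputError(MCESError):
    """Invalid user input (unparseable SMILES, malformed file, bad ids)."""


class ValidationError(MCESError):
    """A structural precondition on graphs or tables is violated."""


class SolverEnvironmentError(MCESError):
    """The requested ILP solver backend is not available."""


class OracleSizeError(MCESError):
    """Input exceeds the size cap of the brute-force oracle."""
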