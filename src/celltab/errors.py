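"""Exception types shared across celltab."""


class CellTabError(Exception):
    """Base class for all celltab errors."""


class ModelIOError(CellTabError):
    """Malformed or inconsistent model-definition files."""


class CompileError(CellTabError):
    """A model-definition set that parses but cannot be compiled."""


class SimulationError(CellTabError):
    """Integrator failure or invalid state during simulation."""
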