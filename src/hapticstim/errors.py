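"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid configuration (bad stimulus set, sampling rate, window...)."""


class SimulationError(RuntimeError):
    """Numerical simulation left its valid operating envelope."""


class ProcedureError(RuntimeError):
    """An experimental procedure (e.g. the staircase) failed to terminate."""


class PipelineError(RuntimeError):
    """A pipeline stage could not run; the message names the missing cells."""
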