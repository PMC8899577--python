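"""Exception types shared across the package."""


class InputError(ValueError):
    """Raised when an input violates a documented precondition."""


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge from every start."""
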