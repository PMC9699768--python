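"""Exception hierarchy shared across the pipeline stages."""


class StrokeCADError(Exception):
    """Base class for all package errors."""


class InputError(StrokeCADError, ValueError):
    """Malformed or out-of-contract input (shapes, ranges, labels)."""


class CapabilityError(StrokeCADError, RuntimeError):
    """A requested optional capability (e.g. a pretrained CNN backend)
    is not available in this installation."""


class RunError(StrokeCADError, RuntimeError):
    """A computation failed mid-run (e.g. an objective returned a
    non-finite value)."""
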