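"""Exception types shared across the package."""


class CrystalignError(Exception):
    """Base class for package errors."""


class FormatError(CrystalignError, ValueError):
    """A file did not conform to the expected dialect."""


class ConvergenceError(CrystalignError, RuntimeError):
    """Sampling too sparse or unstable to produce a usable estimate."""


class DegenerateGeometryError(CrystalignError, ValueError):
    """Atom geometry does not define the requested frame (e.g. collinear ring)."""
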