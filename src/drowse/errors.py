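"""Exception types shared across the package."""


class DegenerateGeometryError(ValueError):
    """Landmark configuration has collapsed (coincident corners, collinear points)."""


class NoConvergenceError(RuntimeError):
    """Iterative solver exhausted its iteration budget above tolerance."""


class OptimizationError(RuntimeError):
    """The objective returned a non-finite value during a search."""
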