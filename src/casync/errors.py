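"""Exception types shared across the package."""


class CasyncError(Exception):
    """Base class for package-specific errors."""


class DegenerateBaselineError(CasyncError):
    """Raised when the per-pixel minimum projection contains non-positive values.

    A ΔF/F movie divides by the minimum projection, so pixels whose minimum
    over frames is <= 0 have no defined baseline.
    """

    def __init__(self, n_bad_pixels: int):
        self.n_bad_pixels = n_bad_pixels
        super().__init__(
            f"{n_bad_pixels} pixel(s) have a minimum-projection value <= 0; "
            "DeltaF/F baseline is undefined for them"
        )


class ConfigError(CasyncError):
    """Raised for missing or contradictory pipeline configuration keys."""
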