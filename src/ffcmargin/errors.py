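"""Exception hierarchy shared across the package."""


class FFCMarginError(Exception):
    """Base class for all package-specific errors."""


class InvalidDispersionError(FFCMarginError, ValueError):
    """A dispersion calibration is requested for a non-decreasing profile
    (Ratio must exceed 1 for R1 to fall with increasing field)."""


class MissingFieldError(FFCMarginError, LookupError):
    """An NMRD profile lacks an evolution field required by a quantifier."""

    def __init__(self, field_mhz: float, sample_id: str | None = None):
        self.field_mhz = field_mhz
        self.sample_id = sample_id
        where = f" in profile '{sample_id}'" if sample_id else ""
        super().__init__(f"no R1 value at {field_mhz} MHz{where}")


class MissingMeasurementError(FFCMarginError, ValueError):
    """A borderline sample needs the second quantifier but it was never
    measured: signals that an extra R1 acquisition is required."""


class EmptyProfileError(FFCMarginError, ValueError):
    """Profile assembly received no converged fits."""


class SelectionError(FFCMarginError, ValueError):
    """No sample meets a reference-profile composition threshold."""
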