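"""Exception hierarchy for extrafib."""


class ExtrafibError(Exception):
    """Base class for all extrafib errors."""


class InvalidGeometryError(ExtrafibError, ValueError):
    """A unit-cell dimension is non-positive or otherwise unusable."""


class UndefinedFractionError(ExtrafibError, ZeroDivisionError):
    """A fraction is requested from an all-zero numerator and denominator."""


class NegativeCorrectedCountError(ExtrafibError, ValueError):
    """Background-corrected count rate came out negative.

    The gap-zone and stack count rates must exceed the overlap-zone rate;
    a negative corrected rate signals region misassignment in the input and
    is raised rather than clamped (clamping would bias the external-mineral
    fraction upward).
    """


class SceneConstructionError(ExtrafibError, ValueError):
    """The synthetic scene cannot be built as configured."""


class NoPeriodError(ExtrafibError, RuntimeError):
    """No periodicity above the noise floor was found in a profile."""


class NoFeatureError(ExtrafibError, RuntimeError):
    """No feature above threshold was found along a transect."""


class EmptyRegionError(ExtrafibError, ValueError):
    """A region mask selects no probe positions."""
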