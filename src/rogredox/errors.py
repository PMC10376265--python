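"""Exception hierarchy for the rogredox pipeline."""


class RogredoxError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(RogredoxError):
    """Invalid scenario configuration or calibration parameters."""


class InputError(RogredoxError):
    """Malformed or degenerate input data (empty masks, missing rows)."""


class MeasurementError(RogredoxError):
    """A measurement could not be made (e.g. every ROI pixel saturated)."""


class CalibrationInversionError(RogredoxError):
    """Calibration endpoints inverted: R_ox <= R_red.

    Usually means the reduced and oxidized image sets were swapped, or one
    of the calibration treatments failed.
    """


class GatingError(RogredoxError):
    """Debris gating rejected every event."""


class UndefinedPotentialError(RogredoxError):
    """Nernst potential requested at a boundary degree of oxidation (0 or 1)."""
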