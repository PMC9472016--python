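"""Exception hierarchy for device-design and simulation failures."""


class SpiralSortError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(SpiralSortError):
    """A channel, spiral or outlet dimension is degenerate or non-physical."""


class InvalidParticleError(SpiralSortError):
    """A particle specification is degenerate (e.g. zero diameter)."""


class DesignInfeasibleError(SpiralSortError):
    """No physically realizable geometry satisfies the requested constraint."""


class CalibrationMissingError(SpiralSortError):
    """A calibrated force ratio was requested without a calibration constant."""


class NoEquilibriumError(SpiralSortError):
    """The lateral force balance has no sign change inside the search bracket."""


class TuningInfeasibleError(SpiralSortError):
    """Cut-off tuning found no crossing of streamline and dividing boundary."""


class ConfigError(SpiralSortError):
    """A device configuration file violates the schema."""
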