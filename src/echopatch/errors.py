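"""Exception hierarchy for echopatch."""


class EchoPatchError(ValueError):
    """Base class for all toolkit errors."""


class GeometryError(EchoPatchError):
    """Invalid transducer-array or surface geometry."""


class SequenceError(EchoPatchError):
    """Invalid transmit event or sequence."""


class SimulationError(EchoPatchError):
    """Invalid forward-simulation input."""


class ImagingError(EchoPatchError):
    """Invalid beamforming / image-formation input."""


class MetricError(EchoPatchError):
    """A quality metric could not be computed from the given data."""


class CardiacError(EchoPatchError):
    """Invalid cardiac-function pipeline input."""
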