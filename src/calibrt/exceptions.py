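"""Exception hierarchy shared across the package."""


class CalibRTError(Exception):
    """Base class for all calibrt errors."""


class SchemaError(CalibRTError):
    """A required column is missing from an input table."""


class EmptyInputError(CalibRTError):
    """An operation received zero usable data points."""


class DegenerateRangeError(CalibRTError):
    """All points coincide in one dimension, so a grid cannot be built."""


class InvalidEdgeError(CalibRTError):
    """A path edge was requested between a node and itself."""


class DegenerateScenarioError(CalibRTError):
    """A benchmark scenario produced no signal points."""
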