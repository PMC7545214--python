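"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, ParseError -> 3,
AnalysisError -> 4.
"""


class FcpinetError(Exception):
    """Base class for all package errors."""


class ConfigError(FcpinetError):
    """Bad or missing configuration (chain map, class map, thresholds)."""


class ParameterError(ConfigError):
    """A numeric parameter is outside its admissible range (e.g. cutoff <= 0)."""


class ParseError(FcpinetError):
    """A coordinate file could not be read or is internally inconsistent."""


class AnalysisError(FcpinetError):
    """A pipeline stage failed on otherwise valid input."""


class InsufficientDataError(AnalysisError):
    """Too few observations to estimate a quantity (e.g. < 10 chlorophylls)."""


class DegenerateLeafletError(AnalysisError):
    """The chlorophyll projections do not separate into two leaflet clusters."""


class CycleError(AnalysisError):
    """The directed step graph contains a cycle and cannot be chained."""
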