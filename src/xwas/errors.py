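"""Exception types shared across the package."""


class XwasError(Exception):
    """Base class for all package-specific errors."""


class SimulationError(XwasError):
    """A synthetic-data generator could not produce a valid draw."""


class HarmonizationError(XwasError):
    """Weight / GWAS / LD-panel SNP sets could not be aligned."""


class DegenerateWeightError(XwasError):
    """The weight variance W'SW is numerically zero; the gene statistic is undefined."""


class ParseError(XwasError):
    """A file did not conform to the expected dialect."""
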