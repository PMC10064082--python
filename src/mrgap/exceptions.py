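"""Exception types shared across the package."""


class MRGapError(Exception):
    """Base class for package errors."""


class InstrumentError(MRGapError, ValueError):
    """Instrument construction failed (no significant SNPs, bad columns, ...)."""


class HarmonizationError(MRGapError, ValueError):
    """Exposure and outcome summary statistics could not be aligned."""


class EstimationError(MRGapError, ValueError):
    """An estimator's preconditions were not met."""


class CollinearityError(EstimationError):
    """The multivariable design matrix is (near-)rank-deficient."""
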