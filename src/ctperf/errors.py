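"""Exception hierarchy.

Every failure mode promised by the public API raises one of these, so callers
can distinguish bad inputs (ContractError), bad files (FormatError/ParseError),
and numerical breakdowns (OptimizationError).
"""


class CTPerfError(Exception):
    """Base class for all errors raised by ctperf."""


class ContractError(CTPerfError):
    """An argument violates a documented precondition (geometry mismatch, ...)."""


class FormatError(CTPerfError):
    """A file is not in a supported volume/landmark format."""


class ParseError(CTPerfError):
    """A file in a supported format could not be decoded."""


class SpecError(CTPerfError):
    """A phantom specification is infeasible or inconsistent."""


class SegmentationError(CTPerfError):
    """Lung segmentation produced an empty or invalid mask."""


class OptimizationError(CTPerfError):
    """Registration optimization produced a non-finite cost."""
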