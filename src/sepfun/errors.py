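"""Exception hierarchy.

Every malformed-input class a reader can reject has a named error so that
callers (and tests) can distinguish "file is broken" from "value is out of
domain" without string matching. Nothing here ever returns NaN in place of
raising — silent propagation of undefined LD or probabilities is the failure
mode this hierarchy exists to prevent.
"""


class SepfunError(Exception):
    """Base class for all package errors."""


class FormatError(SepfunError):
    """A file does not conform to its declared format (missing column, bad field)."""


class DuplicateRecordError(FormatError):
    """Two records claim the same identity, e.g. duplicate (chrom, pos) in one study."""


class CoordinateError(FormatError):
    """Interval coordinates are inconsistent (start >= end after normalization)."""


class PhasingError(FormatError):
    """A VCF genotype is not phased ('0/1' instead of '0|1')."""


class BiallelicError(FormatError):
    """A variant carries more than two alleles."""


class MotifMatrixError(FormatError):
    """A PWM row deviates from a probability distribution beyond tolerance."""


class SequenceError(SepfunError):
    """A DNA sequence contains characters outside ACGT."""


class DomainError(SepfunError, ValueError):
    """A numeric argument is outside its mathematical domain (e.g. p not in (0,1])."""


class ParameterError(SepfunError, ValueError):
    """A configuration parameter is invalid (n_tests < 1, empty universe, ...)."""


class EmptyInputError(SepfunError):
    """An operation that requires at least one record received none."""


class MonomorphicVariantError(SepfunError):
    """LD is undefined because one variant has allele frequency 0 or 1."""


class VariantLookupError(SepfunError, KeyError):
    """A requested rsID is absent from the haplotype panel."""


class ShapeError(SepfunError, ValueError):
    """Dimension mismatch between p-values and the LD matrix."""


class CapacityError(ParameterError):
    """A simulation requests more planted entities than the panel can hold."""


class PipelineStageError(SepfunError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
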