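"""Exception hierarchy shared across the pipeline.

Every error raised by fernhybrid derives from :class:`FernHybridError`, so
callers (and the CLI) can catch one type at a pipeline-stage boundary.
"""


class FernHybridError(Exception):
    """Base class for all fernhybrid errors."""


class AlignmentError(FernHybridError):
    """Ragged alignment, all-gap column, or otherwise malformed alignment."""


class MetadataError(FernHybridError):
    """Sample sheet inconsistent with the sequence records."""


class AlphabetError(FernHybridError):
    """Character outside the permitted alphabet for its row role."""


class SchemaError(FernHybridError):
    """Two objects built over different character schemas were combined."""


class RoleError(FernHybridError):
    """An operation received rows of the wrong role (e.g. IUPAC codes in a
    haplotype-role row)."""


class DataError(FernHybridError):
    """Input values are contradictory or insufficient for the operation."""


class ComplexityError(FernHybridError):
    """Genotype too heterozygous to enumerate resolutions within the bound."""


class ConfigError(FernHybridError):
    """Invalid simulation or pipeline configuration."""


class ClassificationError(FernHybridError):
    """No informative locus available for generation classification."""


class InternalError(FernHybridError):
    """Invariant violated inside the package (a bug, not a user error)."""


class UsageError(FernHybridError):
    """Invalid way of calling an operation (unknown format, bad flag)."""


class PipelineStageError(FernHybridError):
    """Wraps an error with the pipeline stage (and sample) where it arose."""

    def __init__(self, stage: str, message: str, sample: str | None = None):
        self.stage = stage
        self.sample = sample
        ctx = f"[stage={stage}" + (f", sample={sample}]" if sample else "]")
        super().__init__(f"{ctx} {message}")
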