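"""Exception types shared across the pipeline."""


class FdefminerError(Exception):
    """Base class for all package errors."""


class FormatError(FdefminerError):
    """Malformed input file (FASTA, GFF3, catalog TSV)."""


class SpecError(FdefminerError):
    """Infeasible or inconsistent synthetic-genome plan."""


class ValidationError(FdefminerError):
    """Inconsistent in-memory object (overlapping exons, bad matrix, ...)."""
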