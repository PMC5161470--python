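"""Exception hierarchy for snptag."""


class SnptagError(Exception):
    """Base class for all snptag-specific errors."""


class InvalidInputError(SnptagError, ValueError):
    """Raised when an input vector, matrix or parameter violates a precondition."""


class DegenerateSeedError(SnptagError):
    """Raised when a seed SNP is monomorphic: its similarity to every SNP is 0,
    so the initial weight vector is identically zero and no attractor exists."""


class DegenerateAttractorError(SnptagError):
    """Raised when a weight vector collapses to all zeros mid-iteration, or a
    sample has no genotyped SNP under positive weight (metaSNP undefined)."""


class ParseError(SnptagError, ValueError):
    """Raised on malformed genotype input files."""
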