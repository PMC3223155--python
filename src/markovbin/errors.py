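"""Exception hierarchy.

``MarkovbinError`` is the base for everything the package raises on bad
data; the CLI maps it to exit code 2. Parameter/usage problems raise
``InvalidParameterError`` (exit code 1 when they reach the CLI).
"""


class MarkovbinError(Exception):
    """Base class for data-level errors."""


class InvalidParameterError(MarkovbinError, ValueError):
    """A parameter is out of its documented range."""


class DegenerateModelError(MarkovbinError):
    """Training sequences contain no countable transition."""


class DuplicateGenomeError(MarkovbinError):
    """A genome_id occurs more than once."""


class TaxonomyError(MarkovbinError):
    """Malformed lineage table or unknown genome/rank."""


class OrderMismatchError(MarkovbinError):
    """Read vectors and database were built with different k."""


class DatabaseFormatError(MarkovbinError):
    """The on-disk database container is not readable."""


class FastaError(MarkovbinError):
    """Unreadable or empty FASTA input."""
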