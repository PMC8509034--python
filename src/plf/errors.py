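"""Named exceptions raised across the package.

Every validation failure raises a subclass of :class:`PLFError`, so callers
(CLI, drivers) can distinguish bad input from bugs.
"""


class PLFError(Exception):
    """Base class for all package errors."""


class FastaError(PLFError):
    """Malformed or empty FASTA input."""


class DuplicateAccessionError(FastaError):
    """Two FASTA records share an accession."""


class InvalidSequenceError(FastaError):
    """A sequence contains characters outside the amino-acid alphabet."""


class PeptideTableError(PLFError):
    """Malformed peptide table (missing column, bad count, bad label)."""


class UnknownGroupError(PeptideTableError):
    """A group label is not one of the two study groups."""


class UnknownProteinError(PLFError):
    """A peptide record references an accession absent from the FASTA."""


class PeptideNotFoundError(PLFError):
    """A peptide sequence is not a substring of its parent protein."""


class AmbiguousPeptideError(PLFError):
    """A peptide occurs more than once under occurrence_policy='error'."""


class SegmentationError(PLFError):
    """Invalid segmentation arguments or out-of-range coordinates."""


class DesignError(PLFError):
    """Inconsistent sample metadata (e.g. one sample id in two groups)."""


class CompositeScaleError(PLFError):
    """Cross-region composite scaling needs at least two regions."""


class ConfigError(PLFError):
    """Invalid run configuration (missing paths, bad parameter values)."""


class SimulationError(PLFError):
    """Invalid synthetic-study specification."""
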