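"""Exception hierarchy.

Everything user-facing derives from :class:`CountdiffError` so the CLI can
turn any validated failure into a one-line diagnostic with exit status 1.
"""


class CountdiffError(Exception):
    """Base class for all countdiff errors."""


class FormatError(CountdiffError):
    """Malformed count matrix or result table (duplicates, negatives, non-numeric)."""


class MappingError(CountdiffError):
    """Lane/condition/gene lookup failure (missing lane in sample sheet, unknown id)."""


class DegenerateLaneError(CountdiffError):
    """A lane with zero total count where a positive total is required."""


class InsufficientGenesError(CountdiffError):
    """Fewer than two genes survive TMM trimming."""


class UnequalReplicatesError(CountdiffError):
    """Bayesian two-condition test requested with m != n replicates."""


class DesignError(CountdiffError):
    """Invalid simulation design (e.g. type-I experiment with DE genes spiked in)."""
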