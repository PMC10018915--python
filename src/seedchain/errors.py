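"""Exception hierarchy.

Exit-code mapping used by the CLI: input/format problems exit 2,
internal contract or equivalence failures exit 3.
"""


class SeedchainError(Exception):
    """Base class for all package errors."""


class InputError(SeedchainError):
    """Missing, empty or malformed input (FASTA/TSV/arguments)."""


class IndexBuildError(InputError):
    """Reference index could not be built (e.g. empty FASTA)."""


class GroupingError(SeedchainError):
    """Anchors from mixed (rid, strand) groups passed where one group is required."""


class GenerationError(SeedchainError):
    """Synthetic-data request is infeasible (packing/parameter constraints)."""


class ContractViolationError(SeedchainError):
    """An internal invariant was violated (e.g. inconsistent successor ranges)."""


class EquivalenceError(SeedchainError):
    """Forward and backward chaining engines disagreed in verify mode."""
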