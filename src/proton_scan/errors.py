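"""Exception hierarchy for the scan pipeline.

Each pipeline stage raises a distinct subclass so the CLI can report the
failing stage by name.
"""


class ProtonScanError(Exception):
    """Base class for all package errors."""


class PdbFormatError(ProtonScanError):
    """The input stream is not a usable PDB coordinate file."""


class MissingChainError(ProtonScanError):
    """A requested chain ID is absent from the structure."""

    def __init__(self, chain: str, available: list[str]):
        self.chain = chain
        self.available = list(available)
        super().__init__(
            f"chain {chain!r} not found; available chains: {', '.join(available) or '(none)'}"
        )


class ModelError(ProtonScanError):
    """A mutant model could not be built (e.g. incomplete backbone)."""


class StatisticsError(ProtonScanError):
    """Too little data for box-and-whisker statistics."""


class DataError(ProtonScanError):
    """Inconsistent tabular inputs (scores, PSSM coverage, ...)."""
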