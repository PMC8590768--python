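"""Exception hierarchy shared across the package.

``ModscreenError`` is the common base so callers (notably the CLI) can map
package failures to exit codes without catching bare ``Exception``.
"""


class ModscreenError(Exception):
    """Base class for all package-raised errors."""


class FormatError(ModscreenError):
    """A file does not conform to its declared format (FASTA/GFF3/VCF/TSV)."""


class ModelError(ModscreenError):
    """A domain object violates its invariants (e.g. CDS length not 3n)."""


class ConfigError(ModscreenError):
    """Invalid or inconsistent configuration."""


class DomainError(ModscreenError):
    """An operation was asked about a point outside its domain."""


class DataIntegrityError(ModscreenError):
    """Inputs contradict each other (e.g. variant REF mismatching the genome)."""


class SimulationError(ModscreenError):
    """The synthetic-screen generator cannot satisfy its constraints."""


class UsageError(ModscreenError):
    """An operation was called in a state it does not accept."""
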