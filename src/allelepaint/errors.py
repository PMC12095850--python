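"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, FormatError (and
subclasses) -> 3, any other AllelePaintError -> 4.
"""


class AllelePaintError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(AllelePaintError):
    """Invalid run or simulation configuration."""


class FormatError(AllelePaintError):
    """Malformed input file (FASTA / VCF / TSV / PDB dialects)."""


class AlignmentError(FormatError):
    """Alignment invariant violated (ragged rows, bad frame)."""


class UnsupportedRecordError(FormatError):
    """A record is syntactically valid but outside the supported subset
    (indels, non-diploid genotypes, multi-base alleles)."""


class SimulationError(AllelePaintError):
    """The synthetic-data generator could not satisfy its constraints."""


class DomainError(AllelePaintError):
    """An operation was applied outside its mathematical domain
    (stop codons in dN/dS counting, zero compared sites, ...)."""


class AmbiguityError(AllelePaintError):
    """Observed data are ambiguous where the method requires a unique
    answer (e.g. >2 alleles at a column being polarized)."""
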