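"""Core in-memory data model.

Conventions used throughout the package:

* alignment columns are 1-based and inclusive;
* the codon frame starts at column 1, so column ``c`` belongs to codon
  ``(c - 1) // 3 + 1`` (also 1-based);
* ``N`` and ``-`` are missing data and are excluded per-sample from
  counts; denominators are reported alongside every proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import AlignmentError

#: characters treated as missing data in aligned sequences
MISSING = frozenset("N-")

#: nucleotide alphabet for aligned haplotypes
BASES = ("A", "C", "G", "T")


def codon_index(column: int) -> int:
    """1-based codon number of a 1-based alignment column."""
    return (column - 1) // 3 + 1


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    species: str
    lineage: str
    lake: str = ""


@dataclass
class AlignedHaplotype:
    """One phased gene copy of one sample, as an aligned CDS string.

    ``phase`` is 1 or 2 for phased copies, or the string ``"unphased"``
    for a single IUPAC-coded sequence representing both copies.
    """

    sample_id: str
    species: str
    lineage: str
    phase: int | str
    sequence: str

    @property
    def name(self) -> str:
        if self.phase in (1, 2):
            return f"{self.sample_id}_{self.phase}"
        return self.sample_id

    def __len__(self) -> int:
        return len(self.sequence)


def validate_alignment(
    haplotypes: Sequence[AlignedHaplotype], trailing_bases: int = 0
) -> int:
    """Check equal lengths and codon frame; return the alignment length.

    ``trailing_bases`` declares a trailing incomplete codon (0, 1 or 2
    columns) that is ignored when checking that the length is a multiple
    of three.
    """
    if not haplotypes:
        raise AlignmentError("empty alignment")
    lengths = {len(h) for h in haplotypes}
    if len(lengths) != 1:
        raise AlignmentError(
            f"ragged alignment: observed lengths {sorted(lengths)}"
        )
    (length,) = lengths
    if trailing_bases not in (0, 1, 2):
        raise AlignmentError("trailing_bases must be 0, 1 or 2")
    if (length - trailing_bases) % 3 != 0:
        raise AlignmentError(
            f"alignment length {length} minus {trailing_bases} trailing "
            "bases is not a multiple of 3"
        )
    return length


@dataclass(frozen=True)
class GenotypeRecord:
    """One diploid genotype at one alignment column."""

    sample_id: str
    site: int  # 1-based alignment column
    alleles: tuple[str, str]
    phased: bool


@dataclass(frozen=True)
class DiagnosticSite:
    """One alignment column fixed for different states in the two clades."""

    column: int
    state_ancestral: str
    state_derived: str
    codon: int
    aa_ancestral: str
    aa_derived: str
    is_nonsynonymous: bool


@dataclass
class DiagnosticSiteSet:
    """Ordered clade-diagnostic columns with ancestral/derived states."""

    gene: str
    sites: list[DiagnosticSite]
    clade_labels: tuple[str, str] = ("Clade I", "Clade II")

    def __post_init__(self) -> None:
        cols = [s.column for s in self.sites]
        if cols != sorted(cols) or len(set(cols)) != len(cols):
            raise ValueError("diagnostic columns must be strictly increasing")

    @property
    def columns(self) -> list[int]:
        return [s.column for s in self.sites]

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": [s.column for s in self.sites],
                "ancestral": [s.state_ancestral for s in self.sites],
                "derived": [s.state_derived for s in self.sites],
                "codon": [s.codon for s in self.sites],
                "aa_from": [s.aa_ancestral for s in self.sites],
                "aa_to": [s.aa_derived for s in self.sites],
                "nonsynonymous": [s.is_nonsynonymous for s in self.sites],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, gene: str = "gene") -> "DiagnosticSiteSet":
        sites = [
            DiagnosticSite(
                column=int(r.column),
                state_ancestral=str(r.ancestral),
                state_derived=str(r.derived),
                codon=int(r.codon),
                aa_ancestral=str(r.aa_from),
                aa_derived=str(r.aa_to),
                is_nonsynonymous=bool(r.nonsynonymous),
            )
            for r in df.itertuples()
        ]
        return cls(gene=gene, sites=sites)


#: genotype categories, in reporting order
GENOTYPE_CATEGORIES = (
    "homozygote_I",
    "homozygote_II",
    "heterozygote",
    "recombinant",
    "unclassifiable",
)

#: haplotype painting categories
HAPLOTYPE_CATEGORIES = ("ancestral", "derived", "mixture", "unclassifiable")


@dataclass
class PaintingResult:
    """Per-diagnostic-site states of one haplotype.

    ``states`` is a string over {A, D, M}: match to the ancestral state,
    match to the derived state, or missing/third allele.
    """

    sample_id: str
    phase: int | str
    states: str
    category: str
    min_crossovers: int
    n_third_allele: int = 0

    @property
    def name(self) -> str:
        if self.phase in (1, 2):
            return f"{self.sample_id}_{self.phase}"
        return self.sample_id


@dataclass
class LineageAlleleSummary:
    lineage: str
    n_samples: int
    counts: dict[str, int]
    proportions: dict[str, float]
    denominator: int  # classified samples (unclassifiable excluded)


@dataclass
class PairwiseDivergence:
    seq_a_id: str
    seq_b_id: str
    compared_sites: int
    variant_sites: int
    denominator_mode: str = "pairwise"  # or "full_cds"

    @property
    def percent(self) -> float:
        return 100.0 * self.variant_sites / self.compared_sites


@dataclass
class CodonSubstitutionStats:
    """Nei–Gojobori counting statistics for one aligned CDS pair."""

    compared_codons: int
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float | None
    dS: float | None
    omega: float | None
    notes: str = ""


@dataclass
class BranchSubstitutionCounts:
    branch: str  # "parent->child"
    nonsynonymous: int
    synonymous: int
    ambiguous: int
    columns_nonsynonymous: list[int] = field(default_factory=list)
    columns_synonymous: list[int] = field(default_factory=list)
    columns_ambiguous: list[int] = field(default_factory=list)


@dataclass
class EnrichmentResult:
    """2x2 contingency of substitution sites x ligand-binding sites."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    sidedness: str
    p_two_sided: float
    p_one_sided: float
    mode: str = ""  # binding-site mode used (intersection/union)


def metadata_frame(records: Iterable[SampleMetadata]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "species": m.species,
                "lineage": m.lineage,
                "lake": m.lake,
            }
            for m in records
        ]
    )
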