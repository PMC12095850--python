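"""Ligand-related residues and substitution enrichment.

Receptor coordinates and docked ligand poses (PDB-style files, upstream
structure prediction and docking) define the ligand-related residue set:
a residue qualifies when its minimum atom-atom distance to a pose is
within the cutoff (default 5 A), either for ALL poses (intersection, the
default) or for ANY pose (union).  A Fisher exact test then asks whether
the inter-clade amino-acid substitutions fall on ligand-related residues
more often than chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

from .errors import DomainError, FormatError
from .model import DiagnosticSiteSet, EnrichmentResult

log = logging.getLogger(__name__)

SEGMENT_LABELS = (
    "N-term", "TM1", "ICL1", "TM2", "ECL1", "TM3", "ICL2", "TM4",
    "ECL2", "TM5", "ICL3", "TM6", "ECL3", "TM7", "C-term",
)


@dataclass(frozen=True)
class TMSegment:
    label: str
    start: int  # 1-based residue numbers, inclusive
    end: int


@dataclass
class StructureAnnotation:
    """Receptor residues, ligand poses, and optional topology segments."""

    #: ordered (residue number, atom coordinate array of shape (n, 3))
    residues: list[tuple[int, np.ndarray]]
    #: one (m, 3) coordinate array per docked pose
    poses: list[np.ndarray]
    tm_segments: list[TMSegment] = field(default_factory=list)
    cutoff: float = 5.0

    def __post_init__(self) -> None:
        idx = [i for i, _ in self.residues]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise FormatError("residue indices must be strictly increasing")
        prev_end = 0
        for seg in sorted(self.tm_segments, key=lambda s: s.start):
            if seg.start <= prev_end:
                raise FormatError(f"overlapping or unordered segment {seg.label}")
            prev_end = seg.end


def load_residue_coordinates(pdb_path: str | Path) -> list[tuple[int, np.ndarray]]:
    """All-atom coordinates per residue from a PDB coordinate file
    (first model, ATOM records, all chains in order)."""
    structure = PDBParser(QUIET=True).get_structure("receptor", str(pdb_path))
    model = next(structure.get_models())
    residues = []
    for chain in model:
        for res in chain:
            if res.id[0] != " ":  # skip waters/hetero
                continue
            coords = np.array([atom.coord for atom in res], dtype=float)
            residues.append((int(res.id[1]), coords))
    if not residues:
        raise FormatError(f"no ATOM residues in {pdb_path}")
    return residues


def load_poses(paths: str | Path | Iterable[str | Path]) -> list[np.ndarray]:
    """Ligand pose coordinate sets; each MODEL in each file is one pose
    (ATOM and HETATM records alike)."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    poses = []
    parser = PDBParser(QUIET=True)
    for path in paths:
        structure = parser.get_structure("pose", str(path))
        for model in structure:
            coords = np.array(
                [atom.coord for atom in model.get_atoms()], dtype=float
            )
            if coords.size:
                poses.append(coords)
    if not poses:
        raise FormatError("no pose coordinates found")
    return poses


def read_tm_segments(path: str | Path) -> list[TMSegment]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"label", "start", "end"}
    if required - set(df.columns):
        raise FormatError("TM-segment TSV needs columns label/start/end")
    return [
        TMSegment(str(r.label), int(r.start), int(r.end)) for r in df.itertuples()
    ]


def ligand_binding_sites(
    annotation: StructureAnnotation, mode: str = "intersection"
) -> set[int]:
    """Residues within ``cutoff`` A of all poses (intersection, the
    literal reading of "within 5 A of all these poses") or of at least
    one pose (union)."""
    if mode not in ("intersection", "union"):
        raise ValueError(f"unknown mode {mode!r}")
    if not annotation.poses:
        raise FormatError("at least one ligand pose is required")
    if annotation.cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not annotation.residues:
        raise FormatError("empty receptor coordinates")

    selected: set[int] = set()
    for idx, coords in annotation.residues:
        if coords.size == 0:
            raise FormatError(f"residue {idx} has no atoms")
        near = [
            bool(cdist(coords, pose).min() <= annotation.cutoff)
            for pose in annotation.poses
        ]
        if (mode == "intersection" and all(near)) or (
            mode == "union" and any(near)
        ):
            selected.add(idx)
    return selected


def _hypergeom_pmf(k: int, N: int, K: int, n: int) -> Fraction:
    """P[X = k] for X ~ Hypergeom(N, K, n), as an exact rational."""
    if k < max(0, n + K - N) or k > min(n, K):
        return Fraction(0)
    return Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int
) -> tuple[float, float, float]:
    """(odds ratio, two-sided p, one-sided upper p) for table [[a,b],[c,d]].

    The two-sided p sums hypergeometric probabilities not exceeding the
    observed table's probability (exact rational arithmetic, so ties are
    handled without floating-point fuzz); one-sided is the upper tail
    P[X >= a].
    """
    if min(a, b, c, d) < 0:
        raise DomainError("negative cell count")
    N, K, n = a + b + c + d, a + b, a + c
    p_obs = _hypergeom_pmf(a, N, K, n)
    two = Fraction(0)
    upper = Fraction(0)
    for k in range(max(0, n + K - N), min(n, K) + 1):
        pk = _hypergeom_pmf(k, N, K, n)
        if pk <= p_obs:
            two += pk
        if k >= a:
            upper += pk
    odds = (a * d) / (b * c) if b * c else float("inf") if a * d else float("nan")
    return float(odds), float(min(two, Fraction(1))), float(min(upper, Fraction(1)))


def enrichment_test(
    substitution_residues: Iterable[int],
    binding_residues: Iterable[int],
    protein_length: int,
    sidedness: str = "two-sided",
    mode: str = "",
) -> EnrichmentResult:
    """Fisher exact test of substitution-site x ligand-binding-site
    membership over all residues 1..protein_length."""
    subs = set(substitution_residues)
    bind = set(binding_residues)
    for s in subs | bind:
        if not 1 <= s <= protein_length:
            raise DomainError(
                f"residue {s} outside protein of length {protein_length}"
            )
    if sidedness not in ("two-sided", "one-sided"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    a = len(subs & bind)
    b = len(subs - bind)
    c = len(bind - subs)
    d = protein_length - a - b - c
    odds, p_two, p_one = fisher_exact_2x2(a, b, c, d)
    return EnrichmentResult(
        table=((a, b), (c, d)),
        odds_ratio=odds,
        p_value=p_two if sidedness == "two-sided" else p_one,
        sidedness=sidedness,
        p_two_sided=p_two,
        p_one_sided=p_one,
        mode=mode,
    )


def map_substitutions_to_segments(
    substitutions: DiagnosticSiteSet | Iterable[int],
    tm_segments: Sequence[TMSegment],
) -> pd.DataFrame:
    """Label each substitution residue with its topology segment.

    Residues outside all declared segments are labeled "unannotated",
    never dropped.
    """
    if isinstance(substitutions, DiagnosticSiteSet):
        residues = sorted({s.codon for s in substitutions if s.is_nonsynonymous})
    else:
        residues = sorted(set(substitutions))
    rows = []
    for r in residues:
        label = "unannotated"
        for seg in tm_segments:
            if seg.start <= r <= seg.end:
                label = seg.label
                break
        rows.append({"residue": r, "segment": label})
    return pd.DataFrame(rows, columns=["residue", "segment"])
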