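"""Divergence percentages, percent identity, and Nei-Gojobori dN/dS.

The two allele clades of each receptor gene differ by roughly 1% of CDS
columns (e.g. 11 variant sites over a 942-nt CDS = 1.17%).  This module
computes those percentages, a pairwise similarity matrix with its mean,
counting-based NG86 synonymous/nonsynonymous statistics with the
Jukes-Cantor correction, per-branch substitution counts on a Fitch
reconstruction, and a Fisher-exact screen for branches with an excess of
nonsynonymous change.

NG86 conventions: expected site counts treat a single-base change to a
stop codon as nonsynonymous (so N + S = 3 x compared codons exactly);
observed differences in multi-hit codons are averaged over all minimal
mutational pathways that avoid stop-codon intermediates (all pathways,
when every one is blocked).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from math import log as _ln
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diagnostics import AncestralReconstruction, GENETIC_CODE, classify_substitution
from .errors import DomainError
from .model import (
    BranchSubstitutionCounts,
    CodonSubstitutionStats,
    MISSING,
    PairwiseDivergence,
    codon_index,
)


def _missing_mask(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    return (arr == b"N") | (arr == b"-")


def pairwise_divergence(
    seq_a: str,
    seq_b: str,
    seq_a_id: str = "a",
    seq_b_id: str = "b",
    denominator: str = "pairwise",
) -> PairwiseDivergence:
    """Variant columns between two aligned sequences, as a percentage.

    ``denominator="pairwise"`` (default) excludes columns missing in
    either sequence from numerator and denominator;
    ``denominator="full_cds"`` divides by the full alignment length
    instead (the "variant sites / CDS length" convention).
    """
    if len(seq_a) != len(seq_b):
        raise DomainError("sequences differ in length")
    if denominator not in ("pairwise", "full_cds"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    ok = ~(_missing_mask(seq_a) | _missing_mask(seq_b))
    variant = int(((a != b) & ok).sum())
    compared = int(ok.sum()) if denominator == "pairwise" else len(seq_a)
    if compared == 0:
        raise DomainError("zero compared sites; divergence undefined")
    return PairwiseDivergence(
        seq_a_id=seq_a_id,
        seq_b_id=seq_b_id,
        compared_sites=compared,
        variant_sites=variant,
        denominator_mode=denominator,
    )


def similarity_matrix(
    seqs: Sequence[str], ids: Sequence[str] | None = None
) -> tuple[pd.DataFrame, float]:
    """Percent identity per pair over mutually non-missing columns,
    plus the mean over off-diagonal entries."""
    n = len(seqs)
    if ids is None:
        ids = [f"seq{i + 1}" for i in range(n)]
    arr = np.array([list(s.upper()) for s in seqs])
    ok = ~np.isin(arr, list(MISSING))
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            compared = int(both.sum())
            if compared == 0:
                raise DomainError(
                    f"no mutually non-missing columns between {ids[i]} and {ids[j]}"
                )
            ident = 100.0 * ((arr[i] == arr[j]) & both).sum() / compared
            mat[i, j] = mat[j, i] = ident
    mean = float(mat[~np.eye(n, dtype=bool)].mean()) if n > 1 else 100.0
    return pd.DataFrame(mat, index=list(ids), columns=list(ids)), mean


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) expected site counts of a sense codon;
    changes to stop codons count as nonsynonymous, so the pair sums to 3."""
    aa = GENETIC_CODE[codon]
    syn = 0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if GENETIC_CODE[alt] == aa:  # stop translates to "*", never equal
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def _step_type(c1: str, c2: str) -> int:
    """0 = synonymous step, 1 = nonsynonymous step."""
    return 0 if GENETIC_CODE[c1] == GENETIC_CODE[c2] else 1


@lru_cache(maxsize=None)
def _codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, averaged over minimal
    mutational pathways through sense codons."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    if len(diff) == 1:
        s = 1 - _step_type(codon_a, codon_b)
        return float(s), float(1 - s)

    pathways = []
    for order in permutations(diff):
        cur = codon_a
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if GENETIC_CODE[nxt] == "*" and nxt != codon_b:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        pathways.append((blocked, steps))
    usable = [steps for blocked, steps in pathways if not blocked]
    if not usable:  # every pathway passes a stop; fall back to all
        usable = [steps for _, steps in pathways]
    sd = nd = 0.0
    for steps in usable:
        for c1, c2 in steps:
            if _step_type(c1, c2) == 0:
                sd += 1
            else:
                nd += 1
    return sd / len(usable), nd / len(usable)


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * _ln(1 - 4.0 * p / 3.0)


def ng86_dnds(cds_a: str, cds_b: str) -> CodonSubstitutionStats:
    """Nei-Gojobori (1986) counting statistics for an aligned CDS pair.

    Codons containing missing data in either sequence are skipped.
    Internal stop codons in compared codons are a domain error.  ``omega``
    is None (undefined) when dS is zero or a Jukes-Cantor correction is
    out of range.
    """
    if len(cds_a) != len(cds_b) or len(cds_a) % 3:
        raise DomainError("aligned CDS pair required, equal lengths, full codons")
    cds_a, cds_b = cds_a.upper(), cds_b.upper()

    S1 = N1 = S2 = N2 = Sd = Nd = 0.0
    compared = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if set(ca) & MISSING or set(cb) & MISSING:
            continue
        for c in (ca, cb):
            if c not in GENETIC_CODE:
                raise DomainError(f"invalid codon {c!r}")
            if GENETIC_CODE[c] == "*":
                raise DomainError(f"internal stop codon {c!r} at column {i + 1}")
        compared += 1
        s, n = _codon_sites(ca)
        S1 += s
        N1 += n
        s, n = _codon_sites(cb)
        S2 += s
        N2 += n
        sd, nd = _codon_differences(ca, cb)
        Sd += sd
        Nd += nd

    if compared == 0:
        raise DomainError("no comparable codons")
    S_sites = (S1 + S2) / 2.0
    N_sites = (N1 + N2) / 2.0
    pS = Sd / S_sites if S_sites > 0 else 0.0
    pN = Nd / N_sites if N_sites > 0 else 0.0
    dS = _jc_correct(pS)
    dN = _jc_correct(pN)
    notes = []
    if dS is None or dN is None:
        notes.append("jukes-cantor-correction-undefined")
    omega = None
    if dS is not None and dN is not None:
        if dS > 0:
            omega = dN / dS
        else:
            notes.append("omega-undefined-dS-zero")
    return CodonSubstitutionStats(
        compared_codons=compared,
        N_sites=N_sites,
        S_sites=S_sites,
        Nd=Nd,
        Sd=Sd,
        pN=pN,
        pS=pS,
        dN=dN,
        dS=dS,
        omega=omega,
        notes=";".join(notes),
    )


# ---------------------------------------------------------------------------
# branch-wise substitution counts
# ---------------------------------------------------------------------------


def branch_substitutions(
    reconstruction: AncestralReconstruction,
) -> list[BranchSubstitutionCounts]:
    """Per-branch synonymous/nonsynonymous substitution counts from a
    Fitch reconstruction.

    A differing column is flagged ambiguous — counted separately, never
    silently assigned — when either branch endpoint was resolved by the
    blind alphabetical fallback among several equally parsimonious
    states (no outgroup state available to polarize it).  Substitutions
    are classified in the parent codon context.
    """
    out = []
    for parent, child in sorted(reconstruction.branches()):
        p_seq = reconstruction.node_states[parent]
        c_seq = reconstruction.node_states[child]
        res = BranchSubstitutionCounts(
            branch=f"{parent}->{child}", nonsynonymous=0, synonymous=0, ambiguous=0
        )
        for col in range(1, len(p_seq) + 1):
            if p_seq[col - 1] == c_seq[col - 1]:
                continue
            if (
                reconstruction.node_tied[parent][col - 1]
                or reconstruction.node_tied[child][col - 1]
            ):
                res.ambiguous += 1
                res.columns_ambiguous.append(col)
                continue
            cod = codon_index(col)
            start = (cod - 1) * 3
            parent_codon = p_seq[start : start + 3]
            child_codon = (
                parent_codon[: (col - 1) % 3]
                + c_seq[col - 1]
                + parent_codon[(col - 1) % 3 + 1 :]
            )
            try:
                kind = classify_substitution(parent_codon, child_codon)
            except DomainError:
                kind = "nonsynonymous"  # change into/out of a stop context
            if kind == "synonymous":
                res.synonymous += 1
                res.columns_synonymous.append(col)
            else:
                res.nonsynonymous += 1
                res.columns_nonsynonymous.append(col)
        out.append(res)
    return out


@dataclass
class BranchScreenResult:
    branch: str
    nonsynonymous: int
    synonymous: int
    background_nonsynonymous: int
    background_synonymous: int
    p_value: float | None
    elevated: bool
    inconclusive: bool = False


def branch_omega_screen(
    branch_counts: Sequence[BranchSubstitutionCounts],
    background: tuple[int, int] | None = None,
    alpha: float = 0.05,
) -> list[BranchScreenResult]:
    """Fisher-exact contrast of each branch's (nonsyn, syn) counts
    against the pooled background (all other branches by default).

    This is a counting-based screen for branches with an excess of
    nonsynonymous substitutions; it makes no claim of equivalence to a
    codon-model likelihood-ratio test.
    """
    totals_n = sum(b.nonsynonymous for b in branch_counts)
    totals_s = sum(b.synonymous for b in branch_counts)
    out = []
    for b in branch_counts:
        if background is None:
            bg_n, bg_s = totals_n - b.nonsynonymous, totals_s - b.synonymous
        else:
            bg_n, bg_s = background
        if bg_n + bg_s == 0:
            out.append(
                BranchScreenResult(
                    b.branch, b.nonsynonymous, b.synonymous, bg_n, bg_s,
                    p_value=None, elevated=False, inconclusive=True,
                )
            )
            continue
        _, p = stats.fisher_exact(
            [[b.nonsynonymous, b.synonymous], [bg_n, bg_s]], alternative="two-sided"
        )
        fg_tot = b.nonsynonymous + b.synonymous
        fg_rate = b.nonsynonymous / fg_tot if fg_tot else 0.0
        bg_rate = bg_n / (bg_n + bg_s)
        out.append(
            BranchScreenResult(
                b.branch, b.nonsynonymous, b.synonymous, bg_n, bg_s,
                p_value=float(p),
                elevated=bool(p < alpha and fg_rate > bg_rate),
            )
        )
    return out
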