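"""Clade-diagnostic site discovery and ancestral reconstruction.

The two highly divergent allele clades of a gene are separated by a
small set of fixed (or near-fixed) nucleotide differences.  This module
finds those columns, annotates each as synonymous or nonsynonymous in
the Clade-I codon background, reconstructs ancestral sequences on a
rooted tree by Fitch parsimony, and rebuilds the hypothetical "derived
allele" by replacing the ancestral nucleotide at each polymorphic site
with its alternative.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Phylo
from Bio.Data import CodonTable

from .errors import AmbiguityError, DomainError, FormatError
from .io import _IUPAC_EXPAND, consensus_sequence
from .model import (
    AlignedHaplotype,
    BASES,
    DiagnosticSite,
    DiagnosticSiteSet,
    MISSING,
    codon_index,
)

log = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid, with stop codons mapped to "*"
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
GENETIC_CODE.update({c: "*" for c in _TABLE.stop_codons})
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)


def translate_codon(codon: str) -> str:
    codon = codon.upper()
    if codon not in GENETIC_CODE:
        raise DomainError(f"not an unambiguous codon: {codon!r}")
    return GENETIC_CODE[codon]


def classify_substitution(codon_from: str, codon_to: str) -> str:
    """Label a codon change as synonymous / nonsynonymous / multi-hit.

    Single-site changes are labeled by translation equality; codon pairs
    differing at more than one position are labeled ``"multi-hit"`` (the
    divergence module resolves them by pathway averaging).  Stop codons
    are outside the domain.
    """
    codon_from, codon_to = codon_from.upper(), codon_to.upper()
    for c in (codon_from, codon_to):
        if c not in GENETIC_CODE:
            raise DomainError(f"not an unambiguous codon: {c!r}")
        if GENETIC_CODE[c] == "*":
            raise DomainError(f"stop codon {c!r} outside classification domain")
    ndiff = sum(a != b for a, b in zip(codon_from, codon_to))
    if ndiff == 0:
        raise ValueError("codons are identical")
    if ndiff > 1:
        return "multi-hit"
    return (
        "synonymous"
        if GENETIC_CODE[codon_from] == GENETIC_CODE[codon_to]
        else "nonsynonymous"
    )


def _sequences_of(haps: Sequence[AlignedHaplotype] | Sequence[str]) -> list[str]:
    return [h.sequence if isinstance(h, AlignedHaplotype) else str(h) for h in haps]


def _major_allele(column: Iterable[str]) -> tuple[str | None, float, int]:
    """(major base, frequency among non-missing, non-missing count)."""
    counts: dict[str, int] = {}
    for c in column:
        if c not in MISSING:
            counts[c] = counts.get(c, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return None, 0.0, 0
    major = min(counts, key=lambda b: (-counts[b], b))
    return major, counts[major] / total, total


def find_diagnostic_sites(
    cladeI_haps: Sequence[AlignedHaplotype] | Sequence[str],
    cladeII_haps: Sequence[AlignedHaplotype] | Sequence[str],
    fixation_threshold: float = 1.0,
    gene: str = "gene",
    clade_labels: tuple[str, str] = ("Clade I", "Clade II"),
) -> DiagnosticSiteSet:
    """Columns where the clades' major alleles differ and are (near-)fixed.

    A column is diagnostic when each clade's major-allele frequency
    (among non-missing haplotypes of that clade) is at least
    ``fixation_threshold`` and the two major alleles differ.  Sites are
    annotated synonymous/nonsynonymous against the Clade-I consensus
    codon; two diagnostic sites sharing a codon are both labeled from
    the joint codon change, with a warning.
    """
    seqs_I = _sequences_of(cladeI_haps)
    seqs_II = _sequences_of(cladeII_haps)
    if not seqs_I or not seqs_II:
        raise FormatError("each clade needs at least one haplotype")
    lengths = {len(s) for s in seqs_I + seqs_II}
    if len(lengths) != 1:
        raise FormatError("clades are not on a common alignment")
    if not (0.5 < fixation_threshold <= 1.0):
        raise ValueError("fixation_threshold must be in (0.5, 1.0]")
    (length,) = lengths

    raw_sites: list[tuple[int, str, str]] = []
    for col in range(1, length + 1):
        major_I, freq_I, n_I = _major_allele(s[col - 1] for s in seqs_I)
        major_II, freq_II, n_II = _major_allele(s[col - 1] for s in seqs_II)
        if n_I == 0 or n_II == 0:
            log.info("column %d all-missing in one clade; skipped", col)
            continue
        if (
            major_I != major_II
            and freq_I >= fixation_threshold
            and freq_II >= fixation_threshold
        ):
            raw_sites.append((col, major_I, major_II))

    consensus_I = consensus_sequence(seqs_I)
    by_codon: dict[int, list[tuple[int, str, str]]] = {}
    for col, a, d in raw_sites:
        by_codon.setdefault(codon_index(col), []).append((col, a, d))

    sites: list[DiagnosticSite] = []
    for cod, members in sorted(by_codon.items()):
        start = (cod - 1) * 3
        codon_anc = list(consensus_I[start : start + 3])
        codon_der = list(codon_anc)
        for col, a, d in members:
            codon_anc[(col - 1) % 3] = a
            codon_der[(col - 1) % 3] = d
        anc, der = "".join(codon_anc), "".join(codon_der)
        if len(members) > 1:
            log.warning(
                "diagnostic sites %s share codon %d; labeled from the joint change",
                [m[0] for m in members],
                cod,
            )
        try:
            aa_from, aa_to = translate_codon(anc), translate_codon(der)
            nonsyn = aa_from != aa_to
        except DomainError:
            # missing data inside the codon context
            aa_from = aa_to = "?"
            nonsyn = False
        for col, a, d in members:
            sites.append(
                DiagnosticSite(
                    column=col,
                    state_ancestral=a,
                    state_derived=d,
                    codon=cod,
                    aa_ancestral=aa_from,
                    aa_derived=aa_to,
                    is_nonsynonymous=nonsyn,
                )
            )
    sites.sort(key=lambda s: s.column)
    return DiagnosticSiteSet(gene=gene, sites=sites, clade_labels=clade_labels)


# ---------------------------------------------------------------------------
# Fitch parsimony ancestral reconstruction
# ---------------------------------------------------------------------------

_FULL_SET = frozenset(BASES)


@dataclass
class AncestralReconstruction:
    """Fitch state sets and resolved states for every node and column."""

    tree: object  # Bio.Phylo tree with all nodes named
    root: str
    parent_of: dict[str, str]
    children_of: dict[str, tuple[str, ...]]
    node_sets: dict[str, list[frozenset[str]]]
    node_states: dict[str, str]  # resolved sequence per node
    #: per node, per column: True when the resolution fell back to the
    #: alphabetical rule among >1 equally parsimonious states
    node_tied: dict[str, list[bool]]
    column_scores: list[int]
    leaves: frozenset[str] = field(default_factory=frozenset)

    @property
    def score(self) -> int:
        return sum(self.column_scores)

    def branches(self) -> list[tuple[str, str]]:
        return [(p, c) for c, p in self.parent_of.items()]


def _load_tree(tree) -> object:
    if isinstance(tree, (str, Path)):
        p = Path(tree)
        if p.exists():
            return Phylo.read(str(p), "newick")
        return Phylo.read(_io.StringIO(str(tree)), "newick")
    return tree


def fitch_ancestral(
    tree,
    sequences: Mapping[str, str] | Sequence[AlignedHaplotype],
    outgroup: str | None = None,
) -> AncestralReconstruction:
    """Fitch small-parsimony reconstruction on a rooted binary tree.

    ``sequences`` maps leaf names to aligned sequences (``N``/``-`` are
    treated as fully ambiguous).  Ties are resolved preferring the state
    observed in the designated ``outgroup`` leaf, otherwise the
    alphabetically first state; children inherit the parent's resolved
    state whenever it lies in their own state set, which realizes a
    most-parsimonious labeling.
    """
    if not isinstance(sequences, Mapping):
        sequences = {h.name: h.sequence for h in sequences}
    tree = _load_tree(tree)

    clades = list(tree.find_clades(order="preorder"))
    counter = 0
    for cl in clades:
        if not cl.name:
            cl.name = f"node{counter}"
            counter += 1
    names = [cl.name for cl in clades]
    if len(set(names)) != len(names):
        raise FormatError("tree node names are not unique")

    children_of: dict[str, tuple[str, ...]] = {}
    parent_of: dict[str, str] = {}
    leaves: list[str] = []
    for cl in clades:
        kids = tuple(k.name for k in cl.clades)
        children_of[cl.name] = kids
        for k in kids:
            parent_of[k] = cl.name
        if not kids:
            leaves.append(cl.name)
        elif len(kids) != 2:
            raise FormatError(
                f"node {cl.name!r} has {len(kids)} children; tree must be binary"
            )
    missing_leaves = [lf for lf in leaves if lf not in sequences]
    if missing_leaves:
        raise FormatError(f"leaves without sequences: {missing_leaves}")
    if outgroup is not None and outgroup not in leaves:
        raise FormatError(f"outgroup {outgroup!r} is not a leaf")

    lengths = {len(sequences[lf]) for lf in leaves}
    if len(lengths) != 1:
        raise FormatError("leaf sequences differ in length")
    (n_col,) = lengths

    postorder = [cl.name for cl in clades][::-1]
    node_sets: dict[str, list[frozenset[str]]] = {n: [] for n in children_of}
    node_res: dict[str, list[str]] = {n: [] for n in children_of}
    node_tied: dict[str, list[bool]] = {n: [] for n in children_of}
    column_scores: list[int] = []
    root = clades[0].name

    for col in range(n_col):
        score = 0
        sets: dict[str, frozenset[str]] = {}
        for node in postorder:
            kids = children_of[node]
            if not kids:
                c = sequences[node][col].upper()
                if c in MISSING:
                    sets[node] = _FULL_SET
                elif c in BASES:
                    sets[node] = frozenset((c,))
                else:
                    raise FormatError(
                        f"leaf {node!r} column {col + 1}: invalid state {c!r}"
                    )
            else:
                a, b = sets[kids[0]], sets[kids[1]]
                inter = a & b
                if inter:
                    sets[node] = inter
                else:
                    sets[node] = a | b
                    score += 1
        column_scores.append(score)

        out_state = None
        if outgroup is not None:
            c = sequences[outgroup][col].upper()
            if c in BASES:
                out_state = c

        def tie_break(state_set: frozenset[str]) -> tuple[str, bool]:
            if out_state is not None and out_state in state_set:
                return out_state, False
            return min(state_set), len(state_set) > 1

        for node in (cl.name for cl in clades):  # preorder
            s = sets[node]
            parent = parent_of.get(node)
            if parent is None:
                resolved, tied = tie_break(s)
            else:
                p_state = node_res[parent][col]
                if p_state in s:
                    resolved, tied = p_state, False
                else:
                    resolved, tied = tie_break(s)
            node_res[node].append(resolved)
            node_tied[node].append(tied)
            node_sets[node].append(s)

    return AncestralReconstruction(
        tree=tree,
        root=root,
        parent_of=parent_of,
        children_of=children_of,
        node_sets=node_sets,
        node_states={n: "".join(v) for n, v in node_res.items()},
        node_tied=node_tied,
        column_scores=column_scores,
        leaves=frozenset(leaves),
    )


def reconstruct_derived_allele(
    ancestral_seq: str,
    polymorphic_columns: Sequence[int],
    observed_alleles: Mapping[int, Iterable[str]] | Sequence[str],
) -> str:
    """Replace the ancestral base at each polymorphic column by its
    alternative, yielding the hypothetical derived allele.

    ``observed_alleles`` is either a mapping column -> observed bases or
    a collection of aligned sequences (IUPAC heterozygote codes are
    expanded).  Each listed column must be biallelic with the ancestral
    state among the observed alleles.
    """
    ancestral_seq = ancestral_seq.upper()
    if isinstance(observed_alleles, Mapping):
        per_column = {
            int(col): {str(b).upper() for b in bases}
            for col, bases in observed_alleles.items()
        }
    else:
        per_column = {}
        for col in polymorphic_columns:
            bases: set[str] = set()
            for seq in observed_alleles:
                code = seq[col - 1].upper()
                bases |= {b for b in _IUPAC_EXPAND.get(code, frozenset()) if b in BASES}
            per_column[col] = bases

    derived = list(ancestral_seq)
    for col in polymorphic_columns:
        if not (1 <= col <= len(ancestral_seq)):
            raise DomainError(f"column {col} outside sequence of length {len(ancestral_seq)}")
        alleles = {b for b in per_column.get(col, set()) if b in BASES}
        if len(alleles) != 2:
            raise AmbiguityError(
                f"column {col}: expected 2 alleles, observed {sorted(alleles)}"
            )
        anc = ancestral_seq[col - 1]
        if anc not in alleles:
            raise DomainError(
                f"column {col}: ancestral state {anc!r} not among observed "
                f"alleles {sorted(alleles)}"
            )
        (alt,) = alleles - {anc}
        derived[col - 1] = alt
    return "".join(derived)
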