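"""Diagnostic-site discovery, codon classification, Fitch parsimony."""

import itertools

import pytest
from Bio.Seq import Seq

from allelepaint.diagnostics import (
    SENSE_CODONS,
    classify_substitution,
    find_diagnostic_sites,
    fitch_ancestral,
    reconstruct_derived_allele,
)
from allelepaint.errors import AmbiguityError, DomainError, FormatError


def _seq_with(base_seq, changes):
    s = list(base_seq)
    for col, base in changes.items():
        s[col - 1] = base
    return "".join(s)


class TestFindDiagnosticSites:
    BASE = "ATGGCTGCAGCTGGTACTTTGGCAGCTACTGGTGCAACTTTGGCAGCTACT"[:48]

    def test_monomorphic_clades_exact_columns(self):
        clade_I = [self.BASE] * 3
        clade_II = [_seq_with(self.BASE, {10: "C", 25: "A"})] * 3
        sites = find_diagnostic_sites(clade_I, clade_II)
        assert sites.columns == [10, 25]
        for s in sites:
            assert s.state_ancestral != s.state_derived

    def test_threshold_semantics(self):
        """A 60/40 polymorphic column is excluded at threshold 1.0 and
        included at 0.6."""
        alt = _seq_with(self.BASE, {10: "C"})
        clade_I = [self.BASE] * 3 + [alt] * 2  # 60% base, 40% alt
        clade_II = [alt] * 3
        assert find_diagnostic_sites(clade_I, clade_II, 1.0).columns == []
        assert find_diagnostic_sites(clade_I, clade_II, 0.6).columns == [10]

    def test_symmetry_under_clade_swap(self):
        clade_I = [self.BASE] * 2
        clade_II = [_seq_with(self.BASE, {4: "C", 17: "A"})] * 2
        fwd = find_diagnostic_sites(clade_I, clade_II)
        rev = find_diagnostic_sites(clade_II, clade_I)
        assert fwd.columns == rev.columns
        for a, b in zip(fwd, rev):
            assert (a.state_ancestral, a.state_derived) == (
                b.state_derived,
                b.state_ancestral,
            )

    def test_empty_clade_rejected(self):
        with pytest.raises(FormatError):
            find_diagnostic_sites([], [self.BASE])

    def test_simulated_panel_recovery(self, default_panel):
        """All 11 planted sites recovered, no extras, labels correct."""
        cfg, (haps, _, _, truth) = default_panel
        clade_I = [
            h for h in haps if truth.haplotype_labels[h.name][0] == "cladeI"
        ]
        clade_II = [
            h for h in haps if truth.haplotype_labels[h.name][0] == "cladeII"
        ]
        sites = find_diagnostic_sites(clade_I, clade_II)
        assert sites.columns == [c for c, _, _, _ in truth.diagnostic_columns]
        for site, (_, anc, der, ns) in zip(sites, truth.diagnostic_columns):
            assert site.state_ancestral == anc
            assert site.state_derived == der
            assert site.is_nonsynonymous == ns

    def test_nonsyn_flag_matches_translation(self):
        base = "TTTGGT"  # Phe-Gly
        clade_I = [base] * 2
        clade_II = ["TTCGAT"] * 2  # TTT->TTC syn, GGT->GAT nonsyn
        sites = find_diagnostic_sites(clade_I, clade_II)
        assert [s.is_nonsynonymous for s in sites] == [False, True]
        assert sites.sites[1].aa_ancestral == "G"
        assert sites.sites[1].aa_derived == "D"


class TestClassifySubstitution:
    def test_synonymous(self):
        assert classify_substitution("TTT", "TTC") == "synonymous"

    def test_nonsynonymous(self):
        assert classify_substitution("TTT", "TTA") == "nonsynonymous"

    def test_multi_hit(self):
        assert classify_substitution("TTT", "TAC") == "multi-hit"

    def test_stop_rejected(self):
        with pytest.raises(DomainError):
            classify_substitution("TAA", "TTT")

    def test_exhaustive_single_site_scan(self):
        """All 61 x 9 single-site sense-codon pairs agree with a
        translation-table oracle (biopython Seq.translate)."""
        checked = 0
        for codon in SENSE_CODONS:
            for pos in range(3):
                for b in "ACGT":
                    if b == codon[pos]:
                        continue
                    alt = codon[:pos] + b + codon[pos + 1 :]
                    if str(Seq(alt).translate()) == "*":
                        continue
                    expected = (
                        "synonymous"
                        if Seq(codon).translate() == Seq(alt).translate()
                        else "nonsynonymous"
                    )
                    assert classify_substitution(codon, alt) == expected
                    checked += 1
        assert checked > 400


def _brute_force_parsimony(children_of, root, leaves, leaf_states):
    """Exhaustive minimum over all internal-node labelings."""
    internals = [n for n in children_of if children_of[n]]
    best = None
    for labels in itertools.product("ACGT", repeat=len(internals)):
        assign = dict(zip(internals, labels))
        assign.update(leaf_states)
        changes = sum(
            assign[p] != assign[c]
            for p in children_of
            for c in children_of[p]
        )
        best = changes if best is None else min(best, changes)
    return best


class TestFitch:
    def test_uniform_column_zero_changes(self):
        rec = fitch_ancestral("((l1,l2),(l3,l4));", {f"l{i}": "A" for i in range(1, 5)})
        assert rec.score == 0
        assert rec.node_states[rec.root] == "A"

    def test_hand_run_two_cherries(self):
        rec = fitch_ancestral(
            "((l1,l2),(l3,l4));",
            {"l1": "A", "l2": "A", "l3": "C", "l4": "C"},
        )
        assert rec.score == 1
        assert rec.node_sets[rec.root][0] == frozenset("AC")
        # alphabetical tie rule at the root
        assert rec.node_states[rec.root] == "A"

    def test_outgroup_tie_rule(self):
        rec = fitch_ancestral(
            "((l1,l2),(l3,l4));",
            {"l1": "A", "l2": "A", "l3": "C", "l4": "C"},
            outgroup="l3",
        )
        assert rec.node_states[rec.root] == "C"

    def test_missing_leaf_state_is_free(self):
        rec = fitch_ancestral(
            "((l1,l2),(l3,l4));",
            {"l1": "A", "l2": "N", "l3": "A", "l4": "A"},
        )
        assert rec.score == 0
        assert rec.node_states["l2"] == "A"

    def test_leaf_without_sequence_rejected(self):
        with pytest.raises(FormatError, match="without sequences"):
            fitch_ancestral("((l1,l2),(l3,l4));", {"l1": "A"})

    def test_nonbinary_rejected(self):
        with pytest.raises(FormatError, match="binary"):
            fitch_ancestral("(l1,l2,l3);", {f"l{i}": "A" for i in range(1, 4)})

    @pytest.mark.parametrize("newick", ["((a,b),(c,d));", "(((a,b),c),d);"])
    def test_score_equals_brute_force_all_labelings(self, newick):
        """Fitch score equals the exhaustive minimum over internal
        labelings for every leaf labeling of 4-leaf trees (4^4 each)."""
        for states in itertools.product("ACGT", repeat=4):
            seqs = dict(zip("abcd", states))
            rec = fitch_ancestral(newick, seqs)
            brute = _brute_force_parsimony(
                rec.children_of, rec.root, rec.leaves, seqs
            )
            assert rec.score == brute

    def test_score_invariant_under_leaf_reordering(self):
        seqs = {"a": "ACGT", "b": "AGGT", "c": "ACTT", "d": "TCGA"}
        s1 = fitch_ancestral("((a,b),(c,d));", seqs).score
        s2 = fitch_ancestral("((d,c),(b,a));", seqs).score
        assert s1 == s2

    def test_resolved_states_are_members_and_leaves_observed(self):
        seqs = {"a": "ACG", "b": "ATG", "c": "GCG", "d": "ACC"}
        rec = fitch_ancestral("((a,b),(c,d));", seqs)
        for node, sets in rec.node_sets.items():
            for col, s in enumerate(sets):
                assert rec.node_states[node][col] in s
        for leaf, seq in seqs.items():
            assert rec.node_states[leaf] == seq


class TestReconstructDerivedAllele:
    def test_single_site(self):
        assert reconstruct_derived_allele("CCC", [2], {2: "CT"}) == "CTC"

    def test_empty_columns_identity(self):
        assert reconstruct_derived_allele("CCC", [], {}) == "CCC"

    def test_from_observed_sequences(self):
        obs = ["CCC", "CTC", "CYC"]  # IUPAC het expands to C/T
        assert reconstruct_derived_allele("CCC", [2], obs) == "CTC"

    def test_more_than_two_alleles_rejected(self):
        with pytest.raises(AmbiguityError):
            reconstruct_derived_allele("CCC", [2], {2: "CTA"})

    def test_ancestral_absent_rejected(self):
        with pytest.raises(DomainError):
            reconstruct_derived_allele("CCC", [2], {2: "TA"})

    def test_simulation_truth_recovery(self, mosaic_panel):
        """Subtracting the ancestral allele at the 13 polymorphic sites
        recovers the simulator's derived CDS exactly."""
        cfg, (haps, _, _, truth) = mosaic_panel
        cols = [c for c, _, _, _ in truth.diagnostic_columns]
        derived = reconstruct_derived_allele(
            truth.ancestral_cds, cols, [h.sequence for h in haps]
        )
        assert derived == truth.derived_cds
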