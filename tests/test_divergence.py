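"""Divergence percentages, NG86 dN/dS vs an independent pathway oracle,
branch substitution counts."""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from allelepaint.diagnostics import (
    SENSE_CODONS,
    find_diagnostic_sites,
    fitch_ancestral,
)
from allelepaint.divergence import (
    branch_omega_screen,
    branch_substitutions,
    ng86_dnds,
    pairwise_divergence,
    similarity_matrix,
)
from allelepaint.errors import DomainError
from allelepaint.simulate import SimulationConfig, simulate_divergent_alleles

# ---------------------------------------------------------------------------
# independent NG86 oracle (translation via Bio.Seq, explicit enumeration)
# ---------------------------------------------------------------------------


def _aa(codon):
    return str(Seq(codon).translate())


def oracle_codon_sites(codon):
    syn = 0.0
    for pos, base in itertools.product(range(3), "ACGT"):
        if base == codon[pos]:
            continue
        mutant = codon[:pos] + base + codon[pos + 1 :]
        if _aa(mutant) != "*" and _aa(mutant) == _aa(codon):
            syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def oracle_codon_diffs(c1, c2):
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    all_paths, clean_paths = [], []
    for order in itertools.permutations(positions):
        path = [c1]
        for pos in order:
            path.append(path[-1][:pos] + c2[pos] + path[-1][pos + 1 :])
        all_paths.append(path)
        if all(_aa(c) != "*" for c in path[1:-1]):
            clean_paths.append(path)
    paths = clean_paths or all_paths
    sd = nd = 0.0
    for path in paths:
        for x, y in zip(path, path[1:]):
            if _aa(x) == _aa(y):
                sd += 1
            else:
                nd += 1
    return sd / len(paths), nd / len(paths)


def oracle_ng86(cds_a, cds_b):
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        sa, na = oracle_codon_sites(ca)
        sb, nb = oracle_codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = oracle_codon_diffs(ca, cb)
        Sd += sd
        Nd += nd
    pS, pN = Sd / S, Nd / N
    jc = lambda p: None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)
    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "pS": pS, "pN": pN,
            "dS": jc(pS), "dN": jc(pN)}


def random_sense_cds_pair(rng, n_codons, n_mut):
    """A sense-codon CDS and a mutated copy with no internal stops."""
    while True:
        codons = [SENSE_CODONS[i] for i in rng.integers(0, 61, n_codons)]
        b = list("".join(codons))
        for pos in rng.choice(n_codons * 3, size=n_mut, replace=False):
            b[pos] = "ACGT"[rng.integers(0, 4)]
        cds_b = "".join(b)
        if all(
            _aa(cds_b[i : i + 3]) != "*" for i in range(0, len(cds_b), 3)
        ):
            return "".join(codons), cds_b


class TestPairwiseDivergence:
    def test_identical_is_zero(self):
        assert pairwise_divergence("ACGT" * 3, "ACGT" * 3).percent == 0.0

    def test_printed_definition_v1r2(self):
        """11 variant sites over a 942-column CDS -> 1.17% at 2 d.p."""
        a = "A" * 942
        b = "C" * 11 + "A" * 931
        assert round(pairwise_divergence(a, b).percent, 2) == 1.17

    def test_thirteen_sites(self):
        a = "A" * 942
        b = "C" * 13 + "A" * 929
        assert round(pairwise_divergence(a, b).percent, 2) == 1.38

    def test_missing_excluded_pairwise_but_not_full(self):
        a = "ACGTNA"
        b = "ACGTAC"
        d = pairwise_divergence(a, b)
        assert (d.variant_sites, d.compared_sites) == (1, 5)
        d_full = pairwise_divergence(a, b, denominator="full_cds")
        assert d_full.compared_sites == 6

    def test_all_missing_rejected(self):
        with pytest.raises(DomainError):
            pairwise_divergence("NNN", "ACG")

    def test_complement_of_identity(self, rng):
        """identity% + divergence% = 100 on gap-free pairs."""
        a, b = random_sense_cds_pair(rng, 40, 9)
        mat, _ = similarity_matrix([a, b])
        assert mat.iloc[0, 1] + pairwise_divergence(a, b).percent == pytest.approx(100)


class TestSimilarityMatrix:
    def test_symmetric_with_unit_diagonal(self, rng):
        seqs = [random_sense_cds_pair(rng, 20, 4)[1] for _ in range(4)]
        mat, _ = similarity_matrix(seqs)
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 100.0)

    def test_mean_equals_brute_force(self, rng):
        for _ in range(5):
            seqs = [random_sense_cds_pair(rng, 15, 5)[1] for _ in range(5)]
            mat, mean = similarity_matrix(seqs)
            pairs = [
                mat.iloc[i, j]
                for i in range(5)
                for j in range(5)
                if i != j
            ]
            assert mean == pytest.approx(sum(pairs) / len(pairs), abs=1e-12)


class TestNG86:
    def test_identical_pair(self):
        stats = ng86_dnds("TTTGGT", "TTTGGT")
        assert stats.Nd == stats.Sd == 0
        assert stats.omega is None

    def test_single_codon_hand_values(self):
        """TTT vs TTA: S = (1/3 + 2/3)/2, one nonsynonymous difference."""
        stats = ng86_dnds("TTT", "TTA")
        assert stats.S_sites == pytest.approx(0.5, abs=1e-15)
        assert stats.N_sites == pytest.approx(2.5, abs=1e-15)
        assert (stats.Sd, stats.Nd) == (0.0, 1.0)
        assert stats.pN == pytest.approx(0.4, abs=1e-15)
        assert stats.dN == pytest.approx(-0.75 * math.log(1 - 1.6 / 3), abs=1e-15)
        assert stats.dS == 0.0 and stats.omega is None
        assert "omega-undefined" in stats.notes

    def test_sites_sum_to_three_per_codon(self, rng):
        a, b = random_sense_cds_pair(rng, 30, 10)
        stats = ng86_dnds(a, b)
        assert stats.N_sites + stats.S_sites == pytest.approx(3 * 30, abs=1e-9)

    def test_symmetry(self, rng):
        a, b = random_sense_cds_pair(rng, 25, 8)
        x, y = ng86_dnds(a, b), ng86_dnds(b, a)
        assert (x.Nd, x.Sd, x.N_sites, x.S_sites) == (y.Nd, y.Sd, y.N_sites, y.S_sites)

    def test_internal_stop_rejected(self):
        with pytest.raises(DomainError, match="stop"):
            ng86_dnds("TAATTT", "TAATTT")

    def test_missing_codons_skipped(self):
        stats = ng86_dnds("TTTNNN", "TTCAAA")
        assert stats.compared_codons == 1
        assert stats.Sd == 1.0

    def test_matches_pathway_oracle_random_pairs(self, rng):
        """Equality with the independent enumeration oracle to 1e-12
        on random 50-codon pairs (multi-hit codons included)."""
        for _ in range(200):
            a, b = random_sense_cds_pair(rng, 50, int(rng.integers(0, 25)))
            stats = ng86_dnds(a, b)
            exp = oracle_ng86(a, b)
            assert stats.S_sites == pytest.approx(exp["S"], abs=1e-12)
            assert stats.N_sites == pytest.approx(exp["N"], abs=1e-12)
            assert stats.Sd == pytest.approx(exp["Sd"], abs=1e-12)
            assert stats.Nd == pytest.approx(exp["Nd"], abs=1e-12)
            if exp["dN"] is not None:
                assert stats.dN == pytest.approx(exp["dN"], abs=1e-12)

    def test_matches_biopython_on_single_hit_pairs(self, rng):
        """Cross-check against Bio.Align NG86 on pairs where every codon
        differs at <= 1 position (the conventions coincide there)."""
        from Bio import Align
        from Bio.Align.analysis import calculate_dn_ds
        from Bio.Seq import Seq as BSeq

        for _ in range(20):
            while True:
                a, b = random_sense_cds_pair(rng, 30, 6)
                if all(
                    sum(x != y for x, y in zip(a[i : i + 3], b[i : i + 3])) <= 1
                    for i in range(0, len(a), 3)
                ):
                    break
            aln = Align.Alignment([BSeq(a), BSeq(b)])
            dn, ds = calculate_dn_ds(aln, method="NG86")
            stats = ng86_dnds(a, b)
            if stats.dN is not None and dn >= 0:
                assert stats.dN == pytest.approx(dn, abs=1e-9)
            if stats.dS is not None and ds >= 0:
                assert stats.dS == pytest.approx(ds, abs=1e-9)

    def test_planted_all_nonsynonymous_has_zero_ds(self):
        cfg = SimulationConfig(n_codons=100, n_diagnostic=8, seed=21)
        anc, der, _ = simulate_divergent_alleles(cfg)
        stats = ng86_dnds(anc, der)
        assert stats.Sd == 0.0 and stats.dS == 0.0
        assert stats.omega is None and "omega-undefined-dS-zero" in stats.notes


TREE = "(o,((i1,i2),(d1,d2)));"


class TestBranchSubstitutions:
    def _panel(self, seed=31):
        cfg = SimulationConfig(
            n_codons=40, n_diagnostic=6, nonsyn_fraction=0.5, seed=seed
        )
        return simulate_divergent_alleles(cfg)

    def test_no_change_zero_counts(self):
        rec = fitch_ancestral(TREE, {n: "ACGACG" for n in ("o", "i1", "i2", "d1", "d2")})
        counts = branch_substitutions(rec)
        assert all(b.nonsynonymous == b.synonymous == b.ambiguous == 0 for b in counts)

    def test_planted_branch_counts_equal_truth(self):
        """All planted differences land on the clade-divergence branch
        with the planted syn/nonsyn split."""
        anc, der, truth = self._panel()
        rec = fitch_ancestral(
            TREE, {"o": anc, "i1": anc, "i2": anc, "d1": der, "d2": der}
        )
        counts = {b.branch: b for b in branch_substitutions(rec)}
        (derived_branch,) = [
            b for b in counts.values() if b.nonsynonymous + b.synonymous > 0
        ]
        n_truth = sum(ns for _, _, _, ns in truth)
        assert derived_branch.nonsynonymous == n_truth
        assert derived_branch.synonymous == len(truth) - n_truth
        assert derived_branch.ambiguous == 0
        assert sorted(
            derived_branch.columns_nonsynonymous + derived_branch.columns_synonymous
        ) == [c for c, _, _, _ in truth]

    def test_consistency_with_diagnostic_sites(self):
        """Branch counts on the divergence branch equal the fixed
        difference counts from diagnostic-site discovery."""
        anc, der, _ = self._panel(seed=32)
        sites = find_diagnostic_sites([anc] * 2, [der] * 2)
        rec = fitch_ancestral(
            TREE, {"o": anc, "i1": anc, "i2": anc, "d1": der, "d2": der}
        )
        total_n = sum(b.nonsynonymous for b in branch_substitutions(rec))
        total_s = sum(b.synonymous for b in branch_substitutions(rec))
        assert total_n == sum(s.is_nonsynonymous for s in sites)
        assert total_s == sum(not s.is_nonsynonymous for s in sites)

    def test_rootward_tie_flagged_ambiguous_without_outgroup(self):
        """With no outgroup the root state is a blind tie, so the
        differing columns are flagged ambiguous, not assigned."""
        anc, der, truth = self._panel(seed=33)
        rec = fitch_ancestral(
            "((i1,i2),(d1,d2));", {"i1": anc, "i2": anc, "d1": der, "d2": der}
        )
        counts = branch_substitutions(rec)
        assert sum(b.ambiguous for b in counts) == len(truth)


class TestBranchScreen:
    @staticmethod
    def _hyper_two_sided(a, b, c, d):
        """Direct hypergeometric enumeration (math.comb floats)."""
        N, K, n = a + b + c + d, a + b, a + c
        pmf = lambda k: (
            math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
        )
        p_obs = pmf(a)
        return sum(
            pmf(k)
            for k in range(max(0, n + K - N), min(n, K) + 1)
            if pmf(k) <= p_obs * (1 + 1e-9)
        )

    def test_no_signal_p_is_one(self):
        from allelepaint.model import BranchSubstitutionCounts

        counts = [
            BranchSubstitutionCounts("x", 2, 4, 0),
            BranchSubstitutionCounts("y", 4, 8, 0),
        ]
        res = branch_omega_screen(counts)
        assert res[0].p_value == pytest.approx(1.0)
        assert not res[0].elevated

    def test_p_matches_hypergeometric_oracle(self):
        from allelepaint.model import BranchSubstitutionCounts

        counts = [BranchSubstitutionCounts("fg", 10, 0, 0)]
        res = branch_omega_screen(counts, background=(5, 50))
        assert res[0].p_value == pytest.approx(
            self._hyper_two_sided(10, 0, 5, 50), rel=1e-7
        )
        assert res[0].elevated

    def test_label_swap_symmetry(self):
        from allelepaint.model import BranchSubstitutionCounts

        a = branch_omega_screen(
            [BranchSubstitutionCounts("fg", 7, 3, 0)], background=(4, 9)
        )[0]
        b = branch_omega_screen(
            [BranchSubstitutionCounts("fg", 4, 9, 0)], background=(7, 3)
        )[0]
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_zero_background_inconclusive(self):
        from allelepaint.model import BranchSubstitutionCounts

        res = branch_omega_screen(
            [BranchSubstitutionCounts("fg", 3, 1, 0)], background=(0, 0)
        )
        assert res[0].inconclusive and res[0].p_value is None
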