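"""GY94 generator, codon frequencies, trees, and the pruning likelihood."""

import numpy as np
import pytest
from scipy.linalg import expm

from mytilomito.codon_alignment import from_strings
from mytilomito.codon_model import (
    codon_frequencies,
    edge_classes,
    gy94_rate_matrix,
    log_likelihood,
    parse_tree,
    spectral,
)
from mytilomito.genetic_code import get_genetic_code
from mytilomito.synthetic import SimAlignmentSpec, simulate_codon_alignment

CODE = get_genetic_code(5)
N = CODE.n_sense


def uniform_pi():
    return np.full(N, 1.0 / N)


class TestGeneticCode:
    def test_invertebrate_mito_has_62_sense_codons(self):
        assert N == 62
        assert CODE.stop_codons == {"TAA", "TAG"}

    def test_full_initiator_set(self):
        assert CODE.start_codons == {"TTG", "ATT", "ATC", "ATA", "ATG", "GTG"}

    def test_translation_is_literal_for_gtg(self):
        assert CODE.translate("GTGCCTCAATTA") == "VPQL"


class TestRateMatrix:
    def test_omega_zero_kills_nonsynonymous_rates(self):
        Q = gy94_rate_matrix(2.0, 0.0, uniform_pi(), scale=False)
        sense = CODE.sense_codons
        for i, a in enumerate(sense):
            for j, b in enumerate(sense):
                if i != j and CODE.forward[a] != CODE.forward[b]:
                    assert Q[i, j] == 0

    def test_neutral_symmetric_case_equal_rates(self):
        Q = gy94_rate_matrix(1.0, 1.0, uniform_pi(), scale=False)
        off = Q[Q > 0]
        assert np.allclose(off, off[0])

    def test_rows_sum_to_zero_and_unit_rate(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(N))
        Q = gy94_rate_matrix(3.7, 0.3, pi)
        assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_spectral_transition_matches_expm(self):
        rng = np.random.default_rng(1)
        pi = rng.dirichlet(np.ones(N))
        Q = gy94_rate_matrix(2.5, 0.4, pi)
        P_spec = spectral(Q, pi).transition(0.37)
        assert np.allclose(P_spec, expm(Q * 0.37), atol=1e-10)
        assert np.allclose(P_spec.sum(axis=1), 1.0)

    def test_transition_at_zero_is_identity(self):
        Q = gy94_rate_matrix(2.0, 0.5, uniform_pi())
        assert np.allclose(spectral(Q, uniform_pi()).transition(0.0), np.eye(N))


class TestCodonFrequencies:
    def test_uniform(self):
        aln = from_strings({"a": "ATGGCT", "b": "ATGGCA"})
        assert np.allclose(codon_frequencies(aln, "uniform"), 1.0 / N)

    @pytest.mark.parametrize("model", ["F1x4", "F3x4"])
    def test_normalized_and_positive(self, model):
        aln = from_strings({"a": "ATGGCTAAACCC", "b": "ATGGCAAAGCCA"})
        pi = codon_frequencies(aln, model)
        assert pi.sum() == pytest.approx(1.0)
        assert (pi > 0).all()


class TestTrees:
    def test_parse_and_leaf_order(self):
        t = parse_tree("((A:0.1,B:0.2):0.05,C:0.3);")
        assert set(t.taxa) == {"A", "B", "C"}
        assert len(t.edges()) == 4

    def test_edge_classes_inherited_by_clades(self):
        t = parse_tree("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        classes = edge_classes(t, {"A": "deep", "B": "deep"})
        sets = t.leaf_sets()
        for v in t.edges():
            expected = "deep" if sets[v] <= {"A", "B"} else "background"
            assert classes[v] == expected

    def test_duplicate_taxa_rejected(self):
        import pytest as _pytest

        from mytilomito.codon_model import CodonModelError

        with _pytest.raises(CodonModelError):
            parse_tree("(A:0.1,A:0.2);")


class TestLikelihood:
    def test_zero_branch_lengths_identical_sequences(self):
        aln = from_strings({"A": "ATGGCTCAT", "B": "ATGGCTCAT"})
        tree = parse_tree("(A:0.0,B:0.0);")
        pi = uniform_pi()
        idx = CODE.codon_index()
        expected = sum(np.log(pi[idx[c]]) for c in ("ATG", "GCT", "CAT"))
        assert log_likelihood(aln, tree, 2.0, 0.5, pi) == pytest.approx(expected)

    def test_two_taxon_matches_bruteforce_summation(self):
        """Pruning equals exhaustive root-state summation to 1e-8."""
        spec = SimAlignmentSpec(newick="(A:0.3,B:0.5);", n_codons=50, omega=0.4,
                                kappa=3.0, seed=3)
        aln, truth = simulate_codon_alignment(spec)
        pi = uniform_pi()
        Q = gy94_rate_matrix(3.0, 0.4, pi)
        P1, P2 = expm(Q * 0.3), expm(Q * 0.5)
        a = aln.codons[aln.taxa.index("A")]
        b = aln.codons[aln.taxa.index("B")]
        oracle = sum(
            np.log((pi * P1[:, x] * P2[:, y]).sum()) for x, y in zip(a, b)
        )
        ll = log_likelihood(aln, truth["tree"], 3.0, 0.4, pi)
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_invariant_under_rerooting(self):
        """Reversible model: the likelihood does not depend on the rooting."""
        import dendropy

        spec = SimAlignmentSpec(
            newick="((A:0.2,B:0.1):0.05,(C:0.3,D:0.15):0.1,E:0.25);",
            n_codons=40, omega=0.3, seed=5,
        )
        aln, truth = simulate_codon_alignment(spec)
        pi = uniform_pi()
        base = log_likelihood(aln, truth["tree"], 2.0, 0.3, pi)
        dt = dendropy.Tree.get(data=spec.newick, schema="newick")
        node = dt.find_node_with_taxon_label("C").parent_node
        dt.reroot_at_edge(node.edge, update_bipartitions=True,
                          length1=0.02, length2=0.08)
        rerooted = parse_tree(dt.as_string(schema="newick").replace("[&R] ", ""))
        assert log_likelihood(aln, rerooted, 2.0, 0.3, pi) == pytest.approx(
            base, abs=1e-6
        )

    def test_mismatched_taxa_rejected(self):
        from mytilomito.codon_model import CodonModelError
        from mytilomito.selection import FitConfig, fit_one_ratio

        aln = from_strings({"A": "ATGGCT", "B": "ATGGCA"})
        tree = parse_tree("(A:0.1,X:0.1);")
        with pytest.raises(CodonModelError, match="X"):
            fit_one_ratio(aln, tree, FitConfig(n_starts=1))


class TestAlignmentValidation:
    def test_internal_stop_named(self):
        with pytest.raises(ValueError, match="taxon 'B' at codon 2"):
            from_strings({"A": "ATGGCTCAT", "B": "ATGTAACAT"})

    def test_length_not_multiple_of_three(self):
        with pytest.raises(ValueError, match="divisible"):
            from_strings({"A": "ATGGC"})

    def test_unequal_lengths(self):
        with pytest.raises(ValueError, match="unequal"):
            from_strings({"A": "ATGGCT", "B": "ATG"})

    def test_round_trip_through_fasta(self, tmp_path):
        from mytilomito.codon_alignment import (
            load_codon_alignment,
            write_codon_alignment,
        )

        spec = SimAlignmentSpec(newick="(A:0.2,B:0.2);", n_codons=30, seed=8)
        aln, _ = simulate_codon_alignment(spec)
        write_codon_alignment(aln, tmp_path / "a.fasta")
        back = load_codon_alignment(tmp_path / "a.fasta")
        assert back.taxa == aln.taxa
        assert (back.codons == aln.codons).all()

    def test_gap_columns_dropped_before_fitting(self):
        aln = from_strings({"A": "ATG---CAT", "B": "ATGGCTCAT"})
        clean, dropped = aln.drop_incomplete_columns()
        assert dropped == 1 and clean.n_codons == 2
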