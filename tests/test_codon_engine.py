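"""Rate matrix, transition probabilities and pruning likelihood."""

import itertools

import dendropy
import numpy as np
import pytest

import piscisel as ps
from piscisel.codon_engine import (
    CODON_INDEX,
    SENSE_CODONS,
    SpectralPropagator,
    TreeLikelihood,
    build_class_matrices,
)
from piscisel.sequence_io import CodonAlignment


class TestFrequencies:
    def test_equal_scheme(self):
        aln = CodonAlignment(["x"], [["ATG"]])
        pi = ps.estimate_frequencies(aln, "equal")
        assert np.allclose(pi, 1.0 / 61)

    def test_f3x4_uniform_composition_gives_equal(self):
        # all 4 bases equally frequent at every codon position
        rows = [["TTT", "CCC", "AAA", "GGG"], ["CCC", "AAA", "GGG", "TTT"]]
        aln = CodonAlignment(["x", "y"], rows)
        pi = ps.estimate_frequencies(aln, "F3x4")
        assert np.allclose(pi, 1.0 / 61, atol=1e-12)

    def test_f3x4_matches_hand_product(self):
        # 2-codon alignment: position freqs computed by hand
        aln = CodonAlignment(["x"], [["ATG", "ATT"]])
        pi = ps.estimate_frequencies(aln, "F3x4")
        # pos1: A=1; pos2: T=1; pos3: G=.5, T=.5 -> only ATG and ATT possible
        expected = {CODON_INDEX["ATG"]: 0.5, CODON_INDEX["ATT"]: 0.5}
        for i in range(61):
            assert pi[i] == pytest.approx(expected.get(i, 0.0), abs=1e-12)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_f1x4_matches_hand_product(self):
        aln = CodonAlignment(["x"], [["ATG", "ATT"]])
        pi = ps.estimate_frequencies(aln, "F1x4")
        f = {"A": 2 / 6, "T": 3 / 6, "G": 1 / 6, "C": 0.0}
        raw = np.array(
            [f[c[0]] * f[c[1]] * f[c[2]] for c in SENSE_CODONS]
        )
        assert np.allclose(pi, raw / raw.sum(), atol=1e-12)


class TestRateMatrix:
    def test_rows_sum_to_zero(self, equal_pi):
        q = ps.gy94_rate_matrix(3.1, 0.4, equal_pi)
        assert np.abs(q.sum(axis=1)).max() < 1e-12

    def test_unit_symmetric_case_all_single_step_rates_equal(self, equal_pi):
        q = ps.gy94_rate_matrix(1.0, 1.0, equal_pi)
        off = q[(q != 0) & ~np.eye(61, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_detailed_balance(self):
        rng = np.random.default_rng(5)
        pi = rng.dirichlet(np.ones(61))
        q = ps.gy94_rate_matrix(2.5, 0.3, pi)
        flux = pi[:, None] * q
        for _ in range(100):
            i, j = rng.integers(0, 61, 2)
            assert flux[i, j] == pytest.approx(flux[j, i], abs=1e-14)

    def test_unit_expected_rate(self):
        rng = np.random.default_rng(6)
        pi = rng.dirichlet(np.ones(61))
        q = ps.gy94_rate_matrix(2.0, 0.5, pi)
        assert -(pi * np.diag(q)).sum() == pytest.approx(1.0, rel=1e-12)

    def test_negative_parameters_rejected(self, equal_pi):
        with pytest.raises(ValueError):
            ps.gy94_rate_matrix(-1.0, 0.5, equal_pi)


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self, equal_pi):
        q = ps.gy94_rate_matrix(2.0, 0.5, equal_pi)
        assert np.allclose(ps.transition_probabilities(q, 0.0, equal_pi),
                           np.eye(61), atol=1e-12)

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0, 10.0])
    def test_rows_sum_to_one(self, t, equal_pi):
        q = ps.gy94_rate_matrix(2.0, 0.5, equal_pi)
        p = ps.transition_probabilities(q, t, equal_pi)
        assert np.abs(p.sum(axis=1) - 1).max() < 1e-10
        assert p.min() >= 0 and p.max() <= 1

    def test_matches_truncated_series_at_small_t(self, equal_pi):
        q = ps.gy94_rate_matrix(2.0, 0.5, equal_pi)
        t = 0.05
        series = np.eye(61) + t * q + (t * q) @ (t * q) / 2
        p = ps.transition_probabilities(q, t, equal_pi)
        assert np.abs(p - series).max() < 1e-4

    def test_negative_time_rejected(self, equal_pi):
        q = ps.gy94_rate_matrix(2.0, 0.5, equal_pi)
        with pytest.raises(ValueError):
            ps.transition_probabilities(q, -0.1, equal_pi)

    def test_expm_fallback_agrees_with_spectral_form(self):
        rng = np.random.default_rng(8)
        pi = rng.dirichlet(np.ones(61))
        q = ps.gy94_rate_matrix(2.0, 0.5, pi)
        a = ps.transition_probabilities(q, 0.3, pi)
        b = ps.transition_probabilities(q, 0.3)  # scipy expm
        assert np.abs(a - b).max() < 1e-10


def _brute_force_loglik(aln, tree, q, pi):
    """Independent oracle: sum over all internal-node state assignments."""
    prop = SpectralPropagator(q, pi)
    P = {i: prop(tree.edge_length[i]) for i in range(tree.n_nodes)
         if tree.parent[i] >= 0}
    internals = [i for i in range(tree.n_nodes) if tree.children.get(i)]
    root = int(np.flatnonzero(tree.parent < 0)[0])
    total_lnl = 0.0
    for s in range(aln.n_codons):
        col = {i: CODON_INDEX[aln.columns[i][s]] for i in range(aln.n_taxa)}
        total = 0.0
        for states in itertools.product(range(61), repeat=len(internals)):
            st = dict(zip(internals, states))
            st.update(col)
            p = pi[st[root]]
            for i in range(tree.n_nodes):
                if tree.parent[i] >= 0:
                    p *= P[i][st[tree.parent[i]], st[i]]
            total += p
        total_lnl += np.log(total)
    return total_lnl


class TestPruning:
    def test_zero_distance_two_leaves_gives_pi(self):
        tree = ps.read_newick_string("(a:0.0,b:0.0);")
        rng = np.random.default_rng(2)
        pi = rng.dirichlet(np.ones(61))
        codon = SENSE_CODONS[13]
        aln = CodonAlignment(["a", "b"], [[codon], [codon]])
        lnl = ps.site_log_likelihood(aln, tree, 2.0, pi, [0.5], [1.0], site=0)
        assert lnl == pytest.approx(np.log(pi[13]), abs=1e-10)

    @pytest.mark.parametrize("seed,n_taxa,n_cols", [
        (0, 4, 1), (1, 4, 2), (2, 5, 1), (3, 5, 3), (4, 3, 2),
    ])
    def test_matches_brute_force_enumeration(self, seed, n_taxa, n_cols):
        from conftest import random_tree_newick

        rng = np.random.default_rng(seed)
        names = [chr(ord("a") + i) for i in range(n_taxa)]
        tree = ps.read_newick_string(random_tree_newick(names, rng))
        pi = rng.dirichlet(np.ones(61))
        mats = build_class_matrices(2.0, [0.4], [1.0], pi)
        cols = rng.choice(61, size=(n_taxa, n_cols))
        aln = CodonAlignment(
            tree.leaf_names,
            [[SENSE_CODONS[c] for c in cols[i]] for i in range(n_taxa)],
        )
        tl = TreeLikelihood(aln, tree)
        lnl = tl.log_likelihood(mats, [1.0], pi)
        oracle = _brute_force_loglik(aln, tree, mats[0], pi)
        assert lnl == pytest.approx(oracle, abs=1e-10)

    def test_mixture_column_is_weighted_sum_of_class_likelihoods(self):
        tree = ps.read_newick_string("((a:0.1,b:0.2):0.1,(c:0.3,d:0.1):0.2);")
        rng = np.random.default_rng(9)
        pi = rng.dirichlet(np.ones(61))
        aln = CodonAlignment(
            ["a", "b", "c", "d"],
            [[SENSE_CODONS[c]] for c in rng.choice(61, 4)],
        )
        weights = [0.3, 0.7]
        omegas = [0.1, 2.0]
        mats = build_class_matrices(2.0, omegas, weights, pi)
        tl = TreeLikelihood(aln, tree)
        mix = tl.log_likelihood(mats, weights, pi)
        per_class = [
            np.exp(tl.log_likelihood([m], [1.0], pi)) for m in mats
        ]
        assert mix == pytest.approx(
            np.log(weights[0] * per_class[0] + weights[1] * per_class[1]),
            abs=1e-10,
        )

    def test_gap_codons_are_missing_data(self):
        # a leaf observed as "---" carries no information: the likelihood
        # must not depend on the length of its branch
        tree = ps.read_newick_string("((a:0.1,b:0.2):0.1,(c:0.3,d:0.1):0.2);")
        pi = np.full(61, 1 / 61)
        mats = build_class_matrices(2.0, [0.5], [1.0], pi)
        gapped = CodonAlignment(
            ["a", "b", "c", "d"], [["ATG"], ["ATG"], ["AAA"], ["---"]]
        )
        tl = TreeLikelihood(gapped, tree)
        lnl_gap = tl.log_likelihood(mats, [1.0], pi)
        d_node = tree.leaf_names.index("d")
        el = tree.edge_length[tree.edge_nodes()].copy()
        el[tree.edge_nodes().index(d_node)] += 7.0
        assert tl.log_likelihood(mats, [1.0], pi, el) == pytest.approx(
            lnl_gap, abs=1e-12
        )

    def test_all_gap_column_is_an_error(self):
        tree = ps.read_newick_string("(a:0.1,b:0.2);")
        aln = CodonAlignment(["a", "b"], [["---"], ["---"]])
        pi = np.full(61, 1 / 61)
        tl = TreeLikelihood(aln, tree)
        mats = build_class_matrices(2.0, [0.5], [1.0], pi)
        lnl = tl.site_log_likelihoods(mats, [1.0], pi)
        assert lnl[0] == pytest.approx(0.0)  # no data -> likelihood 1


class TestLikelihoodInvariances:
    def test_invariant_to_rerooting(self):
        from conftest import random_tree_newick

        rng = np.random.default_rng(14)
        names = list("abcdef")
        dt = dendropy.Tree.get(
            data=random_tree_newick(names, rng, 0.05, 0.5),
            schema="newick", preserve_underscores=True,
        )
        pi = rng.dirichlet(np.ones(61))
        cols = rng.choice(61, size=(6, 3))
        mats = build_class_matrices(2.0, [0.3, 1.5], [0.6, 0.4], pi)

        def lnl_of(dtree):
            tree = ps.PhyloTree.from_dendropy(dtree)
            aln = CodonAlignment(
                tree.leaf_names,
                [[SENSE_CODONS[c] for c in cols[names.index(n)]]
                 for n in tree.leaf_names],
            )
            return TreeLikelihood(aln, tree).log_likelihood(
                mats, [0.6, 0.4], pi
            )

        base = lnl_of(dt)
        for k in [1, 3]:
            alt = dt.clone(depth=1)
            edge = [e for e in alt.preorder_edge_iter()
                    if e.length is not None][k]
            alt.reroot_at_edge(edge, update_bipartitions=False,
                               length1=edge.length / 2,
                               length2=edge.length / 2)
            assert lnl_of(alt) == pytest.approx(base, abs=1e-8)

    def test_infinite_branches_decouple_leaves(self):
        # at t = 50 every leaf is at equilibrium: likelihood ~ prod pi_leaf
        tree = ps.read_newick_string("((a:50,b:50):50,(c:50,d:50):50);")
        rng = np.random.default_rng(21)
        pi = rng.dirichlet(np.ones(61) * 5)
        codons = rng.choice(61, 4)
        aln = CodonAlignment(
            ["a", "b", "c", "d"], [[SENSE_CODONS[c]] for c in codons]
        )
        mats = build_class_matrices(2.0, [0.5], [1.0], pi)
        lnl = TreeLikelihood(aln, tree).log_likelihood(mats, [1.0], pi)
        assert lnl == pytest.approx(float(np.log(pi[codons]).sum()), abs=1e-6)
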