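"""Rate estimation: branch-length recovery, expected-count mapping
against the event-resolved simulation oracle, and focal path sums."""

import numpy as np
import pandas as pd
import pytest

from gbgcscan import codons as cd, estimate as est, phylo, simulate as sim

TWO_TAXON = "(A:0.1,B:0.1)R;"


def _fit(alignment, newick, **kw):
    return est.fit_branch_lengths(alignment, newick, min_sequences=2, **kw)


class TestFitBranchLengths:
    def test_identical_sequences_give_zero_lengths(self):
        aln = {s: "ATGGCTAAACAT" * 40
               for s in ("Homo_sapiens", "Mus_musculus", "Rattus_norvegicus",
                         "Psammomys_obesus", "Meriones_unguiculatus")}
        fit = est.fit_branch_lengths(aln, phylo.CORE_TREE_NEWICK)
        assert np.all(fit.branch_lengths == 0.0)

    def test_two_taxon_divergence_recovered(self, params, rng):
        tree = phylo.index_tree(phylo.read_tree(TWO_TAXON))
        gene = sim.simulate_gene(tree, params, 2000, rng=rng)
        fit = _fit(gene.alignment, TWO_TAXON)
        assert fit.branch_lengths.sum() == pytest.approx(0.2, rel=0.15)

    def test_likelihood_not_worse_than_initialization(self, params, rng):
        tree = phylo.index_tree(phylo.read_tree(TWO_TAXON))
        gene = sim.simulate_gene(tree, params, 400, rng=rng)
        fit = _fit(gene.alignment, TWO_TAXON)
        engine = fit.engine
        engine.set_model(2.0, 0.2)
        init = est._init_branch_lengths(engine)
        assert fit.loglik >= engine.loglik(init) - 1e-9

    def test_gradient_matches_finite_differences(self, params, rng):
        tree = phylo.index_tree(phylo.read_tree(phylo.CORE_TREE_NEWICK))
        gene = sim.simulate_gene(tree, params, 200, rng=rng)
        engine = est._Engine(tree, gene.alignment)
        engine.set_model(3.0, 0.15)
        b = np.zeros(tree.n_nodes)
        for v in tree.branch_nodes:
            b[v] = 0.07
        lnl, grad = engine.loglik_and_grad(b)
        for v in tree.branch_nodes:
            b2 = b.copy()
            b2[v] += 1e-6
            fd = (engine.loglik(b2) - lnl) / 1e-6
            assert grad[v] == pytest.approx(fd, rel=1e-3, abs=1e-4)

    def test_too_few_sequences_raises(self):
        with pytest.raises(est.FitError):
            est.fit_branch_lengths(
                {"Mus_musculus": "ATG", "Rattus_norvegicus": "ATG"},
                phylo.CORE_TREE_NEWICK,
            )


class TestMapSubstitutions:
    def test_identical_sequences_give_zero_rates(self):
        aln = {s: "ATGGCTAAACAT" * 40
               for s in ("Homo_sapiens", "Mus_musculus", "Psammomys_obesus")}
        fit = est.fit_branch_lengths(aln, phylo.CORE_TREE_NEWICK)
        branch = est.map_substitutions(fit)
        assert np.all(branch.values == 0.0)

    def test_single_synonymous_ws_change(self, params, rng):
        """One third-position A->G Lys codon change among 500 codons maps
        to dS_WS + dS_SW (direction split by the posterior), all other
        categories zero."""
        zero_tree = phylo.index_tree(phylo.read_tree("(A:0,B:0)R;"))
        gene = sim.simulate_gene(zero_tree, params, 500, rng=rng)
        a = gene.alignment["A"]
        pos = 0
        while a[pos : pos + 3] != "AAA":
            pos += 3
        b = a[: pos + 2] + "G" + a[pos + 3 :]
        fit = _fit({"A": a, "B": b}, TWO_TAXON)
        counts = est.map_substitutions(fit).attrs["counts"].sum(axis=0)
        assert counts["dS_WS"] + counts["dS_SW"] == pytest.approx(1.0, rel=0.05)
        others = counts.drop(["dS_WS", "dS_SW"])
        assert others.abs().max() < 1e-3

    def test_category_counts_sum_to_total_substitutions(self, params, rng):
        """The eight categories partition the expected substitutions: the
        sum of the per-branch category counts equals the expected total
        substitution count computed from the full rate matrix."""
        tree = phylo.index_tree(phylo.read_tree(phylo.CORE_TREE_NEWICK))
        gene = sim.simulate_gene(tree, params, 300, rng=rng)
        fit = est.fit_branch_lengths(gene.alignment, phylo.CORE_TREE_NEWICK)
        engine = fit.engine
        engine.set_model(fit.kappa, fit.omega)
        counts, _ = engine.expected_counts(fit.branch_lengths)
        # independent total per branch: one pass with the full
        # off-diagonal rate matrix as the single "category"
        cat = cd.category_matrix()
        pmats = {v: engine.transition_matrix(fit.branch_lengths[v])
                 for v in tree.branch_nodes}
        D, logS, msg, f_raw = engine._forward(fit.branch_lengths, pmats)
        G, logG, _, _ = engine._backward(D, logS, msg, pmats)
        s_root = logS[tree.root]
        q_all = np.where(cat >= 0, engine.q, 0.0)
        a_all = engine.vr @ q_all @ engine.vl
        for v in tree.branch_nodes:
            j = engine._integral_weights(fit.branch_lengths[v])
            m_all = engine.vl @ (a_all * j) @ engine.vr
            if tree.children[v]:
                inner = ((G[v] @ m_all) * D[v]).sum(axis=1)
            else:
                inner = engine._tip_inner(v, G[v], m_all)
            coef = engine.counts * np.exp(logG[v] + logS[v] - s_root) / f_raw
            total = float(coef @ inner)
            assert counts[v].sum() == pytest.approx(total, abs=1e-9)
        # and the gene-level total tracks the simulator truth
        total_est = est.map_substitutions(fit).attrs["counts"].values.sum()
        total_true = gene.total_counts().sum()
        assert total_est == pytest.approx(total_true, rel=0.25)

    def test_ws_bias_monotonicity(self, params, rng):
        """Simulating with a higher weak-to-strong bias increases the
        estimated dS_WS (mean over replicates)."""
        tree = phylo.index_tree(phylo.read_tree(TWO_TAXON))
        means = []
        for bias in (1.0, 6.0):
            vals = []
            for _ in range(30):
                gene = sim.simulate_gene(
                    tree, params, 200, rng=rng,
                    gerbil_override=(bias, 1.0),
                    gerbil_branch_set=("A", "B"),
                )
                fit = _fit(gene.alignment, TWO_TAXON)
                branch = est.map_substitutions(fit)
                vals.append(branch["dS_WS"].sum())
            means.append(np.mean(vals))
        assert means[1] > means[0]


class TestFocalRates:
    def _toy_rates(self):
        newick = "(H:0.3,((M:0.1,R:0.1)Murinae:0.05,(P:0.1,G:0.1)Gerbillinae:0.05)Muridae:0.05)Root;"
        tree = phylo.index_tree(phylo.read_tree(newick))
        names = [tree.names[v] for v in tree.branch_nodes]
        data = np.zeros((len(names), 8))
        frame = pd.DataFrame(data, index=names, columns=list(cd.CATEGORY_LABELS))
        return tree, frame

    def test_path_sum(self):
        tree, frame = self._toy_rates()
        frame.loc["P", "dS_WS"] = 0.2
        frame.loc["Gerbillinae", "dS_WS"] = 0.3
        frame.loc["Murinae", "dS_WS"] = 0.1
        focal = est.focal_rates(frame, tree, focal_species=("P", "M", "G"))
        assert focal.loc["P", "dS_WS"] == pytest.approx(0.5)
        assert focal.loc["M", "dS_WS"] == pytest.approx(0.1)
        assert focal.loc["G", "dS_WS"] == pytest.approx(0.3)

    def test_absent_species_marked_missing(self):
        tree, frame = self._toy_rates()
        focal = est.focal_rates(frame, tree, focal_species=("P", "Absent"))
        assert np.isnan(focal.loc["Absent"].values).all()

    def test_muridae_located_by_label_or_mrca(self):
        newick = "(H:0.3,((M:0.1,R:0.1):0.05,(P:0.1,G:0.1):0.05)X:0.05)Root;"
        tree = phylo.index_tree(phylo.read_tree(newick))
        node = phylo.muridae_node(tree, focal_species=("M", "R", "P", "G"))
        assert tree.names[node] == "X"
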