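"""Distance models, neighbor joining, concordance and NEXUS export."""

import math
import random

import dendropy
import numpy as np
import pytest

import ctrlregion as cr
from ctrlregion.phylo_concordance import DistanceMatrix
from conftest import make_alignment


def random_additive_tree(n_taxa: int, rng: random.Random):
    """A random binary tree with positive branch lengths and its leaf
    distance matrix (additive by construction)."""
    taxa = [f"T{i}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        taxon_namespace=tns, rng=rng,
    )
    for edge in tree.edges():
        edge.length = rng.uniform(0.05, 1.0)
    pdm = tree.phylogenetic_distance_matrix()
    m = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(tns):
        for j, b in enumerate(tns):
            if i < j:
                m[i, j] = m[j, i] = pdm.distance(a, b)
    return tree, DistanceMatrix(taxa, m)


class TestDistanceMatrix:
    def test_identical_pair_zero_both_models(self):
        aln = make_alignment(["ACGT" * 30, "ACGT" * 30, "AGGT" * 30])
        for model in ("p", "k2p"):
            dm = cr.distance_matrix(aln, model=model)
            assert dm.get("s1", "s2") == 0.0

    def test_k2p_closed_form_single_transition(self):
        # 1 transition (A->G) in 100 comparable sites:
        # d = -ln(1 - 2*0.01)/2 - ln(1)/4
        base = "AC" * 50
        seqs = [base, "G" + base[1:], base]
        dm = cr.distance_matrix(make_alignment(seqs), model="k2p")
        expected = -0.5 * math.log(1 - 2 * 0.01)
        assert dm.get("s1", "s2") == pytest.approx(expected)
        assert cr.distance_matrix(make_alignment(seqs), model="p").get(
            "s1", "s2") == pytest.approx(0.01)

    def test_permutation_equivariance(self, default_panel):
        aln, _ = default_panel
        sub = cr.Alignment(aln.records[:6])
        rev = cr.Alignment(list(reversed(sub.records)))
        d1 = cr.distance_matrix(sub)
        d2 = cr.distance_matrix(rev)
        assert d1.get("SA2", "GP1") == d2.get("SA2", "GP1")

    def test_saturated_pair_flagged_and_finite(self):
        # maximally divergent pair drives the K2P log argument non-positive
        a = "A" * 120
        b = "G" * 120  # all transitions: P = 1
        c = ("AG" * 30) + "A" * 60
        dm = cr.distance_matrix(make_alignment([a, b, c]), model="k2p")
        assert ("s1", "s2") in dm.saturated
        assert np.isfinite(dm.matrix).all()

    def test_pair_without_comparable_sites_rejected(self):
        aln = make_alignment(["AANN", "NNAA", "AAAA"])
        with pytest.raises(ValueError, match="no comparable sites"):
            cr.distance_matrix(aln, policy=cr.GapPolicy.PAIRWISE_DELETION)


class TestNeighborJoining:
    def test_three_taxa_unique_topology(self):
        m = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0.0]])
        t = cr.nj_tree(DistanceMatrix(["a", "b", "c"], m))
        assert {lf.taxon.label for lf in t.leaf_node_iter()} == {"a", "b", "c"}

    def test_four_taxon_additive_recovery_with_branch_lengths(self):
        # ((A:1,B:2):1,(C:3,D:4)) as a distance matrix
        ids = ["A", "B", "C", "D"]
        m = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        est = cr.nj_tree(DistanceMatrix(ids, m))
        true = dendropy.Tree.get(data="((A:1,B:2):1,(C:3,D:4):0);",
                                 schema="newick")
        assert cr.robinson_foulds(true, est) == 0
        # additive input: NJ reproduces the path lengths exactly
        pdm = est.phylogenetic_distance_matrix()
        tax = {t.label: t for t in est.taxon_namespace}
        for i in range(4):
            for j in range(i + 1, 4):
                assert pdm.distance(tax[ids[i]], tax[ids[j]]) == pytest.approx(
                    m[i, j])

    def test_random_additive_topologies_recovered(self):
        rng = random.Random(99)
        for _ in range(10):
            true, dm = random_additive_tree(8, rng)
            assert cr.robinson_foulds(true, cr.nj_tree(dm)) == 0

    def test_agrees_with_independent_nj_oracle(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = random.Random(5)
        for _ in range(5):
            true, dm = random_additive_tree(7, rng)
            mine = cr.nj_tree(dm)
            sk_tree = sk_nj(SkDM(dm.matrix, ids=dm.ids))
            other = dendropy.Tree.get(data=str(sk_tree), schema="newick")
            assert cr.robinson_foulds(mine, other) == 0

    def test_fewer_than_three_taxa_rejected(self):
        m = np.zeros((2, 2))
        with pytest.raises(ValueError):
            cr.nj_tree(DistanceMatrix(["a", "b"], m))

    def test_branch_lengths_never_negative(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = 6
            x = rng.random((n, n))
            m = np.triu(x, 1)
            m = m + m.T
            t = cr.nj_tree(DistanceMatrix([f"t{i}" for i in range(n)], m))
            assert all(
                e.length >= 0 for e in t.edges() if e.length is not None)


class TestConcordance:
    def test_identical_trees_rf_zero_agreement_one(self, bornean_panel):
        aln, truth = bornean_panel
        t = cr.nj_tree(cr.distance_matrix(aln, model="p"))
        labels = {
            r: c for r, c in truth.clade_of.items()
            if c != "OUT" and not r.endswith("5")
        }
        gl = cr.GroupLabeling(labels, set(truth.outgroup_ids))
        rep = cr.concordance([t, t], gl)
        assert rep.rf[(0, 1)] == 0
        assert rep.agreement[(0, 1)] == 1.0

    def test_rf_two_for_single_nni(self):
        # one rearrangement around the (A,B) edge: only that bipartition flips
        t1 = dendropy.Tree.get(data="((A,B),C,(D,E));", schema="newick")
        t2 = dendropy.Tree.get(data="((A,C),B,(D,E));", schema="newick")
        assert cr.robinson_foulds(t1, t2) == 2
        assert cr.robinson_foulds(t1, t1) == 0

    def test_segment_and_remainder_assign_queries_to_generating_clades(self):
        """High-divergence 5-clade panels: both partial alignments place
        every held-out query in its generating clade."""
        from ctrlregion.synthetic_data import CladeSpec

        clades = tuple(
            CladeSpec(lbl, 5, 0.01) for lbl in ("SA", "GP", "DS", "SE", "SN"))
        aln, truth = cr.generate(cr.bornean_panel_config(seed=1, clades=clades))
        spec = cr.get_segment("jalil_arora")
        labels = {
            r: c for r, c in truth.clade_of.items()
            if c != "OUT" and not r.endswith("5")
        }
        gl = cr.GroupLabeling(labels, set(truth.outgroup_ids))
        queries = [
            r for r in aln.ids
            if r not in labels and r not in truth.outgroup_ids
        ]
        for sub in (cr.trim(aln, spec), cr.excise_and_concatenate(aln, spec)):
            tree = cr.root_on_outgroup(
                cr.nj_tree(cr.distance_matrix(sub, model="k2p")),
                truth.outgroup_ids,
            )
            asg = cr.assign_queries(tree, gl, queries)
            assert all(asg[q] == truth.clade_of[q] for q in queries)

    def test_group_monophyly_on_clean_panel(self):
        from ctrlregion.synthetic_data import CladeSpec

        clades = tuple(
            CladeSpec(lbl, 5, 0.01) for lbl in ("SA", "GP", "DS", "SE", "SN"))
        aln, truth = cr.generate(cr.bornean_panel_config(seed=2, clades=clades))
        gl = cr.GroupLabeling(
            {r: c for r, c in truth.clade_of.items() if c != "OUT"},
            set(truth.outgroup_ids),
        )
        t = cr.nj_tree(cr.distance_matrix(aln, model="k2p"))
        rep = cr.concordance([t, t], gl)
        assert all(all(flags) for flags in rep.monophyly.values())

    def test_disjoint_leaf_sets_rejected(self):
        t1 = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        t2 = dendropy.Tree.get(data="((W,X),(Y,Z));", schema="newick")
        with pytest.raises(ValueError):
            cr.robinson_foulds(t1, t2)


class TestNexusExport:
    def test_round_trip_through_dendropy(self, tmp_path):
        aln = make_alignment({"a": "ACGT-N", "b": "ACGTAA", "c 1": "ACTTAA"})
        p = tmp_path / "aln.nex"
        cr.export_nexus(aln, p)
        dm = dendropy.DnaCharacterMatrix.get(path=str(p), schema="nexus")
        assert len(dm) == 3
        back = {t.label: str(dm[t]).upper() for t in dm.taxon_namespace}
        assert back["a"] == "ACGT-N"
        assert back["c 1"] == "ACTTAA"

    def test_dimensions_block(self, tmp_path, toy_aln):
        p = tmp_path / "t.nex"
        cr.export_nexus(toy_aln, p)
        text = p.read_text()
        assert f"NTAX={toy_aln.n_records}" in text
        assert f"NCHAR={toy_aln.n_cols}" in text
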