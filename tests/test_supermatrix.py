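import numpy as np
import pytest

from npclkit.io import SequenceSet, ValidationMatrix
from npclkit.supermatrix import (
    SuperMatrix,
    bootstrap_support,
    concatenate,
    distance_matrix,
    nj_tree,
    split_by_partition,
    summarize_validation,
    tree_splits,
    write_raxml_inputs,
)

from _oracles import random_additive_matrix


def _aln(records):
    return SequenceSet(records=records)


class TestConcatenate:
    def test_column_count_sums_partitions(self):
        loci = [
            (f"n{i}", _aln([("t1", "A" * L), ("t2", "C" * L)]))
            for i, L in enumerate([700, 500, 300])
        ]
        sm = concatenate(loci)
        assert sm.n_columns == 1500
        assert [span for _, span in sm.partitions] == [(0, 700), (700, 1200), (1200, 1500)]

    def test_single_locus_identity(self):
        aln = _aln([("t1", "ACGT"), ("t2", "AGGT")])
        sm = concatenate([("only", aln)])
        assert sm.rows == {"t1": "ACGT", "t2": "AGGT"}

    def test_missing_taxon_padded_with_gaps(self):
        sm = concatenate(
            [
                ("a", _aln([("t1", "AAAA"), ("t2", "CCCC")])),
                ("b", _aln([("t1", "GGGG")])),
            ]
        )
        assert sm.rows["t2"] == "CCCC" + "----"
        assert sm.missing_fraction("t2") == pytest.approx(0.5)

    def test_duplicate_taxon_within_locus_rejected(self):
        with pytest.raises(ValueError):
            concatenate([("a", [("t1", "AAAA"), ("t1", "CCCC")])])

    def test_permuting_locus_order_preserves_character_multisets(self, rng):
        loci = [
            (f"n{i}", _aln([("t1", "".join(rng.choice(list("ACGT"), 30))),
                            ("t2", "".join(rng.choice(list("ACGT"), 30)))]))
            for i in range(4)
        ]
        sm1 = concatenate(loci)
        sm2 = concatenate(loci[::-1])
        for taxon in ("t1", "t2"):
            assert sorted(sm1.rows[taxon]) == sorted(sm2.rows[taxon])

    def test_split_by_partition_recovers_inputs(self, rng):
        loci = []
        for i in range(3):
            recs = [
                (f"t{j}", "".join(rng.choice(list("ACGT"), 20)))
                for j in range(4)
                if (i + j) % 4 != 0  # some taxa miss some loci
            ]
            loci.append((f"n{i}", _aln(recs)))
        back = split_by_partition(concatenate(loci))
        for (lid, orig), (lid2, rec) in zip(loci, back):
            assert lid == lid2
            assert sorted(rec.records) == sorted(orig.records)

    def test_raxml_partition_file(self, tmp_path):
        sm = concatenate(
            [("locA", _aln([("t1", "AAAA"), ("t2", "CCCC")])),
             ("locB", _aln([("t1", "GG"), ("t2", "TT")]))]
        )
        write_raxml_inputs(sm, tmp_path / "sm.phy", tmp_path / "parts.txt")
        assert (tmp_path / "parts.txt").read_text() == "DNA, locA = 1-4\nDNA, locB = 5-6\n"
        assert (tmp_path / "sm.phy").read_text().splitlines()[0] == "2 6"


def _path_lengths(newick, labels):
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        newick = nj_tree(d, ["a", "b", "c"])
        assert np.allclose(_path_lengths(newick, ["a", "b", "c"]), d, atol=1e-9)

    def test_additive_four_taxa_recovers_split_and_lengths(self):
        # tree ((A,B),(C,D)) with tip edges 1 and internal edge 1
        d = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], float
        )
        labels = list("ABCD")
        newick = nj_tree(d, labels)
        assert np.allclose(_path_lengths(newick, labels), d, atol=1e-9)
        assert frozenset("CD") in tree_splits(newick, labels) or frozenset(
            "AB"
        ) in tree_splits(newick, labels)

    def test_ultrametric_four_taxa_exact(self):
        d = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]], float
        )
        labels = list("wxyz")
        assert np.allclose(_path_lengths(nj_tree(d, labels), labels), d, atol=1e-9)

    def test_random_additive_matrices_reproduced_exactly(self, rng):
        for _ in range(6):
            n = int(rng.integers(4, 9))
            d, labels, true_splits = random_additive_matrix(rng, n)
            newick = nj_tree(d, labels)
            assert np.allclose(_path_lengths(newick, labels), d, atol=1e-9)
            assert tree_splits(newick, labels) == true_splits

    def test_matches_dendropy_nj_topology(self, rng):
        import dendropy

        d, labels, _ = random_additive_matrix(rng, 7)
        mine = tree_splits(nj_tree(d, labels), labels)
        csv = "," + ",".join(labels) + "\n" + "\n".join(
            labels[i] + "," + ",".join(str(d[i, j]) for j in range(7)) for i in range(7)
        )
        import io as _io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_io.StringIO(csv), delimiter=","
        )
        theirs_tree = pdm.nj_tree()
        theirs = tree_splits(theirs_tree.as_string(schema="newick").strip(), labels)
        assert mine == theirs

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0, 1], [1, 0]], float), ["a", "b"])
        bad = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError):
            nj_tree(bad, list("abc"))


class TestBootstrapSupport:
    def _two_clade_supermatrix(self, rng):
        # two well-separated clades of 3 taxa each
        anc = rng.choice(list("ACGT"), size=400)
        clade = {}
        for name, div in (("A", 0.0), ("B", 0.35)):
            base = anc.copy()
            hit = rng.random(400) < div
            for j in np.flatnonzero(hit):
                base[j] = rng.choice([b for b in "ACGT" if b != base[j]])
            clade[name] = base
        records = []
        for name in ("A", "B"):
            for k in range(3):
                seq = clade[name].copy()
                hit = rng.random(400) < 0.02
                for j in np.flatnonzero(hit):
                    seq[j] = rng.choice([b for b in "ACGT" if b != seq[j]])
                records.append((f"{name}{k}", "".join(seq)))
        return concatenate([("locus", _aln(records))])

    def test_strong_split_for_separated_clades(self, rng):
        sm = self._two_clade_supermatrix(rng)
        st = bootstrap_support(sm, reps=100, seed=5)
        clade_b = frozenset({"B0", "B1", "B2"})
        assert st.support[clade_b] >= 95.0
        assert clade_b in st.strong_splits()

    def test_deterministic_and_in_range(self, rng):
        sm = self._two_clade_supermatrix(rng)
        s1 = bootstrap_support(sm, reps=50, seed=9)
        s2 = bootstrap_support(sm, reps=50, seed=9)
        assert s1.support == s2.support
        assert all(0.0 <= v <= 100.0 for v in s1.support.values())

    def test_rejects_zero_reps(self, rng):
        sm = self._two_clade_supermatrix(rng)
        with pytest.raises(ValueError):
            bootstrap_support(sm, reps=0)


class TestValidationSummary:
    def _vm(self, cells):
        cells = np.asarray(cells, dtype=np.int8)
        return ValidationMatrix(
            markers=[f"m{i}" for i in range(cells.shape[0])],
            taxa=[(f"s{j}", f"O{j % 2}") for j in range(cells.shape[1])],
            cells=cells,
        )

    def test_marker_at_boundary_retained_and_below_excluded(self):
        # 19/23 = 82.6% retained; 18/23 = 78.3% excluded at threshold 0.80
        row_a = [1] * 19 + [0] * 4
        row_b = [1] * 18 + [0] * 5
        panel = summarize_validation(self._vm([row_a, row_b]))
        assert panel.per_marker_psr["m0"] == pytest.approx(19 / 23)
        assert panel.per_marker_psr["m1"] == pytest.approx(18 / 23)
        assert panel.universal == ["m0"]

    def test_counts_partition_the_cells(self):
        cells = [[1, 0, -1], [1, 1, 0]]
        vm = self._vm(cells)
        c = vm.counts()
        assert c["success"] + c["failure"] + c["not_attempted"] == 6
        panel = summarize_validation(vm)
        assert panel.overall_psr == pytest.approx(3 / 5)

    def test_all_na_marker_excluded_with_warning(self):
        panel = summarize_validation(self._vm([[1, 1, 1], [-1, -1, -1]]))
        assert panel.excluded == ["m1"]
        assert "m1" not in panel.per_marker_psr

    def test_per_order_rates(self):
        cells = [[1, 0, 1, 0]]  # orders O0,O1,O0,O1
        panel = summarize_validation(self._vm(cells))
        assert panel.per_order_psr == {"O0": 1.0, "O1": 0.0}
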