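"""Conditional co-occurrence probabilities, networks and Ward ordering."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from cisscan.classification import LocusResult, STATUS_CIS
from cisscan.cooccurrence import (
    bidirectional_network,
    build_presence_matrix,
    conditional_probability,
    gene_count_scores,
    network_to_graphml,
    ward_column_order,
    write_probability_tsv,
)
from cisscan.io_ingest import HomologyHit

from conftest import make_profile


def locus(mag, roles, fams=(), status=STATUS_CIS):
    return LocusResult(
        mag_id=mag,
        contig_id="c1",
        score=50.0,
        roles_present=frozenset(roles),
        families_hit=frozenset(fams or (f"fam_{r}" for r in roles)),
        status=status,
    )


class TestPresenceMatrix:
    def test_two_locus_example(self):
        loci = [locus("A", {"Cis1"}), locus("B", {"Cis1", "Cis8"})]
        m = build_presence_matrix(loci)
        assert list(m.index) == ["Cis1", "Cis8"]
        assert m.values.tolist() == [[1, 1], [0, 1]]

    def test_excluded_locus_not_a_column(self):
        loci = [locus("A", {"Cis1"}), locus("B", {"Cis1"}, status="excluded_T6SS_like")]
        m = build_presence_matrix(loci)
        assert list(m.columns) == ["A|c1"]

    def test_family_level_splits_roles(self):
        loci = [
            locus("A", {"Cis13"}, fams={"fam13a"}),
            locus("B", {"Cis13"}, fams={"fam13b"}),
        ]
        role_level = build_presence_matrix(loci, level="role")
        fam_level = build_presence_matrix(loci, level="family")
        assert list(role_level.index) == ["Cis13"]
        assert list(fam_level.index) == ["fam13a", "fam13b"]

    def test_zero_cis_loci_errors(self):
        with pytest.raises(ValueError, match="no loci"):
            build_presence_matrix([locus("A", {"Cis1"}, status="below_threshold")])


class TestGeneCounts:
    def make_hit(self, gene, fam, locus_id="m|c"):
        mag, contig = locus_id.split("|")
        return HomologyHit(f"{mag}|{contig}|{gene}", mag, contig, fam, 80, 200, 1e-20, 300)

    def test_hit_counts_per_role(self):
        profile = make_profile({"f2a": ("Cis2", 0.5), "f2b": ("Cis2", 0.25)})
        hits = [self.make_hit(f"g{i}", f) for i, f in enumerate(["f2a", "f2a", "f2b"])]
        counts = gene_count_scores({"m|c": hits}, profile)
        assert counts.loc["Cis2", "m|c"] == 3

    def test_hit_free_locus_is_all_zero_column(self):
        profile = make_profile({"f1": ("Cis1", 0.5)})
        counts = gene_count_scores({"m|c": [self.make_hit("g", "f1")], "n|c": []}, profile)
        assert counts.loc["Cis1", "n|c"] == 0

    def test_retained_tie_increments_two_rows(self):
        # one query gene retained against two tied families counts to both roles
        profile = make_profile({"fA": ("Cis2", 0.5), "fB": ("Cis3", 0.5)})
        hits = [self.make_hit("g1", "fA"), self.make_hit("g1", "fB")]
        counts = gene_count_scores({"m|c": hits}, profile)
        assert counts.loc["Cis2", "m|c"] == 1
        assert counts.loc["Cis3", "m|c"] == 1


class TestConditionalProbability:
    def test_enumeration_example(self):
        # i in {A,B}, j in {B,C} over 3 loci -> P(j|i) = P(i|j) = 0.5
        presence = pd.DataFrame(
            [[1, 1, 0], [0, 1, 1]], index=["i", "j"], columns=["A", "B", "C"]
        )
        result = conditional_probability(presence)
        assert result.probabilities.loc["i", "j"] == 0.5
        assert result.probabilities.loc["j", "i"] == 0.5
        assert result.presence_counts.tolist() == [2, 2]

    def test_self_probability_one_when_present(self):
        presence = pd.DataFrame([[1, 0], [1, 1]], index=["a", "b"], columns=["x", "y"])
        p = conditional_probability(presence).probabilities
        assert p.loc["a", "a"] == 1.0 and p.loc["b", "b"] == 1.0

    def test_absent_gene_row_undefined_not_zero(self):
        presence = pd.DataFrame([[1, 1], [0, 0]], index=["a", "b"], columns=["x", "y"])
        result = conditional_probability(presence)
        assert result.probabilities.loc["b"].isna().all()
        assert result.probabilities.loc["a", "b"] == 0.0  # defined: i present, j never with it

    def test_non_binary_rejected(self):
        presence = pd.DataFrame([[2]], index=["a"], columns=["x"])
        with pytest.raises(ValueError, match="binary"):
            conditional_probability(presence)

    def test_matches_exhaustive_enumeration_on_random_matrices(self):
        """Seeded batch of random binary matrices vs a nested-loop oracle."""
        rng = np.random.default_rng(42)
        for _ in range(500):
            n_genes = int(rng.integers(1, 9))
            n_loci = int(rng.integers(1, 13))
            mat = rng.integers(0, 2, size=(n_genes, n_loci))
            presence = pd.DataFrame(
                mat,
                index=[f"g{i}" for i in range(n_genes)],
                columns=[f"l{j}" for j in range(n_loci)],
            )
            result = conditional_probability(presence)
            for i in range(n_genes):
                ni = int(mat[i].sum())
                for j in range(n_genes):
                    both = int(((mat[i] == 1) & (mat[j] == 1)).sum())
                    got = result.probabilities.iat[i, j]
                    if ni == 0:
                        assert np.isnan(got)
                    else:
                        assert got == both / ni

    def test_cooccurrence_counts_symmetric(self):
        rng = np.random.default_rng(7)
        presence = pd.DataFrame(rng.integers(0, 2, size=(6, 10)))
        co = conditional_probability(presence).cooccurrence_counts
        assert (co.values == co.values.T).all()


class TestNetwork:
    def result_from(self, entries, genes):
        p = pd.DataFrame(np.nan, index=genes, columns=genes)
        counts = pd.Series(1, index=genes)
        for (i, j), v in entries.items():
            p.loc[i, j] = v
        for g in genes:
            p.loc[g, g] = 1.0
        from cisscan.cooccurrence import CooccurrenceResult

        return CooccurrenceResult(p, counts, p.notna().astype(int))

    def test_edge_requires_both_directions(self):
        result = self.result_from({("a", "b"): 0.9, ("b", "a"): 0.85}, ["a", "b"])
        assert bidirectional_network(result, 0.8) == {("a", "b")}
        result = self.result_from({("a", "b"): 0.9, ("b", "a"): 0.7}, ["a", "b"])
        assert bidirectional_network(result, 0.8) == set()

    def test_exactly_tau_is_no_edge(self):
        result = self.result_from({("a", "b"): 0.8, ("b", "a"): 0.8}, ["a", "b"])
        assert bidirectional_network(result, 0.8) == set()

    def test_undefined_probability_never_edges(self):
        result = self.result_from({("a", "b"): 0.9}, ["a", "b"])  # P(a|b) stays NaN
        assert bidirectional_network(result, 0.8) == set()

    def test_tau_out_of_range(self):
        result = self.result_from({}, ["a"])
        with pytest.raises(ValueError):
            bidirectional_network(result, 1.5)

    def test_raising_tau_never_adds_edges(self):
        rng = np.random.default_rng(3)
        presence = pd.DataFrame(
            rng.integers(0, 2, size=(7, 12)),
            index=[f"g{i}" for i in range(7)],
        )
        result = conditional_probability(presence)
        previous = None
        for tau in (0.2, 0.4, 0.6, 0.8, 0.95):
            edges = bidirectional_network(result, tau)
            if previous is not None:
                assert edges <= previous
            previous = edges

    def test_graphml_export(self, tmp_path):
        presence = pd.DataFrame(
            [[1, 1], [1, 1], [1, 0]], index=["a", "b", "c"], columns=["x", "y"]
        )
        result = conditional_probability(presence)
        edges = bidirectional_network(result, 0.8)
        assert edges == {("a", "b")}
        g = network_to_graphml(result, edges, tmp_path / "net.graphml")
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 1
        assert (tmp_path / "net.graphml").exists()


class TestWardClustering:
    def test_identical_pair_merges_first(self):
        m = pd.DataFrame(
            {"x": [1, 0, 3], "y": [5, 5, 5], "z": [1, 0, 3]},
        )
        clustering = ward_column_order(m)
        a, b, height, size = clustering.merges[0]
        assert {a, b} == {0, 2} and height == 0.0 and size == 2
        # identical columns are adjacent in the leaf order
        order = list(clustering.order)
        assert abs(order.index("x") - order.index("z")) == 1

    def test_single_column(self):
        m = pd.DataFrame({"only": [1, 2, 3]})
        clustering = ward_column_order(m)
        assert clustering.order == ("only",)
        assert clustering.newick == "only;"

    def test_merge_sequence_matches_stepwise_oracle(self):
        """4-column toy matrix: greedy merge order matches brute-force
        re-evaluation of the Lance-Williams Ward criterion at every step."""
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("abcd"))
        clustering = ward_column_order(m)

        # oracle: recursive cluster distance from singleton Euclidean distances
        x = m.to_numpy().T

        def d(A, B):
            if len(A) == 1 and len(B) == 1:
                return float(np.linalg.norm(x[A[0]] - x[B[0]]))
            if len(B) > 1:  # split the larger side via LW recurrence
                A, B = B, A
            A1, A2 = A[:-1], (A[-1],)
            na1, na2, nb = len(A1), len(A2), len(B)
            return (
                (na1 + nb) * d(A1, B) + (na2 + nb) * d(A2, B) - nb * d(A1, A2)
            ) / (na1 + na2 + nb)

        clusters = [(i,) for i in range(4)]
        for a, b, height, _ in clustering.merges:
            # map linkage ids to current oracle clusters by leaf sets
            def leaves_of(node, merges=clustering.merges, n=4):
                if node < n:
                    return (node,)
                aa, bb, _, _ = merges[node - n]
                return leaves_of(aa) + leaves_of(bb)

            la, lb = leaves_of(a), leaves_of(b)
            best = min(
                (d(c1, c2), i, j)
                for i, c1 in enumerate(clusters)
                for j, c2 in enumerate(clusters)
                if i < j
            )
            assert height == pytest.approx(best[0], rel=1e-9)
            assert {frozenset(la), frozenset(lb)} == {
                frozenset(clusters[best[1]]), frozenset(clusters[best[2]])
            }
            clusters = [
                c for k, c in enumerate(clusters) if k not in (best[1], best[2])
            ] + [tuple(sorted(la + lb))]

    def test_ward_d_matches_r_hclust(self, tmp_path):
        """Independent oracle: R hclust(method='ward.D') on the same
        Euclidean distances reproduces our merge heights."""
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(size=(6, 5)), columns=[f"c{i}" for i in range(5)])
        clustering = ward_column_order(m)
        csv = tmp_path / "m.csv"
        m.to_csv(csv, index=False)
        script = (
            f"m <- read.csv('{csv}'); "
            "h <- hclust(dist(t(m)), method='ward.D'); "
            "cat(sprintf('%.10f', h$height), sep='\\n')"
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        r_heights = [float(x) for x in proc.stdout.split()]
        our_heights = [h for _, _, h, _ in clustering.merges]
        assert our_heights == pytest.approx(r_heights, rel=1e-8)

    def test_ward_d2_matches_scipy(self):
        from scipy.cluster.hierarchy import linkage

        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.normal(size=(6, 5)), columns=[f"c{i}" for i in range(5)])
        clustering = ward_column_order(m, method="ward_d2")
        link = linkage(m.to_numpy().T, method="ward")
        assert [h for _, _, h, _ in clustering.merges] == pytest.approx(
            list(link[:, 2]), rel=1e-9
        )

    def test_newick_has_all_leaves(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(4, 6)), columns=[f"col{i}" for i in range(6)])
        clustering = ward_column_order(m)
        for col in m.columns:
            assert col in clustering.newick
        assert clustering.newick.endswith(";")


def test_probability_tsv_blank_for_undefined(tmp_path):
    presence = pd.DataFrame([[1, 1], [0, 0]], index=["a", "b"], columns=["x", "y"])
    result = conditional_probability(presence)
    path = tmp_path / "p.tsv"
    write_probability_tsv(result, path)
    lines = path.read_text().splitlines()
    assert lines[2].split("\t") == ["b", "", ""]  # undefined row is empty, not 0
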