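import itertools

import numpy as np
import pytest

from copresence.io import HitRecord, SequenceRecord, parse_newick
from copresence.profiling import (
    GeneTree,
    Orthogroup,
    OrthologyNetwork,
    Proteome,
    SpeciesPanel,
    all_vs_all_search,
    assemble_network,
    build_gene_tree,
    confirm_full_presence,
    e_value,
    extract_orthogroups,
    infer_ortholog_pairs,
    match_phyletic_profile,
    neighbor_joining,
    trim_network,
)


def _rand_seq(rng, n=200):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


class TestAllVsAllSearch:
    def test_identical_sequence_ties_self_hit_bitscore(self):
        rng = np.random.default_rng(0)
        seq = _rand_seq(rng, 150)
        p1 = Proteome("S1", [SequenceRecord("a", "S1", seq)])
        p2 = Proteome("S2", [SequenceRecord("b", "S2", seq)])
        hits = all_vs_all_search([p1, p2], evalue_cutoff=1e-5)
        by_query = {}
        for h in hits:
            by_query.setdefault(h.query_id, []).append(h)
        self_hit = next(h for h in by_query["a"] if h.subject_id == "a")
        cross = next(h for h in by_query["a"] if h.subject_id == "b")
        assert cross.bitscore == pytest.approx(self_hit.bitscore)
        assert cross.pident == pytest.approx(100.0)

    def test_random_pairs_never_reach_significance(self):
        """Unrelated uniform-residue sequences score below the E-value bar.

        The Karlin-Altschul conversion is checked directly: for 100 random
        pairs the best local alignment score gives E >> 1e-5.
        """
        from Bio import Align
        from Bio.Align import substitution_matrices

        rng = np.random.default_rng(1)
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        for _ in range(100):
            a, b = _rand_seq(rng), _rand_seq(rng)
            assert e_value(aligner.score(a, b), 200, 400) > 1e-5

    def test_unrelated_proteomes_produce_only_self_hits(self):
        rng = np.random.default_rng(2)
        p1 = Proteome("S1", [SequenceRecord("a", "S1", _rand_seq(rng))])
        p2 = Proteome("S2", [SequenceRecord("b", "S2", _rand_seq(rng))])
        hits = all_vs_all_search([p1, p2], evalue_cutoff=1e-5)
        assert {(h.query_id, h.subject_id) for h in hits} == {("a", "a"), ("b", "b")}

    def test_planted_family_members_all_hit_each_other(self):
        rng = np.random.default_rng(3)
        ancestor = _rand_seq(rng, 150)
        members = []
        for k, sp in enumerate(["S1", "S2", "S3", "S4", "S5"]):
            chars = list(ancestor)
            for i in np.flatnonzero(rng.random(len(chars)) < 0.10):
                chars[i] = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"))
            members.append(Proteome(sp, [
                SequenceRecord(f"m{k}", sp, "".join(chars)),
                SequenceRecord(f"d{k}", sp, _rand_seq(rng, 150)),
            ]))
        hits = all_vs_all_search(members, evalue_cutoff=1e-5)
        fam = {f"m{k}" for k in range(5)}
        pairs = {(h.query_id, h.subject_id) for h in hits}
        for a, b in itertools.permutations(fam, 2):
            assert (a, b) in pairs

    def test_duplicate_and_empty_proteomes_rejected(self):
        rec = SequenceRecord("a", "S1", "MKV")
        with pytest.raises(ValueError, match="duplicate"):
            all_vs_all_search(
                [Proteome("S1", [rec]), Proteome("S2", [SequenceRecord("a", "S2", "MKV")])]
            )
        with pytest.raises(ValueError, match="empty"):
            all_vs_all_search([Proteome("S1", [rec]), Proteome("S2", [])])

    def test_precomputed_hits_are_filtered_and_sorted(self):
        p1 = Proteome("S1", [SequenceRecord("a", "S1", "MKV")])
        p2 = Proteome("S2", [SequenceRecord("b", "S2", "MKV")])
        raw = [
            HitRecord("a", "b", 100, 3, 1, 3, 1, 3, 1e-3, 10.0),
            HitRecord("a", "a", 100, 3, 1, 3, 1, 3, 1e-30, 20.0),
        ]
        hits = all_vs_all_search([p1, p2], evalue_cutoff=1e-2, precomputed=raw)
        assert [h.subject_id for h in hits] == ["a", "b"]


class TestNeighborJoining:
    def test_additive_quartet_recovers_generating_topology(self):
        """NJ on an additive matrix must return the four-point-dominant split.

        The oracle enumerates all three unrooted quartet topologies and picks
        the one whose split satisfies the four-point condition.
        """
        labels = ["A", "B", "C", "D"]
        # additive on ((A,B),(C,D)) with internal branch 3
        D = np.array([
            [0, 2, 7, 8],
            [2, 0, 7, 8],
            [7, 7, 0, 3],
            [8, 8, 3, 0],
        ], dtype=float)
        sums = {
            ("A", "B"): D[0, 1] + D[2, 3],
            ("A", "C"): D[0, 2] + D[1, 3],
            ("A", "D"): D[0, 3] + D[1, 2],
        }
        oracle_pair = min(sums, key=sums.get)  # smallest sum = true cherry
        assert oracle_pair == ("A", "B")
        tree = neighbor_joining(labels, D)
        cherries = set()
        for node in tree.preorder_node_iter():
            kids = node.child_nodes()
            if len(kids) == 2 and all(k.is_leaf() for k in kids):
                cherries.add(tuple(sorted(k.taxon.label for k in kids)))
        assert ("A", "B") in cherries or ("C", "D") in cherries

    def test_two_taxa_form_single_cherry(self):
        tree = neighbor_joining(["x", "y"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert {l.taxon.label for l in tree.leaf_node_iter()} == {"x", "y"}

    def test_q_matrix_tie_broken_lexicographically(self):
        # four equidistant taxa: every pair ties in Q; (a,b) must join first
        D = np.ones((4, 4)) - np.eye(4)
        tree = neighbor_joining(["d", "c", "b", "a"], D)
        for node in tree.preorder_node_iter():
            kids = node.child_nodes()
            if len(kids) == 2 and all(k.is_leaf() for k in kids):
                pair = tuple(sorted(k.taxon.label for k in kids))
                assert pair == ("a", "b")
                return
        pytest.fail("no cherry found")

    def test_topology_matches_scikit_bio_on_random_matrix(self):
        """Independent cross-check against scikit-bio's NJ implementation."""
        from skbio import DistanceMatrix
        from skbio.tree import nj

        rng = np.random.default_rng(11)
        n = 7
        pts = rng.normal(size=(n, 4))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = [f"t{i}" for i in range(n)]
        ours = neighbor_joining(labels, D)
        theirs = nj(DistanceMatrix(D, labels))

        def splits_dendropy(tree):
            leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
            out = set()
            for node in tree.preorder_node_iter():
                side = frozenset(l.taxon.label for l in node.leaf_iter())
                if 1 < len(side) < len(leaves) - 1:
                    out.add(min(side, leaves - side, key=sorted))
            return out

        def splits_skbio(tree):
            leaves = frozenset(t.name for t in tree.tips())
            out = set()
            for node in tree.traverse():
                if node.is_tip() or node.is_root():
                    continue
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < len(leaves) - 1:
                    out.add(min(side, leaves - side, key=sorted))
            return out

        assert splits_dendropy(ours) == splits_skbio(theirs)


def _gene_tree(newick, seed_id, species_of):
    return GeneTree(tree=parse_newick(newick), seed_id=seed_id, species_of=species_of)


class TestSpeciesOverlap:
    def test_pure_speciation_tree_pairs_seed_with_everyone(self):
        gt = _gene_tree(
            "((seed:1,b:1):1,c:1);", "seed",
            {"seed": "sp1", "b": "sp2", "c": "sp3"},
        )
        assert set(infer_ortholog_pairs(gt)) == {("seed", "b"), ("seed", "c")}

    def test_duplication_below_seed_blocks_paralog_not_outgroup(self):
        gt = _gene_tree(
            "((seed:1,a2:1):1,b:1);", "seed",
            {"seed": "sp1", "a2": "sp1", "b": "sp2"},
        )
        assert set(infer_ortholog_pairs(gt)) == {("seed", "b")}

    def test_single_species_tree_yields_no_pairs(self):
        gt = _gene_tree(
            "((seed:1,a2:1):1,a3:1);", "seed",
            {"seed": "sp1", "a2": "sp1", "a3": "sp1"},
        )
        assert infer_ortholog_pairs(gt) == []


class TestNetwork:
    def test_support_counts_asserting_phylomes(self):
        species = {"a": "S1", "b": "S2", "c": "S3"}
        net = assemble_network([[("a", "b")], [("b", "a"), ("b", "c")]], species)
        assert net.graph["a"]["b"]["support"] == 2
        assert net.graph["b"]["c"]["support"] == 1

    def test_empty_input_gives_empty_network(self):
        net = assemble_network([], {})
        assert net.graph.number_of_nodes() == 0

    def test_trim_drops_weak_edges(self):
        species = {"a": "S1", "b": "S2", "c": "S3"}
        net = assemble_network([[("a", "b")], [("b", "a"), ("b", "c")]], species)
        trimmed = trim_network(net, min_support=2)
        assert set(trimmed.graph.edges) == {("a", "b")}

    def test_trim_with_min_support_one_and_no_fusion_is_identity(self):
        species = {"a": "S1", "b": "S2", "c": "S3"}
        net = assemble_network([[("a", "b"), ("a", "c")]], species)
        assert trim_network(net, min_support=1) == net

    def test_fusion_split_by_disjoint_alignment_regions(self):
        """A node hit over residues 1-100 by one neighbour and 150-250 by
        another (interval Jaccard 0) splits into two region sub-nodes."""
        species = {"g": "S1", "n1": "S2", "n2": "S3"}
        net = assemble_network([[("g", "n1"), ("g", "n2")]], species)
        hits = [
            HitRecord("g", "n1", 90, 100, 1, 100, 1, 100, 1e-20, 200.0),
            HitRecord("g", "n2", 90, 101, 150, 250, 1, 101, 1e-20, 200.0),
        ]
        trimmed = trim_network(net, min_support=1, fusion_jaccard_max=0.0, hits=hits)
        assert trimmed.fusion_splits == {"g": ["g#1", "g#2"]}
        assert {frozenset(e) for e in trimmed.graph.edges} == {
            frozenset({"g#1", "n1"}),
            frozenset({"g#2", "n2"}),
        }

    def test_node_without_coordinates_left_intact(self):
        species = {"g": "S1", "n1": "S2", "n2": "S3"}
        net = assemble_network([[("g", "n1"), ("g", "n2")]], species)
        trimmed = trim_network(net, min_support=1, fusion_jaccard_max=0.0, hits=[])
        assert trimmed.fusion_splits == {}
        assert set(trimmed.graph.nodes) == {"g", "n1", "n2"}


def _closure_partition(n_nodes, edges):
    """Oracle: connected components by repeated boolean matrix closure."""
    A = np.eye(n_nodes, dtype=bool)
    for i, j in edges:
        A[i, j] = A[j, i] = True
    while True:
        B = A @ A
        if (B == A).all():
            break
        A = B
    seen, parts = set(), []
    for i in range(n_nodes):
        if i in seen:
            continue
        comp = frozenset(np.flatnonzero(A[i]).tolist())
        seen |= comp
        parts.append(comp)
    return frozenset(parts)


def _network_from(n_nodes, edges):
    net = OrthologyNetwork()
    for i in range(n_nodes):
        net.add_node(f"g{i:02d}", species=f"S{i % 3}")
    for i, j in edges:
        net.add_assertion(f"g{i:02d}", f"g{j:02d}")
    return net


class TestOrthogroups:
    def test_chain_forms_single_group(self):
        net = _network_from(3, [(0, 1), (1, 2)])
        (og,) = extract_orthogroups(net)
        assert og.gene_ids == {"g00", "g01", "g02"}

    def test_disjoint_edges_form_two_groups(self):
        net = _network_from(4, [(0, 1), (2, 3)])
        groups = extract_orthogroups(net)
        assert [sorted(g.gene_ids) for g in groups] == [["g00", "g01"], ["g02", "g03"]]

    def test_matches_transitive_closure_oracle_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(2, 20))
            possible = list(itertools.combinations(range(n), 2))
            k = int(rng.integers(0, len(possible) + 1))
            idx = rng.choice(len(possible), size=k, replace=False)
            edges = [possible[i] for i in idx]
            net = _network_from(n, edges)
            ours = frozenset(
                frozenset(int(g[1:]) for g in og.gene_ids)
                for og in extract_orthogroups(net)
            )
            assert ours == _closure_partition(n, edges)


def _group(gid, members):
    return Orthogroup(id=gid, members=frozenset(members))


class TestPhyleticScreen:
    PANEL = SpeciesPanel(
        positive=["Ngru", "Agod", "Mjak"],
        negative=["Hsap", "Scer"],
        exempt=["Perc"],
        required_all=["Ngru", "Agod"],
    )

    def test_two_positive_no_negative_kept(self):
        og = _group("OG1", [("Ngru", "g1"), ("Agod", "g2")])
        assert match_phyletic_profile([og], self.PANEL) == [og]

    def test_single_positive_dropped(self):
        og = _group("OG1", [("Ngru", "g1"), ("Ngru", "g1b")])
        assert match_phyletic_profile([og], self.PANEL) == []

    def test_negative_member_kills_group_unless_exempted(self):
        bad = _group("OG1", [("Ngru", "g1"), ("Agod", "g2"), ("Mjak", "g3"), ("Hsap", "g4")])
        assert match_phyletic_profile([bad], self.PANEL) == []
        panel2 = SpeciesPanel(
            positive=["Ngru", "Agod", "Mjak"],
            negative=["Scer"],
            exempt=["Perc", "Hsap"],
            required_all=["Ngru", "Agod"],
        )
        assert match_phyletic_profile([bad], panel2) == [bad]

    def test_unknown_species_is_configuration_error(self):
        og = _group("OG1", [("Ngru", "g1"), ("Xxx", "g2")])
        with pytest.raises(ValueError, match="Xxx"):
            match_phyletic_profile([og], self.PANEL)

    def test_monotone_in_exempt_and_negative(self):
        """Moving species to exempt never shrinks the candidate set; adding
        negatives never grows it."""
        rng = np.random.default_rng(9)
        species = [f"S{i}" for i in range(8)]
        for _ in range(30):
            groups = []
            for g in range(6):
                members = [
                    (sp, f"{sp}_g{g}") for sp in species if rng.random() < 0.4
                ]
                if members:
                    groups.append(_group(f"OG{g}", members))
            base = SpeciesPanel(positive=species[:4], negative=species[4:7],
                                exempt=species[7:])
            more_exempt = SpeciesPanel(positive=species[:4], negative=species[4:6],
                                       exempt=species[6:])
            more_negative = SpeciesPanel(positive=species[:4], negative=species[4:],
                                         exempt=[])
            kept = {og.id for og in match_phyletic_profile(groups, base)}
            kept_exempt = {og.id for og in match_phyletic_profile(groups, more_exempt)}
            kept_negative = {og.id for og in match_phyletic_profile(groups, more_negative)}
            assert kept <= kept_exempt
            assert kept_negative <= kept


class TestConfirmation:
    REQUIRED = ["A", "B", "C"]

    def test_full_coverage_is_bona_fide(self):
        og = _group("OG1", [("A", "g1"), ("B", "g2"), ("C", "g3")])
        assert confirm_full_presence([og], self.REQUIRED) == [og]

    def test_missing_species_without_rescue_rejected(self):
        og = _group("OG1", [("A", "g1"), ("B", "g2")])
        assert confirm_full_presence([og], self.REQUIRED) == []

    def test_rescue_hit_supplies_missing_species(self):
        og = _group("OG1", [("A", "g1"), ("B", "g2")])
        (out,) = confirm_full_presence(
            [og], self.REQUIRED, rescue_hits={"OG1": [("C", "g9")]}
        )
        assert ("C", "g9") in out.members

    def test_rescue_for_unknown_group_is_error(self):
        og = _group("OG1", [("A", "g1")])
        with pytest.raises(ValueError, match="OG9"):
            confirm_full_presence([og], self.REQUIRED, rescue_hits={"OG9": [("C", "x")]})


class TestBuildGeneTree:
    def test_seed_plus_one_homolog_is_a_cherry(self):
        rng = np.random.default_rng(12)
        seq = _rand_seq(rng, 100)
        p1 = Proteome("S1", [SequenceRecord("seed", "S1", seq)])
        p2 = Proteome("S2", [SequenceRecord("hom", "S2", seq)])
        hits = all_vs_all_search([p1, p2], evalue_cutoff=1e-5)
        gt = build_gene_tree(p1.records[0], hits, [p1, p2])
        assert {l.taxon.label for l in gt.tree.leaf_node_iter()} == {"seed", "hom"}
        assert gt.seed_id == "seed"

    def test_no_homologs_signals_skip(self):
        from copresence.profiling import SkipSeed

        rng = np.random.default_rng(13)
        p1 = Proteome("S1", [SequenceRecord("seed", "S1", _rand_seq(rng))])
        p2 = Proteome("S2", [SequenceRecord("x", "S2", _rand_seq(rng))])
        hits = all_vs_all_search([p1, p2], evalue_cutoff=1e-5)
        with pytest.raises(SkipSeed):
            build_gene_tree(p1.records[0], hits, [p1, p2])
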