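"""Phylogenetic profiling via pooled per-seed phylomes.

The procedure mirrors the classic phylome architecture: every gene of every
species is used as a seed, its homologues are collected by all-vs-all
similarity search, a fast distance tree is built per seed, orthology is read
off each tree with the species-overlap rule, the per-seed relations are
pooled into one weighted network, the network is trimmed (weak edges,
gene-fusion artefacts) and its connected components become orthogroups.
Orthogroups are then screened against a phyletic profile: present in at
least ``min_positive`` marker-positive species, absent from every
marker-negative species, with data-poor taxa exempted from the negative
test, and finally confirmed by requiring a representative in a fixed set of
well-sampled positive species (targeted rescue hits may supply members that
the automated search missed).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import HitRecord, SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Proteome",
    "GeneTree",
    "OrthologyNetwork",
    "SpeciesPanel",
    "Orthogroup",
    "all_vs_all_search",
    "build_gene_tree",
    "infer_ortholog_pairs",
    "assemble_network",
    "trim_network",
    "extract_orthogroups",
    "match_phyletic_profile",
    "confirm_full_presence",
    "run_profile_pipeline",
]

# Gapped Karlin-Altschul parameters for BLOSUM62 with open 11 / extend 1.
# Used only to turn Smith-Waterman raw scores into approximate bit scores
# and E-values at desk scale; production inputs use external search output.
KA_LAMBDA = 0.267
KA_K = 0.041
GAP_OPEN = 11.0
GAP_EXTEND = 1.0


@dataclass
class Proteome:
    species: str
    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if any(r.species != self.species for r in self.records):
            raise ValueError("all records of a proteome must share its species")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate ids in proteome {self.species!r}")


@dataclass
class GeneTree:
    """A per-seed gene tree with a leaf -> species lookup."""

    tree: dendropy.Tree
    seed_id: str
    species_of: dict[str, str]

    def __post_init__(self) -> None:
        leaves = {l.taxon.label for l in self.tree.leaf_node_iter()}
        if self.seed_id not in leaves:
            raise ValueError("seed must be a leaf of its gene tree")
        if len(leaves) < 2:
            raise ValueError("gene tree needs >= 2 leaves")


class OrthologyNetwork:
    """Weighted orthology graph pooled over phylomes.

    Nodes are gene ids annotated with species; edge weight ``support``
    counts the phylomes asserting the pair (at most 2: one per endpoint
    whose phylome exists). ``fusion_splits`` maps an original gene id to
    its region-restricted sub-ids after fusion splitting.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()
        self.fusion_splits: dict[str, list[str]] = {}

    def add_node(self, gene: str, species: str) -> None:
        self.graph.add_node(gene, species=species)

    def add_assertion(self, gene_a: str, gene_b: str) -> None:
        if gene_a == gene_b:
            raise ValueError("self-loops are not orthology edges")
        if self.graph.has_edge(gene_a, gene_b):
            self.graph[gene_a][gene_b]["support"] += 1
        else:
            self.graph.add_edge(gene_a, gene_b, support=1)

    def species(self, gene: str) -> str:
        return self.graph.nodes[gene]["species"]

    def copy(self) -> "OrthologyNetwork":
        out = OrthologyNetwork()
        out.graph = self.graph.copy()
        out.fusion_splits = {k: list(v) for k, v in self.fusion_splits.items()}
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrthologyNetwork):
            return NotImplemented
        return (
            nx.utils.graphs_equal(self.graph, other.graph)
            and self.fusion_splits == other.fusion_splits
        )


@dataclass
class SpeciesPanel:
    """Positive / negative / exempt species lists plus the confirmation set.

    Exempt species (incomplete genome or transcriptome data) are ignored by
    both the positive and the negative test; ``required_all`` lists the
    well-sampled positive species in which a confirmed family must have a
    representative.
    """

    positive: list[str]
    negative: list[str]
    exempt: list[str] = field(default_factory=list)
    required_all: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        sets = [set(self.positive), set(self.negative), set(self.exempt)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError(
                        f"panel lists overlap: {sorted(sets[i] & sets[j])}"
                    )
        if not set(self.required_all) <= set(self.positive):
            raise ValueError("required_all must be a subset of positive")

    @property
    def all_species(self) -> set[str]:
        return set(self.positive) | set(self.negative) | set(self.exempt)


@dataclass
class Orthogroup:
    id: str
    members: frozenset[tuple[str, str]]  # (species, gene id)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("orthogroup must be non-empty")

    @property
    def profile(self) -> Counter:
        """Species -> member count (paralogues allowed, presence = count>=1)."""
        return Counter(sp for sp, _ in self.members)

    @property
    def gene_ids(self) -> set[str]:
        return {g for _, g in self.members}


# ---------------------------------------------------------------------------
# All-vs-all search (internal Smith-Waterman at desk scale)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def bit_score(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def e_value(raw_score: float, query_len: int, db_len: int) -> float:
    return query_len * db_len * 2.0 ** (-bit_score(raw_score))


def _alignment_stats(aln) -> tuple[int, int, int, int, float, int]:
    """(q_start, q_end, s_start, s_end, pident, length), 1-based inclusive."""
    qa, sa = aln.aligned
    q_start, q_end = int(qa[0][0]) + 1, int(qa[-1][1])
    s_start, s_end = int(sa[0][0]) + 1, int(sa[-1][1])
    q_str, s_str = aln[0], aln[1]
    matches = sum(a == b for a, b in zip(q_str, s_str))
    length = len(q_str)
    pident = 100.0 * matches / length if length else 0.0
    return q_start, q_end, s_start, s_end, pident, length


def all_vs_all_search(
    proteomes: Sequence[Proteome],
    evalue_cutoff: float = 1e-5,
    precomputed: Iterable[HitRecord] | None = None,
) -> list[HitRecord]:
    """All-vs-all protein similarity search.

    With ``precomputed`` the function only validates ids, filters by
    ``evalue_cutoff`` and sorts (pass-through of external tabular search
    output). Otherwise it runs Smith-Waterman (BLOSUM62, affine gaps 11/1)
    on every ordered pair including the self-pair and converts raw scores
    to bits and E-values with the gapped Karlin-Altschul approximation.
    Hits are returned grouped by query, descending bit score, ties broken
    by subject id.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least 2 proteomes")
    all_records: list[SequenceRecord] = []
    seen: set[str] = set()
    for p in proteomes:
        if not p.records:
            raise ValueError(f"empty proteome {p.species!r}")
        for r in p.records:
            if r.id in seen:
                raise ValueError(f"duplicate gene id across proteomes: {r.id!r}")
            seen.add(r.id)
            all_records.append(r)

    if precomputed is not None:
        hits = [h for h in precomputed if h.evalue <= evalue_cutoff]
        for h in hits:
            if h.query_id not in seen or h.subject_id not in seen:
                raise ValueError(
                    f"hit references unknown gene: {h.query_id}->{h.subject_id}"
                )
        return sorted(hits, key=lambda h: (h.query_id, -h.bitscore, h.subject_id))

    aligner = _make_aligner()
    db_len = sum(len(r.seq) for r in all_records)
    hits: list[HitRecord] = []
    for q in all_records:
        for s in all_records:
            raw = aligner.score(q.seq, s.seq)
            ev = e_value(raw, len(q.seq), db_len)
            if ev > evalue_cutoff:
                continue
            aln = next(iter(aligner.align(q.seq, s.seq)))
            qs, qe, ss, se, pident, length = _alignment_stats(aln)
            hits.append(
                HitRecord(
                    query_id=q.id,
                    subject_id=s.id,
                    pident=pident,
                    length=length,
                    q_start=qs,
                    q_end=qe,
                    s_start=ss,
                    s_end=se,
                    evalue=ev,
                    bitscore=bit_score(raw),
                )
            )
    return sorted(hits, key=lambda h: (h.query_id, -h.bitscore, h.subject_id))


# ---------------------------------------------------------------------------
# Distance trees (neighbour joining on Kimura-corrected identities)


def kimura_protein_distance(p_diff: float) -> float:
    """Kimura's empirical correction of an observed proteic difference.

    d = -ln(1 - p - p^2/5); saturates (capped at 10) when p approaches the
    formula's domain boundary.
    """
    arg = 1.0 - p_diff - 0.2 * p_diff * p_diff
    if arg <= math.exp(-10.0):
        return 10.0
    return min(10.0, -math.log(arg))


def _pairwise_distance_matrix(
    records: Sequence[SequenceRecord], aligner: Align.PairwiseAligner | None = None
) -> np.ndarray:
    aligner = aligner or _make_aligner()
    n = len(records)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = next(iter(aligner.align(records[i].seq, records[j].seq)))
            *_, pident, length = _alignment_stats(aln)
            p = 1.0 - pident / 100.0 if length else 1.0
            dist[i, j] = dist[j, i] = kimura_protein_distance(p)
    return dist


def neighbor_joining(
    labels: Sequence[str], dist: np.ndarray
) -> dendropy.Tree:
    """Saitou-Nei neighbour joining with a deterministic tie-break.

    When several pairs minimise the Q criterion, the pair whose (sorted)
    representative gene-id tuple is lexicographically smallest is joined.
    Each cluster is represented by the lexicographically smallest leaf id it
    contains, so the tie-break is stable across merges.
    """
    n = len(labels)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    taxa = dendropy.TaxonNamespace(list(labels))
    nodes: list[dendropy.Node] = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(lab)
        nodes.append(node)
    reps = list(labels)  # representative id per active cluster
    D = dist.astype(float).copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        totals = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - totals[i] - totals[j]
                key = tuple(sorted((reps[i], reps[j])))
                cand = (q, key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        d_ij = D[i, j]
        limb_i = 0.5 * d_ij + (totals[i] - totals[j]) / (2.0 * (len(active) - 2))
        limb_j = d_ij - limb_i
        parent = dendropy.Node()
        nodes[i].edge.length = max(limb_i, 0.0)
        nodes[j].edge.length = max(limb_j, 0.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new_row = np.zeros(D.shape[0] + 1)
        D = np.pad(D, ((0, 1), (0, 1)))
        k = D.shape[0] - 1
        for h in active:
            if h in (i, j):
                continue
            D[k, h] = D[h, k] = 0.5 * (D[i, h] + D[j, h] - d_ij)
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        active = [h for h in active if h not in (i, j)] + [k]

    i, j = active
    root = dendropy.Node()
    half = max(D[i, j], 0.0) / 2.0
    nodes[i].edge.length = half
    nodes[j].edge.length = half
    root.add_child(nodes[i])
    root.add_child(nodes[j])
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


class SkipSeed(Exception):
    """Signal that a seed has too few homologues for a tree (not an error)."""


def build_gene_tree(
    seed: SequenceRecord,
    hits: Sequence[HitRecord],
    proteomes: Sequence[Proteome],
    max_homologs: int = 20,
) -> GeneTree:
    """Neighbour-joining tree over the seed and its top scoring homologues.

    Distances are Kimura-corrected complements of normalised alignment
    identity. Raises :class:`SkipSeed` when fewer than 2 taxa remain.
    """
    by_id = {r.id: r for p in proteomes for r in p.records}
    ranked = [
        h
        for h in hits
        if h.query_id == seed.id and h.subject_id != seed.id and h.subject_id in by_id
    ]
    ranked.sort(key=lambda h: (-h.bitscore, h.subject_id))
    chosen_ids = [seed.id] + [h.subject_id for h in ranked[:max_homologs]]
    if len(chosen_ids) < 2:
        raise SkipSeed(seed.id)
    chosen_ids = sorted(set(chosen_ids))
    records = [by_id[g] for g in chosen_ids]
    dist = _pairwise_distance_matrix(records)
    tree = neighbor_joining(chosen_ids, dist)
    return GeneTree(
        tree=tree,
        seed_id=seed.id,
        species_of={r.id: r.species for r in records},
    )


# ---------------------------------------------------------------------------
# Species-overlap orthology


def _label_duplications(
    tree: dendropy.Tree, species_of: Mapping[str, str]
) -> None:
    """Annotate each node with its species set and a duplication flag.

    A node is a duplication iff the species sets of (at least) two of its
    child subtrees intersect; otherwise a speciation.
    """
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.species_set = frozenset({species_of[node.taxon.label]})
            node.is_duplication = False
        else:
            child_sets = [c.species_set for c in node.child_nodes()]
            union: set[str] = set()
            dup = False
            for cs in child_sets:
                if union & cs:
                    dup = True
                union |= cs
            node.species_set = frozenset(union)
            node.is_duplication = dup


def infer_ortholog_pairs(gene_tree: GeneTree) -> list[tuple[str, str]]:
    """Seed-centred orthology by the species-overlap rule.

    The tree is midpoint rooted, every internal node is labelled duplication
    or speciation by child-subtree species overlap, and (seed, x) is an
    ortholog pair exactly when the most recent common ancestor of seed and x
    is a speciation node. Pairs within the seed's own species never qualify
    (their ancestor necessarily shows species overlap).
    """
    tree = gene_tree.tree.clone(depth=1)
    tree.is_rooted = True
    if len(tree.leaf_nodes()) > 2:
        try:
            tree.reroot_at_midpoint(update_bipartitions=False)
        except Exception:  # zero-length degenerate trees: keep given rooting
            pass
    _label_duplications(tree, gene_tree.species_of)
    seed_leaf = next(
        l for l in tree.leaf_node_iter() if l.taxon.label == gene_tree.seed_id
    )
    seed_ancestors = []
    node = seed_leaf.parent_node
    while node is not None:
        seed_ancestors.append(node)
        node = node.parent_node
    ancestor_rank = {id(n): i for i, n in enumerate(seed_ancestors)}

    pairs: list[tuple[str, str]] = []
    for leaf in tree.leaf_node_iter():
        if leaf is seed_leaf:
            continue
        node = leaf.parent_node
        while id(node) not in ancestor_rank:
            node = node.parent_node
        mrca = node
        if not mrca.is_duplication:
            pairs.append((gene_tree.seed_id, leaf.taxon.label))
    return pairs


# ---------------------------------------------------------------------------
# Network assembly, trimming, orthogroups


def assemble_network(
    edge_sets: Iterable[Iterable[tuple[str, str]]],
    species_of: Mapping[str, str],
) -> OrthologyNetwork:
    """Pool per-seed ortholog pairs; support counts asserting phylomes."""
    net = OrthologyNetwork()
    for edges in edge_sets:
        for a, b in edges:
            net.add_node(a, species_of[a])
            net.add_node(b, species_of[b])
            net.add_assertion(a, b)
    return net


def _interval_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    inter = max(0, hi - lo + 1)
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union if union else 0.0


def trim_network(
    network: OrthologyNetwork,
    min_support: int = 1,
    fusion_jaccard_max: float | None = None,
    hits: Sequence[HitRecord] | None = None,
) -> OrthologyNetwork:
    """Successive trimming: weak-edge removal, then gene-fusion splitting.

    Step 1 drops edges asserted by fewer than ``min_support`` phylomes.
    Step 2 (only when ``fusion_jaccard_max`` is not None) looks at each
    node's neighbours through the query-side alignment spans of ``hits``:
    if the spans partition into >= 2 groups whose pairwise interval Jaccard
    is <= ``fusion_jaccard_max``, the node is split into region-restricted
    sub-nodes (``id#1``, ``id#2``, ...) and each edge is reattached to the
    sub-node whose region contains its span midpoint. Nodes without
    coordinate data are left intact with a logged warning.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    net = network.copy()
    weak = [
        (a, b)
        for a, b, s in net.graph.edges(data="support")
        if s < min_support
    ]
    net.graph.remove_edges_from(weak)

    if fusion_jaccard_max is None:
        return net

    span_of: dict[tuple[str, str], tuple[int, int]] = {}
    for h in hits or []:
        span_of[(h.query_id, h.subject_id)] = (h.q_start, h.q_end)

    for gene in list(net.graph.nodes):
        neighbors = sorted(net.graph.neighbors(gene))
        if len(neighbors) < 2:
            continue
        spans = {}
        for nb in neighbors:
            sp = span_of.get((gene, nb))
            if sp is None:
                logger.warning(
                    "node %s has neighbours without coordinate data; not split",
                    gene,
                )
                spans = None
                break
            spans[nb] = sp
        if not spans:
            continue
        overlap = nx.Graph()
        overlap.add_nodes_from(neighbors)
        for i, na in enumerate(neighbors):
            for nb in neighbors[i + 1 :]:
                if _interval_jaccard(spans[na], spans[nb]) > fusion_jaccard_max:
                    overlap.add_edge(na, nb)
        groups = sorted(
            (sorted(c) for c in nx.connected_components(overlap)),
            key=lambda g: min(spans[m][0] for m in g),
        )
        if len(groups) < 2:
            continue
        regions = [
            (min(spans[m][0] for m in g), max(spans[m][1] for m in g))
            for g in groups
        ]
        species = net.species(gene)
        sub_ids = [f"{gene}#{k + 1}" for k in range(len(groups))]
        for sid in sub_ids:
            net.graph.add_node(sid, species=species)
        for nb in neighbors:
            mid = (spans[nb][0] + spans[nb][1]) / 2.0
            target = None
            for sid, (lo, hi) in zip(sub_ids, regions):
                if lo <= mid <= hi:
                    target = sid
                    break
            if target is None:  # midpoint between regions: nearest region
                target = min(
                    zip(sub_ids, regions),
                    key=lambda t: min(abs(mid - t[1][0]), abs(mid - t[1][1])),
                )[0]
            support = net.graph[gene][nb]["support"]
            net.graph.add_edge(target, nb, support=support)
        net.graph.remove_node(gene)
        net.fusion_splits[gene] = sub_ids
    return net


def extract_orthogroups(network: OrthologyNetwork) -> list[Orthogroup]:
    """Connected components of the trimmed network, deterministically named.

    Components are sorted by their smallest gene id and labelled OG0001,
    OG0002, ... Singleton nodes (no surviving edges) form their own groups.
    """
    components = sorted(
        (sorted(c) for c in nx.connected_components(network.graph)),
        key=lambda c: c[0],
    )
    groups = []
    for k, comp in enumerate(components, start=1):
        members = frozenset((network.species(g), g) for g in comp)
        groups.append(Orthogroup(id=f"OG{k:04d}", members=members))
    return groups


# ---------------------------------------------------------------------------
# Phyletic-profile screening


def match_phyletic_profile(
    orthogroups: Iterable[Orthogroup],
    panel: SpeciesPanel,
    min_positive: int = 2,
    declared_absent: Iterable[str] = (),
) -> list[Orthogroup]:
    """Keep groups present in >= ``min_positive`` positive species and in no
    negative species; exempt species are ignored by both tests.

    A species occurring in a profile but neither in the panel nor in
    ``declared_absent`` is a configuration error.
    """
    known = panel.all_species | set(declared_absent)
    positive = set(panel.positive)
    negative = set(panel.negative)
    kept = []
    for og in orthogroups:
        profile = og.profile
        unknown = set(profile) - known
        if unknown:
            raise ValueError(
                f"orthogroup {og.id}: species not in panel: {sorted(unknown)}"
            )
        n_pos = sum(1 for sp in profile if sp in positive)
        n_neg = sum(1 for sp in profile if sp in negative)
        if n_pos >= min_positive and n_neg == 0:
            kept.append(og)
    return kept


def confirm_full_presence(
    candidates: Iterable[Orthogroup],
    required_all: Iterable[str],
    rescue_hits: Mapping[str, Iterable[tuple[str, str]]] | None = None,
) -> list[Orthogroup]:
    """Bona fide co-occurring families: coverage of every required species.

    ``rescue_hits`` supplies (species, gene id) members found by targeted
    re-search of a candidate's group; they are added to the group before the
    coverage test. A rescue entry keyed by an unknown group id is an error.
    """
    required = set(required_all)
    candidates = list(candidates)
    rescue = {k: list(v) for k, v in (rescue_hits or {}).items()}
    known_ids = {og.id for og in candidates}
    unknown = set(rescue) - known_ids
    if unknown:
        raise ValueError(f"rescue hits reference unknown groups: {sorted(unknown)}")
    confirmed = []
    for og in candidates:
        members = set(og.members) | set(rescue.get(og.id, []))
        covered = {sp for sp, _ in members}
        if required <= covered:
            confirmed.append(Orthogroup(id=og.id, members=frozenset(members)))
    return confirmed


# ---------------------------------------------------------------------------
# End-to-end convenience


def run_profile_pipeline(
    proteomes: Sequence[Proteome],
    panel: SpeciesPanel,
    evalue_cutoff: float = 1e-5,
    max_homologs: int = 20,
    min_support: int = 1,
    fusion_jaccard_max: float | None = None,
    min_positive: int = 2,
    precomputed_hits: Sequence[HitRecord] | None = None,
    rescue_hits: Mapping[str, Iterable[tuple[str, str]]] | None = None,
) -> dict:
    """Full profiling run: search, phylomes, network, screen, confirm.

    Returns a dict with hits, per-seed trees, the trimmed network, all
    orthogroups, profile-matching candidates and confirmed families.
    """
    hits = all_vs_all_search(proteomes, evalue_cutoff, precomputed=precomputed_hits)
    species_of = {r.id: r.species for p in proteomes for r in p.records}
    edge_sets = []
    trees = []
    for p in proteomes:
        for seed in p.records:
            try:
                gtree = build_gene_tree(seed, hits, proteomes, max_homologs)
            except SkipSeed:
                continue
            trees.append(gtree)
            edge_sets.append(infer_ortholog_pairs(gtree))
    network = assemble_network(edge_sets, species_of)
    trimmed = trim_network(network, min_support, fusion_jaccard_max, hits)
    orthogroups = extract_orthogroups(trimmed)
    candidates = match_phyletic_profile(orthogroups, panel, min_positive)
    confirmed = confirm_full_presence(candidates, panel.required_all, rescue_hits)
    return {
        "hits": hits,
        "trees": trees,
        "network": trimmed,
        "orthogroups": orthogroups,
        "candidates": candidates,
        "confirmed": confirmed,
    }
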