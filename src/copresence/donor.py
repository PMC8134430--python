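"""Donor-taxon inference for eukaryotic genes of prokaryotic origin.

A eukaryotic gene family acquired from a prokaryote sits, in a well-resolved
gene tree, as a clade nested among prokaryotic homologues. Because the
apparent donor lineage is sensitive to taxon sampling, the analysis is run
over a series of nested homologue datasets defined by a score cutoff
``c * best_prokaryotic_hit_score`` with ``c`` walked from 0.99 down to 0.70
in steps of 0.01. For each dataset's tree, the tree is artificially rooted
on the branch separating eukaryotes from prokaryotes (when such a branch
exists — otherwise the run is recorded as non-monophyletic), a taxonomic
distribution is propagated from the prokaryotic leaves to the deepest
prokaryotic node by proportional mixing of descendant affiliations, and the
distribution at the parental node of the eukaryotic clade is read off. A
summary across the ``c`` grid reports the modal donor taxon and how stable
the assignment is.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

from .io import TaxonMap, node_support

__all__ = [
    "ScoredHomologSet",
    "NestedDatasetSpec",
    "RootedGeneTree",
    "NonSeparableError",
    "MonophylyResult",
    "ParentalAssignment",
    "PerCResult",
    "DonorSummary",
    "generate_nested_datasets",
    "root_between_domains",
    "test_eukaryote_monophyly",
    "assign_node_taxonomy",
    "infer_parental_taxon",
    "summarize_donor_stability",
    "analyze_tree",
]


@dataclass
class ScoredHomologSet:
    """Eukaryotic seeds plus scored prokaryotic homologues.

    ``prokaryotes`` maps id -> search score in bits; taxonomic affiliation
    comes from the accompanying :class:`~copresence.io.TaxonMap`.
    """

    eukaryotes: list[str]
    prokaryotes: dict[str, float]

    def __post_init__(self) -> None:
        if not self.eukaryotes:
            raise ValueError("need at least one eukaryotic seed")
        if not self.prokaryotes:
            raise ValueError("no prokaryotic homolog: cannot build nested datasets")
        overlap = set(self.eukaryotes) & set(self.prokaryotes)
        if overlap:
            raise ValueError(f"ids in both domains: {sorted(overlap)}")

    @property
    def best_prokaryotic_score(self) -> float:
        return max(self.prokaryotes.values())


@dataclass(frozen=True)
class NestedDatasetSpec:
    """One homologue dataset on the c grid.

    ``cutoff = c * best prokaryotic score``; members are all eukaryotic
    seeds plus every prokaryote scoring at or above the cutoff.
    """

    c: float
    cutoff: float
    member_ids: frozenset[str]


def generate_nested_datasets(
    homologs: ScoredHomologSet,
    c_hi: float = 0.99,
    c_lo: float = 0.70,
    step: float = 0.01,
) -> list[NestedDatasetSpec]:
    """Nested dataset specs for c from ``c_hi`` down to ``c_lo``.

    The grid is inclusive on both ends; c values are rounded to 2 decimals
    to keep the float grid exact. Membership uses score >= cutoff, so a
    smaller c can only add members (datasets are nested).
    """
    if not (c_lo <= c_hi):
        raise ValueError("need c_lo <= c_hi")
    if step <= 0:
        raise ValueError("step must be positive")
    best = homologs.best_prokaryotic_score
    n_steps = int(round((c_hi - c_lo) / step))
    cs = [round(c_hi - k * step, 2) for k in range(n_steps + 1)]
    specs = []
    for c in cs:
        cutoff = c * best
        members = frozenset(homologs.eukaryotes) | frozenset(
            pid for pid, score in homologs.prokaryotes.items() if score >= cutoff
        )
        specs.append(NestedDatasetSpec(c=c, cutoff=cutoff, member_ids=members))
    return specs


# ---------------------------------------------------------------------------
# Rooting between domains


class NonSeparableError(Exception):
    """No single branch separates eukaryotes from prokaryotes.

    ``conflicting_leaves`` holds the smallest observed set of leaves by
    which the best candidate branch fails to realise the domain split.
    """

    def __init__(self, conflicting_leaves: set[str]):
        super().__init__(
            f"eukaryotes not separable; conflicting leaves: {sorted(conflicting_leaves)}"
        )
        self.conflicting_leaves = conflicting_leaves


@dataclass
class RootedGeneTree:
    """Gene tree rooted on the eukaryote/prokaryote boundary branch."""

    tree: dendropy.Tree
    taxon_map: TaxonMap
    euk_clade_support: float | None = None

    def __post_init__(self) -> None:
        children = self.tree.seed_node.child_nodes()
        if len(children) != 2:
            raise ValueError("root must have exactly two children")

    def _domain_child(self, domain: str) -> dendropy.Node:
        for child in self.tree.seed_node.child_nodes():
            leaves = [l.taxon.label for l in child.leaf_iter()]
            if all(self.taxon_map.domain(l) == domain for l in leaves):
                return child
        raise ValueError(f"no pure {domain} child under the root")

    @property
    def eukaryote_child(self) -> dendropy.Node:
        return self._domain_child("eukaryote")

    @property
    def prokaryote_child(self) -> dendropy.Node:
        return self._domain_child("prokaryote")


def root_between_domains(
    tree: dendropy.Tree, taxon_map: TaxonMap
) -> RootedGeneTree:
    """Root a gene tree on the branch splitting eukaryotes from prokaryotes.

    If such a branch exists the tree is rooted at its midpoint and the
    support label of the branch's eukaryote-side node is reported as the
    support for eukaryote monophyly. Otherwise :class:`NonSeparableError`
    carries the smallest conflicting leaf set over all candidate branches.
    """
    work = tree.clone(depth=1)
    leaves = [l.taxon.label for l in work.leaf_node_iter()]
    missing = [l for l in leaves if l not in taxon_map]
    if missing:
        raise ValueError(f"leaves missing from taxon map: {missing}")
    euks = {l for l in leaves if taxon_map.is_eukaryote(l)}
    proks = set(leaves) - euks
    if not euks or not proks:
        raise ValueError("need both eukaryotic and prokaryotic leaves")

    best_conflict: set[str] | None = None
    target_edge = None
    for node in work.preorder_node_iter():
        if node is work.seed_node:
            continue
        side = {l.taxon.label for l in node.leaf_iter()}
        for domain_set in (euks, proks):
            conflict = side ^ domain_set
            if not conflict:
                target_edge = node.edge
                break
            if best_conflict is None or len(conflict) < len(best_conflict):
                best_conflict = conflict
        if target_edge is not None:
            break
    if target_edge is None:
        raise NonSeparableError(best_conflict or set())

    length = target_edge.length
    if length is None:
        work.reroot_at_edge(target_edge, update_bipartitions=False)
    else:
        half = length / 2.0
        work.reroot_at_edge(
            target_edge, length1=half, length2=half, update_bipartitions=False
        )
    work.is_rooted = True
    # collapse any extra root children left by rerooting an unrooted tree
    root_children = work.seed_node.child_nodes()
    if len(root_children) != 2:
        raise ValueError("rerooting did not produce a bifurcating root")

    support: float | None = None
    for child in root_children:
        side = {l.taxon.label for l in child.leaf_iter()}
        if side == euks:
            support = node_support(child)
    return RootedGeneTree(tree=work, taxon_map=taxon_map, euk_clade_support=support)


@dataclass(frozen=True)
class MonophylyResult:
    """``monophyletic`` is True/False, or None when indeterminate (a support
    threshold was requested but the tree carries no support label)."""

    monophyletic: bool | None
    support: float | None


def test_eukaryote_monophyly(
    rooted: RootedGeneTree | NonSeparableError,
    min_support: float | None = None,
) -> MonophylyResult:
    """Monophyly of the eukaryotic sequences, optionally support-gated."""
    if isinstance(rooted, NonSeparableError):
        return MonophylyResult(monophyletic=False, support=None)
    support = rooted.euk_clade_support
    if min_support is None:
        return MonophylyResult(monophyletic=True, support=support)
    if support is None:
        return MonophylyResult(monophyletic=None, support=None)
    return MonophylyResult(monophyletic=support >= min_support, support=support)


# ---------------------------------------------------------------------------
# Proportional node taxonomy


def assign_node_taxonomy(
    rooted: RootedGeneTree,
    taxon_map: TaxonMap | None = None,
    weighting: str = "children",
) -> dict[dendropy.Node, dict[str, float]]:
    """Bottom-up taxonomic distributions over the prokaryotic subtree.

    Each prokaryotic leaf gets an indicator distribution on its taxon.
    With ``weighting="children"`` (default) an internal node's distribution
    is the unweighted mean of its children's distributions — each
    descending node counts equally, regardless of how many leaves it holds.
    ``weighting="leaves"`` instead averages with children weighted by their
    descendant leaf counts, which equals the leaf-frequency distribution.
    Branch lengths play no role.
    """
    if weighting not in ("children", "leaves"):
        raise ValueError("weighting must be 'children' or 'leaves'")
    tmap = taxon_map or rooted.taxon_map
    prok_root = rooted.prokaryote_child
    dist: dict[dendropy.Node, dict[str, float]] = {}
    n_leaves: dict[dendropy.Node, int] = {}
    for node in prok_root.postorder_iter():
        if node.is_leaf():
            label = node.taxon.label
            taxon = tmap.taxon(label)
            if not taxon:
                raise ValueError(f"prokaryotic leaf {label!r} has no taxon")
            dist[node] = {taxon: 1.0}
            n_leaves[node] = 1
        else:
            children = node.child_nodes()
            if weighting == "children":
                weights = [1.0 / len(children)] * len(children)
            else:
                total = sum(n_leaves[c] for c in children)
                weights = [n_leaves[c] / total for c in children]
            merged: dict[str, float] = {}
            for child, w in zip(children, weights):
                for taxon, p in dist[child].items():
                    merged[taxon] = merged.get(taxon, 0.0) + w * p
            dist[node] = merged
            n_leaves[node] = sum(n_leaves[c] for c in children)
    return dist


@dataclass(frozen=True)
class ParentalAssignment:
    """Taxonomic assignment of the eukaryotic clade's parental node."""

    top_taxon: str
    top_weight: float
    distribution: dict[str, float]
    tied: tuple[str, ...] = ()


def infer_parental_taxon(
    dist: Mapping[dendropy.Node, dict[str, float]],
    rooted: RootedGeneTree,
) -> ParentalAssignment:
    """Distribution at the deepest prokaryotic node (the root's prokaryotic
    child); exact ties for the top weight yield ``"unresolved"``."""
    node_dist = dict(dist[rooted.prokaryote_child])
    top_weight = max(node_dist.values())
    tied = tuple(sorted(t for t, w in node_dist.items() if w == top_weight))
    top = tied[0] if len(tied) == 1 else "unresolved"
    return ParentalAssignment(
        top_taxon=top, top_weight=top_weight, distribution=node_dist, tied=tied
    )


# ---------------------------------------------------------------------------
# Per-c analysis and stability summary


@dataclass(frozen=True)
class PerCResult:
    c: float
    n_taxa_in_dataset: int
    euk_monophyletic: bool
    support: float | None
    top_taxon: str | None
    top_weight: float | None
    distribution: dict[str, float] | None = None


@dataclass
class DonorSummary:
    records: list[PerCResult]
    mode_taxon: str
    stability: float
    n_usable: int = 0
    flagged: bool = False


def analyze_tree(
    tree: dendropy.Tree,
    taxon_map: TaxonMap,
    c: float = float("nan"),
    weighting: str = "children",
    min_support: float | None = None,
) -> PerCResult:
    """Root, test monophyly and assign the parental taxon for one dataset."""
    n_taxa = sum(1 for _ in tree.leaf_node_iter())
    try:
        rooted = root_between_domains(tree, taxon_map)
    except NonSeparableError:
        return PerCResult(
            c=c,
            n_taxa_in_dataset=n_taxa,
            euk_monophyletic=False,
            support=None,
            top_taxon=None,
            top_weight=None,
        )
    mono = test_eukaryote_monophyly(rooted, min_support)
    if mono.monophyletic is False:
        return PerCResult(
            c=c,
            n_taxa_in_dataset=n_taxa,
            euk_monophyletic=False,
            support=mono.support,
            top_taxon=None,
            top_weight=None,
        )
    dist = assign_node_taxonomy(rooted, taxon_map, weighting=weighting)
    assignment = infer_parental_taxon(dist, rooted)
    return PerCResult(
        c=c,
        n_taxa_in_dataset=n_taxa,
        euk_monophyletic=True,
        support=mono.support,
        top_taxon=assignment.top_taxon,
        top_weight=assignment.top_weight,
        distribution=assignment.distribution,
    )


def summarize_donor_stability(per_c_results: Sequence[PerCResult]) -> DonorSummary:
    """Modal donor taxon and its frequency among usable (monophyletic) runs.

    Non-monophyletic runs stay in the record table but are excluded from
    the mode and the stability fraction. Zero usable runs yields mode
    ``"none"``, stability 0, flagged.
    """
    if not per_c_results:
        raise ValueError("need at least one per-c result")
    records = list(per_c_results)
    usable = [r for r in records if r.euk_monophyletic and r.top_taxon is not None]
    if not usable:
        return DonorSummary(
            records=records, mode_taxon="none", stability=0.0, n_usable=0, flagged=True
        )
    counts = Counter(r.top_taxon for r in usable)
    top_count = max(counts.values())
    modes = sorted(t for t, n in counts.items() if n == top_count)
    mode = modes[0] if len(modes) == 1 else "unresolved"
    return DonorSummary(
        records=records,
        mode_taxon=mode,
        stability=top_count / len(usable),
        n_usable=len(usable),
        flagged=False,
    )
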