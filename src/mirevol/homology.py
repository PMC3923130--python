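"""Ortholog pairing by reciprocal best hits and parsimony age dating.

Orthologs between two focal species are called as mutual top-scoring global
alignment hits; a tie for the top score on either side rejects the pair, so
accepted pairs are unambiguous 1-to-1 calls. Optional synteny support checks
for a shared flanking gene on each side of the locus.

A family's evolutionary origin is placed, by parsimony, at the most recent
common ancestor of all species in which a homolog is found. The species tree
is ranked: every node carries an integer age rank (1 = youngest clade, e.g.
Drosophilids only, up to R = 7 for the bilaterian root), and the family's
age is the rank of its origin node. Families with multiple members inherit
the age of their oldest member, since paralogs may have duplicated after the
family arose.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import dendropy

from mirevol.alignment import Scoring, score_similarity

_RANK_RE = re.compile(r"rank=(\d+)")


@dataclass(frozen=True)
class OrthologPair:
    locus_a: str
    locus_b: str
    forward_score: float
    reverse_score: float
    synteny_support: bool | None = None


@dataclass(frozen=True)
class AgeAssignment:
    family_id: str
    origin_node: str
    age_rank: int
    supporting_species: frozenset[str]
    duplication_inflated: bool = False


class SpeciesTree:
    """Rooted, ranked species tree.

    Node labels of the form ``<name>|rank=<K>`` (or just ``rank=<K>``) carry
    integer age ranks. Leaves without an explicit rank inherit their parent's
    rank — the terminal branch belongs to the same age class as the youngest
    labelled clade containing it. Ranks must be non-decreasing from the tips
    toward the root.
    """

    def __init__(self, tree: dendropy.Tree, source_newick: str | None = None):
        self._tree = tree
        self._source_newick = source_newick
        self._ranks: dict[int, int] = {}
        self._labels: dict[int, str] = {}
        self._leaf_index: dict[str, dendropy.Node] = {}
        for leaf in tree.leaf_node_iter():
            self._leaf_index[leaf.taxon.label] = leaf
        for node in tree.preorder_node_iter():
            label = node.label if node.label else (node.taxon.label if node.taxon else None)
            rank = None
            if label:
                m = _RANK_RE.search(label)
                if m:
                    rank = int(m.group(1))
            if rank is None:
                if node.parent_node is None:
                    raise ValueError("root node must carry an explicit rank=K label")
                rank = self._ranks[id(node.parent_node)]
            parent = node.parent_node
            if parent is not None and rank > self._ranks[id(parent)]:
                raise ValueError(
                    f"rank {rank} at node {label!r} exceeds parent rank "
                    f"{self._ranks[id(parent)]}: ranks must not increase toward the tips"
                )
            self._ranks[id(node)] = rank
            self._labels[id(node)] = label or f"node{len(self._labels)}"

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick",
            suppress_internal_node_taxa=True, preserve_underscores=True,
        )
        tree.is_rooted = True
        return cls(tree, source_newick=newick)

    @classmethod
    def from_file(cls, path) -> "SpeciesTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @property
    def species(self) -> list[str]:
        return sorted(self._leaf_index)

    @property
    def max_rank(self) -> int:
        return max(self._ranks.values())

    def rank_of(self, node_label: str) -> int:
        for node_id, label in self._labels.items():
            if label == node_label:
                return self._ranks[node_id]
        raise KeyError(node_label)

    def mrca(self, species: set[str]) -> tuple[str, int]:
        """Label and rank of the most recent common ancestor of *species*."""
        missing = set(species) - set(self._leaf_index)
        if missing:
            raise ValueError(f"species not on tree: {sorted(missing)}")
        if len(species) == 1:
            node = self._leaf_index[next(iter(species))]
        else:
            node = self._tree.mrca(taxa=[self._leaf_index[s].taxon for s in species])
        return self._labels[id(node)], self._ranks[id(node)]

    def leaves_under(self, node_label: str) -> set[str]:
        for node in self._tree.preorder_node_iter():
            if self._labels[id(node)] == node_label:
                return {lf.taxon.label for lf in node.leaf_iter()}
        raise KeyError(node_label)

    def as_newick(self) -> str:
        if self._source_newick is not None:
            return self._source_newick.strip()
        # quote labels so rank=K annotations survive a round trip
        out = self._tree.as_string(
            schema="newick", suppress_rooting=True,
            unquoted_underscores=False)
        return out.strip()


def reciprocal_best_hits(
    loci_a: dict[str, str],
    loci_b: dict[str, str],
    scoring: Scoring | None = None,
) -> list[OrthologPair]:
    """1-to-1 ortholog pairs by mutual unique best global-alignment hits.

    A query whose two best targets tie for the top score yields no pair:
    accepted orthologs are unambiguous. Output is symmetric in species order.
    """
    if not loci_a or not loci_b:
        raise ValueError("need at least one locus per species")
    scoring = scoring or Scoring()
    ids_a = sorted(loci_a)
    ids_b = sorted(loci_b)
    scores = {
        (a, b): score_similarity(loci_a[a], loci_b[b], scoring)
        for a in ids_a for b in ids_b
    }

    def unique_best(query, targets, get):
        best = max(targets, key=lambda t: get(t))
        top = get(best)
        if sum(1 for t in targets if get(t) == top) > 1:
            return None, top
        return best, top

    pairs = []
    for a in ids_a:
        b, fwd = unique_best(a, ids_b, lambda t: scores[(a, t)])
        if b is None:
            continue
        a_back, rev = unique_best(b, ids_a, lambda q: scores[(q, b)])
        if a_back == a:
            pairs.append(OrthologPair(a, b, forward_score=fwd, reverse_score=rev))
    return pairs


def synteny_support(
    pair: OrthologPair,
    flanks_a: tuple[list[str], list[str]] | None,
    flanks_b: tuple[list[str], list[str]] | None,
) -> bool | None:
    """Shared-flanking-gene support for an ortholog pair.

    ``flanks_*`` are (upstream, downstream) ordered gene-id lists for the
    locus in each species. Returns True iff at least one gene id is shared
    upstream AND at least one downstream (orientation-aware: upstream is
    compared with upstream); ``None`` (unknown) when flank data is missing.
    """
    if flanks_a is None or flanks_b is None:
        return None
    up_a, down_a = flanks_a
    up_b, down_b = flanks_b
    if not (up_a or down_a) or not (up_b or down_b):
        return None
    return bool(set(up_a) & set(up_b)) and bool(set(down_a) & set(down_b))


def assign_age(
    presence: set[str],
    tree: SpeciesTree,
    reference: str,
    family_id: str = "",
) -> AgeAssignment:
    """Parsimony origin of a family: the MRCA of all species with a homolog.

    The reference species must itself be in the presence set; the family's
    age rank is the rank of the origin node.
    """
    if not presence:
        raise ValueError("presence set is empty")
    if reference not in presence:
        raise ValueError(f"reference species {reference!r} not in presence set")
    origin, rank = tree.mrca(set(presence))
    return AgeAssignment(
        family_id=family_id,
        origin_node=origin,
        age_rank=rank,
        supporting_species=frozenset(presence),
    )


def family_age_propagation(
    ages: dict[str, AgeAssignment],
    families: dict[str, list[str]],
) -> dict[str, AgeAssignment]:
    """Propagate the oldest member's age to every member of each family.

    Members whose own rank is younger than the family age are flagged
    ``duplication_inflated`` (their locus likely arose by a later
    duplication, but the family predates it). ``families`` maps family id to
    its member locus ids; ``ages`` maps locus id to its own assignment.
    """
    out: dict[str, AgeAssignment] = {}
    for fam, members in families.items():
        if not members:
            raise ValueError(f"family {fam} has no members")
        member_ages = [ages[m] for m in members]
        oldest = max(member_ages, key=lambda a: a.age_rank)
        for m, own in zip(members, member_ages):
            out[m] = AgeAssignment(
                family_id=fam,
                origin_node=oldest.origin_node,
                age_rank=oldest.age_rank,
                supporting_species=own.supporting_species,
                duplication_inflated=own.age_rank < oldest.age_rank,
            )
    return out
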