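"""Unrooted gene-tree data model, newick I/O, and clan/split primitives.

A *clan* (sensu Wilkinson) is the unrooted analogue of a clade: a subset of
leaves that forms one side of the bipartition induced by removing a single
edge.  Everything downstream — the incontestable-clan filter, the triplet
classifier, duplicate pruning — is built on the split set of an unrooted
tree, so this module owns that representation.

Trees are parsed from newick via :mod:`dendropy` and converted into a plain
adjacency structure with unrooted semantics: a degree-2 root produced by a
rooted newick string is suppressed (its two incident edges merged), so two
newick strings differing only in root placement yield equal split sets.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Optional, Set, Tuple

import dendropy

logger = logging.getLogger(__name__)

__all__ = [
    "NewickParseError",
    "MappingError",
    "Split",
    "SpeciesMap",
    "UnrootedTree",
    "parse_newick",
    "splits",
    "is_clan",
    "classify_triplet",
    "prune_species_duplicates",
    "is_single_copy",
    "avg_branch_length",
]


class NewickParseError(ValueError):
    """Malformed newick input (unbalanced, duplicate or empty leaf labels)."""


class MappingError(KeyError):
    """A tree leaf could not be resolved to a taxon (or taxon to a group)."""


class Split:
    """An unordered bipartition of a leaf set into two non-empty blocks.

    Orientation-free: ``Split(a, b) == Split(b, a)``.
    """

    __slots__ = ("_blocks",)

    def __init__(self, block_a: Iterable[str], block_b: Iterable[str]):
        a, b = frozenset(block_a), frozenset(block_b)
        if not a or not b:
            raise ValueError("split blocks must be non-empty")
        if a & b:
            raise ValueError(f"split blocks overlap: {sorted(a & b)}")
        self._blocks = frozenset((a, b))

    @property
    def blocks(self) -> FrozenSet[FrozenSet[str]]:
        return self._blocks

    @property
    def smaller(self) -> FrozenSet[str]:
        """The smaller block (ties broken lexicographically) — a canonical handle."""
        return min(self._blocks, key=lambda b: (len(b), tuple(sorted(b))))

    def side_containing(self, leaf: str) -> FrozenSet[str]:
        for b in self._blocks:
            if leaf in b:
                return b
        raise KeyError(leaf)

    def __eq__(self, other) -> bool:
        return isinstance(other, Split) and self._blocks == other._blocks

    def __hash__(self) -> int:
        return hash(self._blocks)

    def __repr__(self) -> str:
        a, b = sorted(self._blocks, key=lambda x: (len(x), tuple(sorted(x))))
        return f"Split({set(sorted(a))} | {set(sorted(b))})"


@dataclass(frozen=True)
class SpeciesMap:
    """Resolution of gene-tree leaf labels to taxa and taxa to groups.

    ``leaf_to_taxon`` may key exact leaf labels or label prefixes (the common
    ``Taxon_name|contig123`` convention); exact matches win, then the longest
    matching prefix.  ``taxon_to_group`` is a partition of the taxon universe
    into named groups (e.g. Anura / Caudata / Gymnophiona / outgroup).
    """

    leaf_to_taxon: Mapping[str, str]
    taxon_to_group: Mapping[str, str] = field(default_factory=dict)

    @property
    def taxa(self) -> FrozenSet[str]:
        return frozenset(self.leaf_to_taxon.values())

    @property
    def groups(self) -> FrozenSet[str]:
        return frozenset(self.taxon_to_group.values())

    def taxa_in_group(self, group: str) -> FrozenSet[str]:
        if self.taxon_to_group and group not in self.taxon_to_group.values():
            raise MappingError(f"unknown group: {group!r}")
        return frozenset(t for t, g in self.taxon_to_group.items() if g == group)

    def taxon_of(self, leaf: str) -> str:
        m = self.leaf_to_taxon.get(leaf)
        if m is not None:
            return m
        # longest-prefix fallback for leaf labels carrying sequence suffixes
        best = None
        for key, taxon in self.leaf_to_taxon.items():
            if leaf.startswith(key) and (best is None or len(key) > len(best[0])):
                best = (key, taxon)
        if best is None:
            raise MappingError(f"leaf {leaf!r} not resolved by species map")
        return best[1]

    def group_of(self, taxon: str) -> str:
        try:
            return self.taxon_to_group[taxon]
        except KeyError:
            raise MappingError(f"taxon {taxon!r} has no group assignment") from None

    @classmethod
    def identity(cls, taxa: Iterable[str], taxon_to_group: Optional[Mapping[str, str]] = None) -> "SpeciesMap":
        """Map each leaf label to itself — the single-tip-per-species case."""
        return cls({t: t for t in taxa}, dict(taxon_to_group or {}))

    @classmethod
    def from_tsv(cls, species_path, groups_path=None) -> "SpeciesMap":
        """Read ``leaf<TAB>taxon`` and optional ``taxon<TAB>group`` tables."""
        leaf_to_taxon: Dict[str, str] = {}
        with open(species_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                leaf, taxon = line.split("\t")[:2]
                leaf_to_taxon[leaf] = taxon
        taxon_to_group: Dict[str, str] = {}
        if groups_path is not None:
            with open(groups_path) as fh:
                for line in fh:
                    line = line.strip()
                    if not line or line.startswith("#"):
                        continue
                    taxon, group = line.split("\t")[:2]
                    taxon_to_group[taxon] = group
        return cls(leaf_to_taxon, taxon_to_group)


class UnrootedTree:
    """A leaf-labelled unrooted tree with optional branch lengths.

    Internally an adjacency map over integer node ids.  Degree-2 nodes are
    suppressed on construction (lengths of merged edges are summed), which
    gives genuinely unrooted semantics: equality is by split set.
    """

    __slots__ = ("_adj", "_leaf_label", "_blocks", "_splits")

    def __init__(self, adj: Dict[int, Dict[int, Optional[float]]], leaf_label: Dict[int, str]):
        self._adj = adj
        self._leaf_label = dict(leaf_label)
        self._suppress_degree_two()
        labels = list(self._leaf_label.values())
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise NewickParseError(f"duplicate leaf labels: {dupes}")
        self._blocks: Optional[FrozenSet[FrozenSet[str]]] = None
        self._splits: Optional[FrozenSet[Split]] = None

    # ------------------------------------------------------------------ build

    def _suppress_degree_two(self) -> None:
        changed = True
        while changed:
            changed = False
            for node in list(self._adj):
                if node in self._leaf_label:
                    continue
                nbrs = self._adj[node]
                if len(nbrs) == 2:
                    (u, lu), (v, lv) = nbrs.items()
                    merged = None if (lu is None and lv is None) else (lu or 0.0) + (lv or 0.0)
                    del self._adj[node]
                    del self._adj[u][node]
                    del self._adj[v][node]
                    self._adj[u][v] = merged
                    self._adj[v][u] = merged
                    changed = True

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Tuple[int, int, Optional[float]]],
        leaf_label: Mapping[int, str],
    ) -> "UnrootedTree":
        adj: Dict[int, Dict[int, Optional[float]]] = {}
        for u, v, ln in edges:
            adj.setdefault(u, {})[v] = ln
            adj.setdefault(v, {})[u] = ln
        return cls(adj, dict(leaf_label))

    # ------------------------------------------------------------- properties

    @property
    def leaves(self) -> FrozenSet[str]:
        return frozenset(self._leaf_label.values())

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_label)

    def edges(self) -> Iterator[Tuple[int, int, Optional[float]]]:
        seen = set()
        for u, nbrs in self._adj.items():
            for v, ln in nbrs.items():
                if (v, u) not in seen:
                    seen.add((u, v))
                    yield u, v, ln

    @property
    def n_edges(self) -> int:
        return sum(1 for _ in self.edges())

    # ------------------------------------------------------------- splits

    def _leafset_below(self, child: int, parent: int) -> FrozenSet[str]:
        """Leaf labels on the *child* side of the edge (child, parent)."""
        out: Set[str] = set()
        stack = [(child, parent)]
        while stack:
            node, came_from = stack.pop()
            if node in self._leaf_label:
                out.add(self._leaf_label[node])
            for nbr in self._adj[node]:
                if nbr != came_from:
                    stack.append((nbr, node))
        return frozenset(out)

    def clan_blocks(self) -> FrozenSet[FrozenSet[str]]:
        """Every edge-induced leaf block, both orientations, trivial included.

        A leaf subset is a clan of the tree iff it is a member of this set
        (or is vacuous — see :func:`is_clan`).
        """
        if self._blocks is None:
            all_leaves = self.leaves
            blocks: Set[FrozenSet[str]] = set()
            for u, v, _ in self.edges():
                side = self._leafset_below(u, v)
                blocks.add(side)
                blocks.add(all_leaves - side)
            self._blocks = frozenset(blocks)
        return self._blocks

    def has_clan(self, leafset: Iterable[str]) -> bool:
        """Leaf-level clan test: does ``leafset`` sit on one side of an edge?"""
        s = frozenset(leafset)
        return s in self.clan_blocks()

    def split_set(self) -> FrozenSet[Split]:
        """Nontrivial splits — one per internal edge."""
        if self._splits is None:
            all_leaves = self.leaves
            out: Set[Split] = set()
            for u, v, _ in self.edges():
                if u in self._leaf_label or v in self._leaf_label:
                    continue
                side = self._leafset_below(u, v)
                if 1 < len(side) < len(all_leaves) - 1:
                    out.add(Split(side, all_leaves - side))
            self._splits = frozenset(out)
        return self._splits

    # ------------------------------------------------------------- distances

    def path_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        label_node = {lab: n for n, lab in self._leaf_label.items()}
        try:
            start, goal = label_node[a], label_node[b]
        except KeyError as exc:
            raise KeyError(f"leaf not in tree: {exc.args[0]}") from None
        stack = [(start, -1, 0.0)]
        while stack:
            node, parent, dist = stack.pop()
            if node == goal:
                return dist
            for nbr, ln in self._adj[node].items():
                if nbr != parent:
                    if ln is None:
                        raise ValueError("path distance undefined: edge without length")
                    stack.append((nbr, node, dist + ln))
        raise RuntimeError("tree is disconnected")  # pragma: no cover

    # ------------------------------------------------------------- editing

    def pruned_to(self, keep: Iterable[str]) -> "UnrootedTree":
        """A new tree restricted to ``keep``; suppressed nodes merge lengths."""
        keep = frozenset(keep)
        missing = keep - self.leaves
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)}")
        adj = {u: dict(nbrs) for u, nbrs in self._adj.items()}
        leaf_label = {n: lab for n, lab in self._leaf_label.items() if lab in keep}
        drop = [n for n, lab in self._leaf_label.items() if lab not in keep]
        for n in drop:
            for v in list(adj[n]):
                del adj[v][n]
            del adj[n]
        # iteratively remove dangling internal nodes
        changed = True
        while changed:
            changed = False
            for n in list(adj):
                if n not in leaf_label and len(adj[n]) == 1:
                    (v,) = adj[n]
                    del adj[v][n]
                    del adj[n]
                    changed = True
        return UnrootedTree(adj, leaf_label)

    # ------------------------------------------------------------- newick

    def to_newick(self, include_lengths: bool = True) -> str:
        """Deterministic serialization: children sorted by minimum leaf label.

        The tree is written rooted at the node adjacent to the
        lexicographically smallest leaf (or at that leaf itself for trees of
        fewer than three leaves).
        """
        if self.n_leaves == 0:
            return ";"
        if self.n_leaves == 1:
            (lab,) = self._leaf_label.values()
            return f"{lab};"
        first_leaf = min(self._leaf_label, key=lambda n: self._leaf_label[n])
        root = next(iter(self._adj[first_leaf]))

        def min_label(node: int, parent: int) -> str:
            if node in self._leaf_label:
                return self._leaf_label[node]
            return min(min_label(c, node) for c in self._adj[node] if c != parent)

        def write(node: int, parent: int) -> str:
            if node in self._leaf_label:
                return self._leaf_label[node]
            kids = sorted(
                (c for c in self._adj[node] if c != parent),
                key=lambda c: min_label(c, node),
            )
            parts = []
            for c in kids:
                sub = write(c, node)
                ln = self._adj[node][c]
                parts.append(sub if (ln is None or not include_lengths) else f"{sub}:{ln!r}")
            return "(" + ",".join(parts) + ")"

        kids = sorted(self._adj[root], key=lambda c: min_label(c, root))
        parts = []
        for c in kids:
            sub = write(c, root)
            ln = self._adj[root][c]
            parts.append(sub if (ln is None or not include_lengths) else f"{sub}:{ln!r}")
        return "(" + ",".join(parts) + ");"

    def __repr__(self) -> str:
        return f"UnrootedTree({self.n_leaves} leaves)"

    def __eq__(self, other) -> bool:
        """Topological equality: same leaves and same nontrivial split set."""
        if not isinstance(other, UnrootedTree):
            return NotImplemented
        return self.leaves == other.leaves and self.split_set() == other.split_set()

    def __hash__(self) -> int:
        return hash((self.leaves, self.split_set()))


# ---------------------------------------------------------------------------
# parsing


def parse_newick(text: str) -> UnrootedTree:
    """Parse a single newick statement into an :class:`UnrootedTree`.

    Branch lengths and polytomies are preserved; internal node labels are
    ignored with a logged warning; duplicate or empty leaf labels and
    unbalanced parentheses raise :class:`NewickParseError`.
    """
    stripped = text.strip()
    if not stripped:
        raise NewickParseError("empty newick string")
    if not stripped.endswith(";"):
        stripped += ";"
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"newick parse failed: {exc}") from exc

    edges: List[Tuple[int, int, Optional[float]]] = []
    leaf_label: Dict[int, str] = {}
    ids: Dict[int, int] = {}

    def nid(node) -> int:
        key = id(node)
        if key not in ids:
            ids[key] = len(ids)
        return ids[key]

    internal_labels = []
    for node in dtree.preorder_node_iter():
        n = nid(node)
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise NewickParseError("empty leaf label in newick input")
            leaf_label[n] = node.taxon.label.replace(" ", "_")
        elif node.label:
            internal_labels.append(node.label)
        if node.parent_node is not None:
            edges.append((nid(node.parent_node), n, node.edge.length))
    if internal_labels:
        logger.warning("ignoring %d internal node label(s): %s", len(internal_labels), internal_labels[:5])
    if not leaf_label:
        raise NewickParseError("newick input contains no leaves")
    return UnrootedTree.from_edges(edges, leaf_label)


def read_tree_table(path) -> List[Tuple[str, UnrootedTree]]:
    """Read a tree set: one newick per line, optional leading id column (TSV).

    Returns ``[(family_id, tree), ...]``; ids default to ``fam0001``-style
    ordinals when absent.
    """
    out: List[Tuple[str, UnrootedTree]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                fam_id, nwk = line.split("\t", 1)
            else:
                fam_id, nwk = f"fam{i + 1:04d}", line
            out.append((fam_id, parse_newick(nwk)))
    return out


# ---------------------------------------------------------------------------
# clan operations


def splits(tree: UnrootedTree) -> FrozenSet[Split]:
    """The nontrivial split set of *tree* (one split per internal edge)."""
    if tree.n_leaves < 3:
        raise ValueError("split enumeration requires at least 3 leaves")
    return tree.split_set()


def is_clan(tree: UnrootedTree, taxa: Iterable[str], species_map: SpeciesMap) -> bool:
    """Do the present members of ``taxa`` form a clan of *tree*?

    Leaves are first resolved to taxa; a clan containing taxon X must hold
    *all* leaves of X.  Members absent from the tree are ignored.  Vacuous
    cases pass by convention: at most one member present, or the present
    members covering the entire leaf set — an untestable clan cannot be
    violated.
    """
    taxa = frozenset(taxa)
    leaf_taxon = {leaf: species_map.taxon_of(leaf) for leaf in tree.leaves}
    present_leaves = frozenset(l for l, t in leaf_taxon.items() if t in taxa)
    present_taxa = {leaf_taxon[l] for l in present_leaves}
    if len(present_taxa) <= 1:
        return True
    if present_leaves == tree.leaves:
        return True
    return tree.has_clan(present_leaves)


def clan_testable(tree: UnrootedTree, taxa: Iterable[str], species_map: SpeciesMap) -> bool:
    """False for the vacuous-pass cases of :func:`is_clan`, True otherwise."""
    taxa = frozenset(taxa)
    leaf_taxon = {leaf: species_map.taxon_of(leaf) for leaf in tree.leaves}
    present_leaves = frozenset(l for l, t in leaf_taxon.items() if t in taxa)
    present_taxa = {leaf_taxon[l] for l in present_leaves}
    return len(present_taxa) > 1 and present_leaves != tree.leaves


def classify_triplet(
    tree: UnrootedTree,
    ingroups: Tuple[str, str, str],
    outgroup: str,
    species_map: SpeciesMap,
) -> Optional[FrozenSet[str]]:
    """Which pair of ingroup groups does this gene tree unite?

    For three ingroup groups (e.g. Anura, Caudata, Gymnophiona) and an
    outgroup, returns the frozenset of the two group ids that jointly form a
    clan to the exclusion of the third group and all outgroups — i.e. the
    resolved rooted triplet — or ``None`` when no pair-clan exists
    (groups interleaved or non-monophyletic).  At most one pair can form a
    clan because the candidate blocks pairwise overlap without nesting.
    """
    g1, g2, g3 = ingroups
    leaf_taxon = {leaf: species_map.taxon_of(leaf) for leaf in tree.leaves}
    present_groups: Dict[str, Set[str]] = {}
    for leaf, taxon in leaf_taxon.items():
        present_groups.setdefault(species_map.group_of(taxon), set()).add(leaf)
    for g in (g1, g2, g3, outgroup):
        if not present_groups.get(g):
            raise ValueError(f"tree has no leaf from required group {g!r}")
    for a, b in itertools.combinations((g1, g2, g3), 2):
        block = frozenset(present_groups[a] | present_groups[b])
        if tree.has_clan(block):
            return frozenset((a, b))
    return None


def prune_species_duplicates(
    tree: UnrootedTree,
    species_map: SpeciesMap,
    seq_lengths: Mapping[str, int],
) -> UnrootedTree:
    """Collapse species-specific duplicate clans to their longest sequence.

    Every maximal set of leaves that (i) all resolve to the same taxon and
    (ii) form a clan of the tree is reduced to the single leaf with the
    greatest sequence length (ties broken by lexicographically smallest
    label).  Same-taxon leaves that do not clan together are left in place —
    they are candidate out-paralogs, not assembly redundancy.
    """
    missing = [l for l in tree.leaves if l not in seq_lengths]
    if missing:
        raise KeyError(f"seq_lengths missing for leaves: {sorted(missing)}")
    by_taxon: Dict[str, Set[str]] = {}
    for leaf in tree.leaves:
        by_taxon.setdefault(species_map.taxon_of(leaf), set()).add(leaf)
    blocks = tree.clan_blocks()
    drop: Set[str] = set()
    for taxon, leaves in by_taxon.items():
        if len(leaves) < 2:
            continue
        same_taxon_clans = [b for b in blocks if b <= leaves]
        # blocks form a laminar family, so maximal ones are disjoint
        maximal = [
            b for b in same_taxon_clans
            if not any(b < other for other in same_taxon_clans)
        ]
        for clan in maximal:
            if len(clan) < 2:
                continue
            keep = min(clan, key=lambda l: (-seq_lengths[l], l))
            drop.update(clan - {keep})
    if not drop:
        return tree
    return tree.pruned_to(tree.leaves - drop)


def is_single_copy(tree: UnrootedTree, species_map: SpeciesMap) -> bool:
    """True iff no taxon labels more than one leaf."""
    seen: Set[str] = set()
    for leaf in tree.leaves:
        taxon = species_map.taxon_of(leaf)
        if taxon in seen:
            return False
        seen.add(taxon)
    return True


def avg_branch_length(tree: UnrootedTree) -> float:
    """Sum of all branch lengths divided by the number of branches.

    Internal and external branches both count; any edge without a length is
    an error (the statistic is undefined).
    """
    lengths = []
    missing = []
    for u, v, ln in tree.edges():
        if ln is None:
            missing.append((u, v))
        else:
            lengths.append(ln)
    if missing:
        raise ValueError(f"{len(missing)} edge(s) lack branch lengths")
    if not lengths:
        raise ValueError("tree has no edges")
    return math.fsum(lengths) / len(lengths)
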