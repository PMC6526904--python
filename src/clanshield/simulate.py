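"""Gene-family simulators for validating the incontestable-clan filter.

Two generative regimes:

* ``ils_only`` — the standard multispecies coalescent (MSC) on a rooted,
  ultrametric species tree measured in coalescent units.  Gene-tree /
  species-tree discordance arises only from incomplete lineage sorting, so
  clans delimited by long stem branches are almost never violated.

* ``dup_late_loss`` — 2**rounds locus copies are created by duplications on
  the root stem (older than every speciation), every copy propagates through
  the species tree, and each sampled taxon then independently retains exactly
  one copy chosen uniformly ("late loss").  Families are single-copy by
  construction yet their histories traverse deep duplication nodes, so
  asserted clans are mixed across copy subtrees and violated at high rate.

Comparing clan-violation fractions between the two regimes is the built-in
validation experiment: the filter should be nearly blind to ILS while
catching duplication + late-loss families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import clanfilter, treeio
from .clanfilter import ClanSet, GeneFamilyRecord
from .treeio import SpeciesMap, UnrootedTree

__all__ = [
    "SpeciesNode",
    "SpeciesModel",
    "SimulationConfig",
    "ViolationSummary",
    "simulate_msc_tree",
    "simulate_duploss_family",
    "sample_occupancy",
    "run_experiment",
]


# ---------------------------------------------------------------------------
# species model


@dataclass
class SpeciesNode:
    """Node of a rooted ultrametric species tree; ``age`` in coalescent units."""

    name: str
    age: float
    children: List["SpeciesNode"] = field(default_factory=list)
    theta: float = 1.0  # per-branch coalescent scaling (branch above this node)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class SpeciesModel:
    """Rooted species tree with node times plus the duplication/loss setup.

    ``dup_spacing`` is the time gap (coalescent units) between successive
    pre-speciation duplication events placed on the root stem; duplications
    are always strictly older than the root age.
    """

    root: SpeciesNode
    dup_spacing: float = 1.0

    def __post_init__(self):
        self._check_times(self.root)

    def _check_times(self, node: SpeciesNode) -> None:
        for c in node.children:
            if c.age >= node.age:
                raise ValueError(
                    f"node times must strictly increase root-ward: "
                    f"{c.name}@{c.age} under {node.name}@{node.age}"
                )
            self._check_times(c)

    @property
    def taxa(self) -> Tuple[str, ...]:
        out: List[str] = []

        def walk(n: SpeciesNode) -> None:
            if n.is_leaf:
                out.append(n.name)
            for c in n.children:
                walk(c)

        walk(self.root)
        return tuple(out)

    def dup_age(self, round_index: int, rounds: int) -> float:
        """Age of duplication ``round_index`` (1 = oldest) for ``rounds`` rounds."""
        if not 1 <= round_index <= rounds:
            raise ValueError("round_index out of range")
        return self.root.age + (rounds - round_index + 1) * self.dup_spacing

    def to_newick(self) -> str:
        def write(n: SpeciesNode, parent_age: Optional[float]) -> str:
            if n.is_leaf:
                body = n.name
            else:
                body = "(" + ",".join(write(c, n.age) for c in n.children) + ")"
                if n.name:
                    body += n.name
            if parent_age is not None:
                body += f":{parent_age - n.age:g}"
            return body

        return write(self.root, None) + ";"

    @classmethod
    def from_newick(cls, text: str, dup_spacing: float = 1.0) -> "SpeciesModel":
        """Build from an ultrametric newick (branch lengths = coalescent units)."""
        import dendropy

        dtree = dendropy.Tree.get(data=text, schema="newick")
        dtree.calc_node_ages(ultrametricity_precision=1e-4)

        def convert(nd) -> SpeciesNode:
            name = nd.taxon.label.replace(" ", "_") if nd.taxon else (nd.label or "")
            node = SpeciesNode(name=name, age=float(nd.age))
            node.children = [convert(c) for c in nd.child_nodes()]
            return node

        return cls(root=convert(dtree.seed_node), dup_spacing=dup_spacing)


# ---------------------------------------------------------------------------
# gene-tree scaffolding


class _GNode:
    __slots__ = ("age", "children", "label")

    def __init__(self, age: float, children: Optional[List["_GNode"]] = None, label: Optional[str] = None):
        self.age = age
        self.children = children or []
        self.label = label


def _gene_tree_to_unrooted(root: _GNode) -> UnrootedTree:
    edges: List[Tuple[int, int, Optional[float]]] = []
    leaf_label: Dict[int, str] = {}
    counter = [0]

    def walk(node: _GNode) -> int:
        nid = counter[0]
        counter[0] += 1
        if node.label is not None:
            leaf_label[nid] = node.label
        for c in node.children:
            cid = walk(c)
            edges.append((nid, cid, node.age - c.age))
        return nid

    walk(root)
    return UnrootedTree.from_edges(edges, leaf_label)


# ---------------------------------------------------------------------------
# multispecies coalescent


def _coalesce(
    lineages: List[_GNode],
    t_start: float,
    t_end: float,
    theta: float,
    rng: np.random.Generator,
) -> List[_GNode]:
    """Pairwise coalescence at rate C(k,2)/theta on [t_start, t_end]."""
    t = t_start
    lineages = list(lineages)
    while len(lineages) > 1:
        k = len(lineages)
        rate = k * (k - 1) / 2.0 / theta
        t_next = t + rng.exponential(1.0 / rate)
        if t_next > t_end:
            break
        i, j = rng.choice(k, size=2, replace=False)
        a = lineages[int(i)]
        b = lineages[int(j)]
        merged = _GNode(age=t_next, children=[a, b])
        lineages = [l for idx, l in enumerate(lineages) if idx not in (int(i), int(j))]
        lineages.append(merged)
        t = t_next
    return lineages


def _msc_rooted(node: SpeciesNode, taxa: FrozenSet[str], rng: np.random.Generator,
                t_stop: Optional[float]) -> List[_GNode]:
    """Lineages surviving at the top of ``node``'s branch (age ``t_stop``)."""
    if node.is_leaf:
        lineages = [_GNode(age=node.age, label=node.name)] if node.name in taxa else []
    else:
        lineages = []
        for c in node.children:
            lineages.extend(_msc_rooted(c, taxa, rng, t_stop=node.age))
    if t_stop is None:  # root branch: coalesce to completion
        lineages = _coalesce(lineages, node.age, math.inf, node.theta, rng)
    elif len(lineages) > 1:
        lineages = _coalesce(lineages, node.age, t_stop, node.theta, rng)
    return lineages


def simulate_msc_tree(
    model: SpeciesModel,
    taxa: Iterable[str],
    rng: np.random.Generator,
) -> UnrootedTree:
    """One gene tree under the multispecies coalescent, one lineage per taxon.

    Within each species-tree branch the extant gene lineages coalesce
    pairwise at rate C(k,2)/theta until the branch ends; survivors are
    passed upward and the root branch coalesces to completion.  Branch
    lengths are in coalescent units; the returned tree is unrooted.
    """
    taxa = frozenset(taxa)
    unknown = taxa - set(model.taxa)
    if unknown:
        raise KeyError(f"taxa not in species model: {sorted(unknown)}")
    if len(taxa) < 3:
        raise ValueError("need at least 3 sampled taxa for an unrooted gene tree")
    (root_lineage,) = _msc_rooted(model.root, taxa, rng, t_stop=None)
    return _gene_tree_to_unrooted(root_lineage)


# ---------------------------------------------------------------------------
# duplication + late loss


def _species_restriction(node: SpeciesNode, taxa: FrozenSet[str]) -> Optional[_GNode]:
    """Gene subtree mirroring the species tree restricted to ``taxa``."""
    if node.is_leaf:
        return _GNode(age=node.age, label=node.name) if node.name in taxa else None
    kids = [k for k in (_species_restriction(c, taxa) for c in node.children) if k is not None]
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    return _GNode(age=node.age, children=kids)


def simulate_duploss_family(
    model: SpeciesModel,
    taxa: Iterable[str],
    rounds: int,
    rng: np.random.Generator,
    ils: bool = False,
) -> UnrootedTree:
    """One single-copy family under pre-LCA duplication and uniform late loss.

    ``rounds`` duplications on the root stem create ``2**rounds`` locus
    copies, each propagating through the whole species tree; every sampled
    taxon then retains exactly one copy, chosen independently and uniformly.
    With ``ils=False`` (default) each copy's propagation follows the species
    tree exactly, isolating the pure duplication signal; with ``ils=True`` a
    coalescent layer is additionally run within each copy.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    taxa = frozenset(taxa)
    unknown = taxa - set(model.taxa)
    if unknown:
        raise KeyError(f"taxa not in species model: {sorted(unknown)}")
    if len(taxa) < 3:
        raise ValueError("need at least 3 sampled taxa")
    n_copies = 2 ** rounds
    choice = {t: int(rng.integers(n_copies)) for t in sorted(taxa)}

    def copy_subtree(copy_idx: int) -> Optional[_GNode]:
        copy_taxa = frozenset(t for t, c in choice.items() if c == copy_idx)
        if not copy_taxa:
            return None
        if len(copy_taxa) == 1:
            (only,) = copy_taxa
            return _GNode(age=0.0, label=only)
        if ils:
            (lineage,) = _msc_rooted(model.root, copy_taxa, rng, t_stop=None)
            return lineage
        return _species_restriction(model.root, copy_taxa)

    def join(lo: int, hi: int, depth: int) -> Optional[_GNode]:
        """Join copy subtrees for copy indices [lo, hi) at duplication depth."""
        if hi - lo == 1:
            return copy_subtree(lo)
        mid = (lo + hi) // 2
        left = join(lo, mid, depth + 1)
        right = join(mid, hi, depth + 1)
        if left is None:
            return right
        if right is None:
            return left
        dup_round = depth + 1  # depth 0 is the oldest duplication, round 1
        age = model.dup_age(dup_round, rounds)
        # under the optional ILS layer a copy-root lineage may postdate the
        # duplication age only through the unbounded root-branch tail; keep
        # the join strictly older than both children
        age = max(age, left.age * (1 + 1e-9) + 1e-9, right.age * (1 + 1e-9) + 1e-9)
        return _GNode(age=age, children=[left, right])

    root = join(0, n_copies, 0)
    assert root is not None
    return _gene_tree_to_unrooted(root)


# ---------------------------------------------------------------------------
# occupancy and the validation experiment


@dataclass
class SimulationConfig:
    """Study conditions for one validation run.

    Defaults mirror the reference experiment this simulator emulates:
    100 replicate data sets of 768 families apiece, with per-taxon inclusion
    probability chosen so family sizes average about 20 of 33 taxa within a
    6-to-32-taxon range.
    """

    n_families: int = 768
    n_replicates: int = 100
    seed: int = 0
    mode: str = "ils_only"  # or "dup_late_loss"
    rounds: int = 2
    ils_under_duploss: bool = False
    taxon_probabilities: Optional[Mapping[str, float]] = None  # default: uniform p
    inclusion_probability: float = 20.0 / 33.0
    size_histogram: Optional[Mapping[int, float]] = None
    min_taxa: int = 6

    def __post_init__(self):
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.mode not in ("ils_only", "dup_late_loss"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.min_taxa < 4:
            raise ValueError("min_taxa must be >= 4")


@dataclass
class ViolationSummary:
    """Per-replicate violated fractions of testable (family, clan) evaluations."""

    fractions: List[float]
    config: SimulationConfig

    def __post_init__(self):
        if any(not 0.0 <= f <= 1.0 for f in self.fractions):
            raise ValueError("violation fractions must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(np.mean(self.fractions))

    @property
    def sd(self) -> float:
        return float(np.std(self.fractions, ddof=1)) if len(self.fractions) > 1 else 0.0


def sample_occupancy(
    config: SimulationConfig,
    taxa: Sequence[str],
    rng: np.random.Generator,
) -> FrozenSet[str]:
    """Draw the taxon subset present in one gene family.

    Either independent per-taxon inclusion (Bernoulli with the configured
    probabilities) or a family-size histogram with uniform taxon choice;
    draws below ``min_taxa`` (never below 4) are rejected and redrawn.
    """
    taxa = list(taxa)
    floor = max(4, config.min_taxa)
    if config.size_histogram is not None:
        sizes = sorted(config.size_histogram)
        weights = np.array([config.size_histogram[s] for s in sizes], dtype=float)
        if weights.sum() <= 0:
            raise ValueError("size histogram has no mass")
        weights = weights / weights.sum()
        for _ in range(10000):
            size = int(rng.choice(sizes, p=weights))
            if floor <= size <= len(taxa):
                chosen = rng.choice(len(taxa), size=size, replace=False)
                return frozenset(taxa[int(i)] for i in chosen)
        raise ValueError("size histogram incompatible with min_taxa / taxon count")
    if config.taxon_probabilities is not None:
        probs = np.array([config.taxon_probabilities.get(t, 0.0) for t in taxa])
    else:
        probs = np.full(len(taxa), config.inclusion_probability)
    if not ((probs >= 0) & (probs <= 1)).all():
        raise ValueError("inclusion probabilities must lie in [0, 1]")
    if probs.sum() == 0:
        raise ValueError("all inclusion probabilities are zero")
    for _ in range(10000):
        mask = rng.random(len(taxa)) < probs
        if mask.sum() >= floor:
            return frozenset(t for t, m in zip(taxa, mask) if m)
    raise ValueError("could not draw an occupancy of the required size")


def _simulate_family(
    model: SpeciesModel,
    config: SimulationConfig,
    species_map: SpeciesMap,
    family_id: str,
    rng: np.random.Generator,
) -> GeneFamilyRecord:
    taxa = sample_occupancy(config, model.taxa, rng)
    if config.mode == "ils_only":
        tree = simulate_msc_tree(model, taxa, rng)
    else:
        tree = simulate_duploss_family(
            model, taxa, config.rounds, rng, ils=config.ils_under_duploss
        )
    return GeneFamilyRecord(family_id=family_id, tree=tree, species_map=species_map)


def simulate_family_set(
    model: SpeciesModel,
    config: SimulationConfig,
    rng: np.random.Generator,
    species_map: Optional[SpeciesMap] = None,
    prefix: str = "fam",
) -> List[GeneFamilyRecord]:
    """One replicate data set of ``config.n_families`` simulated families."""
    if species_map is None:
        species_map = SpeciesMap.identity(model.taxa)
    return [
        _simulate_family(model, config, species_map, f"{prefix}{i + 1:05d}", rng)
        for i in range(config.n_families)
    ]


def run_experiment(
    model: SpeciesModel,
    clans: ClanSet,
    config: SimulationConfig,
    species_map: Optional[SpeciesMap] = None,
) -> ViolationSummary:
    """The validation experiment: clan-violation rate under one regime.

    For each replicate, simulate ``n_families`` families, run the clan
    filter, and record the fraction of *testable* (family, clan)
    evaluations that came out violated; untestable (vacuous) evaluations are
    excluded from the denominator.  Randomness flows from ``config.seed``
    through per-replicate substreams, so results are reproducible and
    independent of replicate order.
    """
    if species_map is None:
        species_map = SpeciesMap.identity(model.taxa)
    model_taxa = set(model.taxa)
    for name, taxa in clans:
        if not taxa & model_taxa:
            raise ValueError(f"clan {name!r} shares no taxa with the species model")
    streams = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    fractions: List[float] = []
    for rep_stream in streams:
        rng = np.random.default_rng(rep_stream)
        records = simulate_family_set(model, config, rng, species_map)
        testable = 0
        violated = 0
        for rec in records:
            report = clanfilter.check_family(rec, clans)
            for status in report.status.values():
                if status is clanfilter.ClanStatus.UNTESTABLE:
                    continue
                testable += 1
                if status is clanfilter.ClanStatus.VIOLATED:
                    violated += 1
        fractions.append(violated / testable if testable else 0.0)
    return ViolationSummary(fractions=fractions, config=config)
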