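"""Exact enumeration of the worst-case late-loss scenario.

Setting: R rounds of gene duplication happen *before* the speciations of
three ingroup lineages, leaving 2**R ancient copies of the locus in their
last common ancestor.  Afterwards each lineage loses all but one copy
("late loss"), so every extant family looks single-copy.  Which rooted
triplet does such a family support?  The surviving pair of lineages whose
copies diverged most recently forms the cherry: the speciation time if two
lineages kept the *same* copy, otherwise the duplication time at the copies'
most recent common duplication node.

With two rounds there are 4 copies and 4**3 = 64 retention combinations.
Enumerating them shows 24 (38%) support the true species topology — but only
4 of those are genuine ortholog families — while each alternative topology
collects 20 (31%).  Random late loss is therefore almost as likely to
support a wrong topology as the right one, which is what makes hidden
paralogy dangerous and worth filtering.

All comparisons use time *ranks* under the strict order
t(SP2) < t(SP1) < t(DUP_R) < ... < t(DUP_1), so ties are impossible by
construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterator, Tuple

__all__ = [
    "CopyTree",
    "SpeciesTimes",
    "RetentionTally",
    "build_copy_tree",
    "classify_combo",
    "enumerate_retention",
]


@dataclass(frozen=True)
class CopyTree:
    """Complete binary tree of gene copies from R pre-speciation duplications.

    Copies are labelled ``c1 .. c{2**R}``; copy *i*'s position is the R-bit
    binary expansion of ``i - 1``, so the most recent common duplication of
    two copies sits at the length of their shared bit prefix.  Duplication
    round 1 is the oldest (the root of the copy tree), round R the most
    recent.
    """

    rounds: int

    def __post_init__(self):
        if self.rounds < 0:
            raise ValueError("rounds must be non-negative")
        if self.rounds > 10:
            raise ValueError("rounds > 10 would enumerate > 2^30 copies")

    @property
    def n_copies(self) -> int:
        return 2 ** self.rounds

    @property
    def copies(self) -> Tuple[str, ...]:
        return tuple(f"c{i + 1}" for i in range(self.n_copies))

    def _index(self, copy: str) -> int:
        i = int(copy[1:]) - 1
        if not 0 <= i < self.n_copies:
            raise KeyError(copy)
        return i

    def mrca_round(self, a: str, b: str) -> int:
        """Duplication round (1 = oldest) at the MRCA of two distinct copies."""
        ia, ib = self._index(a), self._index(b)
        if ia == ib:
            raise ValueError("copies are identical; divergence is a speciation")
        depth = 0
        for bit in range(self.rounds - 1, -1, -1):
            if (ia >> bit) & 1 == (ib >> bit) & 1:
                depth += 1
            else:
                break
        return depth + 1  # duplication at depth d is round d+1

    def mrca_time_rank(self, a: str, b: str) -> int:
        """Time rank of the copies' MRCA under SP2=0 < SP1=1 < DUP_R=2 < ... """
        r = self.mrca_round(a, b)
        return self.rounds + 2 - r


@dataclass(frozen=True)
class SpeciesTimes:
    """Rooted three-lineage species tree ((L1,L2),L3) with ranked node times.

    ``sisters`` is the true cherry; its speciation (SP2) is the most recent
    event, the basal speciation (SP1) the next, and all duplications are
    strictly older.  Defaults carry the Lissamphibia fixture: Batrachia
    (Anura + Caudata) as the true topology, Gymnophiona basal.
    """

    lineages: Tuple[str, str, str] = ("Anura", "Caudata", "Gymnophiona")
    sisters: FrozenSet[str] = frozenset(("Anura", "Caudata"))

    def __post_init__(self):
        if len(set(self.lineages)) != 3:
            raise ValueError("need three distinct lineages")
        if not (len(self.sisters) == 2 and self.sisters <= set(self.lineages)):
            raise ValueError("sisters must be two of the lineages")

    def speciation_rank(self, a: str, b: str) -> int:
        """0 for the sister-pair split (SP2), 1 for the basal split (SP1)."""
        if {a, b} == set(self.sisters):
            return 0
        return 1


def build_copy_tree(rounds: int) -> CopyTree:
    """The complete 2**rounds-copy tree left by ``rounds`` early duplications."""
    return CopyTree(rounds)


def classify_combo(
    assignment: Dict[str, str],
    copy_tree: CopyTree,
    times: SpeciesTimes = SpeciesTimes(),
) -> FrozenSet[str]:
    """Topology supported by one retention combination.

    ``assignment`` maps each lineage to the single copy it retained.  The
    divergence rank of two lineages is the speciation rank when they kept
    the same copy, else the copy-tree MRCA rank; the pair with the unique
    minimum is the supported cherry.
    """
    lineages = times.lineages
    missing = set(lineages) - set(assignment)
    if missing:
        raise ValueError(f"assignment missing lineages: {sorted(missing)}")
    ranks = {}
    for a, b in itertools.combinations(lineages, 2):
        if assignment[a] == assignment[b]:
            ranks[frozenset((a, b))] = times.speciation_rank(a, b)
        else:
            ranks[frozenset((a, b))] = copy_tree.mrca_time_rank(assignment[a], assignment[b])
    ordered = sorted(ranks.items(), key=lambda kv: kv[1])
    if ordered[0][1] == ordered[1][1]:
        # unreachable under the strict rank order; guard the invariant anyway
        raise ValueError(f"tied divergence ranks for {dict(ranks)}")
    return ordered[0][0]


@dataclass
class RetentionTally:
    """Outcome counts of a full retention enumeration."""

    rounds: int
    times: SpeciesTimes
    counts: Dict[FrozenSet[str], int]
    ortholog_count: int
    total: int = field(init=False)

    def __post_init__(self):
        self.total = sum(self.counts.values())

    @property
    def true_pair(self) -> FrozenSet[str]:
        return self.times.sisters

    @property
    def true_count(self) -> int:
        return self.counts[self.true_pair]

    @property
    def alternative_counts(self) -> Dict[FrozenSet[str], int]:
        return {p: c for p, c in self.counts.items() if p != self.true_pair}

    def percentages(self) -> Dict[str, float]:
        """Percent support per topology, rounded to whole percents."""
        return {
            "+".join(sorted(p)): round(100.0 * c / self.total)
            for p, c in self.counts.items()
        }

    def as_dict(self) -> Dict[str, object]:
        out: Dict[str, object] = {
            "rounds": self.rounds,
            "total_combinations": self.total,
            "true_topology": "+".join(sorted(self.true_pair)),
            "true_count": self.true_count,
            "ortholog_count": self.ortholog_count,
        }
        for pair, c in sorted(self.counts.items(), key=lambda kv: "+".join(sorted(kv[0]))):
            out[f"count[{'+'.join(sorted(pair))}]"] = c
        return out


def _all_assignments(copy_tree: CopyTree, lineages: Tuple[str, str, str]) -> Iterator[Dict[str, str]]:
    for combo in itertools.product(copy_tree.copies, repeat=3):
        yield dict(zip(lineages, combo))


def enumerate_retention(rounds: int, times: SpeciesTimes = SpeciesTimes()) -> RetentionTally:
    """Classify every one-copy-per-lineage retention combination.

    Iterates all ``(2**rounds)**3`` assignments of surviving copies to the
    three lineages, classifies each via :func:`classify_combo`, and tallies
    per supported topology; combinations where all three lineages kept the
    same copy are additionally counted as true ortholog families.
    """
    copy_tree = build_copy_tree(rounds)
    lineages = times.lineages
    counts: Dict[FrozenSet[str], int] = {
        frozenset(p): 0 for p in itertools.combinations(lineages, 2)
    }
    orthologs = 0
    for assignment in _all_assignments(copy_tree, lineages):
        counts[classify_combo(assignment, copy_tree, times)] += 1
        if len(set(assignment.values())) == 1:
            orthologs += 1
    return RetentionTally(rounds=rounds, times=times, counts=counts, ortholog_count=orthologs)
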