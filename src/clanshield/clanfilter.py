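"""The incontestable-clan filter over gene-family collections.

A *ClanSet* names taxon groups asserted a priori to be monophyletic
(e.g. mammals).  A single-copy gene family whose tree cannot place the
present members of some clan together on one side of an edge is flagged as a
putative hidden paralog and removed; clans with at most one member present,
or whose present members cover the whole tree, are untestable and never
trigger removal.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import treeio
from .treeio import SpeciesMap, UnrootedTree

logger = logging.getLogger(__name__)

__all__ = [
    "ClanStatus",
    "ClanSet",
    "GeneFamilyRecord",
    "ViolationReport",
    "ClanConfigError",
    "load_clans",
    "check_family",
    "filter_families",
    "informativeness_filter",
    "support_spectrum",
]


class ClanConfigError(ValueError):
    """Invalid clan definition file (duplicate names, singleton clans, ...)."""


class ClanStatus(str, Enum):
    PASS = "pass"
    VIOLATED = "violated"
    UNTESTABLE = "untestable"


@dataclass(frozen=True)
class ClanSet:
    """Ordered, named taxon groups asserted incontestable."""

    clans: Tuple[Tuple[str, FrozenSet[str]], ...]

    def __post_init__(self):
        names = [n for n, _ in self.clans]
        if len(names) != len(set(names)):
            raise ClanConfigError("duplicate clan names")
        for name, taxa in self.clans:
            if len(taxa) < 2:
                raise ClanConfigError(f"clan {name!r} has fewer than 2 taxa")

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, Iterable[str]]]) -> "ClanSet":
        return cls(tuple((name, frozenset(taxa)) for name, taxa in pairs))

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(n for n, _ in self.clans)

    def __len__(self) -> int:
        return len(self.clans)

    def __iter__(self):
        return iter(self.clans)


@dataclass
class GeneFamilyRecord:
    """One gene family: its unrooted tree plus optional alignment."""

    family_id: str
    tree: UnrootedTree
    species_map: SpeciesMap
    alignment: Optional[object] = None

    @property
    def taxa(self) -> FrozenSet[str]:
        return frozenset(self.species_map.taxon_of(l) for l in self.tree.leaves)


@dataclass
class ViolationReport:
    family_id: str
    status: Dict[str, ClanStatus]
    verdict: str = field(init=False)

    def __post_init__(self):
        self.verdict = (
            "remove" if any(s is ClanStatus.VIOLATED for s in self.status.values()) else "keep"
        )

    @property
    def violated_clans(self) -> List[str]:
        return [c for c, s in self.status.items() if s is ClanStatus.VIOLATED]


def load_clans(path, known_taxa: Optional[Iterable[str]] = None) -> ClanSet:
    """Read a clan config: ``clan_name<TAB>taxon1,taxon2,...`` per line.

    Lines starting with ``#`` are skipped.  Taxa not in ``known_taxa`` (when
    given) are retained with a warning — they simply come up absent at test
    time.
    """
    pairs: List[Tuple[str, FrozenSet[str]]] = []
    known = frozenset(known_taxa) if known_taxa is not None else None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                name, taxa_field = line.split("\t")[:2]
            except ValueError:
                raise ClanConfigError(f"{path}:{lineno}: expected 'name<TAB>taxa'") from None
            taxa = frozenset(t.strip() for t in taxa_field.split(",") if t.strip())
            if known is not None:
                unknown = taxa - known
                if unknown:
                    logger.warning(
                        "clan %r references unknown taxa (kept, will test as absent): %s",
                        name, sorted(unknown),
                    )
            pairs.append((name, taxa))
    return ClanSet.from_pairs(pairs)


def check_family(
    record: GeneFamilyRecord,
    clans: ClanSet,
    tolerance: int = 0,
) -> ViolationReport:
    """Evaluate every clan against one single-copy gene family.

    ``tolerance`` is the number of present clan members that may be dropped
    to rescue an otherwise violated clan; the default 0 removes on any
    failure, which is the decision rule the filter is built around.
    """
    if not treeio.is_single_copy(record.tree, record.species_map):
        raise ValueError(
            f"family {record.family_id!r} is multicopy; "
            "run prune_species_duplicates / is_single_copy screening first"
        )
    status: Dict[str, ClanStatus] = {}
    for name, taxa in clans:
        if not treeio.clan_testable(record.tree, taxa, record.species_map):
            status[name] = ClanStatus.UNTESTABLE
        elif treeio.is_clan(record.tree, taxa, record.species_map):
            status[name] = ClanStatus.PASS
        elif tolerance > 0 and _rescuable(record, taxa, tolerance):
            status[name] = ClanStatus.PASS
        else:
            status[name] = ClanStatus.VIOLATED
    return ViolationReport(record.family_id, status)


def _rescuable(record: GeneFamilyRecord, taxa: FrozenSet[str], tolerance: int) -> bool:
    present = frozenset(t for t in record.taxa if t in taxa)
    for k in range(1, min(tolerance, len(present) - 2) + 1):
        for dropped in itertools.combinations(sorted(present), k):
            if treeio.is_clan(record.tree, present - set(dropped), record.species_map):
                return True
    return False


def filter_families(
    records: Sequence[GeneFamilyRecord],
    clans: ClanSet,
    tolerance: int = 0,
) -> Tuple[List[GeneFamilyRecord], List[GeneFamilyRecord], pd.DataFrame]:
    """Partition families into kept / removed, with a full per-clan report.

    The report covers kept families too, so the table doubles as the
    which-clans-were-violated overview.  Input order is preserved and
    ``len(kept) + len(removed) == len(records)``.
    """
    kept: List[GeneFamilyRecord] = []
    removed: List[GeneFamilyRecord] = []
    rows = []
    for rec in records:
        rep = check_family(rec, clans, tolerance=tolerance)
        row = {"family_id": rec.family_id}
        row.update({name: rep.status[name].value for name in clans.names})
        row["verdict"] = rep.verdict
        rows.append(row)
        (kept if rep.verdict == "keep" else removed).append(rec)
    columns = ["family_id", *clans.names, "verdict"]
    report = pd.DataFrame(rows, columns=columns)
    return kept, removed, report


def informativeness_filter(
    records: Sequence[GeneFamilyRecord],
    required_groups: Iterable[str],
    min_taxa: int = 6,
) -> List[GeneFamilyRecord]:
    """Keep families able to address the question: enough taxa, all groups.

    A family passes when it spans at least ``min_taxa`` distinct taxa and
    contains at least one taxon from every required group (e.g. one anuran,
    one salamander, one caecilian and one outgroup; the default minimum of
    six taxa matches the curation rule this screen mirrors).
    """
    if min_taxa < 1:
        raise ValueError("min_taxa must be >= 1")
    required = list(required_groups)
    kept = []
    for rec in records:
        for g in required:
            rec.species_map.taxa_in_group(g)  # raises MappingError on unknown group
        groups_present = {rec.species_map.group_of(t) for t in rec.taxa}
        if len(rec.taxa) >= min_taxa and all(g in groups_present for g in required):
            kept.append(rec)
    return kept


def support_spectrum(
    records: Sequence[GeneFamilyRecord],
    ingroups: Tuple[str, str, str],
    outgroup: str,
) -> Dict[str, int]:
    """Tally which rooted triplet each gene tree supports.

    Returns counts keyed by ``"A+B"`` style sorted group pairs plus
    ``"unresolved"``; counts sum to ``len(records)``.  This is a topology
    classification of the gene trees themselves, not a site-likelihood test.
    """
    g1, g2, g3 = ingroups
    keys = ["+".join(sorted(p)) for p in itertools.combinations((g1, g2, g3), 2)]
    tally = {k: 0 for k in keys}
    tally["unresolved"] = 0
    for rec in records:
        pair = treeio.classify_triplet(rec.tree, ingroups, outgroup, rec.species_map)
        tally["+".join(sorted(pair)) if pair is not None else "unresolved"] += 1
    return tally
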