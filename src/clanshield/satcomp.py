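"""Alignment-level curation screens: saturation and compositional bias.

The saturation screen builds two neighbor-joining trees per amino-acid
alignment — one from uncorrected p-distances, one from multiple-hit-corrected
distances — and compares their total branch lengths.  Corrected distances
grow much faster than p-distances once sites start being hit repeatedly, so
the ratio of the two sums rises with saturation; families whose ratio is an
outlier are flagged.

The compositional screen asks, per taxon, whether its amino-acid usage is
consistent with the alignment-wide frequencies (chi-square), reporting the
fraction of taxa failing at a chosen significance level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .treeio import UnrootedTree, parse_newick

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentBlock",
    "DistanceMatrix",
    "p_distance",
    "corrected_distance",
    "P_MAX",
    "nj_tree",
    "saturation_stat",
    "flag_saturated",
    "composition_test",
    "read_fasta_alignment",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_IGNORED = {"-", "X", "x", "?", "*", "."}

# domain bound of Kimura's protein correction: 1 - p - 0.2 p^2 > 0
P_MAX = (math.sqrt(1.8) - 1.0) / 0.4


@dataclass(frozen=True)
class AlignmentBlock:
    """An amino-acid alignment: equal-length sequences with gap '-'.

    'X' (unknown residue) and '-' are excluded from all statistics.
    """

    labels: Tuple[str, ...]
    sequences: Tuple[str, ...]

    def __post_init__(self):
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences differ in count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")

    @property
    def n_sequences(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, str]]) -> "AlignmentBlock":
        labels, seqs = zip(*pairs) if pairs else ((), ())
        return cls(tuple(labels), tuple(s.upper() for s in seqs))


def read_fasta_alignment(path) -> AlignmentBlock:
    """Read an aligned FASTA file into an :class:`AlignmentBlock`."""
    from Bio import SeqIO

    pairs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not pairs:
        raise ValueError(f"no sequences in {path}")
    return AlignmentBlock.from_pairs(pairs)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances over labels, zero diagonal."""

    labels: Tuple[str, ...]
    values: np.ndarray  # (n, n) float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.isfinite(v).all():
            raise ValueError("distances must be finite")
        object.__setattr__(self, "values", v)


def _comparable_mask(a: str, b: str) -> List[int]:
    return [i for i in range(len(a)) if a[i] not in _IGNORED and b[i] not in _IGNORED]


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites among pairwise-comparable sites.

    Sites where either sequence has a gap or 'X' are excluded (pairwise
    deletion); with no comparable sites the distance is 0 with a warning.
    """
    if len(a) != len(b):
        raise ValueError(f"sequence length mismatch: {len(a)} vs {len(b)}")
    a, b = a.upper(), b.upper()
    sites = _comparable_mask(a, b)
    if not sites:
        logger.warning("no comparable sites between sequences; p-distance set to 0")
        return 0.0
    diffs = sum(1 for i in sites if a[i] != b[i])
    return diffs / len(sites)


def corrected_distance(p: float, cap: float = 5.0) -> float:
    """Multiple-hit-corrected protein distance, d = -ln(1 - p - 0.2 p^2).

    Kimura's empirical correction for amino-acid sequences: d >= p on the
    whole domain and diverges as p approaches ~0.854.  Beyond the domain the
    pair is saturated; the distance is set to ``cap`` (the caller should
    record the pair — saturation is what the screen looks for).
    """
    if p < 0:
        raise ValueError("p-distance must be non-negative")
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0:
        return cap
    return -math.log(arg)


def _pairwise_matrices(
    aln: AlignmentBlock, cap: float = 5.0
) -> Tuple[DistanceMatrix, DistanceMatrix, List[Tuple[str, str]]]:
    n = aln.n_sequences
    pmat = np.zeros((n, n))
    cmat = np.zeros((n, n))
    saturated: List[Tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(aln.sequences[i], aln.sequences[j])
            d = corrected_distance(p, cap=cap)
            if p >= P_MAX:
                saturated.append((aln.labels[i], aln.labels[j]))
            pmat[i, j] = pmat[j, i] = p
            cmat[i, j] = cmat[j, i] = d
    return (
        DistanceMatrix(aln.labels, pmat),
        DistanceMatrix(aln.labels, cmat),
        saturated,
    )


def nj_tree(d: DistanceMatrix) -> UnrootedTree:
    """Saitou–Nei neighbor joining; exact on additive matrices.

    Negative branch-length estimates are clamped to zero with the deficit
    logged.  Delegates the agglomeration to scikit-bio.
    """
    if len(d.labels) < 3:
        raise ValueError("neighbor joining requires at least 3 labels")
    sk_dm = _SkbioDM(d.values, ids=list(d.labels))
    raw = _skbio_nj(sk_dm, neg_as_zero=False)
    deficit = sum(
        -node.length for node in raw.traverse() if node.length is not None and node.length < 0
    )
    if deficit > 0:
        logger.info("clamped negative NJ branch lengths (total deficit %.4g)", deficit)
        for node in raw.traverse():
            if node.length is not None and node.length < 0:
                node.length = 0.0
    return parse_newick(str(raw))


def _total_branch_length(tree: UnrootedTree) -> float:
    return math.fsum((ln or 0.0) for _, _, ln in tree.edges())


def saturation_stat(aln: AlignmentBlock, cap: float = 5.0) -> Tuple[float, float, float]:
    """(sum of p-distance NJ branch lengths, corrected sum, their ratio).

    The ratio ``sum_corrected / sum_p`` is the per-family saturation
    statistic (1.0 when the alignment is invariant, growing with
    divergence); saturated pairs enter the corrected matrix at ``cap``.
    """
    if aln.n_sequences < 3:
        raise ValueError("saturation statistic requires at least 3 sequences")
    pdm, cdm, saturated = _pairwise_matrices(aln, cap=cap)
    if saturated:
        logger.warning("%d saturated pair(s), capped at %g: %s", len(saturated), cap, saturated[:5])
    if not pdm.values.any():
        return 0.0, 0.0, 1.0
    sum_p = _total_branch_length(nj_tree(pdm))
    sum_c = _total_branch_length(nj_tree(cdm))
    ratio = sum_c / sum_p if sum_p > 0 else 1.0
    return sum_p, sum_c, ratio


def flag_saturated(
    stats_by_family: Mapping[str, Tuple[float, float, float]],
    k: float = 5.0,
    ratio_cap: float = 3.0,
) -> List[str]:
    """Flag families whose saturation ratio is an outlier.

    A family is flagged when its ratio exceeds ``median + k * MAD`` across
    families, or exceeds the absolute ``ratio_cap``.  This replaces a
    by-eye inspection with an explicit, reproducible rule; both knobs can be
    set to ``inf`` to disable either arm.
    """
    if len(stats_by_family) < 5:
        raise ValueError("robust outlier rule needs at least 5 families")
    ratios = {fam: s[2] for fam, s in stats_by_family.items()}
    vals = np.array(list(ratios.values()))
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    threshold = med + k * mad if math.isfinite(k) else math.inf
    return sorted(
        fam for fam, r in ratios.items() if r > threshold or r > ratio_cap
    )


def composition_test(
    aln: AlignmentBlock, alpha: float = 0.05
) -> Tuple[Dict[str, float], float]:
    """Per-taxon compositional-heterogeneity chi-square test.

    Each taxon's amino-acid counts (gaps and X excluded) are tested against
    the alignment-wide residue frequencies; degrees of freedom are the
    number of states observed alignment-wide minus one.  Returns
    ``(p_values, fraction_failing)`` where the fraction is the share of
    testable taxa with p < alpha.  Taxa without comparable sites are
    excluded with a warning.
    """
    if aln.n_sequences < 2:
        raise ValueError("composition test requires at least 2 sequences")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    counts = np.zeros((aln.n_sequences, len(AMINO_ACIDS)))
    for row, seq in enumerate(aln.sequences):
        for ch in seq:
            idx = aa_index.get(ch)
            if idx is not None:
                counts[row, idx] += 1
    global_counts = counts.sum(axis=0)
    observed_states = global_counts > 0
    if not observed_states.any():
        raise ValueError("alignment contains no scorable residues")
    global_freq = global_counts[observed_states] / global_counts[observed_states].sum()
    p_values: Dict[str, float] = {}
    for row, label in enumerate(aln.labels):
        row_counts = counts[row, observed_states]
        total = row_counts.sum()
        if total == 0:
            logger.warning("taxon %r has no scorable sites; excluded from composition test", label)
            continue
        expected = global_freq * total
        statistic = float(((row_counts - expected) ** 2 / expected).sum())
        df = int(observed_states.sum()) - 1
        p_values[label] = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    failing = sum(1 for p in p_values.values() if p < alpha)
    fraction = failing / len(p_values) if p_values else 0.0
    return p_values, fraction
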