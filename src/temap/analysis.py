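"""Statistical comparisons and consensus-coordinate analyses.

Covers three questions asked of locus-level mappability: do two groups of
loci (e.g. young vs old copies of a subfamily) differ in mean percent
unique (two-sided permutation test on the difference of group means); how
does mappability vary along the subfamily consensus once each locus is
mapped onto consensus coordinates (median/quartile profile with locus
depth); and which sub-clade a locus belongs to, read off diagnostic bases
at fixed consensus positions (e.g. the 3' UTR trinucleotide ACA for
L1HS-Ta vs ACG for L1HS-preTa).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from .io_formats import MappabilityTrack, TELocus
from .mapcore import revcomp
from .synthgenome import GAP

__all__ = [
    "PermutationResult",
    "ConsensusProfile",
    "permutation_test",
    "align_to_consensus",
    "consensus_profile",
    "classify_subclade",
    "locus_scores_oriented",
]


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationResult:
    """Two-sided permutation test on a difference of group means."""

    obs_diff: float
    n_perm: int
    p_value: float
    seed: int | None
    exact: bool


def permutation_test(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 9999,
    seed: int = 0,
    *,
    exact: bool | None = None,
    exact_cap: int = 20000,
) -> PermutationResult:
    """Two-sided test of mean(a) - mean(b) by label permutation.

    Labels are shuffled over the pooled values preserving group sizes. In
    sampled mode the add-one rule gives p = (1 + #{|perm| >= |obs|}) /
    (n_perm + 1), so the smallest attainable p is 1/(n_perm + 1) and p = 0
    is impossible. When the number of distinct label splits C(n, |a|) is at
    most ``exact_cap`` (or ``exact=True``), all splits are enumerated and p
    is the exact fraction with |perm| >= |obs|; the observed split is one of
    them, so p >= 1/C(n, |a|).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    na, n = a.size, a.size + b.size
    obs = float(a.mean() - b.mean())
    # tolerance guards against FP noise in "|perm| >= |obs|" at ties
    eps = 1e-9 * max(1.0, abs(obs))
    total_splits = math.comb(n, na)
    if exact is None:
        exact = total_splits <= exact_cap
    pooled_sum = pooled.sum()
    if exact:
        count = 0
        for idx in itertools.combinations(range(n), na):
            sa = pooled[list(idx)].sum()
            diff = sa / na - (pooled_sum - sa) / (n - na)
            if abs(diff) >= abs(obs) - eps:
                count += 1
        return PermutationResult(obs, total_splits, count / total_splits, None, True)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        diff = perm[:na].mean() - perm[na:].mean()
        if abs(diff) >= abs(obs) - eps:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return PermutationResult(obs, n_perm, p, seed, False)


# ---------------------------------------------------------------------------
# Consensus alignment and coordinate maps
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    # free end gaps on the consensus (target) only: the locus is aligned in
    # full, consensus overhangs cost nothing (semi-global); unaligned target
    # termini are "end deletions" in PairwiseAligner naming
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


def align_to_consensus(
    locus_seq: str,
    consensus: str,
    *,
    min_score: float | None = None,
) -> np.ndarray | None:
    """Map each locus position to its consensus coordinate (or GAP).

    Semi-global alignment with free end gaps on the consensus; scores are
    match +1, mismatch -1, gap open -5 (first gapped base), gap extend -1.
    Ties resolve deterministically to the first (leftmost) optimal
    alignment. Returns None (unalignable) when the optimal score falls
    below ``min_score``.
    """
    if not locus_seq or not consensus:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner()
    alignments = aligner.align(consensus, locus_seq)
    best = alignments[0]
    if min_score is not None and best.score < min_score:
        return None
    coord_map = np.full(len(locus_seq), GAP, dtype=np.int64)
    target_blocks, query_blocks = best.aligned
    for (ts, te), (qs, qe) in zip(target_blocks, query_blocks):
        coord_map[qs:qe] = np.arange(ts, te)
    return coord_map


def locus_scores_oriented(track: MappabilityTrack, locus: TELocus) -> np.ndarray:
    """Per-position scores of a locus in element (5'->3') orientation.

    Scores sit on + strand start coordinates; for - strand loci the vector
    is reversed so index i corresponds to base i of the element sequence.
    """
    arr = track[locus.chrom][locus.start : locus.end]
    return arr[::-1].copy() if locus.strand == "-" else arr.copy()


def oriented_sequence(genome_seq: str, locus: TELocus) -> str:
    """Locus sequence in element orientation (revcomp for - strand)."""
    sub = genome_seq[locus.start : locus.end]
    return revcomp(sub) if locus.strand == "-" else sub


# ---------------------------------------------------------------------------
# Consensus profile
# ---------------------------------------------------------------------------

@dataclass
class ConsensusProfile:
    """Median/quartile mappability and locus depth per consensus position.

    Quartiles use linear interpolation; positions covered by no locus hold
    NaN with depth 0.
    """

    median: np.ndarray
    q1: np.ndarray
    q3: np.ndarray
    depth: np.ndarray

    def __len__(self) -> int:
        return len(self.median)


def consensus_profile(
    score_vectors: Sequence[np.ndarray],
    coord_maps: Sequence[np.ndarray],
    consensus_length: int,
) -> ConsensusProfile:
    """Pool per-locus scores onto consensus coordinates.

    ``score_vectors[i][j]`` is the score of locus i at element position j
    (NaN where undefined); ``coord_maps[i][j]`` its consensus coordinate or
    GAP. Depth counts loci contributing at least one defined score to the
    position.
    """
    if len(score_vectors) != len(coord_maps):
        raise ValueError("need one coordinate map per score vector")
    pools: list[list[float]] = [[] for _ in range(consensus_length)]
    depth = np.zeros(consensus_length, dtype=np.int64)
    for scores, cmap in zip(score_vectors, coord_maps):
        if len(scores) != len(cmap):
            raise ValueError("score vector and coordinate map length mismatch")
        seen = np.zeros(consensus_length, dtype=bool)
        for j, c in enumerate(cmap):
            if c == GAP:
                continue
            v = scores[j]
            if np.isnan(v):
                continue
            pools[c].append(float(v))
            seen[c] = True
        depth += seen
    median = np.full(consensus_length, np.nan)
    q1 = np.full(consensus_length, np.nan)
    q3 = np.full(consensus_length, np.nan)
    for c, vals in enumerate(pools):
        if vals:
            q1[c], median[c], q3[c] = np.percentile(vals, [25, 50, 75])
    return ConsensusProfile(median, q1, q3, depth)


# ---------------------------------------------------------------------------
# Sub-clade classification
# ---------------------------------------------------------------------------

def classify_subclade(
    coord_map: np.ndarray,
    locus_seq: str,
    diagnostic: tuple[Sequence[int], Mapping[str, str]],
) -> str:
    """Read diagnostic consensus positions off a locus and label it.

    ``diagnostic`` is (consensus positions, variant -> label table), e.g.
    ((c1, c2, c3), {"ACA": "Ta", "ACG": "preTa"}). Returns "unclassified"
    when any diagnostic site is truncated away, gapped, or the observed
    variant is not in the table.
    """
    positions, table = diagnostic
    if not table:
        raise ValueError("diagnostic table must be non-empty")
    inverse: dict[int, int] = {}
    for j, c in enumerate(coord_map):
        if c != GAP:
            inverse[int(c)] = j
    bases = []
    for c in positions:
        j = inverse.get(int(c))
        if j is None:
            return "unclassified"
        bases.append(locus_seq[j])
    return table.get("".join(bases), "unclassified")
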