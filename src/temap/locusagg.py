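"""Locus-level aggregation of per-position mappability.

A TE locus is scored over the read/fragment start positions that fall
inside its interval; reads may extend past the locus end. UNDEFINED
positions (N windows, chromosome edge) are excluded from both numerator and
denominator — those reads never existed in the simulated libraries. The
locus-level call is deliberately conservative: a locus is uniquely mappable
only when *every* defined start position has score exactly 1, which also
prevents inflation from unique flanking sequence since the whole interval
must pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import MappabilityTrack, TELocus

__all__ = [
    "LocusScore",
    "SubfamilySummary",
    "score_locus",
    "score_loci",
    "summarize",
    "compare_libraries",
    "filter_for_comparison",
]


@dataclass(frozen=True)
class LocusScore:
    """Aggregate mappability of one TE locus.

    percent_unique and mean_score are None when the locus has no defined
    start positions; is_unique then reports False.
    """

    locus: TELocus
    n_positions: int
    n_unique: int
    percent_unique: float | None
    is_unique: bool
    mean_score: float | None

    @property
    def locus_id(self) -> str:
        return self.locus.locus_id


@dataclass(frozen=True)
class SubfamilySummary:
    """Per-subfamily rollup: copy number and uniqueness percentages.

    avg_percent_unique averages per-locus percent_unique over loci that
    have defined positions.
    """

    subfamily: str
    family: str
    te_class: str
    copy_number: int
    n_unique_loci: int
    percent_loci_unique: float
    avg_percent_unique: float | None


def score_locus(track: MappabilityTrack, locus: TELocus) -> LocusScore:
    """Score one locus over defined start positions inside its interval."""
    if locus.chrom not in track:
        raise ValueError(f"track has no chromosome {locus.chrom!r}")
    arr = track[locus.chrom]
    if locus.end > len(arr):
        raise ValueError(
            f"locus {locus.locus_id!r} extends past chromosome "
            f"({locus.end} > {len(arr)})"
        )
    window = arr[locus.start : locus.end]
    defined = window[~np.isnan(window)]
    n_pos = int(defined.size)
    if n_pos == 0:
        return LocusScore(locus, 0, 0, None, False, None)
    n_unique = int((defined == 1.0).sum())
    return LocusScore(
        locus,
        n_pos,
        n_unique,
        100.0 * n_unique / n_pos,
        n_unique == n_pos,
        float(defined.mean()),
    )


def score_loci(track: MappabilityTrack, loci: Sequence[TELocus]) -> list[LocusScore]:
    """Score every locus; output ordered by (chrom, start)."""
    return [
        score_locus(track, loc)
        for loc in sorted(loci, key=lambda l: (l.chrom, l.start, l.locus_id))
    ]


def _rollup(rows: list[dict], by: list[str]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    grouped = (
        df.groupby(by, as_index=False)
        .agg(
            copy_number=("locus_id", "size"),
            n_unique_loci=("is_unique", "sum"),
            avg_percent_unique=("percent_unique", "mean"),
        )
        .sort_values(by)
        .reset_index(drop=True)
    )
    grouped["percent_loci_unique"] = (
        100.0 * grouped["n_unique_loci"] / grouped["copy_number"]
    )
    return grouped


def summarize(
    scores: Sequence[LocusScore],
) -> tuple[list[SubfamilySummary], pd.DataFrame, pd.DataFrame]:
    """Group locus scores by subfamily, with family- and class-level rollups.

    Returns (subfamily summaries, family DataFrame, class DataFrame); all
    three sorted by (te_class, family, subfamily) prefix for reproducible
    output. percent_loci_unique = 100 * unique loci / copy number.
    """
    if not scores:
        return [], pd.DataFrame(), pd.DataFrame()
    rows = [
        {
            "locus_id": s.locus_id,
            "subfamily": s.locus.subfamily,
            "family": s.locus.family,
            "te_class": s.locus.te_class,
            "is_unique": s.is_unique,
            "percent_unique": s.percent_unique,
        }
        for s in scores
    ]
    sub_df = _rollup(rows, ["te_class", "family", "subfamily"])
    fam_df = _rollup(rows, ["te_class", "family"])
    cls_df = _rollup(rows, ["te_class"])
    subs = [
        SubfamilySummary(
            subfamily=r.subfamily,
            family=r.family,
            te_class=r.te_class,
            copy_number=int(r.copy_number),
            n_unique_loci=int(r.n_unique_loci),
            percent_loci_unique=float(r.percent_loci_unique),
            avg_percent_unique=(
                None if pd.isna(r.avg_percent_unique) else float(r.avg_percent_unique)
            ),
        )
        for r in sub_df.itertuples()
    ]
    return subs, fam_df, cls_df


def _as_map(scores: Sequence[LocusScore]) -> dict[str, LocusScore]:
    return {s.locus_id: s for s in scores}


def compare_libraries(
    score_sets: Mapping[str, Sequence[LocusScore]],
) -> pd.DataFrame:
    """Per-locus percent_unique differences between named score sets.

    For every ordered pair of set names (A, B) the column ``A_minus_B``
    holds percent_unique(A) - percent_unique(B) per locus (NaN where either
    side is undefined). All sets must cover the identical locus set.
    """
    names = list(score_sets)
    maps = {name: _as_map(score_sets[name]) for name in names}
    ref_ids = set(maps[names[0]])
    for name in names[1:]:
        missing = ref_ids.symmetric_difference(maps[name])
        if missing:
            raise ValueError(
                f"score set {name!r} locus mismatch: {sorted(missing)[:10]}"
            )
    some = score_sets[names[0]]
    ordered = [
        s.locus_id
        for s in sorted(some, key=lambda s: (s.locus.chrom, s.locus.start, s.locus_id))
    ]
    data: dict[str, list] = {"locus_id": ordered}
    for a in names:
        data[a] = [
            np.nan if maps[a][i].percent_unique is None else maps[a][i].percent_unique
            for i in ordered
        ]
    df = pd.DataFrame(data)
    for a in names:
        for b in names:
            if a != b:
                df[f"{a}_minus_{b}"] = df[a] - df[b]
    return df


def filter_for_comparison(
    loci: Sequence[TELocus],
    paired_score_sets: Mapping[str, Sequence[LocusScore]],
    min_len: int = 300,
) -> list[TELocus]:
    """Exclusion filter for paired-vs-single comparisons.

    Drops loci shorter than ``min_len`` and loci at which every paired-end
    library already reaches 100% unique — both are uninformative when
    looking for the positions where library geometry changes the call.
    """
    maps = {name: _as_map(s) for name, s in paired_score_sets.items()}
    kept: list[TELocus] = []
    for loc in loci:
        if loc.length < min_len:
            continue
        percents = [
            maps[name][loc.locus_id].percent_unique
            for name in maps
            if loc.locus_id in maps[name]
        ]
        if percents and all(p is not None and p == 100.0 for p in percents):
            continue
        kept.append(loc)
    return kept
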