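"""On-disk formats and core domain containers.

Reads and writes everything the toolkit touches on disk: FASTA genomes,
RepeatMasker ``.out`` / BED6+ transposable-element annotations, bedGraph and
fixedStep-wiggle mappability tracks, and TSV locus-score tables.

All internal coordinates are 0-based half-open; conversions to and from
1-based conventions (RepeatMasker, wiggle) happen only at the parse /
serialize boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Genome",
    "TELocus",
    "MappabilityTrack",
    "UNDEFINED",
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "write_annotation_bed",
    "write_track",
    "read_track",
    "write_locus_table",
    "read_locus_table",
]

#: Sentinel for positions whose read/fragment window leaves the chromosome or
#: contains N: stored as NaN in track arrays.
UNDEFINED = float("nan")

_ALPHABET = set("ACGTN")
_IUPAC_AMBIGUOUS = set("RYSWKMBDHVU")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    """Named chromosome sequences over {A, C, G, T, N}.

    ``sequences`` preserves insertion order; lengths are derived.
    """

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("genome must contain at least one sequence")
        for name, seq in self.sequences.items():
            if not name:
                raise ValueError("empty chromosome name")
            if not seq:
                raise ValueError(f"empty sequence for {name!r}")
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValueError(
                    f"sequence {name!r} contains non-ACGTN symbols: {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]


@dataclass(frozen=True)
class TELocus:
    """One annotated repeat interval (one RepeatMasker row).

    ``start``/``end`` are 0-based half-open. ``subfamily``/``family``/
    ``te_class`` carry the nested repeat taxonomy (e.g. L1HS / L1 / LINE).
    """

    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    family: str
    te_class: str
    locus_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.locus_id!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MappabilityTrack:
    """Per-chromosome arrays of mappability scores.

    Each array spans the full chromosome and holds, at index ``p``, the score
    of the read (or fragment) starting at ``p`` — a value ``1/n`` for a
    positive integer ``n`` — or NaN (:data:`UNDEFINED`) where the window runs
    off the chromosome or contains N. ``params`` records the scoring
    parameters used (a :class:`temap.mapcore.MapParams` in practice).
    """

    scores: dict[str, np.ndarray]
    params: object = None

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.scores[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.scores

    def defined_mask(self, chrom: str) -> np.ndarray:
        return ~np.isnan(self.scores[chrom])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, *, ambiguous: str = "error") -> Genome:
    """Read a multi-record FASTA into a :class:`Genome`.

    Sequences are uppercased. IUPAC ambiguity codes other than N are rejected
    (``ambiguous="error"``, the default) or mapped to N (``ambiguous="to_n"``).
    Empty files and duplicate record names are hard errors.
    """
    if ambiguous not in ("error", "to_n"):
        raise ValueError("ambiguous must be 'error' or 'to_n'")
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in sequences:
            raise ValueError(f"duplicate FASTA record name {name!r}")
        seq = str(record.seq).upper()
        extra = set(seq) - _ALPHABET
        if extra:
            if ambiguous == "to_n" and extra <= _IUPAC_AMBIGUOUS:
                seq = "".join(c if c in _ALPHABET else "N" for c in seq)
            else:
                raise ValueError(
                    f"record {name!r} contains unsupported symbols: {sorted(extra)}"
                )
        sequences[name] = seq
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(sequences)


def write_fasta(genome: Genome, path: str | Path, *, width: int = 70) -> None:
    """Write a :class:`Genome` as multi-record FASTA (fixed line width)."""
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotations: RepeatMasker .out and BED6+
# ---------------------------------------------------------------------------

def _split_class_family(label: str) -> tuple[str, str]:
    # RepeatMasker "class/family" column, e.g. "LINE/L1"; a bare class
    # (e.g. "Simple_repeat") doubles as its own family.
    if "/" in label:
        te_class, family = label.split("/", 1)
    else:
        te_class = family = label
    return te_class, family


def read_annotation(
    path: str | Path,
    dialect: str = "repeatmasker_out",
    *,
    genome: Genome | None = None,
    keep_overlapping: bool = True,
) -> list[TELocus]:
    """Parse a TE annotation file into a list of :class:`TELocus`.

    ``dialect="repeatmasker_out"`` reads the RepeatMasker ``.out`` format:
    1-based inclusive begin/end converted to 0-based half-open, strand ``C``
    mapped to ``-``, the class/family column split on ``/``. Rows flagged
    with a trailing ``*`` (overlapped by a higher-scoring match) are kept by
    default; pass ``keep_overlapping=False`` to drop them.

    ``dialect="bed"`` reads BED6+ with ``subfamily:family:class`` packed in
    the name column (a bare name is taken as the subfamily with family and
    class repeating it).

    If ``genome`` is supplied, coordinates exceeding the chromosome are a
    hard error listing every offending locus.
    """
    if dialect not in ("repeatmasker_out", "bed"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    loci: list[TELocus] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if dialect == "repeatmasker_out":
                fields = line.split()
                # header lines: "SW score", "score div ..." or blank
                if not fields[0].replace(".", "").isdigit():
                    continue
                if len(fields) < 15:
                    raise ValueError(f"{path}:{lineno}: truncated RepeatMasker row")
                chrom = fields[4]
                start = int(fields[5]) - 1  # 1-based inclusive -> 0-based
                end = int(fields[6])
                strand = "-" if fields[8] in ("C", "-") else "+"
                subfamily = fields[9]
                te_class, family = _split_class_family(fields[10])
                rm_id = fields[14]
                overlapped = len(fields) > 15 and fields[15] == "*"
                if overlapped and not keep_overlapping:
                    continue
                locus_id = f"{subfamily}_{rm_id}_{chrom}_{start}"
            else:
                fields = line.split()
                if fields[0] in ("track", "browser", "#"):
                    continue
                if len(fields) < 6:
                    raise ValueError(f"{path}:{lineno}: BED6+ requires 6 columns")
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                name = fields[3]
                strand = fields[5]
                parts = name.split(":")
                if len(parts) >= 3:
                    subfamily, family, te_class = parts[0], parts[1], parts[2]
                    locus_id = ":".join(parts[3:]) if len(parts) > 3 else (
                        f"{subfamily}_{chrom}_{start}"
                    )
                else:
                    subfamily = family = te_class = parts[0]
                    locus_id = f"{subfamily}_{chrom}_{start}"
            if locus_id in seen_ids:
                raise ValueError(f"{path}:{lineno}: duplicate locus_id {locus_id!r}")
            seen_ids.add(locus_id)
            loci.append(
                TELocus(chrom, start, end, strand, subfamily, family, te_class, locus_id)
            )
    if genome is not None:
        offenders = [
            loc.locus_id
            for loc in loci
            if loc.chrom not in genome or loc.end > len(genome[loc.chrom])
        ]
        if offenders:
            raise ValueError(
                "loci exceed genome bounds: " + ", ".join(sorted(offenders))
            )
    return loci


def write_annotation_bed(loci: Sequence[TELocus], path: str | Path) -> None:
    """Write loci as BED6 with ``subfamily:family:class:locus_id`` names."""
    with open(path, "w") as fh:
        for loc in sorted(loci, key=lambda l: (l.chrom, l.start, l.end)):
            name = f"{loc.subfamily}:{loc.family}:{loc.te_class}:{loc.locus_id}"
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{name}\t0\t{loc.strand}\n"
            )


# ---------------------------------------------------------------------------
# Mappability tracks: bedGraph / fixedStep wiggle
# ---------------------------------------------------------------------------

def _score_runs(arr: np.ndarray) -> Iterable[tuple[int, int, float]]:
    """Yield maximal (start, end, score) runs of equal defined score."""
    n = len(arr)
    i = 0
    while i < n:
        v = arr[i]
        if math.isnan(v):
            i += 1
            continue
        j = i + 1
        while j < n and (not math.isnan(arr[j])) and arr[j] == v:
            j += 1
        yield i, j, float(v)
        i = j


def write_track(
    track: MappabilityTrack,
    path: str | Path,
    format: str = "bedgraph",
    *,
    name: str = "mappability",
) -> None:
    """Serialize a track as bedGraph or fixedStep wiggle.

    bedGraph intervals are 0-based half-open maximal runs of equal score;
    wiggle blocks are 1-based fixedStep with UNDEFINED runs omitted. Scores
    are printed with ``repr`` so a round-trip read-back reproduces every
    defined score bit-exactly.
    """
    if format not in ("bedgraph", "fixed_step_wiggle"):
        raise ValueError(f"unknown track format {format!r}")
    with open(path, "w") as fh:
        if format == "bedgraph":
            fh.write(f'track type=bedGraph name="{name}"\n')
            for chrom, arr in track.scores.items():
                for start, end, score in _score_runs(arr):
                    fh.write(f"{chrom}\t{start}\t{end}\t{score!r}\n")
        else:
            fh.write(f'track type=wiggle_0 name="{name}"\n')
            for chrom, arr in track.scores.items():
                defined = ~np.isnan(arr)
                i = 0
                n = len(arr)
                while i < n:
                    if not defined[i]:
                        i += 1
                        continue
                    j = i
                    while j < n and defined[j]:
                        j += 1
                    fh.write(f"fixedStep chrom={chrom} start={i + 1} step=1\n")
                    for p in range(i, j):
                        fh.write(f"{float(arr[p])!r}\n")
                    i = j


def read_track(
    path: str | Path,
    lengths: Mapping[str, int],
    *,
    params: object = None,
) -> MappabilityTrack:
    """Parse a bedGraph or wiggle file written by :func:`write_track`.

    ``lengths`` supplies chromosome lengths so undefined positions come back
    as NaN. The format is sniffed from the track header.
    """
    scores = {
        chrom: np.full(length, np.nan, dtype=np.float64)
        for chrom, length in lengths.items()
    }
    with open(path) as fh:
        header = fh.readline()
        is_wiggle = "wiggle_0" in header
        if is_wiggle:
            chrom, pos = None, 0
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("fixedStep"):
                    kv = dict(f.split("=") for f in line.split()[1:])
                    chrom = kv["chrom"]
                    pos = int(kv["start"]) - 1
                else:
                    scores[chrom][pos] = float(line)
                    pos += 1
        else:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                chrom, start, end, value = line.split("\t")
                scores[chrom][int(start) : int(end)] = float(value)
    return MappabilityTrack(scores, params=params)


# ---------------------------------------------------------------------------
# Locus tables
# ---------------------------------------------------------------------------

_LOCUS_COLUMNS = [
    "locus_id",
    "chrom",
    "start",
    "end",
    "strand",
    "subfamily",
    "family",
    "te_class",
    "n_positions",
    "n_unique",
    "percent_unique",
    "is_unique",
    "mean_score",
]


def write_locus_table(scores: Sequence, path: str | Path) -> None:
    """Write per-locus scores as a TSV, one row per ``locus_id``.

    Rows are ordered by (chrom, start); percentages and mean scores are
    printed with fixed 4-decimal formatting for deterministic output.
    Duplicate ``locus_id`` values are an error. ``scores`` is a sequence of
    :class:`temap.locusagg.LocusScore`.
    """
    ids = [s.locus_id for s in scores]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate locus_id values: {dupes}")
    rows = []
    for s in sorted(scores, key=lambda s: (s.locus.chrom, s.locus.start)):
        loc = s.locus
        rows.append(
            {
                "locus_id": s.locus_id,
                "chrom": loc.chrom,
                "start": loc.start,
                "end": loc.end,
                "strand": loc.strand,
                "subfamily": loc.subfamily,
                "family": loc.family,
                "te_class": loc.te_class,
                "n_positions": s.n_positions,
                "n_unique": s.n_unique,
                "percent_unique": (
                    "NA" if s.percent_unique is None else f"{s.percent_unique:.4f}"
                ),
                "is_unique": str(s.is_unique),
                "mean_score": (
                    "NA" if s.mean_score is None else f"{s.mean_score:.4f}"
                ),
            }
        )
    pd.DataFrame(rows, columns=_LOCUS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_locus_table(path: str | Path) -> pd.DataFrame:
    """Read a locus-score TSV back as a DataFrame (NA preserved)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
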