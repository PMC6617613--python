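"""Synthetic genomes with planted transposable-element subfamilies.

Generates a random background sequence and plants mutated copies of
user-supplied consensus sequences, emulating the structure that makes real
TE annotations hard to map: subfamilies of varying copy number, per-copy
divergence (an age proxy), 5'-truncated L1-like insertions, and recent
segmental duplications that copy a finished region verbatim. Truth
annotations and per-locus consensus-coordinate maps are returned alongside
the genome so every downstream stage can be validated without external
data.

Mutated copies carry substitutions only — no indels — matching the gapless
Hamming-distance alignment model of the scorer. Truncation is 5'-only
(retaining a 3' suffix), the shape produced by target-primed reverse
transcription that initiates from the 3' end of the L1 RNA and often fails
to reach the 5' end; other TE shapes are approximated by full-length
copies. Copies are placed uniformly without overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .io_formats import Genome, TELocus
from .mapcore import revcomp

__all__ = [
    "SubfamilySpec",
    "SegDupSpec",
    "SimConfig",
    "TruthMap",
    "GAP",
    "simulate_genome",
    "mutate_copy",
    "random_sequence",
    "load_sim_config",
    "write_truth_maps",
]

#: Sentinel in truth maps for locus positions with no consensus coordinate.
GAP = -1

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SubfamilySpec:
    """One planted TE subfamily.

    sub_rate is the per-base substitution probability applied independently
    to every copy (an age proxy: older subfamilies have diverged further
    from their consensus). truncation_5p gives the retained 3' fraction per
    copy: a float (fixed), a (low, high) tuple (uniform draw), or a callable
    rng -> fraction; 1.0 plants full-length copies. strand_prob is the
    probability a copy lands on the + strand.
    """

    name: str
    consensus: str
    copy_number: int
    sub_rate: float = 0.0
    truncation_5p: object = 1.0
    strand_prob: float = 0.5
    family: str = ""
    te_class: str = ""

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if not (0.0 <= self.sub_rate < 1.0):
            raise ValueError("sub_rate must be in [0, 1)")
        if set(self.consensus) - set("ACGT"):
            raise ValueError("consensus must be over {A,C,G,T}")
        if not self.family:
            object.__setattr__(self, "family", self.name)
        if not self.te_class:
            object.__setattr__(self, "te_class", self.name)

    def draw_retained_fraction(self, rng: np.random.Generator) -> float:
        t = self.truncation_5p
        if callable(t):
            frac = float(t(rng))
        elif isinstance(t, (tuple, list)):
            frac = float(rng.uniform(t[0], t[1]))
        else:
            frac = float(t)
        if not (0.0 < frac <= 1.0):
            raise ValueError(f"retained fraction must be in (0, 1], got {frac}")
        return frac


@dataclass(frozen=True)
class SegDupSpec:
    """Duplicate ``n_copies`` verbatim copies of [start, end) after planting."""

    start: int
    end: int
    n_copies: int = 1


@dataclass
class SimConfig:
    """Full description of one simulated genome."""

    background_length: int
    gc_content: float = 0.41
    subfamilies: list[SubfamilySpec] = field(default_factory=list)
    segdups: list[SegDupSpec] = field(default_factory=list)
    seed: int = 0
    chrom_name: str = "chr1"

    def __post_init__(self) -> None:
        if self.background_length <= 0:
            raise ValueError("background_length must be > 0")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")


@dataclass
class TruthMap:
    """Per-locus map from element-oriented position to consensus coordinate.

    ``consensus_coords[i]`` is the consensus position of base ``i`` of the
    locus read 5'->3' in element orientation (reverse-complemented for -
    strand loci), or GAP. With substitution-only mutation the non-gap
    entries are strictly increasing and start at the truncation offset.
    """

    locus_id: str
    subfamily: str
    consensus_coords: np.ndarray


def load_sim_config(path) -> SimConfig:
    """Load a :class:`SimConfig` from a JSON key/value file.

    Schema: top-level keys mirror SimConfig fields; ``subfamilies`` is a
    list of objects with SubfamilySpec fields (``truncation_5p`` a number or
    [low, high] pair); ``segdups`` a list of {start, end, n_copies}.
    """
    import json

    with open(path) as fh:
        raw = json.load(fh)
    subs = [
        SubfamilySpec(
            name=s["name"],
            consensus=s["consensus"],
            copy_number=int(s["copy_number"]),
            sub_rate=float(s.get("sub_rate", 0.0)),
            truncation_5p=(
                tuple(s["truncation_5p"])
                if isinstance(s.get("truncation_5p"), list)
                else float(s.get("truncation_5p", 1.0))
            ),
            strand_prob=float(s.get("strand_prob", 0.5)),
            family=s.get("family", ""),
            te_class=s.get("te_class", ""),
        )
        for s in raw.get("subfamilies", [])
    ]
    dups = [
        SegDupSpec(int(d["start"]), int(d["end"]), int(d.get("n_copies", 1)))
        for d in raw.get("segdups", [])
    ]
    return SimConfig(
        background_length=int(raw["background_length"]),
        gc_content=float(raw.get("gc_content", 0.41)),
        subfamilies=subs,
        segdups=dups,
        seed=int(raw.get("seed", 0)),
        chrom_name=raw.get("chrom_name", "chr1"),
    )


def write_truth_maps(truth: Sequence[TruthMap], path) -> None:
    """TSV of (locus_id, subfamily, locus_pos, consensus_pos) truth rows."""
    with open(path, "w") as fh:
        fh.write("locus_id\tsubfamily\tlocus_pos\tconsensus_pos\n")
        for tm in truth:
            for i, c in enumerate(tm.consensus_coords):
                fh.write(f"{tm.locus_id}\t{tm.subfamily}\t{i}\t{int(c)}\n")


def random_sequence(length: int, gc_content: float, rng: np.random.Generator) -> str:
    """Random i.i.d. sequence with the given GC fraction."""
    at, gc = (1.0 - gc_content) / 2.0, gc_content / 2.0
    draws = rng.choice(4, size=length, p=[at, gc, gc, at])
    return "".join(_BASES[draws])


def mutate_copy(
    consensus: str, spec: SubfamilySpec, rng: np.random.Generator
) -> tuple[str, np.ndarray]:
    """Derive one copy: 5' truncation first, then i.i.d. substitutions.

    Returns the copy sequence (element orientation) and its truth map —
    the surviving consensus coordinate of each copy base. Substituted
    positions keep their coordinate; there are no indels.
    """
    n = len(consensus)
    if n < 1:
        raise ValueError("consensus must be non-empty")
    frac = spec.draw_retained_fraction(rng)
    retained = max(1, int(round(frac * n)))
    offset = n - retained
    arr = np.frombuffer(consensus[offset:].encode(), dtype=np.uint8).copy()
    hit = rng.random(retained) < spec.sub_rate
    if hit.any():
        base_idx = {ord(b): i for i, b in enumerate("ACGT")}
        cur = np.array([base_idx[b] for b in arr[hit]])
        # uniformly chosen *different* base: shift by 1..3 mod 4
        new = (cur + rng.integers(1, 4, size=cur.shape)) % 4
        arr[hit] = np.frombuffer("ACGT".encode(), dtype=np.uint8)[new]
    coords = np.arange(offset, n, dtype=np.int64)
    return arr.tobytes().decode(), coords


def _place_intervals(
    lengths: Sequence[int],
    genome_length: int,
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    max_tries: int = 1000,
) -> list[int]:
    """Uniform non-overlapping starts for intervals of the given lengths."""
    starts: list[int] = []
    for length in lengths:
        if length > genome_length:
            raise ValueError("insertion longer than genome")
        for _ in range(max_tries):
            s = int(rng.integers(0, genome_length - length + 1))
            e = s + length
            if all(e <= a or s >= b for a, b in occupied):
                occupied.append((s, e))
                starts.append(s)
                break
        else:
            raise RuntimeError(
                f"could not place interval of length {length} without overlap "
                f"after {max_tries} tries; genome too crowded"
            )
    return starts


def simulate_genome(
    config: SimConfig,
) -> tuple[Genome, list[TELocus], list[TruthMap]]:
    """Build the genome, its truth annotation, and per-locus truth maps.

    Copies are planted (written over background) at uniform non-overlapping
    positions; segmental duplications then copy a finished region verbatim
    into un-occupied background, so TE loci inside a duplicated region
    reappear with distinct locus_ids and identical sequence. Fully
    reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.background_length
    chrom = config.chrom_name
    seq = np.frombuffer(
        random_sequence(n, config.gc_content, rng).encode(), dtype=np.uint8
    ).copy()

    loci: list[TELocus] = []
    truth: list[TruthMap] = []
    occupied: list[tuple[int, int]] = []

    for spec in config.subfamilies:
        copies = [mutate_copy(spec.consensus, spec, rng) for _ in range(spec.copy_number)]
        starts = _place_intervals([len(c) for c, _ in copies], n, rng, occupied)
        for i, ((copy_seq, coords), start) in enumerate(zip(copies, starts)):
            strand = "+" if rng.random() < spec.strand_prob else "-"
            planted = copy_seq if strand == "+" else revcomp(copy_seq)
            seq[start : start + len(copy_seq)] = np.frombuffer(
                planted.encode(), dtype=np.uint8
            )
            locus_id = f"{spec.name}.{i + 1}"
            loci.append(
                TELocus(
                    chrom, start, start + len(copy_seq), strand,
                    spec.name, spec.family, spec.te_class, locus_id,
                )
            )
            truth.append(TruthMap(locus_id, spec.name, coords))

    for d, dup in enumerate(config.segdups):
        if not (0 <= dup.start < dup.end <= n):
            raise ValueError(f"segdup region [{dup.start}, {dup.end}) out of range")
        region_len = dup.end - dup.start
        inside = [
            (loc, tm)
            for loc, tm in zip(loci, truth)
            if dup.start <= loc.start and loc.end <= dup.end
        ]
        # the source region must stay untouched by later placements
        if (dup.start, dup.end) not in occupied:
            occupied.append((dup.start, dup.end))
        starts = _place_intervals([region_len] * dup.n_copies, n, rng, occupied)
        for c, new_start in enumerate(starts):
            seq[new_start : new_start + region_len] = seq[dup.start : dup.end]
            for loc, tm in inside:
                shift = new_start - dup.start
                locus_id = f"{loc.locus_id}.segdup{d + 1}.{c + 1}"
                loci.append(
                    TELocus(
                        chrom, loc.start + shift, loc.end + shift, loc.strand,
                        loc.subfamily, loc.family, loc.te_class, locus_id,
                    )
                )
                truth.append(TruthMap(locus_id, tm.subfamily, tm.consensus_coords.copy()))

    genome = Genome({chrom: seq.tobytes().decode()})
    order = np.argsort([loc.start for loc in loci], kind="stable")
    loci = [loci[i] for i in order]
    truth = [truth[i] for i in order]
    return genome, loci, truth
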