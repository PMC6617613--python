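"""Shared fixtures: deterministic micro-genomes built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from temap import Genome

_BASES = np.array(list("ACGT"))
_GT = np.array(list("GT"))


def random_seq(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(_BASES[rng.integers(0, 4, n)])


def gt_spacer(n: int, seed: int) -> str:
    """Spacer over {G,T}: cannot come within 1 mismatch of an A/C-only word."""
    rng = np.random.default_rng(seed)
    return "".join(_GT[rng.integers(0, 2, n)])


def random_genome(seed: int, n: int, name: str = "chr1") -> Genome:
    return Genome({name: random_seq(n, seed)})


@pytest.fixture
def five_copy_genome() -> tuple[Genome, str, list[int]]:
    """A 12-mer over {A,C} planted 5 times in {G,T} spacers.

    With m=1 the word's mismatch neighborhood present in the genome is the
    word itself: every 1-substitution neighbor differs from all spacer-
    overlapping windows in >=2 positions, and the reverse complement lives
    in the {G,T} alphabet where the spacers are random.
    """
    w = "AACACCAACCAC"
    parts, starts, pos = [], [], 0
    for i in range(5):
        s = gt_spacer(25, 100 + i)
        parts.append(s)
        pos += len(s)
        starts.append(pos)
        parts.append(w)
        pos += len(w)
    parts.append(gt_spacer(25, 105))
    return Genome({"chr1": "".join(parts)}), w, starts


@pytest.fixture
def two_kmer_genome() -> tuple[Genome, str, str, int]:
    """Focal 12-mer occurring once plus a 1-mismatch neighbor occurring 3x."""
    f = "CCACAACACCAA"
    w = f[:5] + "C" + f[6:]
    parts = [gt_spacer(25, 200), f]
    for i in range(3):
        parts.append(gt_spacer(25, 201 + i))
        parts.append(w)
    parts.append(gt_spacer(25, 205))
    genome_seq = "".join(parts)
    return Genome({"chr1": genome_seq}), f, w, genome_seq.index(f)


@pytest.fixture
def tandem_genome() -> dict:
    """Unique flank feeding a period-10 tandem repeat.

    Fragments starting in the unique flank place their mate inside the
    repeat, where it matches at several offsets: same start, different
    insert sizes. Embedded in 2 kb of unique sequence so such positions are
    a small minority of the fixture.
    """
    unit = "ACGGTCAATC"  # period exactly 10
    left = random_seq(1000, 42)
    tandem = unit * 8
    right = random_seq(1000, 43)
    seq = left + tandem + right
    return {
        "genome": Genome({"chr1": seq}),
        "unit": unit,
        "tandem_start": len(left),
        "tandem_end": len(left) + len(tandem),
        "period": len(unit),
    }
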