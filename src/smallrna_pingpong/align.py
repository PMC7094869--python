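"""Ungapped placement of small-RNA reads on reference features.

Reads are placed end-to-end (fully contained) on either strand of each
feature, allowing substitutions only, and only placements in the best
mismatch stratum observed for the read are kept. This emulates short
ungapped alignment of 20-30-mers at "at most 1 mismatch" without an
external aligner.

Coordinates are 0-based, half-open ``[start, start+len)`` on the plus
strand. A sense read's biological 5' end is ``start``; an antisense read's
biological 5' end is the rightmost plus-strand base, ``start + len - 1``,
so the 5'-5' overlap between a sense read at s and an antisense 5' end at
a is the single subtraction ``a - s + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .io_formats import ReferenceFeature, SmallRNARead

SENSE = "sense"
ANTISENSE = "antisense"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Alignment:
    """A read placed on a feature."""

    read_id: str
    feature: str
    start: int  # 0-based plus-strand offset of the read's leftmost base
    orientation: Literal["sense", "antisense"]
    mismatches: int
    weight: float
    length: int

    @property
    def five_prime(self) -> int:
        """Plus-strand position of the read's biological 5' end."""
        if self.orientation == SENSE:
            return self.start
        return self.start + self.length - 1


def _mismatches_at(read: str, ref: str, pos: int, limit: int) -> int:
    """Hamming distance of read vs ref[pos:pos+len(read)], early-abandoned."""
    mm = 0
    for a, b in zip(read, ref[pos : pos + len(read)]):
        if a != b:
            mm += 1
            if mm > limit:
                return mm
    return mm


def _find_all(needle: str, haystack: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def _candidate_starts(read: str, ref: str, max_mismatch: int) -> set[int]:
    """Candidate placements via pigeonhole seeding.

    A placement with <= m substitutions leaves at least one of m+1
    contiguous read pieces exact, so exact occurrences of each piece seed
    all candidates. Falls back to the full offset scan for m >= 2.
    """
    n, L = len(read), len(ref)
    if n > L:
        return set()
    if max_mismatch >= 2:
        return set(range(L - n + 1))
    candidates: set[int] = set()
    if max_mismatch == 0:
        pieces = [(read, 0)]
    else:
        half = n // 2
        pieces = [(read[:half], 0), (read[half:], half)]
    for piece, offset in pieces:
        for hit in _find_all(piece, ref):
            start = hit - offset
            if 0 <= start <= L - n:
                candidates.add(start)
    return candidates


def scan_placements(
    read: SmallRNARead, feature: ReferenceFeature, max_mismatch: int = 1
) -> list[Alignment]:
    """All end-to-end placements on either strand with <= max_mismatch substitutions.

    Returns unweighted alignments (weight 1.0) without stratum filtering.
    """
    out: list[Alignment] = []
    n = read.length
    for orientation, query in ((SENSE, read.seq), (ANTISENSE, revcomp(read.seq))):
        for start in sorted(_candidate_starts(query, feature.seq, max_mismatch)):
            mm = _mismatches_at(query, feature.seq, start, max_mismatch)
            if mm <= max_mismatch:
                out.append(
                    Alignment(read.read_id, feature.name, start, orientation, mm, 1.0, n)
                )
    return out


def align_read(
    read: SmallRNARead, feature: ReferenceFeature, max_mismatch: int = 1
) -> list[Alignment]:
    """Best-stratum placements of one read on one feature.

    All placements at the minimum observed mismatch count are reported;
    an empty list means unaligned.
    """
    hits = scan_placements(read, feature, max_mismatch)
    if not hits:
        return []
    best = min(a.mismatches for a in hits)
    return [a for a in hits if a.mismatches == best]


@dataclass
class FivePrimeIndex:
    """Per-feature maps from plus-strand 5'-end position to total weight."""

    sense: dict[str, dict[int, float]] = field(default_factory=dict)
    antisense: dict[str, dict[int, float]] = field(default_factory=dict)

    def add(self, aln: Alignment) -> None:
        table = self.sense if aln.orientation == SENSE else self.antisense
        positions = table.setdefault(aln.feature, {})
        positions[aln.five_prime] = positions.get(aln.five_prime, 0.0) + aln.weight

    @classmethod
    def from_alignments(cls, alignments: Iterable[Alignment]) -> "FivePrimeIndex":
        index = cls()
        for aln in alignments:
            index.add(aln)
        return index

    def total_weight(self, feature: str) -> float:
        return sum(self.sense.get(feature, {}).values()) + sum(
            self.antisense.get(feature, {}).values()
        )


@dataclass
class AssignmentResult:
    alignments: list[Alignment]
    index: FivePrimeIndex
    n_aligned: int
    n_unaligned: int
    n_multimap_dropped: int


def assign_reads(
    reads: Sequence[SmallRNARead],
    features: Sequence[ReferenceFeature],
    policy: Literal["fractional", "unique_only"] = "fractional",
    max_mismatch: int = 1,
) -> AssignmentResult:
    """Place reads on a feature set and resolve multi-mappers.

    The best stratum is taken across all features: only placements at the
    read's global minimum mismatch count survive. Under ``fractional`` each
    of the k surviving placements gets weight 1/k; under ``unique_only``
    reads with k > 1 are dropped and counted separately.
    """
    if policy not in ("fractional", "unique_only"):
        raise ValueError(f"unknown multi-mapper policy: {policy!r}")
    if not features:
        raise ValueError("empty feature set")
    out: list[Alignment] = []
    n_aligned = n_unaligned = n_multimap = 0
    for read in reads:
        hits: list[Alignment] = []
        for feature in features:
            hits.extend(scan_placements(read, feature, max_mismatch))
        if not hits:
            n_unaligned += 1
            continue
        best = min(a.mismatches for a in hits)
        hits = [a for a in hits if a.mismatches == best]
        if policy == "unique_only" and len(hits) > 1:
            n_multimap += 1
            continue
        w = 1.0 / len(hits)
        for a in hits:
            a.weight = w
        out.extend(hits)
        n_aligned += 1
    return AssignmentResult(
        alignments=out,
        index=FivePrimeIndex.from_alignments(out),
        n_aligned=n_aligned,
        n_unaligned=n_unaligned,
        n_multimap_dropped=n_multimap,
    )


def alignments_to_frame(alignments: Sequence[Alignment]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "feature": a.feature,
                "start": a.start,
                "orientation": a.orientation,
                "mismatches": a.mismatches,
                "weight": a.weight,
                "length": a.length,
            }
            for a in alignments
        ],
        columns=["read_id", "feature", "start", "orientation", "mismatches", "weight", "length"],
    )
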