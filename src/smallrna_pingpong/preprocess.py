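"""Adapter clipping, rRNA/miRNA-hairpin depletion, and length classification.

Stage order is fixed: clip -> deplete -> classify. Depletion matching is
end-to-end (the read fully contained in a depletion reference, either
strand) with substitutions only; the count of reads depleted to miRNA
hairpins is kept as the between-library normalizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import scan_placements
from .io_formats import DEPLETION_CLASSES, FeatureClass, ReferenceFeature, SmallRNARead

PIRNA_RANGE = (23, 29)  # inclusive, nt
SIRNA_RANGE = (20, 22)  # inclusive, nt
PROFILE_LENGTHS = range(18, 36)


def classify_by_length(read: SmallRNARead | int) -> str:
    """Map a read (or a length) to its small-RNA class label.

    piRNA: 23-29 nt; siRNA: 20-22 nt; everything else: other. Total on all
    lengths.
    """
    length = read if isinstance(read, int) else read.length
    if PIRNA_RANGE[0] <= length <= PIRNA_RANGE[1]:
        return "piRNA"
    if SIRNA_RANGE[0] <= length <= SIRNA_RANGE[1]:
        return "siRNA"
    return "other"


def clip_adapter(
    read: SmallRNARead,
    adapter: str,
    min_insert: int = 18,
    min_match: int = 8,
    keep_unclipped: bool = False,
) -> Optional[SmallRNARead]:
    """Clip a 3' adapter by exact prefix match; None means discarded.

    The read is truncated at the leftmost position where at least
    ``min_match`` bases of the adapter prefix match exactly (a shorter
    terminal match is accepted only if the read ends before ``min_match``
    adapter bases fit -- such suffixes are ambiguous and left unclipped).
    Reads with no adapter hit are discarded unless ``keep_unclipped``;
    clipped inserts shorter than ``min_insert`` are always discarded.
    """
    adapter = adapter.upper().replace("U", "T")
    if len(adapter) < min_match:
        raise ValueError(f"adapter ({len(adapter)} nt) shorter than min_match={min_match}")
    if min_match < 6:
        raise ValueError("min_match must be >= 6")
    seq = read.seq
    clip_at = None
    for i in range(0, len(seq) - min_match + 1):
        m = min(len(adapter), len(seq) - i)
        if seq[i : i + m] == adapter[:m]:
            clip_at = i
            break
    if clip_at is None:
        if keep_unclipped:
            return read
        return None
    if clip_at < min_insert:
        return None
    return SmallRNARead(read_id=read.read_id, seq=seq[:clip_at])


@dataclass
class DepletionResult:
    retained: list[SmallRNARead]
    depleted_counts: dict[str, int]  # feature-class value -> read count
    hairpin_total: int
    warning: Optional[str] = None


def deplete_matching(
    reads: Sequence[SmallRNARead],
    depletion_refs: Sequence[ReferenceFeature],
    max_mismatch: int = 1,
) -> DepletionResult:
    """Remove reads matching rRNA or miRNA-hairpin references.

    A read is depleted iff it aligns end-to-end on either strand to any
    depletion reference with at most ``max_mismatch`` substitutions.
    miRNA-hairpin references are checked first so a read matching both
    classes counts toward the normalizer.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    bad = [r for r in depletion_refs if r.feature_class not in DEPLETION_CLASSES]
    if bad:
        raise ValueError(f"non-depletion classes in depletion set: {[r.name for r in bad]}")
    hairpins = [r for r in depletion_refs if r.feature_class is FeatureClass.miRNA_hairpin]
    rrnas = [r for r in depletion_refs if r.feature_class is FeatureClass.rRNA]
    warning = None
    if not depletion_refs:
        warning = "empty depletion set: all reads retained, hairpin normalizer is 0"
    retained: list[SmallRNARead] = []
    counts = {FeatureClass.miRNA_hairpin.value: 0, FeatureClass.rRNA.value: 0}
    for read in reads:
        hit_class = None
        for refs, cls in ((hairpins, FeatureClass.miRNA_hairpin), (rrnas, FeatureClass.rRNA)):
            for ref in refs:
                if read.length <= ref.length and scan_placements(read, ref, max_mismatch):
                    hit_class = cls
                    break
            if hit_class:
                break
        if hit_class:
            counts[hit_class.value] += 1
        else:
            retained.append(read)
    return DepletionResult(
        retained=retained,
        depleted_counts=counts,
        hairpin_total=counts[FeatureClass.miRNA_hairpin.value],
        warning=warning,
    )


@dataclass
class FivePrimeProfile:
    """Per-length 5'-nucleotide identity fractions (RNA alphabet in output).

    ``fractions`` rows cover lengths 18-35; rows for lengths with zero
    reads are all-zero and flagged absent via ``counts``.
    """

    fractions: pd.DataFrame  # index: length, columns: A, C, G, U
    counts: pd.Series  # reads per length

    def to_frame(self) -> pd.DataFrame:
        out = self.fractions.copy()
        out.insert(0, "length", out.index)
        out["n_reads"] = self.counts.values
        return out.reset_index(drop=True)


def five_prime_profile(reads: Sequence[SmallRNARead]) -> FivePrimeProfile:
    """Fraction of first-base identity per read length (lengths 18-35)."""
    lengths = list(PROFILE_LENGTHS)
    bases = ["A", "C", "G", "T"]
    counts = pd.DataFrame(0, index=lengths, columns=bases, dtype=float)
    for read in reads:
        if read.length in counts.index and read.seq[0] in bases:
            counts.loc[read.length, read.seq[0]] += 1
    totals = counts.sum(axis=1)
    fractions = counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    fractions = fractions.rename(columns={"T": "U"})
    return FivePrimeProfile(fractions=fractions, counts=totals.astype(int))


@dataclass
class PreprocessResult:
    """Bookkeeping for one library through clip -> deplete -> classify."""

    piRNA: list[SmallRNARead]
    siRNA: list[SmallRNARead]
    other: list[SmallRNARead]
    hairpin_total: int
    depleted_counts: dict[str, int]
    n_input: int
    n_discarded_clip: int
    library_total: int  # reads entering depletion/classification (post-clip)

    @property
    def retained(self) -> list[SmallRNARead]:
        return self.piRNA + self.siRNA + self.other

    def class_counts(self) -> dict[str, int]:
        return {"piRNA": len(self.piRNA), "siRNA": len(self.siRNA), "other": len(self.other)}


def preprocess_library(
    reads: Sequence[SmallRNARead],
    depletion_refs: Sequence[ReferenceFeature],
    adapter: Optional[str] = None,
    min_insert: int = 18,
    min_match: int = 8,
    keep_unclipped: bool = False,
    max_mismatch: int = 1,
) -> PreprocessResult:
    """Run the fixed clip -> deplete -> classify stage order on one library."""
    n_input = len(reads)
    if adapter:
        clipped = [clip_adapter(r, adapter, min_insert, min_match, keep_unclipped) for r in reads]
        clipped = [r for r in clipped if r is not None]
    else:
        clipped = list(reads)
    n_discarded = n_input - len(clipped)
    depletion = deplete_matching(clipped, depletion_refs, max_mismatch=max_mismatch)
    groups: dict[str, list[SmallRNARead]] = {"piRNA": [], "siRNA": [], "other": []}
    for read in depletion.retained:
        groups[classify_by_length(read)].append(read)
    return PreprocessResult(
        piRNA=groups["piRNA"],
        siRNA=groups["siRNA"],
        other=groups["other"],
        hairpin_total=depletion.hairpin_total,
        depleted_counts=depletion.depleted_counts,
        n_input=n_input,
        n_discarded_clip=n_discarded,
        library_total=len(clipped),
    )
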