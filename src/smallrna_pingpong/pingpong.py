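"""The 5'-5' ping-pong signature: overlap histogram, qualifying pairs, ratio.

The ping-pong amplification cycle leaves sense/antisense piRNA pairs whose
5' ends overlap by exactly 10 nt, with the secondary (sense) piRNA carrying
an A at position 10 and the primary (antisense) piRNA a 5' U. Per
transposon this module computes:

* the overlap histogram: for every sense 5' end at plus-strand position s
  and antisense 5' end at position a, the overlap is ``o = a - s + 1`` and
  bin o accumulates the product of the two 5'-end weights;
* the qualifying weight: a (sense, antisense) pair qualifies iff its
  overlap is exactly 10 AND (the sense read's 10th base is A OR the
  antisense read's 1st base is U). The default numerator sums the
  alignment weights of all distinct reads participating in at least one
  qualifying pair (each read once), which bounds the ratio by 1; a
  ``pairs`` mode sums the weight products of the qualifying pairs instead;
* the ping-pong ratio: qualifying weight divided by the total piRNA weight
  on the feature (both orientations). Being a within-library proportion it
  needs no library-size normalization.

Base checks use the read's own sequence, not the reference: the signature
is a property of the piRNA molecule, so a mismatch-bearing read is judged
by its own 10th/1st base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import ANTISENSE, SENSE, Alignment, FivePrimeIndex
from .differential import wilcoxon_signed_rank

PINGPONG_OVERLAP = 10  # nt, the signature overlap
DEFAULT_O_MAX = 30


def overlap_histogram(
    index: FivePrimeIndex, feature: str, o_max: int = DEFAULT_O_MAX
) -> dict[int, float]:
    """Weighted 5'-5' overlap histogram over bins 1..o_max for one feature."""
    if o_max < PINGPONG_OVERLAP:
        raise ValueError(f"o_max must be >= {PINGPONG_OVERLAP} (the signature bin)")
    sense = index.sense.get(feature, {})
    antisense = index.antisense.get(feature, {})
    hist = {o: 0.0 for o in range(1, o_max + 1)}
    for a_pos, a_w in antisense.items():
        for o in range(1, o_max + 1):
            s_w = sense.get(a_pos - o + 1)
            if s_w:
                hist[o] += s_w * a_w
    return hist


@dataclass
class QualifyingResult:
    read_weight: float  # summed weight of distinct reads in >=1 qualifying pair
    pair_weight: float  # summed weight product over qualifying pairs
    n_short_excluded: int  # sense-role reads shorter than 10 nt


def qualifying_pairs(
    alignments: Sequence[Alignment],
    read_seqs: Mapping[str, str],
    feature: str,
) -> QualifyingResult:
    """Qualifying-pair weight for one feature under the 10A/1U OR rule."""
    sense_by_pos: dict[int, list[Alignment]] = {}
    anti_by_pos: dict[int, list[Alignment]] = {}
    n_short = 0
    for a in alignments:
        if a.feature != feature:
            continue
        if a.orientation == SENSE:
            if a.length < PINGPONG_OVERLAP:
                n_short += 1
                continue
            sense_by_pos.setdefault(a.five_prime, []).append(a)
        else:
            anti_by_pos.setdefault(a.five_prime, []).append(a)

    qualifying: dict[str, float] = {}  # read_id -> weight on this feature
    pair_weight = 0.0
    for a_pos, anti_alns in anti_by_pos.items():
        sense_alns = sense_by_pos.get(a_pos - PINGPONG_OVERLAP + 1)
        if not sense_alns:
            continue
        for s_aln in sense_alns:
            tenth_is_a = read_seqs[s_aln.read_id][PINGPONG_OVERLAP - 1] == "A"
            for a_aln in anti_alns:
                first_is_u = read_seqs[a_aln.read_id][0] == "T"
                if tenth_is_a or first_is_u:
                    pair_weight += s_aln.weight * a_aln.weight
                    qualifying[s_aln.read_id] = s_aln.weight
                    qualifying[a_aln.read_id] = a_aln.weight
    return QualifyingResult(
        read_weight=sum(qualifying.values()),
        pair_weight=pair_weight,
        n_short_excluded=n_short,
    )


def pingpong_ratio(qualifying_weight: float, total_pirna_weight: float) -> float:
    """Qualifying weight over total piRNA weight; 0 when the total is 0."""
    if total_pirna_weight <= 0:
        return 0.0
    return qualifying_weight / total_pirna_weight


@dataclass
class PingPongResult:
    feature: str
    qualifying_weight: float
    total_pirna_weight: float
    ratio: float
    histogram: dict[int, float] = field(default_factory=dict)


def compute_pingpong(
    alignments: Sequence[Alignment],
    read_seqs: Mapping[str, str],
    features: Sequence[str],
    o_max: int = DEFAULT_O_MAX,
    numerator: Literal["reads", "pairs"] = "reads",
    denominator: Literal["per_feature", "library"] = "per_feature",
) -> list[PingPongResult]:
    """Per-feature ping-pong statistics from piRNA-class alignments.

    ``denominator='library'`` divides every feature's qualifying weight by
    the total piRNA weight across all listed features instead of the
    feature's own total.
    """
    if numerator not in ("reads", "pairs"):
        raise ValueError(f"unknown numerator mode: {numerator!r}")
    index = FivePrimeIndex.from_alignments(alignments)
    totals = {f: index.total_weight(f) for f in features}
    library_total = sum(totals.values())
    results = []
    for feature in features:
        qual = qualifying_pairs(alignments, read_seqs, feature)
        weight = qual.read_weight if numerator == "reads" else qual.pair_weight
        total = library_total if denominator == "library" else totals[feature]
        results.append(
            PingPongResult(
                feature=feature,
                qualifying_weight=weight,
                total_pirna_weight=totals[feature],
                ratio=pingpong_ratio(weight, total),
                histogram=overlap_histogram(index, feature, o_max),
            )
        )
    return results


@dataclass
class RatioComparison:
    per_replicate_a: pd.DataFrame  # index: feature; columns: replicates
    per_replicate_b: pd.DataFrame
    mean_diff: pd.Series  # per-feature mean(b) - mean(a)
    p_value: float  # Wilcoxon signed-rank over per-feature mean ratios; NaN if <5 TEs


def compare_ratios(
    cond_a: pd.DataFrame, cond_b: pd.DataFrame, min_features: int = 5
) -> RatioComparison:
    """Compare per-transposon ping-pong ratios between two conditions.

    Inputs are feature x replicate tables of ratios. The test is a
    Wilcoxon signed-rank over per-feature replicate-mean ratios, shared
    with the differential module; fewer than ``min_features`` shared
    features leaves the p-value undefined (NaN).
    """
    shared = cond_a.index.intersection(cond_b.index)
    a = cond_a.loc[shared]
    b = cond_b.loc[shared]
    diffs = (b.mean(axis=1) - a.mean(axis=1)).astype(float)
    p = wilcoxon_signed_rank(diffs.values) if len(shared) >= min_features else float("nan")
    return RatioComparison(per_replicate_a=a, per_replicate_b=b, mean_diff=diffs, p_value=p)


def histograms_to_frame(results: Sequence[PingPongResult]) -> pd.DataFrame:
    rows = [
        {"feature": r.feature, "overlap": o, "weight": w}
        for r in results
        for o, w in sorted(r.histogram.items())
    ]
    return pd.DataFrame(rows, columns=["feature", "overlap", "weight"])


def ratios_to_frame(results: Sequence[PingPongResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "qualifying_weight": r.qualifying_weight,
                "total_weight": r.total_pirna_weight,
                "ratio": r.ratio,
            }
            for r in results
        ],
        columns=["feature", "qualifying_weight", "total_weight", "ratio"],
    )
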