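"""Per-feature and per-class quantification with the two normalizations.

Two normalizers are carried side by side and never mixed silently:
``hairpin_total`` (reads depleted to miRNA hairpins; a piRNA-pathway-
independent denominator used for per-transposon abundances and density
tracks) and ``library_total`` (all reads entering classification; used for
per-class library fractions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .align import SENSE, Alignment
from .io_formats import FeatureClass

HAIRPIN_SCALE = 1e6  # reads per million hairpin reads


@dataclass
class LibraryCounts:
    """Weighted per-feature counts plus the library's normalizers."""

    counts: pd.DataFrame  # index: feature; columns: sense_weight, antisense_weight
    hairpin_total: int
    library_total: int

    def __post_init__(self) -> None:
        if self.hairpin_total > self.library_total:
            raise ValueError("hairpin_total cannot exceed library_total")

    def total_weight(self, feature: str) -> float:
        if feature not in self.counts.index:
            return 0.0
        row = self.counts.loc[feature]
        return float(row["sense_weight"] + row["antisense_weight"])


def count_by_feature(
    alignments: Sequence[Alignment], hairpin_total: int = 0, library_total: int = 0
) -> LibraryCounts:
    """Weighted read-count sums per (feature, orientation)."""
    rows: dict[str, list[float]] = {}
    for a in alignments:
        entry = rows.setdefault(a.feature, [0.0, 0.0])
        entry[0 if a.orientation == SENSE else 1] += a.weight
    counts = pd.DataFrame.from_dict(
        rows, orient="index", columns=["sense_weight", "antisense_weight"]
    ).sort_index()
    counts.index.name = "feature"
    return LibraryCounts(counts=counts, hairpin_total=hairpin_total, library_total=library_total)


def normalize_hairpin(count, hairpin_total: int):
    """Abundance per million miRNA-hairpin reads: count / hairpin_total * 1e6."""
    if hairpin_total <= 0:
        raise ValueError("hairpin_total is 0: library cannot be hairpin-normalized")
    return count / hairpin_total * HAIRPIN_SCALE


def class_summary(
    counts: LibraryCounts, annotation: dict[str, FeatureClass], library_total: int | None = None
) -> pd.Series:
    """Per-feature-class fraction of total library reads."""
    total = counts.library_total if library_total is None else library_total
    if total <= 0:
        raise ValueError("library_total must be positive")
    missing = [f for f in counts.counts.index if f not in annotation]
    if missing:
        raise ValueError(f"unannotated features: {missing}")
    fractions = pd.Series(0.0, index=[c.value for c in FeatureClass])
    for feature, row in counts.counts.iterrows():
        cls = annotation[feature].value
        fractions[cls] += (row["sense_weight"] + row["antisense_weight"]) / total
    return fractions


@dataclass
class DensityProfile:
    feature: str
    sense: np.ndarray
    antisense: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(len(self.sense)),
                "sense": self.sense,
                "antisense": self.antisense,
            }
        )


def density_profile(
    alignments: Sequence[Alignment],
    feature: str,
    feature_length: int,
    hairpin_total: int,
    mode: Literal["coverage", "five_prime"] = "coverage",
) -> DensityProfile:
    """Per-position hairpin-normalized read density across one feature.

    ``coverage`` adds each alignment's weight to every position it covers;
    ``five_prime`` adds it only at the biological 5' end.
    """
    if mode not in ("coverage", "five_prime"):
        raise ValueError(f"unknown density mode: {mode!r}")
    sense = np.zeros(feature_length)
    antisense = np.zeros(feature_length)
    for a in alignments:
        if a.feature != feature:
            continue
        track = sense if a.orientation == SENSE else antisense
        if mode == "coverage":
            track[a.start : a.start + a.length] += a.weight
        else:
            track[a.five_prime] += a.weight
    scale = HAIRPIN_SCALE / hairpin_total if hairpin_total > 0 else np.nan
    return DensityProfile(feature=feature, sense=sense * scale, antisense=antisense * scale)


def normalized_counts_table(
    counts: LibraryCounts, annotation: dict[str, FeatureClass]
) -> pd.DataFrame:
    """Counts TSV body: raw and hairpin-normalized weights per feature."""
    df = counts.counts.reset_index()
    df.insert(1, "class", [annotation[f].value for f in df["feature"]])
    if counts.hairpin_total > 0:
        df["norm_hairpin_sense"] = normalize_hairpin(df["sense_weight"], counts.hairpin_total)
        df["norm_hairpin_antisense"] = normalize_hairpin(
            df["antisense_weight"], counts.hairpin_total
        )
    else:
        df["norm_hairpin_sense"] = np.nan
        df["norm_hairpin_antisense"] = np.nan
    return df
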