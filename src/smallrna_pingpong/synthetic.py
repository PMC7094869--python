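"""Synthetic small-RNA libraries with known ping-pong structure.

The generator emulates the statistical structure a testis small-RNA
library presents to this analysis: a read-length mixture (piRNAs 23-29 nt,
siRNAs 20-22 nt, hairpin- and rRNA-derived reads), the 5'-U bias of
antisense piRNAs, sense/antisense transposon-derived reads of which a
controllable fraction is emitted as exact 10-nt 5'-overlap pairs bearing
the 10A/1U signature, and replicate libraries for two conditions with
per-class fold changes against a fixed miRNA-hairpin normalizer.

Reads are exact substrings (or reverse complements) of the reference
except for the deliberately forced signature bases, so with 1-mismatch
alignment every read maps back to its emission site and the pipeline can
be checked against ground truth exactly.

Ground truth records *every* emission (feature, strand, coordinates,
final sequence). Because unpaired reads can also land in exact 10-nt
overlap by chance, the truth's qualifying-read count is recomputed by an
all-pairs brute force over the emission table — independent of the
aligner and the indexed histogram path — rather than from the count of
deliberately emitted pairs (kept separately as ``intended_pairs``).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import revcomp
from .io_formats import FeatureClass, ReferenceFeature, SmallRNARead
from .pingpong import PINGPONG_OVERLAP

BASES = np.array(list("ACGT"))

#: read classes emitted by the generator, keyed as in ``class_mix``
READ_CLASSES = ("te_piRNA", "siRNA", "miRNA_hairpin", "rRNA")

#: map from feature class to the read class whose emission it drives
_FOLD_KEYS = {
    "transposon": "te_piRNA",
    "siRNA": "siRNA",
    "miRNA_hairpin": "miRNA_hairpin",
    "rRNA": "rRNA",
}

# default length mixtures: piRNA peaked at 26 nt, siRNA flat on 20-22
DEFAULT_PIRNA_LENGTHS = {23: 0.08, 24: 0.12, 25: 0.18, 26: 0.24, 27: 0.18, 28: 0.12, 29: 0.08}
DEFAULT_SIRNA_LENGTHS = {20: 1 / 3, 21: 1 / 3, 22: 1 / 3}


@dataclass
class LibraryParams:
    """Parameters of one simulated library.

    Defaults describe a wild-type-like testis library: half the reads
    transposon-derived piRNAs, a strong (0.8) antisense 5'-U bias, a 0.7
    10-A bias on pair-borne sense piRNAs, 40% of TE piRNA reads emitted in
    exact 10-nt 5'-overlap pairs, and a quarter of the library from miRNA
    hairpins to give the normalizer depth.
    """

    n_reads: int = 20_000
    class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "te_piRNA": 0.50,
            "siRNA": 0.15,
            "miRNA_hairpin": 0.25,
            "rRNA": 0.10,
        }
    )
    pingpong_fraction: float = 0.4
    u1_bias: float = 0.8
    a10_bias: float = 0.7
    sense_fraction: float = 0.4
    # fraction of piRNA-class reads drawn from piRNA-cluster features
    # (unpaired primary piRNAs, sense to the precursor, 5'-U biased);
    # ignored when the reference set has no cluster features
    cluster_fraction: float = 0.15
    pirna_length_probs: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PIRNA_LENGTHS)
    )
    sirna_length_probs: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SIRNA_LENGTHS)
    )
    adapter: Optional[str] = None  # if set, appended 3' of every read
    error_rate: float = 0.0  # uniform substitution rate applied last
    placement: str = "uniform"  # or "hotspot": 5' ends cluster at fixed sites
    n_hotspots: int = 25  # 5'-end sites per (feature, strand) in hotspot mode
    sites_seed: int = 0  # hotspot sites depend on this, not the library seed
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.pingpong_fraction,
            self.u1_bias,
            self.a10_bias,
            self.sense_fraction,
            self.error_rate,
            self.cluster_fraction,
        ] + list(self.class_mix.values())
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if set(self.class_mix) != set(READ_CLASSES):
            raise ValueError(f"class_mix must have exactly the keys {READ_CLASSES}")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.placement not in ("uniform", "hotspot"):
            raise ValueError(f"unknown placement mode: {self.placement!r}")
        if self.placement == "hotspot" and self.n_hotspots < 1:
            raise ValueError("n_hotspots must be >= 1")
        for dist in (self.pirna_length_probs, self.sirna_length_probs):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("length distributions must sum to 1")

    @property
    def max_read_length(self) -> int:
        return max(list(self.pirna_length_probs) + list(self.sirna_length_probs))


@dataclass
class GroundTruth:
    """Everything the generator emitted, plus truth recomputations.

    ``emissions`` has one row per read: read_id, feature, read_class,
    orientation, start (plus-strand, 0-based), length, five_prime
    (plus-strand position of the biological 5' end), pair_id (-1 for
    unpaired), seq (final read sequence, adapter excluded).
    """

    emissions: pd.DataFrame
    intended_pairs: dict[str, int]  # feature -> deliberately emitted pairs
    class_totals: dict[str, int]
    fold_by_class: dict[str, float] = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return len(self.emissions)

    def strand_counts(self) -> pd.DataFrame:
        """Emitted read counts per (feature, orientation), TE piRNAs only."""
        te = self.emissions[self.emissions["read_class"] == "te_piRNA"]
        return (
            te.groupby(["feature", "orientation"]).size().unstack(fill_value=0).astype(int)
        )

    def te_pirna_total(self, feature: str) -> int:
        te = self.emissions[self.emissions["read_class"] == "te_piRNA"]
        return int((te["feature"] == feature).sum())

    def qualifying_read_count(self, feature: str) -> int:
        """Brute-force qualifying-read count over the emission table.

        All-pairs double loop over emitted TE piRNA 5' ends: a (sense,
        antisense) pair qualifies iff the 5'-5' overlap is exactly 10 and
        the sense read's 10th base is A or the antisense read's 1st base
        is U(T); each read participating in >= 1 such pair counts once.
        Deliberate and chance pairs are treated identically, matching the
        statistic's definition on real data.
        """
        te = self.emissions[
            (self.emissions["read_class"] == "te_piRNA")
            & (self.emissions["feature"] == feature)
        ]
        sense = te[te["orientation"] == "sense"]
        anti = te[te["orientation"] == "antisense"]
        sense_rows = list(zip(sense["read_id"], sense["five_prime"], sense["seq"]))
        anti_rows = list(zip(anti["read_id"], anti["five_prime"], anti["seq"]))
        qualifying: set[str] = set()
        for s_id, s_fp, s_seq in sense_rows:
            for a_id, a_fp, a_seq in anti_rows:
                if a_fp - s_fp + 1 != PINGPONG_OVERLAP:
                    continue
                if s_seq[PINGPONG_OVERLAP - 1] == "A" or a_seq[0] == "T":
                    qualifying.add(s_id)
                    qualifying.add(a_id)
        return len(qualifying)

    def truth_ratio(self, feature: str) -> float:
        total = self.te_pirna_total(feature)
        return self.qualifying_read_count(feature) / total if total else 0.0

    def to_table(self) -> pd.DataFrame:
        """Truth TSV body: feature, strand, emitted_count, qualifying_pairs."""
        counts = self.strand_counts()
        rows = []
        for feature in counts.index:
            for strand in ("sense", "antisense"):
                rows.append(
                    {
                        "feature": feature,
                        "strand": strand,
                        "emitted_count": int(counts.loc[feature].get(strand, 0)),
                        "qualifying_pairs": self.intended_pairs.get(feature, 0),
                    }
                )
        return pd.DataFrame(rows, columns=["feature", "strand", "emitted_count", "qualifying_pairs"])


def _hotspot_sites(
    params: LibraryParams, feature_name: str, strand: str, lo: int, hi: int
) -> np.ndarray:
    """Fixed 5'-end sites for one (feature, strand).

    Derived from the feature name and ``sites_seed`` only, so every
    library simulated over the same references shares the same sites --
    5'-end clustering in real piRNA data is a property of the locus, not
    of the library.
    """
    key = f"{feature_name}:{strand}:{params.sites_seed}"
    rng = np.random.default_rng(zlib.crc32(key.encode()))
    return np.sort(rng.integers(lo, hi + 1, size=params.n_hotspots))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def generate_reference_set(
    n_te: int,
    te_length: int = 1000,
    n_hairpins: int = 5,
    seed: int = 0,
    n_genes: int = 2,
    n_clusters: int = 2,
    gene_length: int = 600,
    hairpin_length: int = 80,
    rrna_length: int = 200,
    max_read_length: int = 29,
) -> list[ReferenceFeature]:
    """Uniform-random reference features, deterministic given the seed.

    Includes the requested transposon consensus sequences and miRNA
    hairpins, at least one rRNA decoy, and (by default) a couple of genes
    and piRNA clusters so the per-class summary has every class to land on.
    """
    if n_te < 1:
        raise ValueError("n_te must be >= 1")
    if te_length < max_read_length + 10:
        raise ValueError(f"te_length must be >= {max_read_length + 10}")
    rng = np.random.default_rng(seed)
    features = []
    for i in range(n_te):
        features.append(
            ReferenceFeature(f"TE{i + 1}", _random_seq(rng, te_length), FeatureClass.transposon)
        )
    for i in range(n_hairpins):
        features.append(
            ReferenceFeature(
                f"HAIRPIN{i + 1}", _random_seq(rng, hairpin_length), FeatureClass.miRNA_hairpin
            )
        )
    features.append(ReferenceFeature("RRNA1", _random_seq(rng, rrna_length), FeatureClass.rRNA))
    for i in range(n_genes):
        features.append(
            ReferenceFeature(f"GENE{i + 1}", _random_seq(rng, gene_length), FeatureClass.gene)
        )
    for i in range(n_clusters):
        features.append(
            ReferenceFeature(
                f"CLUSTER{i + 1}", _random_seq(rng, te_length), FeatureClass.piRNA_cluster
            )
        )
    return features


def _draw_length(rng: np.random.Generator, dist: dict[int, float]) -> int:
    lengths = sorted(dist)
    return int(rng.choice(lengths, p=[dist[l] for l in lengths]))


def _biased_base(rng: np.random.Generator, p: float, base: str) -> str:
    """``base`` with probability exactly p, else uniform over the other three."""
    if rng.random() < p:
        return base
    return str(rng.choice(BASES[BASES != base]))


def _force_base(seq: str, pos: int, base: str) -> str:
    return seq[:pos] + base + seq[pos + 1 :]


class _Emitter:
    """Accumulates emitted reads and their truth rows."""

    def __init__(self, params: LibraryParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.reads: list[SmallRNARead] = []
        self.rows: list[dict] = []

    def emit(
        self,
        feature: ReferenceFeature,
        read_class: str,
        orientation: str,
        start: int,
        length: int,
        force: Optional[tuple[int, str]] = None,
        pair_id: int = -1,
    ) -> dict:
        window = feature.seq[start : start + length]
        seq = revcomp(window) if orientation == "antisense" else window
        if force is not None:
            seq = _force_base(seq, force[0], force[1])
        if self.params.error_rate > 0:
            chars = list(seq)
            for i in range(length):
                if self.rng.random() < self.params.error_rate:
                    chars[i] = str(self.rng.choice(BASES[BASES != chars[i]]))
            seq = "".join(chars)
        read_id = f"r{len(self.reads)}"
        five_prime = start if orientation == "sense" else start + length - 1
        out = self.params.adapter.upper().replace("U", "T") if self.params.adapter else ""
        self.reads.append(SmallRNARead(read_id=read_id, seq=seq + out))
        row = {
            "read_id": read_id,
            "feature": feature.name,
            "read_class": read_class,
            "orientation": orientation,
            "start": start,
            "length": length,
            "five_prime": five_prime,
            "pair_id": pair_id,
            "seq": seq,
        }
        self.rows.append(row)
        return row


def simulate_library(
    params: LibraryParams,
    refs: Sequence[ReferenceFeature],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[SmallRNARead], GroundTruth]:
    """Emit one library of exactly ``params.n_reads`` reads with ground truth.

    TE piRNA reads are drawn per transposon uniformly. A fraction
    ``pingpong_fraction`` of them is emitted pairwise: a sense read with
    5' end at plus-strand position s and an antisense read whose 5' end
    sits at s + 9, the sense 10th base forced to A with probability
    ``a10_bias`` and the antisense 1st base forced to U with probability
    ``u1_bias``. Unpaired antisense piRNAs receive the same 5'-U forcing;
    unpaired sense piRNAs are left as the reference dictates.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    tes = [r for r in refs if r.feature_class is FeatureClass.transposon]
    hairpins = [r for r in refs if r.feature_class is FeatureClass.miRNA_hairpin]
    rrnas = [r for r in refs if r.feature_class is FeatureClass.rRNA]
    if not tes:
        raise ValueError("reference set has no transposon feature")
    if not hairpins:
        raise ValueError("reference set has no miRNA_hairpin feature")

    classes = list(READ_CLASSES)
    n_by_class = dict(
        zip(classes, rng.multinomial(params.n_reads, [params.class_mix[c] for c in classes]))
    )
    emitter = _Emitter(params, rng)
    intended_pairs: dict[str, int] = {t.name: 0 for t in tes}
    max_pirna_len = max(params.pirna_length_probs)

    # --- piRNAs: cluster-derived primaries, then TE paired + unpaired ----
    clusters = [r for r in refs if r.feature_class is FeatureClass.piRNA_cluster]
    n_pirna_reads = n_by_class["te_piRNA"]
    n_cluster = (
        rng.binomial(n_pirna_reads, params.cluster_fraction)
        if clusters and n_pirna_reads
        else 0
    )
    for _ in range(n_cluster):
        cl = clusters[rng.integers(len(clusters))]
        length = _draw_length(rng, params.pirna_length_probs)
        start = int(rng.integers(0, cl.length - length + 1))
        force = (0, _biased_base(rng, params.u1_bias, "T"))
        emitter.emit(cl, "cluster_piRNA", "sense", start, length, force=force)

    n_te_reads = n_pirna_reads - n_cluster
    n_flagged = rng.binomial(n_te_reads, params.pingpong_fraction) if n_te_reads else 0
    n_pairs = n_flagged // 2
    pair_s_min = max_pirna_len - PINGPONG_OVERLAP  # keeps the antisense mate on-feature

    hotspot = params.placement == "hotspot"
    sense_sites: dict[str, np.ndarray] = {}
    anti_sites: dict[str, np.ndarray] = {}
    if hotspot:
        for te in tes:
            sense_sites[te.name] = _hotspot_sites(
                params, te.name, "sense", 0, te.length - max_pirna_len
            )
            anti_sites[te.name] = _hotspot_sites(
                params, te.name, "antisense", max_pirna_len - 1, te.length - 1
            )

    def _sense_start(te: ReferenceFeature, length: int, for_pair: bool) -> int:
        lo = pair_s_min if for_pair else 0
        if hotspot:
            sites = sense_sites[te.name]
            valid = sites[sites >= lo] if for_pair else sites
            if len(valid):
                return int(rng.choice(valid))
        return int(rng.integers(lo, te.length - (max_pirna_len if for_pair else length) + 1))

    def _anti_five_prime(te: ReferenceFeature, length: int) -> int:
        if hotspot:
            return int(rng.choice(anti_sites[te.name]))
        return int(rng.integers(length - 1, te.length))

    for pair_id in range(n_pairs):
        te = tes[rng.integers(len(tes))]
        l_sense = _draw_length(rng, params.pirna_length_probs)
        l_anti = _draw_length(rng, params.pirna_length_probs)
        s = _sense_start(te, l_sense, for_pair=True)
        force_s = (PINGPONG_OVERLAP - 1, _biased_base(rng, params.a10_bias, "A"))
        emitter.emit(te, "te_piRNA", "sense", s, l_sense, force=force_s, pair_id=pair_id)
        anti_start = s + PINGPONG_OVERLAP - l_anti
        force_a = (0, _biased_base(rng, params.u1_bias, "T"))
        emitter.emit(te, "te_piRNA", "antisense", anti_start, l_anti, force=force_a, pair_id=pair_id)
        intended_pairs[te.name] += 1
    for _ in range(n_te_reads - 2 * n_pairs):
        te = tes[rng.integers(len(tes))]
        length = _draw_length(rng, params.pirna_length_probs)
        if rng.random() < params.sense_fraction:
            emitter.emit(te, "te_piRNA", "sense", _sense_start(te, length, False), length)
        else:
            start = _anti_five_prime(te, length) - length + 1
            force = (0, _biased_base(rng, params.u1_bias, "T"))
            emitter.emit(te, "te_piRNA", "antisense", start, length, force=force)

    # --- siRNAs (TE-derived, either strand, 20-22 nt) --------------------
    for _ in range(n_by_class["siRNA"]):
        te = tes[rng.integers(len(tes))]
        length = _draw_length(rng, params.sirna_length_probs)
        start = int(rng.integers(0, te.length - length + 1))
        orientation = "sense" if rng.random() < 0.5 else "antisense"
        emitter.emit(te, "siRNA", orientation, start, length)

    # --- miRNA-hairpin reads (exact sense substrings, 21-23 nt) ----------
    for _ in range(n_by_class["miRNA_hairpin"]):
        hp = hairpins[rng.integers(len(hairpins))]
        length = int(rng.integers(21, 24))
        start = int(rng.integers(0, hp.length - length + 1))
        emitter.emit(hp, "miRNA_hairpin", "sense", start, length)

    # --- rRNA fragments (any small-RNA length) ---------------------------
    for _ in range(n_by_class["rRNA"]):
        rr = rrnas[rng.integers(len(rrnas))] if rrnas else hairpins[0]
        length = int(rng.integers(20, 30))
        start = int(rng.integers(0, rr.length - length + 1))
        emitter.emit(rr, "rRNA", "sense", start, length)

    truth = GroundTruth(
        emissions=pd.DataFrame(
            emitter.rows,
            columns=[
                "read_id", "feature", "read_class", "orientation",
                "start", "length", "five_prime", "pair_id", "seq",
            ],
        ),
        intended_pairs=intended_pairs,
        class_totals={
            **{c: int(n_by_class[c]) for c in classes},
            "te_piRNA": int(n_te_reads),
            "cluster_piRNA": int(n_cluster),
        },
    )
    return emitter.reads, truth


@dataclass
class ConditionPair:
    """Replicate libraries for two conditions plus the applied fold design."""

    libraries_a: list[tuple[list[SmallRNARead], GroundTruth]]
    libraries_b: list[tuple[list[SmallRNARead], GroundTruth]]
    params_a: list[LibraryParams]
    params_b: list[LibraryParams]
    fold_by_class: dict[str, float]


def _replicate_seed(seed: int, condition: int, replicate: int) -> int:
    # fixed arithmetic so truth tables are reproducible from the root seed
    return (seed + 1000 * condition + replicate) % 2**31


def scaled_params(base: LibraryParams, fold_by_class: dict[str, float]) -> LibraryParams:
    """Condition-B parameters: class emissions scaled, hairpin count fixed.

    Expected per-class read counts are multiplied by the fold factor for
    that class (feature-class keys such as ``transposon`` map onto the
    read classes); the total read count grows accordingly, so a class
    with fold 1 — in particular the miRNA-hairpin normalizer — keeps its
    absolute expected emission.
    """
    folds = {c: 1.0 for c in READ_CLASSES}
    for key, fold in fold_by_class.items():
        read_class = _FOLD_KEYS.get(key, key)
        if read_class not in folds:
            raise ValueError(f"unknown class in fold_by_class: {key!r}")
        if fold <= 0:
            raise ValueError("fold factors must be > 0")
        folds[read_class] = fold
    expected = {c: base.n_reads * base.class_mix[c] * folds[c] for c in READ_CLASSES}
    total = sum(expected.values())
    return replace(
        base,
        n_reads=int(round(total)),
        class_mix={c: expected[c] / total for c in READ_CLASSES},
    )


def simulate_condition_pair(
    base: LibraryParams,
    fold_by_class: dict[str, float],
    n_replicates: int,
    refs: Sequence[ReferenceFeature],
    seed: int = 0,
) -> ConditionPair:
    """Simulate two conditions x n_replicates libraries from one design."""
    if n_replicates < 2:
        raise ValueError("differential tests need >= 2 replicates")
    base.validate()
    params_b_proto = scaled_params(base, fold_by_class)
    libraries_a, libraries_b, params_a, params_b = [], [], [], []
    for rep in range(n_replicates):
        pa = replace(base, seed=_replicate_seed(seed, 0, rep))
        pb = replace(params_b_proto, seed=_replicate_seed(seed, 1, rep))
        reads_a, truth_a = simulate_library(pa, refs)
        reads_b, truth_b = simulate_library(pb, refs)
        truth_a.fold_by_class = {k: 1.0 for k in fold_by_class}
        truth_b.fold_by_class = dict(fold_by_class)
        libraries_a.append((reads_a, truth_a))
        libraries_b.append((reads_b, truth_b))
        params_a.append(pa)
        params_b.append(pb)
    return ConditionPair(
        libraries_a=libraries_a,
        libraries_b=libraries_b,
        params_a=params_a,
        params_b=params_b,
        fold_by_class=dict(fold_by_class),
    )
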