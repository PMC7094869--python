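"""Readers/writers for the formats the pipeline touches.

All sequences are held as DNA internally: U is converted to T on input and
rendered back as U only where an output explicitly reports RNA identity
(the 5' nucleotide profile). FASTQ quality strings are validated for length
but carry no meaning downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_RNA_TO_DNA = str.maketrans("uU", "tT")


class ParseError(ValueError):
    """A malformed record in an input file; message names the file and line."""


class FeatureClass(str, enum.Enum):
    """Genomic class of a reference feature."""

    transposon = "transposon"
    piRNA_cluster = "piRNA_cluster"
    gene = "gene"
    miRNA_hairpin = "miRNA_hairpin"
    rRNA = "rRNA"


#: classes whose references reads are aligned to for quantification
QUANTIFIED_CLASSES = frozenset(
    {FeatureClass.transposon, FeatureClass.piRNA_cluster, FeatureClass.gene}
)
#: classes used for depletion (reads matching these are parsed out)
DEPLETION_CLASSES = frozenset({FeatureClass.rRNA, FeatureClass.miRNA_hairpin})


@dataclass
class SmallRNARead:
    """One sequencing read: identifier and base string (DNA alphabet)."""

    read_id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().translate(_RNA_TO_DNA)
        if not self.seq:
            raise ValueError(f"read {self.read_id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class ReferenceFeature:
    """A named reference sequence with a genomic-class label."""

    name: str
    seq: str
    feature_class: FeatureClass

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().translate(_RNA_TO_DNA)
        self.feature_class = FeatureClass(self.feature_class)

    @property
    def length(self) -> int:
        return len(self.seq)


def read_fastq(path: str | Path) -> Iterator[SmallRNARead]:
    """Yield reads from a Sanger FASTQ file in file order.

    Lowercase bases are uppercased and U converted to T. Raises
    :class:`ParseError` naming the (approximate, 4-line-record) line number
    on malformed records.
    """
    path = Path(path)
    with open(path) as handle:
        record_idx = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                if len(qual) != len(seq):
                    raise ValueError("quality/sequence length mismatch")
                yield SmallRNARead(read_id=title.split()[0], seq=seq)
                record_idx += 1
        except ValueError as exc:
            raise ParseError(
                f"{path}: malformed FASTQ record near line {4 * record_idx + 1}: {exc}"
            ) from exc


def write_fastq(reads: Iterable[SmallRNARead], path: str | Path) -> int:
    """Write reads as 4-line FASTQ with constant placeholder quality 'I'."""
    n = 0
    with open(path, "w") as handle:
        for read in reads:
            handle.write(f"@{read.read_id}\n{read.seq}\n+\n{'I' * read.length}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (name, seq) records; name is the first whitespace token.

    Multi-line sequences are concatenated. Sequence text before the first
    '>' header is a :class:`ParseError`.
    """
    path = Path(path)
    with open(path) as handle:
        for line in handle:
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path}: sequence data before first '>' header"
                    )
                break
        handle.seek(0)
        for title, seq in SimpleFastaParser(handle):
            yield title.split()[0], seq.upper().translate(_RNA_TO_DNA)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> int:
    n = 0
    with open(path, "w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
            n += 1
    return n


def read_reference_fasta(path: str | Path, annotation: dict[str, FeatureClass]) -> list[ReferenceFeature]:
    """Load a reference FASTA and attach feature classes from an annotation map."""
    features = []
    for name, seq in read_fasta(path):
        if name not in annotation:
            raise ValueError(f"reference {name!r} missing from annotation table")
        features.append(ReferenceFeature(name, seq, annotation[name]))
    return features


def load_annotation(path: str | Path) -> dict[str, FeatureClass]:
    """Load the two-column (name, class) TSV mapping features to classes.

    A literal ``name<TAB>class`` header row is tolerated. Unknown class
    tokens and duplicate names with conflicting classes are errors listing
    the offending rows.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "class"], dtype=str)
    if not df.empty and df.iloc[0].tolist() == ["name", "class"]:
        df = df.iloc[1:]
    valid = {c.value for c in FeatureClass}
    bad = df[~df["class"].isin(valid)]
    if not bad.empty:
        rows = ", ".join(f"{r.name!s}:{r['class']!s}" for _, r in bad.iterrows())
        raise ValueError(f"unknown feature class in annotation rows: {rows}")
    mapping: dict[str, FeatureClass] = {}
    conflicts = []
    for _, row in df.iterrows():
        cls = FeatureClass(row["class"])
        if row["name"] in mapping and mapping[row["name"]] is not cls:
            conflicts.append(row["name"])
        mapping[row["name"]] = cls
    if conflicts:
        raise ValueError(f"conflicting duplicate annotation for: {sorted(set(conflicts))}")
    return mapping


def write_annotation(annotation: dict[str, FeatureClass], path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, cls in annotation.items():
            handle.write(f"{name}\t{cls.value}\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV with a one-line header; floats at 6 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
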