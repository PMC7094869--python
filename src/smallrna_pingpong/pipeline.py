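"""End-to-end orchestration: clip -> deplete -> classify -> align -> count
-> ping-pong -> differential, from a single validated config.

Outputs are plain TSVs plus a JSON run manifest recording parameters,
input checksums and per-stage read reconciliation, so identical config +
inputs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import (
    class_summary,
    count_by_feature,
    normalize_hairpin,
    normalized_counts_table,
)
from .align import assign_reads
from .differential import class_tests, differential_table, global_fold_wilcoxon
from .io_formats import (
    DEPLETION_CLASSES,
    FeatureClass,
    read_fastq,
    read_reference_fasta,
    load_annotation,
    write_annotation,
    write_fasta,
    write_fastq,
    write_table,
)
from .pingpong import (
    compare_ratios,
    compute_pingpong,
    histograms_to_frame,
    ratios_to_frame,
)
from .preprocess import five_prime_profile, preprocess_library
from .synthetic import LibraryParams, generate_reference_set, simulate_condition_pair


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    fastq_a: list[Path]
    fastq_b: list[Path]
    references: Path
    annotation: Path
    output_dir: Path
    adapter: Optional[str] = None
    min_insert: int = 18
    min_match: int = 8
    max_mismatch: int = 1
    policy: str = "fractional"
    o_max: int = 30
    numerator: str = "reads"
    denominator: str = "per_feature"
    test: str = "t"
    fold_cut: float = 1.5
    fdr_cut: float = 0.1
    pseudocount: float = 1.0
    density_mode: str = "coverage"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        base = path.parent
        params = raw.get("parameters", {})
        cfg = cls(
            fastq_a=[base / p for p in raw["libraries"]["condition_a"]],
            fastq_b=[base / p for p in raw["libraries"]["condition_b"]],
            references=base / raw["references"],
            annotation=base / raw["annotation"],
            output_dir=base / raw.get("output_dir", "pipeline_out"),
            **{k: v for k, v in params.items() if k in cls.__dataclass_fields__},
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in [*self.fastq_a, *self.fastq_b, self.references, self.annotation]:
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if len(self.fastq_a) < 1 or len(self.fastq_b) < 1:
            raise ConfigError("each condition needs at least one library")
        if self.policy not in ("fractional", "unique_only"):
            raise ConfigError(f"unknown policy {self.policy!r}")
        if self.o_max < 10:
            raise ConfigError("o_max must be >= 10")


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class LibraryResult:
    name: str
    counts_table: pd.DataFrame
    class_fractions: pd.Series
    pingpong_table: pd.DataFrame
    histogram_table: pd.DataFrame
    hairpin_total: int
    library_total: int
    reconciliation: dict


@dataclass
class PipelineResult:
    libraries_a: list[LibraryResult]
    libraries_b: list[LibraryResult]
    differential: pd.DataFrame
    class_test_table: pd.DataFrame
    ratio_comparison_p: float
    global_fold_p: float
    output_dir: Path

    def abundance_matrix(self, condition: str) -> pd.DataFrame:
        libs = self.libraries_a if condition == "a" else self.libraries_b
        cols = {}
        for lib in libs:
            tab = lib.counts_table.set_index("feature")
            cols[lib.name] = tab["norm_hairpin_sense"] + tab["norm_hairpin_antisense"]
        return pd.DataFrame(cols).fillna(0.0)

    def ratio_matrix(self, condition: str) -> pd.DataFrame:
        libs = self.libraries_a if condition == "a" else self.libraries_b
        cols = {
            lib.name: lib.pingpong_table.set_index("feature")["ratio"] for lib in libs
        }
        return pd.DataFrame(cols)


def _process_library(
    name: str, fastq: Path, features, annotation, config: PipelineConfig, out_dir: Path
) -> LibraryResult:
    reads = list(read_fastq(fastq))
    depletion_refs = [f for f in features if f.feature_class in DEPLETION_CLASSES]
    quant_refs = [f for f in features if f.feature_class not in DEPLETION_CLASSES]
    pre = preprocess_library(
        reads,
        depletion_refs,
        adapter=config.adapter,
        min_insert=config.min_insert,
        min_match=config.min_match,
        max_mismatch=config.max_mismatch,
    )
    profile = five_prime_profile(pre.retained)
    assignment = assign_reads(
        pre.piRNA, quant_refs, policy=config.policy, max_mismatch=config.max_mismatch
    )
    counts = count_by_feature(
        assignment.alignments,
        hairpin_total=pre.hairpin_total,
        library_total=pre.library_total,
    )
    fractions = class_summary(counts, annotation)
    te_names = [f.name for f in quant_refs if f.feature_class is FeatureClass.transposon]
    read_seqs = {r.read_id: r.seq for r in pre.piRNA}
    pp = compute_pingpong(
        assignment.alignments,
        read_seqs,
        te_names,
        o_max=config.o_max,
        numerator=config.numerator,
        denominator=config.denominator,
    )
    counts_table = normalized_counts_table(counts, annotation)
    result = LibraryResult(
        name=name,
        counts_table=counts_table,
        class_fractions=fractions,
        pingpong_table=ratios_to_frame(pp),
        histogram_table=histograms_to_frame(pp),
        hairpin_total=pre.hairpin_total,
        library_total=pre.library_total,
        reconciliation={
            "n_input": pre.n_input,
            "n_discarded_clip": pre.n_discarded_clip,
            "n_depleted": sum(pre.depleted_counts.values()),
            "depleted_counts": pre.depleted_counts,
            "n_retained": len(pre.retained),
            "class_counts": pre.class_counts(),
            "n_piRNA_aligned": assignment.n_aligned,
            "n_piRNA_unaligned": assignment.n_unaligned,
            "n_multimap_dropped": assignment.n_multimap_dropped,
        },
    )
    write_table(counts_table, out_dir / f"counts_{name}.tsv")
    write_table(result.pingpong_table, out_dir / f"pingpong_ratios_{name}.tsv")
    write_table(result.histogram_table, out_dir / f"overlap_histogram_{name}.tsv")
    write_table(profile.to_frame(), out_dir / f"five_prime_profile_{name}.tsv")
    frac = fractions.rename("fraction").reset_index().rename(columns={"index": "class"})
    write_table(frac, out_dir / f"class_summary_{name}.tsv")
    return result


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the output TSVs plus a run manifest."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        annotation = load_annotation(config.annotation)
        features = read_reference_fasta(config.references, annotation)
    except Exception as exc:
        raise StageError("load_references", exc) from exc

    libs_a, libs_b = [], []
    for cond, paths, store in (("a", config.fastq_a, libs_a), ("b", config.fastq_b, libs_b)):
        for i, fastq in enumerate(paths):
            name = f"{cond}{i + 1}"
            try:
                store.append(
                    _process_library(name, fastq, features, annotation, config, out_dir)
                )
            except Exception as exc:
                raise StageError(f"library_{name}", exc) from exc

    result = PipelineResult(
        libraries_a=libs_a,
        libraries_b=libs_b,
        differential=pd.DataFrame(),
        class_test_table=pd.DataFrame(),
        ratio_comparison_p=float("nan"),
        global_fold_p=float("nan"),
        output_dir=out_dir,
    )
    try:
        abund_a = result.abundance_matrix("a")
        abund_b = result.abundance_matrix("b")
        diff = differential_table(
            abund_a,
            abund_b,
            test=config.test,
            pseudocount=config.pseudocount,
            fold_cut=config.fold_cut,
            fdr_cut=config.fdr_cut,
        )
        diff.insert(0, "class", [annotation[f].value for f in diff.index])
        result.differential = diff
        result.global_fold_p = global_fold_wilcoxon(
            diff.loc[diff["class"] == FeatureClass.transposon.value, "log2fc"].values
        )
        frac_a = pd.DataFrame({l.name: l.class_fractions for l in libs_a})
        frac_b = pd.DataFrame({l.name: l.class_fractions for l in libs_b})
        result.class_test_table = class_tests(frac_a, frac_b)
        comparison = compare_ratios(result.ratio_matrix("a"), result.ratio_matrix("b"))
        result.ratio_comparison_p = comparison.p_value
    except Exception as exc:
        raise StageError("differential", exc) from exc

    write_table(diff.reset_index(), out_dir / "differential.tsv")
    write_table(result.class_test_table, out_dir / "class_tests.tsv")
    manifest = {
        "version": __version__,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in vars(config).items()
            if k not in ("fastq_a", "fastq_b")
        },
        "inputs": {
            str(p): _md5(Path(p))
            for p in [*config.fastq_a, *config.fastq_b, config.references, config.annotation]
        },
        "libraries": {l.name: l.reconciliation for l in [*libs_a, *libs_b]},
        "ratio_comparison_p": None
        if np.isnan(result.ratio_comparison_p)
        else result.ratio_comparison_p,
        "global_fold_wilcoxon_p": None
        if np.isnan(result.global_fold_p)
        else result.global_fold_p,
    }
    with open(out_dir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return result


def simulate_dataset(
    out_dir: str | Path,
    base: Optional[LibraryParams] = None,
    fold_by_class: Optional[dict[str, float]] = None,
    n_replicates: int = 3,
    n_te: int = 6,
    te_length: int = 1000,
    n_hairpins: int = 5,
    seed: int = 0,
) -> Path:
    """Write a ready-to-run synthetic dataset (FASTQs, refs, truth, config).

    Three biological replicates per condition by default, matching the
    study design the differential analysis assumes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = base if base is not None else LibraryParams()
    fold_by_class = fold_by_class or {"transposon": 1.0}
    refs = generate_reference_set(
        n_te=n_te, te_length=te_length, n_hairpins=n_hairpins, seed=seed
    )
    pair = simulate_condition_pair(base, fold_by_class, n_replicates, refs, seed=seed)
    write_fasta([(f.name, f.seq) for f in refs], out_dir / "references.fasta")
    write_annotation({f.name: f.feature_class for f in refs}, out_dir / "annotation.tsv")
    lib_paths: dict[str, list[str]] = {"condition_a": [], "condition_b": []}
    for cond, libs in (("a", pair.libraries_a), ("b", pair.libraries_b)):
        for i, (reads, truth) in enumerate(libs):
            name = f"{cond}{i + 1}"
            fastq = f"{name}.fastq"
            write_fastq(reads, out_dir / fastq)
            write_table(truth.to_table(), out_dir / f"truth_{name}.tsv")
            lib_paths[f"condition_{cond}"].append(fastq)
    config = {
        "libraries": lib_paths,
        "references": "references.fasta",
        "annotation": "annotation.tsv",
        "output_dir": "pipeline_out",
        "parameters": {
            "adapter": base.adapter,
            "seed": seed,
        },
    }
    with open(out_dir / "config.yaml", "w") as handle:
        yaml.safe_dump(config, handle, sort_keys=True)
    with open(out_dir / "params.yaml", "w") as handle:
        yaml.safe_dump(
            {
                "n_reads": base.n_reads,
                "class_mix": base.class_mix,
                "pingpong_fraction": base.pingpong_fraction,
                "u1_bias": base.u1_bias,
                "a10_bias": base.a10_bias,
                "sense_fraction": base.sense_fraction,
                "fold_by_class": fold_by_class,
                "n_replicates": n_replicates,
                "seed": seed,
            },
            handle,
            sort_keys=True,
        )
    return out_dir
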