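#!/usr/bin/env python
"""Summarize differential piRNA abundance between conditions.

Reads the pipeline's differential table (hairpin-normalized abundances,
log2 fold changes, BH-adjusted q, calls at >1.5-fold and FDR<0.1) and
the per-class t-tests, and reports which feature classes moved. Writes
results/differential_summary.tsv.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "dataset" / "pipeline_out"


def main() -> None:
    diff = pd.read_csv(OUT / "differential.tsv", sep="\t")
    classes = pd.read_csv(OUT / "class_tests.tsv", sep="\t")

    print("per-feature differential calls (fold >1.5, FDR <0.1):")
    cols = ["feature", "class", "mean_abundance_a", "mean_abundance_b", "log2fc", "q", "call"]
    print(diff[cols].to_string(index=False, float_format=lambda x: f"{x:.3g}"))

    by_class = diff.groupby("class")["call"].value_counts().unstack(fill_value=0)
    print("\ncalls by feature class:")
    print(by_class.to_string())

    print("\nper-class library-fraction t-tests:")
    print(classes.to_string(index=False, float_format=lambda x: f"{x:.3g}"))

    n_up = (diff["call"] == "up").sum()
    te = diff[diff["class"] == "transposon"]
    print(
        f"\n{n_up} features called up; transposon median fold "
        f"{(2 ** te['log2fc']).median():.2f} (design: 3.0)"
    )
    out_path = ROOT / "results" / "differential_summary.tsv"
    diff.to_csv(out_path, sep="\t", index=False, float_format="%.6g")
    print(f"differential table written to {out_path}")


if __name__ == "__main__":
    main()
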