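"""Replicate-aware differential abundance: t-tests, Wilcoxon, BH, calls.

The per-feature negative-binomial model of dedicated count-based tools is
deliberately replaced by a defined test battery on hairpin-normalized
abundances: equal-variance Student's t per feature/class across
replicates, a global Wilcoxon signed-rank on per-feature fold changes,
Benjamini-Hochberg adjustment, and calls at a fold-change plus FDR cutoff
(defaults 1.5-fold, FDR < 0.1).
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_WILCOXON_MAX_N = 25


def log2_fold_change(a: float, b: float, pseudocount: float = 1.0) -> float:
    """log2((b + pseudocount) / (a + pseudocount)); inputs must be >= 0."""
    if a < 0 or b < 0:
        raise ValueError("abundances must be non-negative")
    return float(np.log2((b + pseudocount) / (a + pseudocount)))


def students_t(
    group_a: Sequence[float], group_b: Sequence[float], equal_var: bool = True
) -> float:
    """Two-sided two-sample t-test p-value (Student's by default, Welch by flag)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def wilcoxon_signed_rank(
    diffs: Sequence[float],
    alternative: Literal["two-sided", "greater", "less"] = "two-sided",
) -> float:
    """Signed-rank p-value on paired differences.

    Zero differences are dropped; ties are mid-ranked. The exact null
    distribution is used for n <= 25, the normal approximation with
    continuity correction above. All differences zero gives p = 1; 1-4
    nonzero differences leave p undefined (NaN).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    if len(d) < 5:
        return float("nan")
    method = "exact" if len(d) <= EXACT_WILCOXON_MAX_N else "approx"
    res = stats.wilcoxon(d, alternative=alternative, correction=True, method=method)
    return float(res.pvalue)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, permutation-stable)."""
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    records: pd.DataFrame, fold_cut: float = 1.5, fdr_cut: float = 0.1
) -> pd.DataFrame:
    """Attach up/down/unchanged calls from log2fc and BH-adjusted q."""
    out = records.copy()
    fold = 2.0 ** out["log2fc"].astype(float)
    up = (fold > fold_cut) & (out["q"] < fdr_cut)
    down = (fold < 1.0 / fold_cut) & (out["q"] < fdr_cut)
    out["call"] = np.where(up, "up", np.where(down, "down", "unchanged"))
    return out


def differential_table(
    abund_a: pd.DataFrame,
    abund_b: pd.DataFrame,
    test: Literal["t", "wilcoxon"] = "t",
    pseudocount: float = 1.0,
    fold_cut: float = 1.5,
    fdr_cut: float = 0.1,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-feature differential records between two replicate tables.

    Inputs are feature x replicate tables of hairpin-normalized
    abundances (missing features count as 0). The per-feature test runs on
    log2(abundance + pseudocount) across replicates; fold change is taken
    on replicate means with the same pseudocount.
    """
    features = abund_a.index.union(abund_b.index)
    a = abund_a.reindex(features).fillna(0.0)
    b = abund_b.reindex(features).fillna(0.0)
    rows = []
    for feature in features:
        va, vb = a.loc[feature].values, b.loc[feature].values
        la, lb = np.log2(va + pseudocount), np.log2(vb + pseudocount)
        if test == "t":
            p = students_t(la, lb, equal_var=equal_var)
        elif test == "wilcoxon":
            if len(la) != len(lb):
                raise ValueError("wilcoxon per-feature test needs paired replicates")
            p = wilcoxon_signed_rank(lb - la)
        else:
            raise ValueError(f"unknown test: {test!r}")
        rows.append(
            {
                "feature": feature,
                "mean_abundance_a": float(np.mean(va)),
                "mean_abundance_b": float(np.mean(vb)),
                "log2fc": log2_fold_change(float(np.mean(va)), float(np.mean(vb)), pseudocount),
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    out["q"] = bh_adjust(np.nan_to_num(out["p"].values, nan=1.0))
    return call_differential(out, fold_cut=fold_cut, fdr_cut=fdr_cut)


def global_fold_wilcoxon(log2fcs: Sequence[float]) -> float:
    """Global Wilcoxon signed-rank on per-feature log2 fold changes (vs 0)."""
    return wilcoxon_signed_rank(np.asarray(log2fcs, dtype=float))


def class_tests(frac_a: pd.DataFrame, frac_b: pd.DataFrame, equal_var: bool = True) -> pd.DataFrame:
    """Per-class Student's t on library-fraction replicates between conditions."""
    classes = frac_a.index.intersection(frac_b.index)
    rows = []
    for cls in classes:
        va, vb = frac_a.loc[cls].values, frac_b.loc[cls].values
        rows.append(
            {
                "class": cls,
                "mean_fraction_a": float(np.mean(va)),
                "mean_fraction_b": float(np.mean(vb)),
                "p": students_t(va, vb, equal_var=equal_var),
            }
        )
    return pd.DataFrame(rows, columns=["class", "mean_fraction_a", "mean_fraction_b", "p"])
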