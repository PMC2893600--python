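"""Differential expression between genotypes and mask-condition comparison.

Genes differentially expressed between the two genotypes within one tissue
are detected on the summarized log2 expression with a two-sample pooled-
variance t-test (Welch optional), Benjamini-Hochberg FDR across all tested
probe sets, and a fold-change cutoff.  Defaults follow the conventional
strict microarray setting: p < 0.001, FDR < 0.05, >= 2-fold.

``mask_condition_compare`` contrasts the DE gene sets obtained with no
mask, an ISV mask, and the ISV+SFP double mask to estimate putative false
positives and negatives attributable to sequence variation.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["bh_fdr", "ttest_de", "mask_condition_compare"]


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def ttest_de(expr: pd.DataFrame, group_a: list[str], group_b: list[str],
             p_cut: float = 0.001, fdr_cut: float = 0.05, fold_cut: float = 2.0,
             exclude: Iterable[str] = (), welch: bool = False) -> pd.DataFrame:
    """Per-probe-set two-sample t-test of group A vs group B.

    ``exclude`` holds regular-expression patterns; probe sets whose id
    matches any pattern (e.g. microsymbiont controls) are removed before
    testing, so they do not enter the FDR correction.  Significance requires
    p < p_cut, FDR < fdr_cut and |log2fc| >= log2(fold_cut).  Probe sets
    with zero variance in both groups and equal means get t=0, p=1 by
    convention.  Returns a DataFrame indexed by probeset_id with columns
    log2fc, t_stat, p_value, fdr, significant.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    tested = expr
    if exclude:
        patterns = [re.compile(p) for p in exclude]
        keep = [pid for pid in expr.index if not any(p.search(pid) for p in patterns)]
        tested = expr.loc[keep]
    a = tested.loc[:, group_a].to_numpy()
    b = tested.loc[:, group_b].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    degenerate = ~np.isfinite(p)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    fdr = bh_fdr(p)
    significant = (p < p_cut) & (fdr < fdr_cut) & (np.abs(log2fc) >= np.log2(fold_cut))
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t_stat": t,
            "p_value": p,
            "fdr": fdr,
            "significant": significant,
        },
        index=tested.index,
    )


def de_gene_set(results: pd.DataFrame) -> set[str]:
    """Ids of significant probe sets from a ``ttest_de`` result frame."""
    return set(results.index[results["significant"]])


def mask_condition_compare(de_none: set[str], de_isv: set[str],
                           de_double: set[str]) -> Mapping[str, object]:
    """Label the Venn regions of three DE sets from the same contrast.

    Returns the putative-false-positive and false-negative counts implied
    by treating the double-masked calls as the reference, plus the full
    3-set Venn region counts.
    """
    de_none, de_isv, de_double = set(de_none), set(de_isv), set(de_double)
    venn = {
        "none_only": len(de_none - de_isv - de_double),
        "isv_only": len(de_isv - de_none - de_double),
        "double_only": len(de_double - de_none - de_isv),
        "none_isv": len((de_none & de_isv) - de_double),
        "none_double": len((de_none & de_double) - de_isv),
        "isv_double": len((de_isv & de_double) - de_none),
        "all": len(de_none & de_isv & de_double),
    }
    return {
        "putative_fp_isv_sfp": len(de_none - de_double),
        "putative_fp_sfp": len(de_isv - de_double),
        "putative_fn": len(de_double - (de_none | de_isv)),
        "venn": venn,
    }
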