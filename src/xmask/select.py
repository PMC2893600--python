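"""Choosing the masking threshold from cross-species sensitivity and accuracy.

For each candidate threshold the target-species data are masked and
summarized, the PES/ES log2 ratio is computed per gene, and two quantities
are evaluated against the unmasked reference-species ratios:

* sensitivity — the number of commonly-selected genes, i.e. genes with at
  least a 2-fold PES-vs-ES difference in BOTH species;
* accuracy — the Pearson correlation of the two species' log2(PES/ES)
  ratios over those common genes.

The operating threshold is the one that maximizes the worse of the two
metrics after min-max scaling each over the threshold series (a maximin
formalization of the point where the rising accuracy curve and the falling
sensitivity curve intersect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MaskFile, ProbeIntensityMatrix, ProbeSetMap, SampleSheet
from .masking import apply_mask
from .summarize import median_polish_summarize

__all__ = [
    "ThresholdCurve",
    "log_ratio",
    "commonly_selected",
    "threshold_curve",
    "pick_threshold",
    "species_log_ratios",
]

MIN_COMMON_FOR_R = 3


@dataclass(frozen=True)
class ThresholdCurve:
    """Sensitivity/accuracy summary of one masking threshold."""

    threshold: float
    n_probes_retained: int
    n_probesets_retained: int
    n_common_genes: int
    pearson_r: float  # NaN when fewer than 3 common genes

    @property
    def r_defined(self) -> bool:
        return np.isfinite(self.pearson_r)


def log_ratio(expr: pd.DataFrame, group_a: list[str], group_b: list[str]) -> pd.Series:
    """Mean log2 expression of group A minus group B, per probe set."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    return expr.loc[:, list(group_a)].mean(axis=1) - expr.loc[:, list(group_b)].mean(axis=1)


def commonly_selected(ratios_ref: pd.Series, ratios_target: pd.Series,
                      fold: float = 2.0, concordant: bool = False) -> pd.Index:
    """Genes with |log2 ratio| >= log2(fold) in both species.

    Direction need not agree unless ``concordant=True``.
    """
    shared = ratios_ref.index.intersection(ratios_target.index)
    if len(shared) == 0:
        raise ValueError("ratio vectors share no genes")
    cut = np.log2(fold)
    a = ratios_ref.loc[shared]
    b = ratios_target.loc[shared]
    sel = (a.abs() >= cut) & (b.abs() >= cut)
    if concordant:
        sel &= np.sign(a) == np.sign(b)
    return shared[sel]


def species_log_ratios(expr: pd.DataFrame, sheet: SampleSheet, species: str,
                       genotype: str | None = None) -> pd.Series:
    """log2(PES/ES) per probe set for one species (optionally one genotype)."""
    pes = sheet.samples_of(species, genotype=genotype, tissue="PES")
    es = sheet.samples_of(species, genotype=genotype, tissue="ES")
    return log_ratio(expr, pes, es)


def threshold_curve(norm_target: ProbeIntensityMatrix, ref_expr: pd.DataFrame,
                    masks: list[MaskFile], pmap: ProbeSetMap,
                    ref_samples: SampleSheet, *,
                    target_genotype: str | None = None, fold: float = 2.0,
                    concordant: bool = False,
                    min_probes: int = 1) -> list[ThresholdCurve]:
    """Evaluate every mask of a threshold series.

    ``norm_target`` holds the normalized target-species probe data;
    ``ref_expr`` is the reference species' expression computed once without
    masking.  The PES/ES ratio in the target is taken within
    ``target_genotype`` when given, else across all target samples.
    """
    ratios_ref = species_log_ratios(ref_expr, ref_samples, "reference")
    sheet = norm_target.samples
    pes = sheet.samples_of("target", genotype=target_genotype, tissue="PES")
    es = sheet.samples_of("target", genotype=target_genotype, tissue="ES")
    curves: list[ThresholdCurve] = []
    for mask in masks:
        masked = apply_mask(norm_target, mask)
        expr = median_polish_summarize(masked, pmap, min_probes=min_probes)
        if expr.empty:
            curves.append(ThresholdCurve(mask.threshold, masked.n_probes, 0, 0, float("nan")))
            continue
        ratios_t = log_ratio(expr, pes, es)
        common = commonly_selected(ratios_ref, ratios_t, fold=fold, concordant=concordant)
        if len(common) >= MIN_COMMON_FOR_R:
            r = float(stats.pearsonr(ratios_ref.loc[common], ratios_t.loc[common])[0])
        else:
            r = float("nan")
        curves.append(
            ThresholdCurve(
                threshold=mask.threshold,
                n_probes_retained=masked.n_probes,
                n_probesets_retained=expr.shape[0],
                n_common_genes=int(len(common)),
                pearson_r=r,
            )
        )
    return curves


def _minmax(x: np.ndarray) -> np.ndarray:
    rng = x.max() - x.min()
    if rng <= 0:
        return np.ones_like(x)
    return (x - x.min()) / rng


def pick_threshold(curves: list[ThresholdCurve]) -> float:
    """Maximin of min-max-scaled sensitivity and accuracy; ties -> smaller.

    Only thresholds with a defined correlation compete; scaling is performed
    over that subset.
    """
    defined = [c for c in curves if c.r_defined]
    if len(defined) < 2:
        raise ValueError("need at least two thresholds with a defined correlation")
    sens = _minmax(np.array([c.n_common_genes for c in defined], dtype=float))
    acc = _minmax(np.array([c.pearson_r for c in defined]))
    score = np.minimum(sens, acc)
    thresholds = np.array([c.threshold for c in defined])
    order = np.lexsort((thresholds, -score))  # best score, then smallest threshold
    return float(thresholds[order[0]])


def curves_to_frame(curves: list[ThresholdCurve]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "threshold": [c.threshold for c in curves],
            "n_probes_retained": [c.n_probes_retained for c in curves],
            "n_probesets_retained": [c.n_probesets_retained for c in curves],
            "n_common_genes": [c.n_common_genes for c in curves],
            "pearson_r": [c.pearson_r for c in curves],
        }
    )
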