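"""Multi-chip probe set summarization by Tukey median polish.

After masking, each probe set's retained log2 intensities form a probes x
samples table which is decomposed additively as
``log2(I) = overall + probe effect + sample effect + residual`` by median
polish (row sweeps then column sweeps, as in R's ``medpolish``).  The probe
set expression index per sample is ``overall + sample effect`` — the RMA
summary for PM probes.

Probe sets are polished in stacks grouped by their retained probe count so
that thousands of small polishes reduce to a handful of vectorized sweeps;
convergence is tracked per probe set, so results are identical to polishing
each table on its own.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .io import ProbeIntensityMatrix, ProbeSetMap

__all__ = ["median_polish", "median_polish_summarize"]

log = logging.getLogger(__name__)

_MAX_ITER = 10
_EPS = 0.01


def _polish_stack(X: np.ndarray, max_iter: int = _MAX_ITER,
                  eps: float = _EPS) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Median-polish a stack of G tables of identical shape (G, p, n).

    Returns (overall, row_effects, col_effects) with shapes (G,), (G, p)
    and (G, n).  Sweeps rows
    then columns; a table stops updating once the change in its total
    absolute residual drops below ``eps`` relative, matching the classic
    medpolish stopping rule.
    """
    G, p, n = X.shape
    overall = np.zeros(G)
    row_eff = np.zeros((G, p))
    col_eff = np.zeros((G, n))
    z = X.astype(float).copy()
    oldsum = np.zeros(G)
    active = np.arange(G)
    for _ in range(max_iter):
        if active.size == 0:
            break
        za = z[active]
        rdelta = np.median(za, axis=2)
        za -= rdelta[:, :, None]
        row_eff[active] += rdelta
        delta = np.median(col_eff[active], axis=1)
        col_eff[active] -= delta[:, None]
        overall[active] += delta
        cdelta = np.median(za, axis=1)
        za -= cdelta[:, None, :]
        col_eff[active] += cdelta
        delta = np.median(row_eff[active], axis=1)
        row_eff[active] -= delta[:, None]
        overall[active] += delta
        z[active] = za
        newsum = np.abs(za).sum(axis=(1, 2))
        converged = (newsum == 0) | (np.abs(newsum - oldsum[active]) < eps * newsum)
        oldsum[active] = newsum
        active = active[~converged]
    return overall, row_eff, col_eff


def median_polish(table: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Polish a single probes x samples table; returns (overall, row, col)."""
    X = np.asarray(table, dtype=float)[None, :, :]
    overall, row_eff, col_eff = _polish_stack(X)
    return float(overall[0]), row_eff[0], col_eff[0]


def median_polish_summarize(masked: ProbeIntensityMatrix, pmap: ProbeSetMap,
                            min_probes: int = 1) -> pd.DataFrame:
    """Summarize retained probes into probe set log2 expression indexes.

    Probe sets retaining fewer than ``min_probes`` probes are dropped (and
    counted in the log); a probe set with a single retained probe reduces to
    that probe's log2 values.  Returns a probeset x sample DataFrame sorted
    by probe set id.
    """
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    if masked.n_probes == 0:
        warnings.warn("empty matrix; empty expression returned")
        return pd.DataFrame(columns=masked.values.columns, dtype=float).rename_axis("probeset_id")
    vals = masked.values
    if masked.scale == "linear":
        vals = np.log2(vals)
    membership = pmap.probeset_of()
    probesets = membership.reindex(vals.index)
    known = probesets.notna()
    if not known.all():
        log.info("dropping %d probes absent from the probe map", int((~known).sum()))
        vals = vals.loc[known]
        probesets = probesets.loc[known]
    sizes = probesets.groupby(probesets).size()
    n_total_sets = len(pmap.probeset_ids)
    dropped = n_total_sets - len(sizes) + int((sizes < min_probes).sum())
    log.info(
        "summarizing %d probe sets (%d of %d dropped below min_probes=%d)",
        int((sizes >= min_probes).sum()), dropped, n_total_sets, min_probes,
    )
    keep_sets = sizes.index[sizes >= min_probes]
    order = np.argsort(probesets.to_numpy(), kind="stable")
    vals_sorted = vals.to_numpy()[order]
    sets_sorted = probesets.to_numpy()[order]
    uniq, starts, counts = np.unique(sets_sorted, return_index=True, return_counts=True)

    n_samples = vals.shape[1]
    results: dict[str, np.ndarray] = {}
    for size in np.unique(counts):
        if size < min_probes:
            continue
        sel = counts == size
        block_starts = starts[sel]
        ids = uniq[sel]
        stack = np.stack(
            [vals_sorted[s:s + size] for s in block_starts]
        ) if size > 0 else np.empty((0, 0, n_samples))
        overall, _, col_eff = _polish_stack(stack)
        expr = overall[:, None] + col_eff
        for pid, row in zip(ids, expr):
            results[pid] = row
    out = pd.DataFrame.from_dict(results, orient="index", columns=vals.columns)
    out = out.loc[sorted(set(out.index) & set(keep_sets))]
    out.index.name = "probeset_id"
    return out
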