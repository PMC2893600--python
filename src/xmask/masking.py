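"""Construction and application of probe masks.

The ISV (inter-species variable region) mask is intensity-driven: at a given
signal intensity threshold a probe is kept only if at least R of the Ts
normalized arrays show it at or above the threshold, where R is the number
of replicates per sample type.  Equivalently the probe is masked when it
falls below threshold in at least ceil(P * Ts) = Ts - R + 1 arrays, with the
defined percentage P = (Ts - R + 1) / Ts.  A mask applies to all samples.

SFP masks simply list probes overlapping known single-feature polymorphisms
between the two genotypes; double-masking is the union of the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import MaskFile, ProbeIntensityMatrix, SampleSheet, SchemaError

__all__ = [
    "DEFAULT_THRESHOLDS",
    "MaskRuleParams",
    "compute_mask_percentage",
    "build_isv_mask",
    "build_threshold_series",
    "build_sfp_mask",
    "combine_masks",
    "apply_mask",
]

#: The signal intensity points at which ISV masks are built by default.
DEFAULT_THRESHOLDS: tuple[float, ...] = (
    5, 7, 10, 15, 20, 30, 40, 60, 80, 100, 120, 160, 320, 640, 1280, 2560,
)


def compute_mask_percentage(ts: int, r: int, s: int = 1) -> float:
    """Defined percentage P of the retention rule, rounded to 2 decimals.

    A probe is kept iff at least R of the Ts arrays are at/above threshold,
    i.e. masked iff below threshold in >= Ts - R + 1 arrays, so
    P = (Ts - R + 1) / Ts.  For the balanced 2x2x3 design (Ts=12, R=3)
    this gives 0.83.
    """
    if not (1 <= r <= ts):
        raise ValueError(f"need 1 <= R <= Ts, got R={r}, Ts={ts}")
    if s < 1:
        raise ValueError(f"need S >= 1, got S={s}")
    return round((ts - r + 1) / ts, 2)


@dataclass(frozen=True)
class MaskRuleParams:
    """Design constants (Ts, R, S) of one species plus the percentage P."""

    ts: int
    r: int
    s: int
    p: float = 0.0

    def __post_init__(self) -> None:
        p = compute_mask_percentage(self.ts, self.r, self.s)
        if self.p and abs(self.p - p) > 0.005 + 1e-9:
            raise ValueError(f"P={self.p} inconsistent with (Ts-R+1)/Ts={p}")
        object.__setattr__(self, "p", p)

    @classmethod
    def from_sample_sheet(cls, sheet: SampleSheet, species: str) -> "MaskRuleParams":
        ts, r, s = sheet.design(species)
        return cls(ts=ts, r=r, s=s)


def build_isv_mask(norm: ProbeIntensityMatrix, threshold: float,
                   params: MaskRuleParams) -> MaskFile:
    """Mask every probe seen at/above ``threshold`` in fewer than R arrays."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    if params.ts != len(norm.samples.sample_ids):
        raise SchemaError(
            f"params expect Ts={params.ts} samples, matrix has "
            f"{len(norm.samples.sample_ids)}"
        )
    n_above = (norm.values.to_numpy() >= threshold).sum(axis=1)
    masked = norm.probe_ids[n_above < params.r]
    return MaskFile(
        masked_probe_ids=frozenset(masked),
        threshold=float(threshold),
        percentage_p=params.p,
        provenance="ISV",
    )


def build_threshold_series(norm: ProbeIntensityMatrix,
                           thresholds: Sequence[float] | None = None,
                           params: MaskRuleParams | None = None) -> list[MaskFile]:
    """One ISV mask per threshold; masked sets are nested in threshold."""
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    thresholds = [float(t) for t in thresholds]
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    if params is None:
        species = norm.samples.species
        if len(species) != 1:
            raise SchemaError("matrix spans several species; pass params explicitly")
        params = MaskRuleParams.from_sample_sheet(norm.samples, species[0])
    return [build_isv_mask(norm, t, params) for t in thresholds]


def build_sfp_mask(sfps: Iterable[str], universe: Iterable[str]) -> MaskFile:
    """Mask the listed SFP probes; unknown ids are dropped with a warning."""
    sfp_set = set(sfps)
    known = set(universe)
    unknown = sfp_set - known
    if unknown:
        warnings.warn(
            f"dropping {len(unknown)} SFP probe ids absent from the probe universe"
        )
    kept = sfp_set & known
    if not kept:
        warnings.warn("SFP mask is empty")
    return MaskFile(frozenset(kept), threshold=0.0, percentage_p=1.0, provenance="SFP")


def combine_masks(a: MaskFile, b: MaskFile) -> MaskFile:
    """Union of two masks (double-masking)."""
    return MaskFile(
        a.masked_probe_ids | b.masked_probe_ids,
        threshold=max(a.threshold, b.threshold),
        percentage_p=min(a.percentage_p, b.percentage_p),
        provenance="combined",
    )


def apply_mask(m: ProbeIntensityMatrix, mask: MaskFile) -> ProbeIntensityMatrix:
    """Drop masked probes from all samples."""
    keep = ~m.probe_ids.isin(mask.masked_probe_ids)
    if not keep.any():
        warnings.warn("mask removes every probe; matrix is empty")
    return m.with_values(m.values.loc[keep])
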