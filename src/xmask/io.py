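"""Domain types and flat-file readers/writers shared by the whole pipeline.

Every table the pipeline touches is tab-separated UTF-8 with a single header
row; lines starting with ``#`` are comments and are ignored on read.  Mask
files are plain probe-id lists with a small ``# key=value`` header carrying
the threshold metadata that produced them.  Coordinates in locus tables are
0-based; genome windows are half-open ``[start, start + W)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "SchemaError",
    "SampleSheet",
    "ProbeIntensityMatrix",
    "ProbeSetMap",
    "MaskFile",
    "LocusTable",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_probe_matrix",
    "write_probe_matrix",
    "read_probe_map",
    "write_probe_map",
    "read_mask_file",
    "write_mask_file",
    "read_expression",
    "write_expression",
    "read_locus_table",
    "write_locus_table",
    "read_sfp_list",
    "write_sfp_list",
]

SPECIES_VALUES = ("reference", "target")
TISSUE_VALUES = ("ES", "PES")


class FormatError(ValueError):
    """A file is syntactically malformed (bad header, duplicate ids, ...)."""


class SchemaError(ValueError):
    """Inputs are individually well formed but mutually inconsistent."""


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def _write_tsv(df: pd.DataFrame, path, header_comments: Sequence[str] = ()) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSheet:
    """The hybridization design: one row per array/sample.

    Columns: ``sample_id``, ``species`` (reference|target), ``genotype``,
    ``tissue`` (ES|PES), ``replicate``.  Within one species the design must
    be balanced: every (genotype, tissue) sample type has the same number of
    replicates R.  ``Ts`` is the total number of sample files of a species,
    ``S`` the number of sample types and ``R`` the replicates per type.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "species", "genotype", "tissue", "replicate"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        t = self.table.loc[:, required].copy()
        t["replicate"] = t["replicate"].astype(int)
        if (t["replicate"] < 1).any():
            raise FormatError("replicate numbers must be positive integers")
        if t["sample_id"].duplicated().any():
            dups = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        bad = set(t["species"]) - set(SPECIES_VALUES)
        if bad:
            raise FormatError(f"unknown species labels: {sorted(bad)}")
        bad = set(t["tissue"]) - set(TISSUE_VALUES)
        if bad:
            raise FormatError(f"unknown tissue labels: {sorted(bad)}")
        object.__setattr__(self, "table", t.reset_index(drop=True))
        for sp in self.species:
            self.design(sp)  # validates balance

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def species(self) -> list[str]:
        return sorted(self.table["species"].unique())

    def subset(self, species: str) -> "SampleSheet":
        sub = self.table[self.table["species"] == species]
        if sub.empty:
            raise SchemaError(f"no samples for species {species!r}")
        return SampleSheet(sub)

    def design(self, species: str) -> tuple[int, int, int]:
        """Return (Ts, R, S) for one species, validating a balanced design."""
        sub = self.table[self.table["species"] == species]
        if sub.empty:
            raise SchemaError(f"no samples for species {species!r}")
        sizes = sub.groupby(["genotype", "tissue"]).size()
        if sizes.nunique() != 1:
            raise SchemaError(
                f"unbalanced design for species {species!r}: "
                f"replicate counts {sorted(set(sizes))}"
            )
        ts = len(sub)
        s = len(sizes)
        r = int(sizes.iloc[0])
        return ts, r, s

    def samples_of(self, species: str, genotype: str | None = None,
                   tissue: str | None = None) -> list[str]:
        sub = self.table[self.table["species"] == species]
        if genotype is not None:
            sub = sub[sub["genotype"] == genotype]
        if tissue is not None:
            sub = sub[sub["tissue"] == tissue]
        return sub["sample_id"].tolist()


def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(_read_tsv(path))


def write_sample_sheet(sheet: SampleSheet, path) -> Path:
    return _write_tsv(sheet.table, path)


# ---------------------------------------------------------------------------
# Probe intensity matrix
# ---------------------------------------------------------------------------


@dataclass
class ProbeIntensityMatrix:
    """Probe-level intensities, probes x samples, plus the sample sheet.

    ``values`` is indexed by probe_id with one column per sample_id, in the
    sample-sheet order.  ``scale`` records whether values are linear
    intensities (strictly positive) or log2.
    """

    values: pd.DataFrame
    samples: SampleSheet
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be linear or log2, got {self.scale!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate probe ids: {dups[:5]}")
        sheet_ids = self.samples.sample_ids
        cols = list(self.values.columns)
        if set(cols) != set(sheet_ids):
            raise SchemaError(
                "matrix columns do not match sample sheet: "
                f"matrix-only={sorted(set(cols) - set(sheet_ids))[:5]} "
                f"sheet-only={sorted(set(sheet_ids) - set(cols))[:5]}"
            )
        self.values = self.values.loc[:, sheet_ids].astype(float)
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite intensities")
        if self.scale == "linear" and (self.values.to_numpy() <= 0).any():
            raise ValueError("linear-scale intensities must be strictly positive")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_probes(self) -> int:
        return len(self.values)

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ProbeIntensityMatrix":
        return ProbeIntensityMatrix(values, self.samples, scale or self.scale)

    def subset_samples(self, species: str) -> "ProbeIntensityMatrix":
        sub = self.samples.subset(species)
        return ProbeIntensityMatrix(self.values.loc[:, sub.sample_ids], sub, self.scale)


def read_probe_matrix(path, samplesheet) -> ProbeIntensityMatrix:
    """Read a probe x sample TSV (header: probe_id then sample ids)."""
    sheet = samplesheet if isinstance(samplesheet, SampleSheet) else read_sample_sheet(samplesheet)
    df = _read_tsv(path)
    if df.columns[0] != "probe_id":
        raise FormatError(f"first column must be 'probe_id', got {df.columns[0]!r}")
    if df["probe_id"].isna().any() or df["probe_id"].duplicated().any():
        raise FormatError("missing or duplicate probe ids")
    values = df.set_index("probe_id").astype(float)
    return ProbeIntensityMatrix(values, sheet, "linear")


def write_probe_matrix(m: ProbeIntensityMatrix, path,
                       header_comments: Sequence[str] = ()) -> Path:
    df = m.values.reset_index()
    df.columns = ["probe_id", *m.values.columns]
    return _write_tsv(df, path, header_comments)


# ---------------------------------------------------------------------------
# Probe -> probe set map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeSetMap:
    """Assignment of probes to probe sets (the CDF-like table), PM only."""

    table: pd.DataFrame  # probe_id, probeset_id, probe_index

    def __post_init__(self) -> None:
        required = ["probe_id", "probeset_id", "probe_index"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise FormatError(f"probe map missing columns: {missing}")
        t = self.table.loc[:, required].copy()
        t["probe_index"] = t["probe_index"].astype(int)
        if (t["probe_index"] < 1).any():
            raise FormatError("probe_index must be >= 1")
        if t["probe_id"].duplicated().any():
            raise FormatError("a probe maps to more than one probe set")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    @property
    def probeset_ids(self) -> pd.Index:
        return pd.Index(self.table["probeset_id"].unique())

    def probeset_of(self) -> pd.Series:
        """probe_id -> probeset_id."""
        return self.table.set_index("probe_id")["probeset_id"]


def read_probe_map(path) -> ProbeSetMap:
    return ProbeSetMap(_read_tsv(path))


def write_probe_map(pmap: ProbeSetMap, path) -> Path:
    return _write_tsv(pmap.table, path)


# ---------------------------------------------------------------------------
# Mask files
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaskFile:
    """A set of probe ids masked for all samples, plus its provenance.

    ``threshold`` and ``percentage_p`` record the intensity point and the
    defined percentage P of the retention rule that produced an ISV mask;
    SFP masks carry threshold 0.  ``provenance`` is ISV, SFP or combined.
    """

    masked_probe_ids: frozenset[str]
    threshold: float = 0.0
    percentage_p: float = 1.0
    provenance: str = "ISV"

    def __post_init__(self) -> None:
        if self.provenance not in ("ISV", "SFP", "combined"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.threshold < 0:
            raise ValueError("threshold must be nonnegative")
        if not (0 < self.percentage_p <= 1):
            raise ValueError("percentage P must be in (0, 1]")
        object.__setattr__(self, "masked_probe_ids", frozenset(self.masked_probe_ids))

    def __len__(self) -> int:
        return len(self.masked_probe_ids)


def write_mask_file(mask: MaskFile, path) -> Path:
    """Write header lines then one masked probe id per line, sorted."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# threshold={mask.threshold:g}\n")
        fh.write(f"# P={mask.percentage_p:g}\n")
        fh.write(f"# provenance={mask.provenance}\n")
        for pid in sorted(mask.masked_probe_ids):
            fh.write(pid + "\n")
    return path


def read_mask_file(path) -> MaskFile:
    meta = {"threshold": 0.0, "P": 1.0, "provenance": "ISV"}
    ids: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            ids.append(line)
    try:
        threshold = float(meta["threshold"])
        pct = float(meta["P"])
    except ValueError as exc:  # pragma: no cover - defensive
        raise FormatError(f"bad mask header in {path}: {exc}") from exc
    return MaskFile(frozenset(ids), threshold, pct, str(meta["provenance"]))


# ---------------------------------------------------------------------------
# Expression matrices (probe set x sample, log2)
# ---------------------------------------------------------------------------


def read_expression(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if df.columns[0] != "probeset_id":
        raise FormatError(f"first column must be 'probeset_id', got {df.columns[0]!r}")
    if df["probeset_id"].duplicated().any():
        raise FormatError("duplicate probe set ids")
    return df.set_index("probeset_id").astype(float)


def write_expression(expr: pd.DataFrame, path,
                     header_comments: Sequence[str] = ()) -> Path:
    df = expr.reset_index()
    df.columns = ["probeset_id", *expr.columns]
    return _write_tsv(df, path, header_comments)


# ---------------------------------------------------------------------------
# Locus tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusTable:
    """One genomic locus (top hit) per probe set; 0-based positions."""

    table: pd.DataFrame  # probeset_id, chromosome, position_bp

    def __post_init__(self) -> None:
        required = ["probeset_id", "chromosome", "position_bp"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise FormatError(f"locus table missing columns: {missing}")
        t = self.table.loc[:, required].copy()
        t["position_bp"] = t["position_bp"].astype(np.int64)
        if (t["position_bp"] < 0).any():
            raise FormatError("positions must be nonnegative")
        if t["probeset_id"].duplicated().any():
            warnings.warn(
                "multiple loci per probe set; keeping the first (top hit) row",
                stacklevel=2,
            )
            t = t.drop_duplicates("probeset_id", keep="first")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, probeset_ids: Iterable[str]) -> "LocusTable":
        wanted = set(probeset_ids)
        return LocusTable(self.table[self.table["probeset_id"].isin(wanted)])


def read_locus_table(path) -> LocusTable:
    return LocusTable(_read_tsv(path))


def write_locus_table(loci: LocusTable, path) -> Path:
    return _write_tsv(loci.table, path)


# ---------------------------------------------------------------------------
# SFP lists
# ---------------------------------------------------------------------------


def read_sfp_list(path) -> list[str]:
    """One probe id per line; '#' comments allowed; order preserved."""
    ids: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return ids


def write_sfp_list(ids: Iterable[str], path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for pid in ids:
            fh.write(pid + "\n")
    return path
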