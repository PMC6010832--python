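"""Tabular input/output: genotype tables, locus panels, and lek count tables.

The genotype CSV dialect is this package's own (see README): one row per
sample with ``sample_id, lek_id, lat, lon, source`` metadata columns
followed by two integer columns per locus named ``<locus>_1`` and
``<locus>_2``.  A missing genotype is encoded as ``0`` or an empty field
in *both* allele columns; a half-missing call (one allele present) is
coerced to missing with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from lekgraph.errors import FormatError, ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Sentinel allele value for a missing call (locus-level: both alleles).
MISSING = 0

META_COLUMNS = ("sample_id", "lek_id", "lat", "lon", "source")
SOURCES = ("feather", "blood", "synthetic")


@dataclass(frozen=True)
class Locus:
    """One microsatellite locus: name, repeat-motif length, optional ladder anchor."""

    name: str
    motif_length: int = 1
    known_offset: int = 0

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise ValidationError(f"locus {self.name}: motif_length must be >= 1")
        if self.known_offset < 0:
            raise ValidationError(f"locus {self.name}: known_offset must be >= 0")


@dataclass(frozen=True)
class LocusPanel:
    """An ordered set of loci with unique names."""

    loci: tuple[Locus, ...]

    def __post_init__(self) -> None:
        names = [lc.name for lc in self.loci]
        if len(set(names)) != len(names):
            raise ValidationError("locus names must be unique")

    @classmethod
    def from_names(cls, names: Sequence[str], motif_length: int = 1) -> "LocusPanel":
        return cls(tuple(Locus(n, motif_length) for n in names))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(lc.name for lc in self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    def __getitem__(self, name: str) -> Locus:
        for lc in self.loci:
            if lc.name == name:
                return lc
        raise KeyError(name)


@dataclass
class GenotypeTable:
    """Individuals x loci allele-length matrix with sample metadata.

    ``calls`` has shape ``(n_samples, n_loci, 2)``; a missing genotype is
    ``(0, 0)``.  Row order of ``meta`` matches the first axis of ``calls``.
    """

    meta: pd.DataFrame
    loci: tuple[str, ...]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.meta = self.meta.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n = len(self.meta)
        if self.calls.shape != (n, len(self.loci), 2):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} samples x {len(self.loci)} loci"
            )
        missing_cols = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing_cols:
            raise FormatError(f"metadata missing columns: {missing_cols}")
        if self.meta["sample_id"].duplicated().any():
            dups = self.meta.loc[self.meta["sample_id"].duplicated(), "sample_id"]
            raise ValidationError(f"duplicate sample_id: {sorted(set(dups))}")
        lat = self.meta["lat"].to_numpy(float)
        lon = self.meta["lon"].to_numpy(float)
        if np.any((lat < -90) | (lat > 90)):
            raise ValidationError("latitude out of [-90, 90]")
        if np.any((lon < -180) | (lon > 180)):
            raise ValidationError("longitude out of [-180, 180]")
        if np.any(self.calls < 0):
            raise ValidationError("negative allele length")
        # enforce locus-level missingness: one zero allele implies both zero
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValidationError("half-missing call present; coerce before construction")

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.meta)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.meta["sample_id"].to_numpy()

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_loci): True where the call is MISSING."""
        return self.calls[:, :, 0] == MISSING

    def missing_per_sample(self) -> np.ndarray:
        return self.missing_mask().sum(axis=1)

    def subset(self, rows: Iterable[int]) -> "GenotypeTable":
        rows = np.asarray(list(rows), dtype=int)
        return GenotypeTable(self.meta.iloc[rows], self.loci, self.calls[rows])

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
            and self.meta.reset_index(drop=True).equals(other.meta.reset_index(drop=True))
        )


@dataclass
class LekCountTable:
    """Per-lek yearly high male counts; at most one record per (lek, year)."""

    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["lek_id", "year", "high_male_count"]))

    def __post_init__(self) -> None:
        df = self.records.reset_index(drop=True)
        required = ["lek_id", "year", "high_male_count"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"lek count table missing columns: {missing}")
        df["lek_id"] = df["lek_id"].astype(str)
        df["year"] = df["year"].astype(int)
        df["high_male_count"] = df["high_male_count"].astype(int)
        if (df["high_male_count"] < 0).any():
            bad = df.loc[df["high_male_count"] < 0]
            raise ValidationError(f"negative high_male_count at rows {list(bad.index)}")
        dup = df.duplicated(subset=["lek_id", "year"])
        if dup.any():
            pairs = df.loc[dup, ["lek_id", "year"]].itertuples(index=False)
            raise ValidationError(f"duplicate (lek, year) records: {list(pairs)}")
        self.records = df

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# genotype CSV reader / writer
# ---------------------------------------------------------------------------

def _parse_allele(raw: object, row: int, column: str) -> int:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return MISSING
    s = str(raw).strip()
    if s == "" or s.lower() == "na":
        return MISSING
    try:
        value = int(s)
    except ValueError as exc:
        raise ParseError(
            f"row {row}: non-integer allele {s!r} in column {column!r}"
        ) from exc
    if value < 0:
        raise ParseError(f"row {row}: negative allele {value} in column {column!r}")
    return value


def read_genotype_table(path: str | Path, panel: LocusPanel) -> GenotypeTable:
    """Read and validate a genotype CSV against a locus panel.

    Half-missing calls (exactly one allele present) are coerced to MISSING
    with a logged warning.  Row order is preserved.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("sample_id", "lek_id", "lat", "lon"):
        if col not in df.columns:
            raise FormatError(f"genotype CSV missing column {col!r}")
    for name in panel.names:
        for suffix in ("_1", "_2"):
            if name + suffix not in df.columns:
                raise FormatError(f"genotype CSV missing column {name + suffix!r}")
    n = len(df)
    loci = panel.names
    calls = np.zeros((n, len(loci), 2), dtype=np.int64)
    for j, name in enumerate(loci):
        for k, suffix in enumerate(("_1", "_2")):
            col = name + suffix
            calls[:, j, k] = [
                _parse_allele(v, i + 2, col) for i, v in enumerate(df[col])
            ]
    half = (calls == MISSING).sum(axis=2) == 1
    if half.any():
        for i, j in zip(*np.nonzero(half)):
            logger.warning(
                "half-missing call at sample %s locus %s coerced to MISSING",
                df["sample_id"].iloc[i], loci[j],
            )
        calls[half] = MISSING

    try:
        lat = df["lat"].astype(float)
        lon = df["lon"].astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric coordinate: {exc}") from exc
    source = df["source"] if "source" in df.columns else "feather"
    meta = pd.DataFrame({
        "sample_id": df["sample_id"].astype(str),
        "lek_id": df["lek_id"].astype(str),
        "lat": lat,
        "lon": lon,
        "source": source,
    })
    table = GenotypeTable(meta, loci, calls)
    logger.info("read %d samples x %d loci from %s", n, len(loci), path)
    return table


def write_genotype_table(table: GenotypeTable, path: str | Path) -> None:
    """Write a genotype table in the package CSV dialect (round-trips)."""
    out = table.meta[list(META_COLUMNS)].copy()
    for j, name in enumerate(table.loci):
        out[name + "_1"] = table.calls[:, j, 0]
        out[name + "_2"] = table.calls[:, j, 1]
    out.to_csv(path, index=False)


def split_concatenated_calls(
    df: pd.DataFrame, loci: Sequence[str], digits: int = 3
) -> pd.DataFrame:
    """Converter hook for GENEPOP-style layouts with one concatenated
    column per locus (e.g. ``"150152"`` with ``digits=3``).

    Returns a copy with each locus column replaced by ``<locus>_1`` and
    ``<locus>_2`` columns in the package dialect.
    """
    out = df.copy()
    for name in loci:
        raw = out.pop(name).astype(str).str.strip()
        padded = raw.str.zfill(2 * digits)
        a1 = padded.str[:digits].astype(int)
        a2 = padded.str[digits:].astype(int)
        # GENEPOP encodes missing as all zeros; one-sided zero is half-missing
        out[name + "_1"] = a1
        out[name + "_2"] = a2
    return out


# ---------------------------------------------------------------------------
# lek count CSV reader / writer
# ---------------------------------------------------------------------------

def read_lek_counts(path: str | Path) -> LekCountTable:
    """Read a lek count CSV with columns lek_id, year, high_male_count."""
    df = pd.read_csv(path, dtype={"lek_id": str})
    if "count" in df.columns and "high_male_count" not in df.columns:
        df = df.rename(columns={"count": "high_male_count"})
    return LekCountTable(df)


def write_lek_counts(table: LekCountTable, path: str | Path) -> None:
    table.records.to_csv(path, index=False)
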