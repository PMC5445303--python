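"""Tabular I/O for the MAGE analysis pipeline.

Three plain-text dialects are supported:

* **Genotype tables** — wide TSV, one row per clone.  Metadata columns
  ``clone_id``, ``lineage``, ``cycle``, ``doubling_time_min`` are followed by
  one column per allele (opaque ids such as ``T1263523C`` or ``dn12_3``),
  coded ``1`` when the engineered change (reversion to wild type, or a de
  novo mutation) is present relative to the starting strain, ``0`` when
  absent, and ``NA``/empty when the call is missing.  Missing is a distinct
  state and is never conflated with 0.
* **Plate-reader kinetics** — wide CSV with a ``time_min`` column at a
  constant sampling interval followed by one OD600 column per well.
* **Allele-effect tables** — TSV with columns ``allele_id``,
  ``mean_coefficient``, ``selection_round_survived``, ``rank``.

All parsing is locale-independent (decimal point, no thousands separators).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: metadata columns recognised at the front of a genotype table, in order
GENOTYPE_META_COLUMNS = ("clone_id", "lineage", "cycle", "doubling_time_min")

#: literal spellings accepted for a missing genotype cell
MISSING_TOKENS = ("NA", "")


class GenotypeParseError(ValueError):
    """A genotype table cell or header could not be interpreted."""


class ValidationError(ValueError):
    """A table violated a structural invariant."""


@dataclass
class GenotypeTable:
    """Clones x alleles binary genotype matrix with clone metadata.

    ``genotypes`` is a float DataFrame indexed by clone_id with values in
    {0.0, 1.0, NaN}; NaN marks a missing call.  ``meta`` is indexed
    identically and carries lineage, cycle and doubling_time_min.
    """

    genotypes: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.genotypes.index.has_duplicates:
            dupes = self.genotypes.index[self.genotypes.index.duplicated()].unique()
            raise ValidationError(f"duplicate clone_id values: {list(dupes)}")
        if self.genotypes.shape[1] == 0:
            raise ValidationError("no allele columns")
        vals = self.genotypes.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | (vals == 0.0) | (vals == 1.0))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise GenotypeParseError(
                f"genotype value {vals[r, c]!r} at clone "
                f"{self.genotypes.index[r]!r}, allele "
                f"{self.genotypes.columns[c]!r} is not 0/1/missing"
            )
        if (self.meta["cycle"].dropna() < 0).any():
            raise ValidationError("negative MAGE cycle")

    @property
    def clone_ids(self) -> list[str]:
        return list(self.genotypes.index)

    @property
    def allele_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    @property
    def n_clones(self) -> int:
        return self.genotypes.shape[0]

    def restrict(self, alleles: list[str]) -> "GenotypeTable":
        """Sub-table over the given allele columns (order preserved)."""
        missing = [a for a in alleles if a not in self.genotypes.columns]
        if missing:
            raise KeyError(f"unknown alleles: {missing}")
        return GenotypeTable(self.genotypes[alleles].copy(), self.meta.copy())


@dataclass
class PlateReaderTable:
    """Kinetic OD600 readings on a shared, evenly spaced time axis (minutes)."""

    time_min: np.ndarray
    wells: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        if len(self.time_min) < 2:
            raise ValidationError("time axis needs at least two points")
        diffs = np.diff(self.time_min)
        interval = diffs[0]
        bad = np.nonzero(~np.isclose(diffs, interval, rtol=1e-6, atol=1e-9))[0]
        if interval <= 0:
            raise ValidationError("time axis must be strictly increasing")
        if bad.size:
            raise ValidationError(f"non-constant interval at index {bad[0] + 1}")
        for well, od in self.wells.items():
            arr = np.asarray(od, dtype=float)
            if arr.shape != self.time_min.shape:
                raise ValidationError(
                    f"well {well!r}: {arr.size} readings for "
                    f"{self.time_min.size} time points"
                )
            self.wells[well] = arr

    @property
    def interval_min(self) -> float:
        return float(self.time_min[1] - self.time_min[0])


def _parse_genotype_cell(raw: object, clone: str, allele: str) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return np.nan
    text = str(raw).strip()
    if text in MISSING_TOKENS:
        return np.nan
    if text in ("0", "0.0"):
        return 0.0
    if text in ("1", "1.0"):
        return 1.0
    raise GenotypeParseError(
        f"cannot parse genotype {text!r} at clone {clone!r}, allele {allele!r}"
    )


def read_genotype_table(path, dialect: str = "wide_tsv") -> GenotypeTable:
    """Read a wide-TSV genotype table (see module docstring for the layout)."""
    if dialect != "wide_tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "clone_id" not in df.columns:
        raise GenotypeParseError("header must contain clone_id")
    allele_cols = [c for c in df.columns if c not in GENOTYPE_META_COLUMNS]
    if not allele_cols:
        raise ValidationError("no allele columns")
    meta = pd.DataFrame(index=pd.Index(df["clone_id"], name="clone_id"))
    meta["lineage"] = (
        df["lineage"].replace("", pd.NA).to_numpy() if "lineage" in df else pd.NA
    )
    meta["cycle"] = (
        pd.to_numeric(df["cycle"].replace("", np.nan)).to_numpy()
        if "cycle" in df
        else np.nan
    )
    meta["doubling_time_min"] = (
        pd.to_numeric(df["doubling_time_min"].replace({"": np.nan, "NA": np.nan})).to_numpy()
        if "doubling_time_min" in df
        else np.nan
    )
    geno = pd.DataFrame(
        {
            col: [
                _parse_genotype_cell(v, cid, col)
                for cid, v in zip(df["clone_id"], df[col])
            ]
            for col in allele_cols
        },
        index=meta.index,
        dtype=float,
    )
    return GenotypeTable(geno, meta)


def write_genotype_table(gt: GenotypeTable, path) -> None:
    """Write a GenotypeTable in the wide-TSV dialect (NA for missing cells)."""
    out = gt.meta.reset_index()[list(GENOTYPE_META_COLUMNS)].copy()
    geno = gt.genotypes.reset_index(drop=True)
    cells = geno.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out = pd.concat([out, cells], axis=1)
    out["cycle"] = out["cycle"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out["doubling_time_min"] = out["doubling_time_min"].map(
        lambda v: "" if pd.isna(v) else repr(float(v))
    )
    out["lineage"] = out["lineage"].fillna("")
    out.to_csv(path, sep="\t", index=False)


def read_plate_reader(path, layout: str = "wide_csv") -> PlateReaderTable:
    """Read a wide-CSV kinetic plate-reader export (time_min, then wells)."""
    if layout != "wide_csv":
        raise ValueError(f"unknown layout {layout!r}")
    df = pd.read_csv(path)
    if df.columns[0] != "time_min":
        raise GenotypeParseError("first column must be time_min")
    well_cols = list(df.columns[1:])
    if not well_cols:
        raise ValidationError("no well columns")
    for col in well_cols:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise GenotypeParseError(f"non-numeric OD reading in well {col!r}")
    return PlateReaderTable(
        time_min=df["time_min"].to_numpy(dtype=float),
        wells={c: df[c].to_numpy(dtype=float) for c in well_cols},
    )


def write_plate_reader(table: PlateReaderTable, path) -> None:
    df = pd.DataFrame({"time_min": table.time_min, **table.wells})
    df.to_csv(path, index=False)


def write_effect_table(effects, path) -> None:
    """Write ranked allele effects as TSV.

    ``effects`` is a sequence of objects with ``feature_id``,
    ``mean_coefficient`` and ``survived_round`` attributes, already ranked.
    """
    if not effects:
        raise ValidationError("refusing to write an empty effect table")
    df = pd.DataFrame(
        {
            "allele_id": [e.feature_id for e in effects],
            "mean_coefficient": [repr(float(e.mean_coefficient)) for e in effects],
            "selection_round_survived": [int(e.survived_round) for e in effects],
            "rank": np.arange(1, len(effects) + 1),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_effect_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = {"allele_id", "mean_coefficient", "selection_round_survived", "rank"}
    missing = expected - set(df.columns)
    if missing:
        raise GenotypeParseError(f"effect table missing columns {sorted(missing)}")
    return df


KNOWN_CONFIG_SECTIONS = ("growth", "model", "simulate", "power")


def load_config(path) -> dict:
    """Load a YAML config; unknown top-level sections produce a warning."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a YAML mapping")
    for key in cfg:
        if key not in KNOWN_CONFIG_SECTIONS:
            logger.warning("unknown config section %r ignored", key)
    return cfg
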