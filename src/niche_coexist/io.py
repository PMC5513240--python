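"""Data model and strict CSV input/output.

Four tables describe a survey of a stream reach:

``sites``
    one row per sampling site (a fyke-net deployment): habitat type
    (pool/riffle), dominant substratum on a five-class Wentworth-style
    scale, mean depth in metres, and optional water chemistry.
``counts``
    site x species catch (fish per net-night), non-negative integers.
``isotopes``
    per-individual bivariate stable-isotope values (d13C, d15N, both per
    mil) with a group label (consumer species or diet source) and an
    optional C:N ratio used to screen for lipid bias.
``traits``
    long-format species trait table: quantitative traits in size-adjusted
    log units plus categorical traits (mouth position, locomotor mode).

Readers are strict: mandatory columns must be present, numeric fields must
parse, and categorical fields come from closed vocabularies.  Unknown
columns are preserved so user metadata survives a round trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ._errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

SUBSTRATUM_LEVELS = ("sand", "gravel", "cobble", "boulder", "bedrock")
HABITAT_LEVELS = ("pool", "riffle")
#: Mean depth (m) at or above which a site is a pool when habitat type is
#: derived rather than recorded.  The boundary itself derives to "pool".
POOL_DEPTH_THRESHOLD = 1.0
#: C:N ratio at or above which lipid accumulation may bias d13C.
LIPID_CN_THRESHOLD = 3.5

TABLE_SCHEMAS: dict[str, dict[str, tuple[str, ...]]] = {
    "sites": {
        "mandatory": ("site_id", "substratum", "depth"),
        "optional": ("position", "habitat_type", "temperature", "pH",
                     "conductivity", "tds"),
        "numeric": ("position", "depth", "temperature", "pH",
                    "conductivity", "tds"),
    },
    "counts": {
        "mandatory": ("site_id", "species", "count"),
        "optional": (),
        "numeric": ("count",),
    },
    "isotopes": {
        "mandatory": ("sample_id", "group", "d13C", "d15N"),
        "optional": ("cn_ratio",),
        "numeric": ("d13C", "d15N", "cn_ratio"),
    },
    "traits": {
        "mandatory": ("species", "trait", "value", "trait_type"),
        "optional": (),
        "numeric": (),
    },
}


@dataclass
class Dataset:
    """In-memory container for one survey's tables (pandas DataFrames)."""

    sites: pd.DataFrame | None = None
    counts: pd.DataFrame | None = None
    isotopes: pd.DataFrame | None = None
    traits: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def species(self) -> list[str]:
        if self.counts is None:
            return []
        return sorted(self.counts["species"].unique())


def derive_habitat_type(depth: float) -> str:
    """Classify a site as pool or riffle from mean depth (m).

    Depths >= 1 m are pools; the 1 m tie goes to "pool" because the pool
    class is the deep one and the boundary must close on one side.
    """
    return "pool" if depth >= POOL_DEPTH_THRESHOLD else "riffle"


def _check_columns(kind: str, df: pd.DataFrame) -> None:
    schema = TABLE_SCHEMAS[kind]
    for col in schema["mandatory"]:
        if col not in df.columns:
            raise SchemaError(f"{kind} table is missing mandatory column {col!r}")


def _coerce_numeric(kind: str, df: pd.DataFrame) -> pd.DataFrame:
    schema = TABLE_SCHEMAS[kind]
    for col in schema["numeric"]:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{kind} table: non-numeric value {df[col].iloc[row]!r} in "
                f"column {col!r} at data row {row + 1}"
            )
        df = df.assign(**{col: coerced})
    return df


def _validate_sites(df: pd.DataFrame) -> pd.DataFrame:
    bad = ~df["substratum"].isin(SUBSTRATUM_LEVELS)
    if bad.any():
        value = df.loc[bad, "substratum"].iloc[0]
        raise ValidationError(
            f"unknown substratum level {value!r}; allowed: {', '.join(SUBSTRATUM_LEVELS)}"
        )
    if (df["depth"] <= 0).any() or df["depth"].isna().any():
        raise ValidationError("site depth must be a positive number of metres")
    if df["site_id"].duplicated().any():
        dup = df.loc[df["site_id"].duplicated(), "site_id"].iloc[0]
        raise ValidationError(f"duplicate site_id {dup!r}")
    derived = df["depth"].map(derive_habitat_type)
    if "habitat_type" in df.columns and df["habitat_type"].notna().any():
        bad = df["habitat_type"].notna() & ~df["habitat_type"].isin(HABITAT_LEVELS)
        if bad.any():
            value = df.loc[bad, "habitat_type"].iloc[0]
            raise ValidationError(
                f"unknown habitat_type {value!r}; allowed: {', '.join(HABITAT_LEVELS)}"
            )
        conflict = df["habitat_type"].notna() & (df["habitat_type"] != derived)
        for sid in df.loc[conflict, "site_id"]:
            logger.warning(
                "site %s: recorded habitat_type conflicts with the 1 m depth "
                "rule; keeping the recorded value", sid,
            )
        df = df.assign(habitat_type=df["habitat_type"].where(
            df["habitat_type"].notna(), derived))
    else:
        df = df.assign(habitat_type=derived)
    return df


def _validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    if df["count"].isna().any():
        raise ValidationError("counts table contains missing count values")
    counts = df["count"].to_numpy()
    if np.any(counts < 0):
        raise ValidationError("counts must be non-negative")
    if np.any(counts != np.floor(counts)):
        raise ValidationError("counts must be integers (fish per fyke net)")
    df = df.assign(count=counts.astype(int))
    if df.duplicated(subset=["site_id", "species"]).any():
        pair = df.loc[df.duplicated(subset=["site_id", "species"]),
                      ["site_id", "species"]].iloc[0]
        raise ValidationError(
            f"duplicate (site, species) pair ({pair.site_id!r}, {pair.species!r})"
        )
    return df


def _validate_isotopes(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("d13C", "d15N"):
        if df[col].isna().any() or not np.isfinite(df[col].to_numpy(float)).all():
            raise ValidationError(f"isotope column {col!r} must be finite per-mil values")
    if (df["group"].astype(str).str.strip() == "").any():
        raise ValidationError("isotope group labels must be non-empty")
    return df


def _validate_traits(df: pd.DataFrame) -> pd.DataFrame:
    allowed = {"quantitative", "categorical"}
    bad = ~df["trait_type"].isin(allowed)
    if bad.any():
        value = df.loc[bad, "trait_type"].iloc[0]
        raise ValidationError(
            f"unknown trait_type {value!r}; allowed: quantitative, categorical"
        )
    quant = df["trait_type"] == "quantitative"
    if quant.any():
        vals = pd.to_numeric(df.loc[quant, "value"], errors="coerce")
        if vals.isna().any():
            raise ParseError("quantitative trait values must be numeric")
    if df.duplicated(subset=["species", "trait"]).any():
        raise ValidationError("duplicate (species, trait) row in traits table")
    return df


_VALIDATORS = {
    "sites": _validate_sites,
    "counts": _validate_counts,
    "isotopes": _validate_isotopes,
    "traits": _validate_traits,
}


def read_table(kind: str, path: str | Path) -> pd.DataFrame:
    """Read and validate one of the four survey tables from CSV.

    Parameters
    ----------
    kind
        One of ``{"sites", "counts", "isotopes", "traits"}``.
    path
        CSV file: comma-separated, UTF-8, ``.`` decimal, header row first.

    Returns
    -------
    pandas.DataFrame
        Validated table; unknown columns are preserved, row order kept.
    """
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    _check_columns(kind, df)
    df = _coerce_numeric(kind, df)
    return _VALIDATORS[kind](df)


def write_table(kind: str, df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as CSV in the package's interchange dialect."""
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_dataset(directory: str | Path) -> Dataset:
    """Load every recognised table found under ``directory``."""
    directory = Path(directory)
    ds = Dataset()
    for kind in TABLE_SCHEMAS:
        path = directory / f"{kind}.csv"
        if path.exists():
            setattr(ds, kind, read_table(kind, path))
    return ds


def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """Convert an isotope ratio to delta notation (per mil).

    delta = (R_sample / R_standard - 1) * 1000, with R the heavy/light
    isotope ratio and R_standard the international standard (VPDB for
    carbon, atmospheric N2 for nitrogen).
    """
    r_standard = float(r_standard)
    if not r_standard > 0:
        raise ValueError("r_standard must be strictly positive")
    return (float(r_sample) / r_standard - 1.0) * 1000.0


def lipid_screen(samples: pd.DataFrame,
                 threshold: float = LIPID_CN_THRESHOLD) -> pd.Series:
    """Flag isotope samples whose C:N ratio suggests lipid bias in d13C.

    Returns a Series aligned with ``samples``: ``True`` where
    ``cn_ratio >= threshold`` (candidate for lipid bias), ``False`` below
    it, and the string ``"unknown"`` where no C:N ratio was recorded.
    Muscle tissue below the threshold needs no lipid normalisation.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    if "cn_ratio" not in samples.columns:
        return pd.Series(["unknown"] * len(samples), index=samples.index,
                         dtype=object)
    cn = pd.to_numeric(samples["cn_ratio"], errors="coerce")
    out = pd.Series(np.where(cn >= threshold, True, False), dtype=object,
                    index=samples.index)
    out[cn.isna()] = "unknown"
    return out


def validate_dataset(ds: Dataset) -> list[str]:
    """Cross-table referential checks.  Empty list iff the dataset is valid."""
    report: list[str] = []
    if ds.counts is not None and ds.sites is not None:
        known_sites = set(ds.sites["site_id"])
        for sid in ds.counts.loc[~ds.counts["site_id"].isin(known_sites),
                                 "site_id"].unique():
            report.append(f"counts reference unknown site {sid!r}")
    if ds.counts is not None and ds.traits is not None:
        known_species = set(ds.traits["species"])
        for sp in ds.counts.loc[~ds.counts["species"].isin(known_species),
                                "species"].unique():
            report.append(f"species {sp!r} in counts is missing from traits")
    return report


def counts_matrix(ds: Dataset) -> pd.DataFrame:
    """Site x species count matrix (absences filled with 0), sites in
    the order of the site table."""
    if ds.sites is None or ds.counts is None:
        raise ValueError("dataset needs both sites and counts tables")
    mat = (ds.counts.pivot(index="site_id", columns="species", values="count")
           .reindex(ds.sites["site_id"]).fillna(0).astype(int))
    mat.columns.name = None
    return mat


def trait_value(ds: Dataset, species: str, trait: str):
    """Look up one trait value; quantitative values returned as float."""
    if ds.traits is None:
        raise ValueError("dataset has no traits table")
    rows = ds.traits[(ds.traits["species"] == species)
                     & (ds.traits["trait"] == trait)]
    if rows.empty:
        raise KeyError(f"trait {trait!r} not recorded for species {species!r}")
    row = rows.iloc[0]
    if row["trait_type"] == "quantitative":
        return float(row["value"])
    return row["value"]


def iter_species_counts(ds: Dataset, species: Iterable[str] | None = None):
    """Yield (species, per-site count vector as ndarray) pairs."""
    mat = counts_matrix(ds)
    for sp in (species if species is not None else mat.columns):
        yield sp, mat[sp].to_numpy()
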