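"""Reading and writing the tabular formats of a quantitative fitness screen.

Arrayed-culture screens are photographed repeatedly; an image-analysis tool
(Colonyzer) reduces each photograph to one integrated optical density (IOD,
"Trimmed Area", arbitrary units) per spotted culture, and the provenance
database (ROD) exports those measurements as tab-delimited text.  This module
parses those exports, joins them to the strain layout, converts absolute
photograph timestamps into elapsed days since inoculation, and round-trips
the downstream logistic-parameter / fitness tables.

Column names in real exports vary between database versions, so every reader
accepts a *dialect*: a mapping from the canonical field names used here to
the column headers found in the file.  Dialects can be loaded from YAML.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("qfa")

#: Plate geometry for 384-position arrays (16 rows x 24 columns), 1-based.
N_ROWS = 16
N_COLS = 24

#: Canonical column order for density-observation tables.
OBSERVATION_COLUMNS = ["barcode", "row", "col", "timestamp", "density"]

#: Canonical column order for logistic/fitness tables (the curated export
#: produced after growth-model fitting).
LOGISTIC_COLUMNS = [
    "orf", "gene", "query", "temperature", "library", "replicate",
    "barcode", "row", "col",
    "g0", "r", "K", "rss", "n_points", "converged",
    "t_double", "mdr", "mdp", "fitness", "flag",
]

#: Default dialect: canonical names map to themselves.
DEFAULT_DIALECT: dict[str, str] = {c: c for c in OBSERVATION_COLUMNS}

#: Number formatting used when writing tables, so that write -> read is the
#: identity at text level.
_FLOAT_FORMAT = "%.10g"


class FormatError(ValueError):
    """A file name or file content does not match the expected format."""


class ConfigurationError(ValueError):
    """A dialect/config is missing information required to read a file."""


class ValidationError(ValueError):
    """Parsed records violate a domain invariant."""


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DensityObservation:
    """One image-derived density measurement of one spotted culture."""

    barcode: str
    row: int
    col: int
    timestamp: _dt.datetime
    density: float

    def __post_init__(self) -> None:
        if not (1 <= self.row <= N_ROWS):
            raise ValidationError(f"row {self.row} outside 1..{N_ROWS}")
        if not (1 <= self.col <= N_COLS):
            raise ValidationError(f"col {self.col} outside 1..{N_COLS}")
        if self.density < 0:
            raise ValidationError(f"negative density {self.density}")


@dataclass(frozen=True)
class StrainAnnotation:
    """What is growing at one plate position, and under which condition.

    ``query`` is the background mutation of the screen (e.g. ``cdc13-1``,
    ``yku70D``, or the neutral ``ura3D`` control); ``library`` identifies the
    source deletion-collection version (replicates are typically split
    across two library versions, four replicates each).
    """

    orf: str
    gene: str
    query: str
    temperature: float
    library: str
    replicate: int
    barcode: str
    row: int
    col: int

    def __post_init__(self) -> None:
        if not self.orf:
            raise ValidationError("orf must be non-empty")
        if not (1 <= self.row <= N_ROWS) or not (1 <= self.col <= N_COLS):
            raise ValidationError(
                f"position ({self.row}, {self.col}) outside the "
                f"{N_ROWS}x{N_COLS} grid")


@dataclass
class CultureSeries:
    """Elapsed-time density series for one culture, ready for model fitting.

    ``times`` are days since inoculation, strictly increasing; ``densities``
    are non-negative IOD values of the same length.
    """

    annotation: StrainAnnotation
    times: np.ndarray
    densities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.times.shape != self.densities.shape:
            raise ValidationError("times and densities differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.densities < 0):
            raise ValidationError("densities must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# Image-name parsing
# ---------------------------------------------------------------------------

_IMAGE_NAME_RE = re.compile(
    r"^(?P<barcode>.+)-"
    r"(?P<date>\d{4}-\d{2}-\d{2})_(?P<time>\d{2}-\d{2}-\d{2})"
    r"(?:\.(?P<ext>[A-Za-z0-9]+))?$"
)


def parse_image_name(name: str) -> tuple[str, _dt.datetime]:
    """Split a plate-photograph file name into (barcode, timestamp).

    Names follow the convention ``<barcode>-YYYY-MM-DD_HH-MM-SS.<ext>``,
    e.g. ``DLY00000516-2008-12-24_23-59-59.jpg``.
    """
    m = _IMAGE_NAME_RE.match(name)
    if m is None:
        raise FormatError(
            f"image name {name!r} does not match <barcode>-YYYY-MM-DD_HH-MM-SS.<ext>"
        )
    stamp = f"{m.group('date')}_{m.group('time')}"
    try:
        ts = _dt.datetime.strptime(stamp, "%Y-%m-%d_%H-%M-%S")
    except ValueError as exc:
        raise FormatError(f"image name {name!r}: bad timestamp {stamp!r}") from exc
    return m.group("barcode"), ts


def format_image_name(barcode: str, timestamp: _dt.datetime, ext: str = "jpg") -> str:
    """Inverse of :func:`parse_image_name`."""
    return f"{barcode}-{timestamp.strftime('%Y-%m-%d_%H-%M-%S')}.{ext}"


# ---------------------------------------------------------------------------
# ROD density exports
# ---------------------------------------------------------------------------

def load_dialect(path: str | Path) -> dict[str, str]:
    """Load a column-mapping dialect from a YAML file."""
    with open(path) as fh:
        dialect = yaml.safe_load(fh)
    if not isinstance(dialect, Mapping):
        raise ConfigurationError(f"dialect file {path} is not a mapping")
    return dict(dialect)


def read_rod_export(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    on_bad_rows: str = "skip",
) -> pd.DataFrame:
    """Read a tab-delimited ROD density export.

    Parameters
    ----------
    path
        Tab-delimited text file, one row per plate-image per spot.
    dialect
        Maps canonical field names (``barcode``, ``row``, ``col``,
        ``timestamp``, ``density``) to the column headers in the file.
        Defaults to the identity mapping.
    on_bad_rows
        ``"skip"`` drops rows failing type coercion (logging a count);
        ``"strict"`` raises :class:`ValidationError` instead.

    Returns
    -------
    DataFrame with the canonical observation columns; rejected-row count is
    stored in ``df.attrs["n_rejected"]``.
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    missing = [f for f in OBSERVATION_COLUMNS if f not in dialect]
    if missing:
        raise ConfigurationError(f"dialect missing mappings for {missing}")

    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.empty:
        raise FormatError(f"{path}: export contains no data rows")
    absent = [dialect[f] for f in OBSERVATION_COLUMNS if dialect[f] not in raw.columns]
    if absent:
        raise ConfigurationError(f"{path}: mandatory columns absent: {absent}")

    df = pd.DataFrame({f: raw[dialect[f]] for f in OBSERVATION_COLUMNS})
    n_input = len(df)

    coerced = pd.DataFrame({
        "barcode": df["barcode"].astype(str),
        "row": pd.to_numeric(df["row"], errors="coerce"),
        "col": pd.to_numeric(df["col"], errors="coerce"),
        "timestamp": pd.to_datetime(df["timestamp"], errors="coerce"),
        "density": pd.to_numeric(df["density"], errors="coerce"),
    })
    ok = (
        coerced[["row", "col", "timestamp", "density"]].notna().all(axis=1)
        & coerced["row"].between(1, N_ROWS)
        & coerced["col"].between(1, N_COLS)
        & (coerced["density"] >= 0)
    )
    n_rejected = int(n_input - ok.sum())
    if n_rejected and on_bad_rows == "strict":
        bad = coerced.index[~ok].tolist()[:10]
        raise ValidationError(f"{path}: {n_rejected} malformed rows (first: {bad})")
    if n_rejected:
        logger.warning("%s: skipped %d malformed rows of %d", path, n_rejected, n_input)

    out = coerced[ok].reset_index(drop=True)
    out["row"] = out["row"].astype(int)
    out["col"] = out["col"].astype(int)
    out["density"] = out["density"].astype(float)
    out.attrs["n_rejected"] = n_rejected
    return out


def write_rod_export(
    observations: pd.DataFrame,
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> None:
    """Write observations as a tab-delimited ROD-style export (LF, UTF-8)."""
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    df = observations[OBSERVATION_COLUMNS].rename(columns=dialect)
    df = df.copy()
    tscol = dialect["timestamp"]
    df[tscol] = pd.to_datetime(df[tscol]).dt.strftime("%Y-%m-%d %H:%M:%S")
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT,
              lineterminator="\n")


# ---------------------------------------------------------------------------
# Layout (strain annotation) files
# ---------------------------------------------------------------------------

def read_layout(path: str | Path) -> list[StrainAnnotation]:
    """Read a YAML experiment layout mapping plate positions to strains.

    Expected structure::

        query: cdc13-1
        temperature: 27.0
        plates:
          - barcode: DLY00000516
            library: SGAv2
            replicate: 1
            spots:
              - {row: 1, col: 1, orf: YBL091C, gene: MAP2}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    annotations = []
    for plate in doc.get("plates", []):
        for spot in plate.get("spots", []):
            annotations.append(StrainAnnotation(
                orf=str(spot["orf"]),
                gene=str(spot.get("gene", spot["orf"])),
                query=str(plate.get("query", doc.get("query", ""))),
                temperature=float(plate.get("temperature", doc.get("temperature", float("nan")))),
                library=str(plate.get("library", "")),
                replicate=int(plate.get("replicate", 1)),
                barcode=str(plate["barcode"]),
                row=int(spot["row"]),
                col=int(spot["col"]),
            ))
    return annotations


def write_layout(annotations: Iterable[StrainAnnotation], path: str | Path) -> None:
    """Inverse of :func:`read_layout` (one plate entry per barcode)."""
    plates: dict[str, dict] = {}
    query = temperature = None
    for a in annotations:
        plate = plates.setdefault(a.barcode, {
            "barcode": a.barcode, "library": a.library, "replicate": a.replicate,
            "query": a.query, "temperature": a.temperature, "spots": [],
        })
        plate["spots"].append({"row": a.row, "col": a.col, "orf": a.orf, "gene": a.gene})
        query, temperature = a.query, a.temperature
    doc = {"query": query, "temperature": temperature, "plates": list(plates.values())}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Series assembly
# ---------------------------------------------------------------------------

def assemble_series(
    observations: pd.DataFrame,
    annotations: Sequence[StrainAnnotation],
    inoculation_times: Mapping[str, _dt.datetime] | None = None,
    fallback_offset_days: float | None = 0.0,
) -> list[CultureSeries]:
    """Join density observations to strains and convert to elapsed time.

    Elapsed time is measured in days from the barcode's inoculation
    timestamp.  When a barcode is absent from ``inoculation_times`` the
    origin falls back to (first photograph time − ``fallback_offset_days``);
    pass ``fallback_offset_days=None`` to make missing barcodes an error.
    Duplicate timestamps within a culture are collapsed by mean density.
    Output is independent of input row order.
    """
    inoculation_times = dict(inoculation_times or {})
    obs = observations.sort_values(["barcode", "row", "col", "timestamp"])
    grouped = {k: g for k, g in obs.groupby(["barcode", "row", "col"], sort=False)}

    origins: dict[str, _dt.datetime] = {}
    for barcode, g in obs.groupby("barcode", sort=False):
        if barcode in inoculation_times:
            origins[barcode] = inoculation_times[barcode]
        elif fallback_offset_days is not None:
            origins[barcode] = (g["timestamp"].min()
                                - _dt.timedelta(days=fallback_offset_days))
        else:
            raise KeyError(f"no inoculation time for barcode {barcode!r}")

    series: list[CultureSeries] = []
    for ann in annotations:
        key = (ann.barcode, ann.row, ann.col)
        g = grouped.get(key)
        if g is None or g.empty:
            continue
        origin = origins[ann.barcode]
        elapsed = (g["timestamp"] - origin).dt.total_seconds() / 86400.0
        pts = (pd.DataFrame({"t": elapsed.values, "d": g["density"].values})
               .groupby("t", sort=True)["d"].mean())
        series.append(CultureSeries(
            annotation=ann,
            times=pts.index.to_numpy(),
            densities=pts.to_numpy(),
        ))
    return series


# ---------------------------------------------------------------------------
# Logistic/fitness tables
# ---------------------------------------------------------------------------

def write_logistic_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a fitted logistic/fitness table, tab-delimited, canonical order."""
    cols = [c for c in LOGISTIC_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT,
                       lineterminator="\n")


def read_logistic_table(path: str | Path, validate: bool = True) -> pd.DataFrame:
    """Read a logistic/fitness table written by :func:`write_logistic_table`.

    Negative ``r`` or ``K`` values fail validation; rows with ``K < g0`` are
    flagged (``flag`` column) but retained.
    """
    df = pd.read_csv(path, sep="\t")
    if validate:
        bad = []
        if "r" in df.columns:
            bad += df.index[df["r"] < 0].tolist()
        if "K" in df.columns:
            bad += df.index[df["K"] < 0].tolist()
        if bad:
            raise ValidationError(f"{path}: negative r or K in rows {sorted(set(bad))}")
        if {"K", "g0"} <= set(df.columns):
            suspect = df["K"] < df["g0"]
            if suspect.any():
                logger.warning("%s: %d rows with K < G0 flagged", path, int(suspect.sum()))
                if "flag" not in df.columns:
                    df["flag"] = ""
                df.loc[suspect, "flag"] = "K_below_G0"
    # Canonical dtypes regardless of how the numbers were printed.
    for col in ("temperature", "g0", "r", "K", "rss", "t_double",
                "mdr", "mdp", "fitness"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    for col in ("replicate", "n_points"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    if "converged" in df.columns:
        df["converged"] = df["converged"].astype(bool)
    return df
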