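"""Tabular I/O for screen artifacts: siRNA libraries, plate layouts, well
measurements, and 96-well coordinate parsing.

All files are plain CSV (comma-separated, UTF-8, one header row).  Schemas:

``library.csv``
    gene_symbol, refseq, sirna_index, sense, antisense, gene_class

``layout.csv``
    plate_id, replicate_index, well, content_type, gene_symbol, sirna_index

``measurements.csv``
    plate_id, well, channel, value

Well coordinates are 0-based ``(row, column)`` internally and "A1"-style
externally (rows A-H, columns 1-12, row-major when a flat index is needed).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

from .errors import IntegrityError, WellParseError

logger = logging.getLogger(__name__)

# -- plate geometry -----------------------------------------------------------

PLATE_ROWS = 8
PLATE_COLS = 12
ROW_LETTERS = "ABCDEFGH"

# measurement channels
CHANNEL_IRES = "fluc_ires"   # firefly luciferase, IRES-driven reporter
CHANNEL_CAP = "fluc_cap"     # firefly luciferase, cap-driven reporter
CHANNEL_ATP = "atp"          # ATP luminescence (cell viability)
CHANNELS = (CHANNEL_IRES, CHANNEL_CAP, CHANNEL_ATP)

# well content types
CONTENT_GENE = "gene"
CONTENT_SCRAMBLED = "scrambled_control"
CONTENT_FLUC = "fluc_control"
CONTENT_PLK1 = "plk1_control"
CONTENT_MOCK = "mock"
CONTENT_EMPTY = "empty"
CONTENT_TYPES = (
    CONTENT_GENE,
    CONTENT_SCRAMBLED,
    CONTENT_FLUC,
    CONTENT_PLK1,
    CONTENT_MOCK,
    CONTENT_EMPTY,
)

GENE_CLASSES = ("kinase", "phosphatase", "other")

LIBRARY_COLUMNS = ["gene_symbol", "refseq", "sirna_index", "sense", "antisense", "gene_class"]
LAYOUT_COLUMNS = ["plate_id", "replicate_index", "well", "content_type", "gene_symbol", "sirna_index"]
MEASUREMENT_COLUMNS = ["plate_id", "well", "channel", "value"]

_WELL_RE = re.compile(r"^([A-Ha-h])(\d{1,2})$")
_SEQ_RE = re.compile(r"^[ACGUT]{21}$")


@dataclass(frozen=True)
class SiRNAReagent:
    """One siRNA duplex targeting a gene (sense/antisense 21-mers)."""

    gene_symbol: str
    refseq_id: str
    sirna_index: int
    sense_seq: str | None
    antisense_seq: str | None


def parse_well(coord: str) -> tuple[int, int]:
    """Parse an "A1"-style coordinate to a 0-based ``(row, column)`` pair.

    Accepts case-insensitive row letters and zero-padded columns ("a01").
    Raises :class:`WellParseError` for anything off an 8x12 plate.
    """
    if not isinstance(coord, str):
        raise WellParseError(f"well coordinate must be a string, got {coord!r}")
    m = _WELL_RE.match(coord.strip())
    if m is None:
        raise WellParseError(f"malformed well coordinate {coord!r}")
    row = ROW_LETTERS.index(m.group(1).upper())
    col = int(m.group(2))
    if not 1 <= col <= PLATE_COLS:
        raise WellParseError(f"column out of range 1-{PLATE_COLS} in {coord!r}")
    return row, col - 1


def format_well(row: int, col: int) -> str:
    """Format a 0-based ``(row, column)`` pair as canonical unpadded "A1"."""
    if not (0 <= row < PLATE_ROWS and 0 <= col < PLATE_COLS):
        raise WellParseError(f"well indices ({row}, {col}) off an 8x12 plate")
    return f"{ROW_LETTERS[row]}{col + 1}"


def well_index(coord: str) -> int:
    """Row-major flat index of a well (A1=0, A12=11, B1=12, ... H12=95)."""
    r, c = parse_well(coord)
    return r * PLATE_COLS + c


def _canonicalize_wells(wells: pd.Series) -> pd.Series:
    return wells.map(lambda w: format_well(*parse_well(w)))


# -- library ------------------------------------------------------------------

def validate_library(library: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a library table.

    Upper-cases sequences; sequences that are not 21-mers over {A,C,G,U,T}
    are flagged missing (set to NA) with a warning, the record is kept.
    Duplicate (gene_symbol, sirna_index) pairs raise :class:`IntegrityError`.
    """
    missing = set(LIBRARY_COLUMNS) - set(library.columns)
    if missing:
        raise IntegrityError(f"library table missing columns: {sorted(missing)}")
    lib = library.loc[:, LIBRARY_COLUMNS].copy()
    lib["gene_symbol"] = lib["gene_symbol"].astype(str)
    lib["sirna_index"] = lib["sirna_index"].astype(int)
    dup = lib.duplicated(subset=["gene_symbol", "sirna_index"], keep=False)
    if dup.any():
        first = lib.loc[dup, ["gene_symbol", "sirna_index"]].iloc[0]
        raise IntegrityError(
            f"duplicate siRNA entry for gene {first['gene_symbol']!r} "
            f"index {int(first['sirna_index'])}"
        )
    bad_class = ~lib["gene_class"].isin(GENE_CLASSES)
    if bad_class.any():
        raise IntegrityError(
            f"unknown gene_class {lib.loc[bad_class, 'gene_class'].iloc[0]!r}; "
            f"allowed: {GENE_CLASSES}"
        )
    for col in ("sense", "antisense"):
        seqs = lib[col].astype("string").str.upper()
        ok = seqs.str.match(_SEQ_RE, na=False)
        n_bad = int((~ok & seqs.notna()).sum())
        if n_bad:
            genes = lib.loc[~ok & seqs.notna(), "gene_symbol"].unique()[:5].tolist()
            logger.warning(
                "%d %s sequence(s) are not 21-nt RNA/DNA and were flagged "
                "missing (e.g. %s)", n_bad, col, genes,
            )
        lib[col] = seqs.where(ok)
    return lib.reset_index(drop=True)


def read_library(path) -> pd.DataFrame:
    """Read and validate a library CSV."""
    return validate_library(pd.read_csv(path, dtype={"gene_symbol": str}))


def write_library(library: pd.DataFrame, path) -> None:
    validate_library(library).to_csv(path, index=False)


def gene_classes(library: pd.DataFrame) -> pd.Series:
    """Per-gene class map (gene_symbol -> kinase/phosphatase/other)."""
    return library.drop_duplicates("gene_symbol").set_index("gene_symbol")["gene_class"]


# -- layouts ------------------------------------------------------------------

def validate_layout(layout: pd.DataFrame) -> pd.DataFrame:
    missing = set(LAYOUT_COLUMNS) - set(layout.columns)
    if missing:
        raise IntegrityError(f"layout table missing columns: {sorted(missing)}")
    lay = layout.loc[:, LAYOUT_COLUMNS].copy()
    lay["well"] = _canonicalize_wells(lay["well"])
    bad = ~lay["content_type"].isin(CONTENT_TYPES)
    if bad.any():
        raise IntegrityError(
            f"unknown content_type {lay.loc[bad, 'content_type'].iloc[0]!r}; "
            f"allowed: {CONTENT_TYPES}"
        )
    dup = lay.duplicated(subset=["plate_id", "well"], keep=False)
    if dup.any():
        first = lay.loc[dup].iloc[0]
        raise IntegrityError(
            f"duplicate well {first['well']} on plate {first['plate_id']}"
        )
    return lay.reset_index(drop=True)


def read_layout(path) -> pd.DataFrame:
    lay = pd.read_csv(path, dtype={"plate_id": str, "gene_symbol": str})
    return validate_layout(lay)


def write_layout(layout: pd.DataFrame, path) -> None:
    validate_layout(layout).to_csv(path, index=False)


# -- measurements -------------------------------------------------------------

def validate_measurements(measurements: pd.DataFrame) -> pd.DataFrame:
    missing = set(MEASUREMENT_COLUMNS) - set(measurements.columns)
    if missing:
        raise IntegrityError(f"measurement table missing columns: {sorted(missing)}")
    meas = measurements.loc[:, MEASUREMENT_COLUMNS].copy()
    meas["well"] = _canonicalize_wells(meas["well"])
    meas["value"] = pd.to_numeric(meas["value"], errors="raise").astype(float)
    bad_chan = ~meas["channel"].isin(CHANNELS)
    if bad_chan.any():
        raise IntegrityError(
            f"unknown channel {meas.loc[bad_chan, 'channel'].iloc[0]!r}; "
            f"allowed: {CHANNELS}"
        )
    neg = meas["value"] < 0
    if neg.any():
        first = meas.loc[neg].iloc[0]
        raise IntegrityError(
            f"negative luminescence {first['value']} at plate "
            f"{first['plate_id']} well {first['well']}"
        )
    dup = meas.duplicated(subset=["plate_id", "well", "channel"], keep=False)
    if dup.any():
        first = meas.loc[dup].iloc[0]
        raise IntegrityError(
            f"duplicate measurement for plate {first['plate_id']} well "
            f"{first['well']} channel {first['channel']}"
        )
    return meas.reset_index(drop=True)


def read_measurements(path) -> pd.DataFrame:
    return validate_measurements(pd.read_csv(path, dtype={"plate_id": str}))


def write_measurements(measurements: pd.DataFrame, path) -> None:
    validate_measurements(measurements).to_csv(path, index=False)
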