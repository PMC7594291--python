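"""Shared domain types and CSV interchange readers/writers.

Coordinates are planar metres (UTM-style easting/northing); the package does
no geodetic reprojection, so inputs must already be projected. Timestamps are
UTC at second resolution; calendar months are taken in UTC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("deerseed")

FIXES_COLUMNS = ["animal_id", "timestamp", "easting_m", "northing_m",
                 "elevation_m", "quality_ok"]
DUNG_COLUMNS = ["sample_id", "animal_id", "collection_date", "volume_ml"]
SEEDLING_COLUMNS = ["sample_id", "species", "count"]
CONTROL_COLUMNS = ["tray_id", "species"]
PASSAGE_COLUMNS = ["trial", "species", "interval_upper_h", "prob"]

#: Upper bounds (h) of the 14 excretion intervals of the retention model.
DEFAULT_INTERVAL_BOUNDS = (1.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0,
                           24.0, 30.0, 36.0, 42.0, 48.0, 54.0)


class TableFormatError(ValueError):
    """A CSV is missing required columns or has an unusable layout."""


class RowParseError(ValueError):
    """One or more data rows failed validation; offending lines are listed."""

    def __init__(self, message: str, lines: list[int]):
        super().__init__(f"{message} (lines {lines})")
        self.lines = lines


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPSFix:
    """One GPS position of one animal (planar metres, UTC timestamp)."""

    animal_id: str
    timestamp: pd.Timestamp
    easting: float
    northing: float
    elevation: float
    quality_ok: bool


@dataclass
class Trajectory:
    """Time-ordered, quality-screened fixes of one individual.

    Positions are stored as parallel numpy arrays so the dispersal simulator
    can interpolate without per-fix Python overhead.
    """

    animal_id: str
    times: np.ndarray        # datetime64[ns], strictly increasing
    easting: np.ndarray
    northing: np.ndarray
    elevation: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        for arr in (self.easting, self.northing, self.elevation):
            if len(arr) != n:
                raise ValueError("trajectory arrays must share one length")
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.easting = np.asarray(self.easting, dtype=float)
        self.northing = np.asarray(self.northing, dtype=float)
        self.elevation = np.asarray(self.elevation, dtype=float)
        if n >= 2 and not (np.diff(self.times.astype("int64")) > 0).all():
            raise ValueError(
                f"{self.animal_id}: timestamps must be strictly increasing")
        if not (np.isfinite(self.easting).all()
                and np.isfinite(self.northing).all()
                and np.isfinite(self.elevation).all()):
            raise ValueError(f"{self.animal_id}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def t_seconds(self) -> np.ndarray:
        """Fix times as float seconds since the Unix epoch (UTC)."""
        return self.times.astype("int64") / 1e9

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "animal_id": self.animal_id,
            "timestamp": pd.DatetimeIndex(self.times, tz="UTC"),
            "easting_m": self.easting,
            "northing_m": self.northing,
            "elevation_m": self.elevation,
            "quality_ok": True,
        })


@dataclass
class PassageTimeModel:
    """Interval-probability model of seed passage (retention) time.

    ``cell_probs`` maps each (trial, species) combination of the feeding
    experiment to a probability vector over the excretion intervals whose
    upper bounds are ``interval_upper_bounds`` (the first interval spans
    [0, first bound)).
    """

    interval_upper_bounds: np.ndarray
    cell_probs: dict[tuple[str, str], np.ndarray]

    def __post_init__(self) -> None:
        b = np.asarray(self.interval_upper_bounds, dtype=float)
        if not ((b > 0).all() and (np.diff(b) > 0).all()):
            raise ValueError("interval bounds must be positive and increasing")
        self.interval_upper_bounds = b
        for cell, p in self.cell_probs.items():
            p = np.asarray(p, dtype=float)
            if len(p) != len(b):
                raise ValueError(f"cell {cell}: expected {len(b)} probabilities")
            if (p < 0).any():
                raise ValueError(f"cell {cell}: negative probability")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"cell {cell}: probabilities sum to {p.sum()}")
            self.cell_probs[cell] = p

    @property
    def n_cells(self) -> int:
        return len(self.cell_probs)

    @property
    def interval_lower_bounds(self) -> np.ndarray:
        return np.concatenate([[0.0], self.interval_upper_bounds[:-1]])

    @property
    def max_hours(self) -> float:
        return float(self.interval_upper_bounds[-1])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (trial, species), p in sorted(self.cell_probs.items()):
            for ub, prob in zip(self.interval_upper_bounds, p):
                rows.append((trial, species, ub, prob))
        return pd.DataFrame(rows, columns=PASSAGE_COLUMNS)


@dataclass
class DungSample:
    """One pellet group: volume plus seedling counts per plant species."""

    sample_id: str
    animal_id: str
    collection_date: pd.Timestamp
    volume_ml: float
    species_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.volume_ml > 0:
            raise ValueError(f"{self.sample_id}: volume must be positive")
        for sp, c in self.species_counts.items():
            if c < 0 or int(c) != c:
                raise ValueError(f"{self.sample_id}/{sp}: bad count {c}")

    @property
    def month(self) -> int:
        return int(self.collection_date.month)


@dataclass
class SeedLoadTable:
    """Seed load Q (seedlings per gram dung dry mass) per cell.

    ``cells`` is a long frame (animal_id, month, species, q); ``totals``
    holds the per-(animal, month) sum across species.
    """

    cells: pd.DataFrame
    totals: pd.DataFrame
    sample_q: pd.DataFrame | None = None  # per-sample q, pre-aggregation

    def species(self) -> list[str]:
        return sorted(self.cells["species"].unique())

    def species_cells(self, species: str) -> pd.DataFrame:
        return self.cells[self.cells["species"] == species]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")


def read_fixes(path: str | Path) -> list[GPSFix]:
    """Read a GPS-fix CSV into a list of :class:`GPSFix`.

    Malformed rows (unparseable timestamps, non-finite coordinates) raise
    :class:`RowParseError` naming the offending data lines (1-based counting
    including the header, as an editor shows them).
    """
    df = pd.read_csv(path)
    _require_columns(df, FIXES_COLUMNS, path)
    if df.empty:
        log.warning("%s: no data rows", path)
        return []
    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce")
    bad = ts.isna()
    for col in ("easting_m", "northing_m", "elevation_m"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad |= ~np.isfinite(vals)
        df[col] = vals
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +1 header, +1 one-based
        raise RowParseError(f"{path}: unparseable rows", lines)
    quality = df["quality_ok"].astype(str).str.strip().str.lower().isin(
        ("true", "1", "yes", "t"))
    return [
        GPSFix(str(a), t, float(e), float(n), float(z), bool(q))
        for a, t, e, n, z, q in zip(df["animal_id"], ts, df["easting_m"],
                                    df["northing_m"], df["elevation_m"],
                                    quality)
    ]


def filter_and_split(fixes: list[GPSFix]) -> dict[str, Trajectory]:
    """Quality-screen fixes and split them into per-animal trajectories.

    Keeps only ``quality_ok`` fixes, sorts by timestamp per animal, collapses
    duplicate timestamps to the first occurrence (logged), and drops animals
    left with fewer than two fixes (logged). Never raises on degraded input.
    """
    out: dict[str, Trajectory] = {}
    by_animal: dict[str, list[GPSFix]] = {}
    for f in fixes:
        if f.quality_ok:
            by_animal.setdefault(f.animal_id, []).append(f)
    n_dropped_quality = len(fixes) - sum(len(v) for v in by_animal.values())
    if n_dropped_quality:
        log.info("dropped %d fixes failing the quality screen",
                 n_dropped_quality)
    for animal_id, group in by_animal.items():
        group.sort(key=lambda f: f.timestamp)
        seen: set = set()
        kept = []
        for f in group:
            if f.timestamp in seen:
                continue
            seen.add(f.timestamp)
            kept.append(f)
        n_dup = len(group) - len(kept)
        if n_dup:
            log.warning("%s: collapsed %d duplicate timestamps", animal_id,
                        n_dup)
        if len(kept) < 2:
            log.warning("%s: fewer than 2 usable fixes, excluded", animal_id)
            continue
        out[animal_id] = Trajectory(
            animal_id=animal_id,
            times=np.array([f.timestamp.tz_convert("UTC").tz_localize(None)
                            for f in kept], dtype="datetime64[ns]"),
            easting=np.array([f.easting for f in kept]),
            northing=np.array([f.northing for f in kept]),
            elevation=np.array([f.elevation for f in kept]),
        )
    if not out:
        log.warning("no animal had >= 2 usable fixes")
    return out


def read_dung(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, DUNG_COLUMNS, path)
    df["collection_date"] = pd.to_datetime(df["collection_date"])
    bad = df.index[~(pd.to_numeric(df["volume_ml"], errors="coerce") > 0)]
    if len(bad):
        raise RowParseError(f"{path}: non-positive or missing volumes",
                            (bad + 2).tolist())
    return df


def read_seedlings(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SEEDLING_COLUMNS, path)
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = df.index[counts.isna() | (counts < 0) | (counts % 1 != 0)]
    if len(bad):
        raise RowParseError(f"{path}: counts must be non-negative integers",
                            (bad + 2).tolist())
    df["count"] = counts.astype(int)
    return df


def read_control(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, CONTROL_COLUMNS, path)
    return df


def read_passage(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, PASSAGE_COLUMNS, path)
    return df


def assemble_samples(dung: pd.DataFrame,
                     seedlings: pd.DataFrame) -> list[DungSample]:
    """Join the dung and long seedling tables into :class:`DungSample` objects.

    Seedling rows whose sample_id has no dung record are an error; dung
    samples without seedling rows get an empty species map (zero load).
    """
    known = set(dung["sample_id"].astype(str))
    orphans = sorted(set(seedlings["sample_id"].astype(str)) - known)
    if orphans:
        raise TableFormatError(
            f"seedling rows reference unknown sample_ids: {orphans[:5]}")
    counts: dict[str, dict[str, int]] = {}
    for sid, sp, c in zip(seedlings["sample_id"].astype(str),
                          seedlings["species"], seedlings["count"]):
        counts.setdefault(sid, {})
        counts[sid][str(sp)] = counts[sid].get(str(sp), 0) + int(c)
    return [
        DungSample(sample_id=str(r.sample_id), animal_id=str(r.animal_id),
                   collection_date=pd.Timestamp(r.collection_date),
                   volume_ml=float(r.volume_ml),
                   species_counts=counts.get(str(r.sample_id), {}))
        for r in dung.itertuples()
    ]


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a tabular result as CSV with a deterministic column order.

    Floats use Python's shortest-repr formatting, so a write/read round trip
    is bit-exact for text and numeric fields alike.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    # round_trip parsing so written floats come back bit-exact
    return pd.read_csv(path, float_precision="round_trip")


def trajectories_to_frame(trajs: dict[str, Trajectory]) -> pd.DataFrame:
    if not trajs:
        return pd.DataFrame(columns=FIXES_COLUMNS)
    return pd.concat([t.to_frame() for t in trajs.values()],
                     ignore_index=True)
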