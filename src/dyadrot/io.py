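"""Readers and writers for tracking, cell and bond tables.

The pipeline starts at tabular exports: MTrackJ-style centroid tracks
and Tissue-Analyzer-style cell/bond tables.  Coordinates are continuous
2-D, x increasing posterior (the anteroposterior axis), y increasing
dorsal.  Frames are 0-based; times are ``frame * frame_interval`` unless
an explicit ``time_min`` column is present, in which case the column
wins.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig

__all__ = [
    "TrackTable",
    "CellBondTables",
    "TableFormatError",
    "TableValidationError",
    "read_track_table",
    "read_cell_bond_tables",
    "write_results",
    "encode_polyline",
    "decode_polyline",
]

logger = logging.getLogger("dyadrot")

TRACK_COLUMNS = ["track_id", "frame", "time_min", "x_um", "y_um"]
CELL_COLUMNS = ["cell_id", "frame", "cx_um", "cy_um", "area_um2", "perimeter_um"]
BOND_COLUMNS = ["frame", "cell_id_a", "cell_id_b", "length_um"]


class TableFormatError(ValueError):
    """A file does not expose the required columns."""


class TableValidationError(ValueError):
    """Parsed rows violate a structural invariant."""


def encode_polyline(points: np.ndarray) -> str:
    """Serialize an (N, 2) coordinate array as ``"x y;x y;..."``."""
    pts = np.asarray(points, dtype=float)
    return ";".join(f"{x:.6g} {y:.6g}" for x, y in pts)


def decode_polyline(text: str) -> np.ndarray:
    pairs = [p.split() for p in str(text).split(";") if p.strip()]
    return np.array([[float(x), float(y)] for x, y in pairs])


@dataclass
class TrackTable:
    """Centroid tracks on a common time base.

    ``df`` has columns ``track_id, frame, time_min, x_um, y_um`` with
    strictly increasing frames within a track and no duplicate
    ``(track_id, frame)``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRACK_COLUMNS if c not in self.df.columns]
        if missing:
            raise TableFormatError(f"track table missing columns: {missing}")
        self.df = self.df[TRACK_COLUMNS].reset_index(drop=True)
        dup = self.df.duplicated(subset=["track_id", "frame"])
        if dup.any():
            rows = self.df.loc[dup, ["track_id", "frame"]].values.tolist()
            raise TableValidationError(f"duplicate (track_id, frame) rows: {rows[:5]}")
        for tid, grp in self.df.groupby("track_id", sort=False):
            frames = grp["frame"].to_numpy()
            if np.any(np.diff(frames) <= 0):
                raise TableValidationError(
                    f"frames not strictly increasing within track {tid!r}"
                )
        if (self.df["frame"] < 0).any():
            raise TableValidationError("negative frame indices")

    @property
    def track_ids(self) -> list:
        return list(dict.fromkeys(self.df["track_id"]))

    def track(self, track_id) -> pd.DataFrame:
        sub = self.df[self.df["track_id"] == track_id]
        if sub.empty:
            raise KeyError(f"no track {track_id!r}")
        return sub.reset_index(drop=True)

    def positions(self, track_id) -> np.ndarray:
        return self.track(track_id)[["x_um", "y_um"]].to_numpy()


@dataclass
class CellBondTables:
    """Per-frame cell geometry plus the membrane-sharing bond list.

    Every bond must reference two cell rows present at that frame;
    lengths must be positive and a bond may not join a cell to itself.
    """

    cells: pd.DataFrame
    bonds: pd.DataFrame
    orphan_bonds: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise TableFormatError(f"cell table missing columns: {missing}")
        missing = [c for c in BOND_COLUMNS if c not in self.bonds.columns]
        if missing:
            raise TableFormatError(f"bond table missing columns: {missing}")
        if "polyline" not in self.bonds.columns:
            self.bonds = self.bonds.assign(polyline=None)
        self.cells = self.cells.reset_index(drop=True)
        self.bonds = self.bonds.reset_index(drop=True)
        if len(self.bonds):
            if (self.bonds["length_um"] <= 0).any():
                raise TableValidationError("bond lengths must be > 0")
            if (self.bonds["cell_id_a"] == self.bonds["cell_id_b"]).any():
                raise TableValidationError("bond joins a cell to itself")
        present = set(zip(self.cells["cell_id"], self.cells["frame"]))
        bad = [
            i
            for i, row in self.bonds.iterrows()
            if (row["cell_id_a"], row["frame"]) not in present
            or (row["cell_id_b"], row["frame"]) not in present
        ]
        self.orphan_bonds = self.bonds.loc[bad].copy()
        if bad:
            raise TableValidationError(
                f"{len(bad)} bond row(s) reference cells absent at their frame; "
                f"first offending rows: {self.bonds.loc[bad[:5]].to_dict('records')}"
            )

    def bonds_at(self, frame: int) -> pd.DataFrame:
        return self.bonds[self.bonds["frame"] == frame]

    def cells_at(self, frame: int) -> pd.DataFrame:
        return self.cells[self.cells["frame"] == frame]

    @property
    def frames(self) -> np.ndarray:
        return np.unique(self.cells["frame"].to_numpy())


def read_track_table(path: str | Path, config: RunConfig | None = None) -> TrackTable:
    """Parse an MTrackJ-style centroid export into a :class:`TrackTable`.

    Required columns: ``track_id, frame, x, y`` (or already-converted
    ``x_um, y_um``); an optional ``time_min`` column overrides the
    frame-derived times.  Rows beyond ``config.max_observation_min`` are
    dropped and the exclusion is logged.
    """
    config = config or RunConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in raw.columns}

    def pick(*names):
        for n in names:
            if n in cols:
                return cols[n]
        return None

    tid = pick("track_id", "track", "tid")
    frame = pick("frame", "t", "timepoint")
    x = pick("x_um", "x")
    y = pick("y_um", "y")
    if None in (tid, frame, x, y):
        raise TableFormatError(
            f"{path.name}: need track_id/frame/x/y columns, found {list(raw.columns)}"
        )
    df = pd.DataFrame(
        {
            "track_id": raw[tid].astype(str),
            "frame": raw[frame].astype(int),
            "x_um": raw[x].astype(float) * config.scale,
            "y_um": raw[y].astype(float) * config.scale,
        }
    )
    tcol = pick("time_min", "time")
    if tcol is not None:
        df["time_min"] = raw[tcol].astype(float)
    else:
        df["time_min"] = df["frame"] * config.frame_interval_min
    n0 = len(df)
    df = df[df["time_min"] <= config.max_observation_min + 1e-9]
    if len(df) < n0:
        logger.info(
            "%s: dropped %d row(s) beyond %.0f min observation cap",
            path.name,
            n0 - len(df),
            config.max_observation_min,
        )
    return TrackTable(df.reset_index(drop=True))


def read_cell_bond_tables(
    cell_path: str | Path, bond_path: str | Path, config: RunConfig | None = None
) -> CellBondTables:
    """Parse Tissue-Analyzer-style cell and bond exports."""
    config = config or RunConfig()
    cell_path, bond_path = Path(cell_path), Path(bond_path)
    for p in (cell_path, bond_path):
        if not p.exists():
            raise FileNotFoundError(p)
    cells_raw = pd.read_csv(cell_path)
    missing = [c for c in CELL_COLUMNS if c not in cells_raw.columns]
    if missing:
        raise TableFormatError(f"{cell_path.name}: missing columns {missing}")
    cells = cells_raw[CELL_COLUMNS].copy()
    cells["cell_id"] = cells["cell_id"].astype(str)
    s = config.scale
    cells[["cx_um", "cy_um"]] *= s
    cells["area_um2"] *= s * s
    cells["perimeter_um"] *= s

    try:
        bonds_raw = pd.read_csv(bond_path)
    except pd.errors.EmptyDataError:
        bonds_raw = pd.DataFrame(columns=BOND_COLUMNS)
    if bonds_raw.empty:
        logger.warning("%s: empty bond table", bond_path.name)
        bonds = pd.DataFrame(columns=BOND_COLUMNS + ["polyline"])
    else:
        missing = [c for c in BOND_COLUMNS if c not in bonds_raw.columns]
        if missing:
            raise TableFormatError(f"{bond_path.name}: missing columns {missing}")
        keep = BOND_COLUMNS + (["polyline"] if "polyline" in bonds_raw.columns else [])
        bonds = bonds_raw[keep].copy()
        bonds["cell_id_a"] = bonds["cell_id_a"].astype(str)
        bonds["cell_id_b"] = bonds["cell_id_b"].astype(str)
        bonds["length_um"] *= s
        if "polyline" in bonds.columns and s != 1.0:
            bonds["polyline"] = [
                encode_polyline(decode_polyline(p) * s) if isinstance(p, str) else p
                for p in bonds["polyline"]
            ]
    return CellBondTables(cells=cells, bonds=bonds)


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write one TSV per result table plus a JSON run manifest.

    Floats are written with 4 decimal places (angles are reported in
    degrees at that precision) so re-running on identical inputs yields
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    hashes = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.4f", lineterminator="\n")
        written[name] = path
        hashes[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "tables": {k: p.name for k, p in written.items()},
        "sha256": hashes,
        "config": (config or RunConfig()).to_dict(),
        "seed": seed,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    written["manifest"] = mpath
    return written


def write_track_table(table: TrackTable, path: str | Path) -> Path:
    """Write a :class:`TrackTable` in the CSV dialect `read_track_table` parses."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")
    return path


def write_cell_bond_tables(
    tables: CellBondTables, cell_path: str | Path, bond_path: str | Path
) -> tuple[Path, Path]:
    cell_path, bond_path = Path(cell_path), Path(bond_path)
    cell_path.parent.mkdir(parents=True, exist_ok=True)
    tables.cells.to_csv(cell_path, index=False, float_format="%.6f", lineterminator="\n")
    tables.bonds.to_csv(bond_path, index=False, float_format="%.6f", lineterminator="\n")
    return cell_path, bond_path
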