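"""Domain types, 3D geometry, validation and tabular I/O for arrangement data.

The unit of analysis is an :class:`ArrangementDataset`: a tidy collection of
object placements (3D centers, meters) produced by participants arranging
virtual rooms, plus the grab / gaze / search event streams recorded while they
did so.  Rooms have a 3 x 3 m floor plan; coordinates are right-handed, meters,
origin at the room-floor center, z up.  Every room holds 15 objects: 10
*local* objects (small, movable, acted upon) and 5 *global* objects (large,
static scene anchors).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ROOM_CATEGORIES = ("kitchen", "bathroom", "bedroom", "living_room", "gym")
OBJECT_TYPES = ("global", "local")
CONDITIONS = ("consistent", "inconsistent")
PHASES = ("build", "recall")
ROOM_TYPES = ("own", "other")

#: half-width of the square floor plan, meters
ROOM_HALF_WIDTH = 1.5
#: slack beyond the floor plan allowed for object centers leaning on walls
BOUNDS_TOL = 0.25

PLACEMENT_COLUMNS = [
    "participant_id", "room_id", "room_category", "condition", "phase",
    "room_type", "object_id", "object_type", "x", "y", "z",
]
GRAB_COLUMNS = [
    "participant_id", "room_id", "condition", "phase", "object_id",
    "object_type", "duration_s", "grab_index",
]
SEARCH_COLUMNS = [
    "participant_id", "room_id", "condition", "room_type", "object_id",
    "object_type", "trial_index", "rt_s", "error",
]
GAZE_COLUMNS = ["participant_id", "room_id", "object_id", "gaze_s"]


class ParseError(ValueError):
    """Raised when an input table violates the documented schema."""


@dataclass(frozen=True)
class ObjectSpec:
    """Inventory entry: one object and its canonical place in the scene grammar.

    Local objects carry a canonical anchor (the id of a global object of the
    same room category) and a canonical offset from that anchor, in meters.
    Global objects are anchors themselves and have no anchor link.
    """

    object_id: str
    name: str
    room_category: str
    object_type: str
    canonical_anchor: str | None = None
    canonical_offset: tuple[float, float, float] | None = None
    canonical_position: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.room_category not in ROOM_CATEGORIES:
            raise ValueError(f"unknown room_category {self.room_category!r}")
        if self.object_type not in OBJECT_TYPES:
            raise ValueError(f"unknown object_type {self.object_type!r}")
        if self.object_type == "global" and self.canonical_anchor is not None:
            raise ValueError("global objects cannot have a canonical_anchor")
        if self.object_type == "local" and self.canonical_anchor is None:
            raise ValueError("local objects require a canonical_anchor")


@dataclass
class DesignConfig:
    """The design constants a dataset instantiates."""

    n_participants: int
    room_categories: int
    rooms_per_category: int
    n_local: int = 10
    n_global: int = 5
    spawn_radius: float = 1.5
    spawn_height: float = 1.0
    room_half_width: float = ROOM_HALF_WIDTH

    @property
    def objects_per_room(self) -> int:
        return self.n_local + self.n_global

    @property
    def rooms_per_participant(self) -> int:
        return self.room_categories * self.rooms_per_category


@dataclass
class ArrangementDataset:
    """Tidy container for one experiment's worth of arrangement data.

    Attributes
    ----------
    inventory
        List of :class:`ObjectSpec`, one per distinct object.
    placements
        One row per (participant, room, phase, object): 3D center position
        plus condition labels (columns ``PLACEMENT_COLUMNS``).
    grabs
        One row per first grab of an object within a trial: duration of all
        grabs summed is *not* implied — ``duration_s`` is the summed grab
        duration for that object, ``grab_index`` the 1-based order of its
        first grab.
    gaze_totals
        Summed gaze duration per (participant, room, object), seconds.
    searches
        One row per search trial (target cue -> button press).
    design
        The :class:`DesignConfig` the dataset instantiates.
    """

    inventory: list[ObjectSpec] = field(default_factory=list)
    placements: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=PLACEMENT_COLUMNS))
    grabs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=GRAB_COLUMNS))
    gaze_totals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=GAZE_COLUMNS))
    searches: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=SEARCH_COLUMNS))
    design: DesignConfig | None = None

    def inventory_by_id(self) -> dict[str, ObjectSpec]:
        return {spec.object_id: spec for spec in self.inventory}


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def distance3d(p, q) -> float:
    """Euclidean distance between two 3D object centers, meters.

    Raises ``ValueError`` on non-finite coordinates.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != (3,) or q.shape != (3,):
        raise ValueError("distance3d expects 3-vectors")
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise ValueError("non-finite coordinates")
    return float(np.linalg.norm(p - q))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    def add(self, msg: str) -> None:
        self.violations.append(msg)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy iff clean
        return self.ok


def validate_dataset(ds: ArrangementDataset) -> ValidationReport:
    """Check a dataset against the design invariants.

    Violations are collected and reported, never raised: per-room object
    counts (10 local + 5 global), positions within the floor plan (with
    ``BOUNDS_TOL`` slack for wall-leaning objects, z >= 0), duplicate
    placement keys, placements referring to objects missing from the
    inventory, condition labels constant within (participant, room), and
    positive grab durations / search RTs.
    """
    report = ValidationReport()
    known_ids = {s.object_id for s in ds.inventory}
    specs = ds.inventory_by_id()

    for spec in ds.inventory:
        if spec.object_type == "local":
            anchor = specs.get(spec.canonical_anchor)
            if anchor is None:
                report.add(f"inventory: local {spec.object_id} has dangling "
                           f"anchor {spec.canonical_anchor}")
            elif anchor.object_type != "global":
                report.add(f"inventory: anchor of {spec.object_id} is not global")
            elif anchor.room_category != spec.room_category:
                report.add(f"inventory: anchor of {spec.object_id} is in "
                           f"another room category")

    pl = ds.placements
    if len(pl):
        half = (ds.design.room_half_width if ds.design else ROOM_HALF_WIDTH)
        lim = half + BOUNDS_TOL
        bad = pl[(pl.x.abs() > lim) | (pl.y.abs() > lim) | (pl.z < 0)]
        for _, row in bad.iterrows():
            report.add(f"placement out of bounds: {row.participant_id}/"
                       f"{row.room_id}/{row.phase}/{row.object_id} "
                       f"at ({row.x:.2f}, {row.y:.2f}, {row.z:.2f})")

        key = ["participant_id", "room_id", "phase", "object_id"]
        dups = pl[pl.duplicated(key, keep=False)]
        for k, _ in dups.groupby(key):
            report.add(f"duplicate placement key: {k}")

        if known_ids:
            dangling = set(pl.object_id) - known_ids
            for oid in sorted(dangling):
                report.add(f"placement references unknown object {oid}")

        if ds.design is not None:
            counts = pl.groupby(
                ["participant_id", "room_id", "phase"], sort=False)
            for (p, r, ph), grp in counts:
                n_local = int((grp.object_type == "local").sum())
                n_global = int((grp.object_type == "global").sum())
                if len(grp) != ds.design.objects_per_room:
                    report.add(f"room {p}/{r}/{ph} has {len(grp)} objects, "
                               f"expected {ds.design.objects_per_room}")
                elif (n_local, n_global) != (ds.design.n_local,
                                             ds.design.n_global):
                    report.add(f"room {p}/{r}/{ph} has {n_local} local + "
                               f"{n_global} global objects")

        cond = pl.groupby(["participant_id", "room_id"]).condition.nunique()
        for key_, n in cond[cond > 1].items():
            report.add(f"condition not constant within {key_}")

    if len(ds.grabs) and (ds.grabs.duration_s <= 0).any():
        report.add("non-positive grab duration present")
    if len(ds.searches) and (ds.searches.rt_s <= 0).any():
        report.add("non-positive search RT present")
    return report


# ---------------------------------------------------------------------------
# summed durations
# ---------------------------------------------------------------------------

def summed_durations(events: pd.DataFrame,
                     value_col: str = "duration_s") -> pd.Series:
    """Sum event durations per (participant, room, object).

    Works for grab streams and gaze-sample streams alike; an object with no
    events is simply absent from the result.  Raises on negative durations.
    """
    if len(events) == 0:
        return pd.Series(dtype=float, name=value_col)
    if (events[value_col] < 0).any():
        raise ValueError("negative duration in event stream")
    return events.groupby(
        ["participant_id", "room_id", "object_id"])[value_col].sum()


# ---------------------------------------------------------------------------
# I/O — CSV for the long tables, JSON for inventory and design
# ---------------------------------------------------------------------------

_FILES = {
    "placements": "placements.csv",
    "grabs": "grabs.csv",
    "searches": "searches.csv",
    "gaze": "gaze.csv",
    "inventory": "inventory.json",
    "design": "design.json",
}


def _check_tokens(df: pd.DataFrame, col: str, allowed: tuple[str, ...],
                  fname: str, optional: bool = False) -> None:
    for i, v in df[col].items():
        if optional and (v is None or (isinstance(v, float) and np.isnan(v))
                         or v == ""):
            continue
        if v not in allowed:
            raise ParseError(
                f"{fname} row {i + 2}: unknown {col} token {v!r}")


def _read_csv(path: Path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=columns)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing column(s) {missing}")
    return df[columns]


def read_dataset(directory: str | Path) -> ArrangementDataset:
    """Read an :class:`ArrangementDataset` from the documented CSV/JSON files.

    Schema violations raise :class:`ParseError` naming the file and the
    1-based data row (header is row 1).
    """
    d = Path(directory)
    ds = ArrangementDataset()

    inv_path = d / _FILES["inventory"]
    if inv_path.exists():
        records = json.loads(inv_path.read_text())
        ds.inventory = [
            ObjectSpec(
                object_id=r["object_id"], name=r["name"],
                room_category=r["room_category"],
                object_type=r["object_type"],
                canonical_anchor=r.get("canonical_anchor"),
                canonical_offset=(tuple(r["canonical_offset"])
                                  if r.get("canonical_offset") else None),
                canonical_position=(tuple(r["canonical_position"])
                                    if r.get("canonical_position") else None),
            )
            for r in records
        ]

    design_path = d / _FILES["design"]
    if design_path.exists():
        ds.design = DesignConfig(**json.loads(design_path.read_text()))

    p_path = d / _FILES["placements"]
    if p_path.exists():
        df = _read_csv(p_path, PLACEMENT_COLUMNS)
        if len(df):
            _check_tokens(df, "condition", CONDITIONS, p_path.name)
            _check_tokens(df, "phase", PHASES, p_path.name)
            _check_tokens(df, "room_category", ROOM_CATEGORIES, p_path.name)
            _check_tokens(df, "object_type", OBJECT_TYPES, p_path.name)
            _check_tokens(df, "room_type", ROOM_TYPES, p_path.name,
                          optional=True)
            for c in ("x", "y", "z"):
                df[c] = pd.to_numeric(df[c], errors="raise")
            key = ["participant_id", "room_id", "phase", "object_id"]
            dup = df.duplicated(key)
            if dup.any():
                row = int(df.index[dup][0]) + 2
                raise ParseError(f"{p_path.name} row {row}: duplicate "
                                 f"placement key")
        ds.placements = df

    g_path = d / _FILES["grabs"]
    if g_path.exists():
        df = _read_csv(g_path, GRAB_COLUMNS)
        if len(df):
            _check_tokens(df, "condition", CONDITIONS, g_path.name)
            _check_tokens(df, "phase", PHASES, g_path.name)
            _check_tokens(df, "object_type", OBJECT_TYPES, g_path.name)
            df["duration_s"] = pd.to_numeric(df["duration_s"], errors="raise")
            df["grab_index"] = pd.to_numeric(
                df["grab_index"], errors="raise").astype(int)
        ds.grabs = df

    s_path = d / _FILES["searches"]
    if s_path.exists():
        df = _read_csv(s_path, SEARCH_COLUMNS)
        if len(df):
            _check_tokens(df, "condition", CONDITIONS, s_path.name)
            _check_tokens(df, "room_type", ROOM_TYPES, s_path.name)
            _check_tokens(df, "object_type", OBJECT_TYPES, s_path.name)
            df["trial_index"] = pd.to_numeric(
                df["trial_index"], errors="raise").astype(int)
            df["rt_s"] = pd.to_numeric(df["rt_s"], errors="raise")
            bad = ~df["error"].isin(("True", "False", "0", "1"))
            if bad.any():
                row = int(df.index[bad][0]) + 2
                raise ParseError(f"{s_path.name} row {row}: error flag must "
                                 f"be True/False")
            df["error"] = df["error"].isin(("True", "1"))
        ds.searches = df

    z_path = d / _FILES["gaze"]
    if z_path.exists():
        df = _read_csv(z_path, GAZE_COLUMNS)
        if len(df):
            df["gaze_s"] = pd.to_numeric(df["gaze_s"], errors="raise")
        ds.gaze_totals = df

    return ds


def write_dataset(ds: ArrangementDataset, directory: str | Path) -> None:
    """Write a dataset to the documented CSV/JSON files (lossless round trip).

    Floats are written with 12 significant digits, well inside the 1e-9
    round-trip tolerance.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    inv = []
    for s in ds.inventory:
        rec = asdict(s)
        if rec["canonical_offset"] is not None:
            rec["canonical_offset"] = list(rec["canonical_offset"])
        if rec["canonical_position"] is not None:
            rec["canonical_position"] = list(rec["canonical_position"])
        inv.append(rec)
    (d / _FILES["inventory"]).write_text(json.dumps(inv, indent=1))
    if ds.design is not None:
        (d / _FILES["design"]).write_text(
            json.dumps(asdict(ds.design), indent=1))

    ds.placements.to_csv(d / _FILES["placements"], index=False,
                         float_format="%.12g")
    ds.grabs.to_csv(d / _FILES["grabs"], index=False, float_format="%.12g")
    ds.searches.to_csv(d / _FILES["searches"], index=False,
                       float_format="%.12g")
    ds.gaze_totals.to_csv(d / _FILES["gaze"], index=False,
                          float_format="%.12g")
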