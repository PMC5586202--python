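"""Data model, file I/O, nest geometry, spatial discretization and brood lookup.

Trajectories are regular sequences of 2-D fixes recorded inside a small
rectangular nest at a fixed sampling interval (10 min by default).  Missing
fixes -- ants leaving the nest or being hidden -- are kept in-band as NaN
coordinates rather than dropped rows, so the temporal gap structure of each
trajectory stays explicit.  Space is discretized into a regular square grid
("sites"); all downstream visitation statistics are defined on sites.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MISSING",
    "BROOD_STAGES",
    "NestGeometry",
    "Trajectory",
    "GridSpec",
    "SiteSequence",
    "BroodCensus",
    "RunConfig",
    "read_trajectories",
    "write_trajectories",
    "read_brood",
    "write_brood",
    "make_grid",
    "assign_sites",
    "brood_counts_at",
]

#: sentinel site index for a missing fix in an integer site sequence
MISSING = -1

#: brood developmental stages, in the order used throughout
BROOD_STAGES = ("egg", "small_larva", "large_larva", "pupa")

CASTES = ("queen", "worker")


class ValidationError(ValueError):
    """Raised when input data violate the nest/trajectory invariants."""


@dataclass(frozen=True)
class NestGeometry:
    """Axis-aligned rectangular nest [0, width] x [0, height], in mm.

    The entrance is a point on the rectangle perimeter (the physical nests
    are flat cavities; the vertical dimension is ignored).
    """

    width: float
    height: float
    entrance_xy: tuple[float, float] = (25.0, 0.0)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError("nest dimensions must be positive")
        ex, ey = self.entrance_xy
        on_x = 0.0 <= ex <= self.width and (ey == 0.0 or ey == self.height)
        on_y = 0.0 <= ey <= self.height and (ex == 0.0 or ex == self.width)
        if not (on_x or on_y):
            raise ValidationError(
                f"entrance {self.entrance_xy} does not lie on the nest perimeter"
            )

    def contains(self, x, y) -> np.ndarray:
        """Vectorised inside-the-rectangle test (boundary inclusive)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= 0) & (x <= self.width) & (y >= 0) & (y <= self.height)


@dataclass
class Trajectory:
    """One individual's fix sequence on a contiguous tick grid.

    ``x``/``y`` are float arrays aligned with ``ticks``; missing fixes are
    NaN in both.  Ticks are integer multiples of the sampling interval
    (``tick_minutes``), contiguous from the first to the last observed fix.
    """

    colony_id: str
    ant_id: str
    caste: str
    ticks: np.ndarray
    x: np.ndarray
    y: np.ndarray
    tick_minutes: float = 10.0

    def __post_init__(self) -> None:
        self.ticks = np.asarray(self.ticks, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.caste not in CASTES:
            raise ValidationError(f"unknown caste {self.caste!r}")
        if not (len(self.ticks) == len(self.x) == len(self.y)):
            raise ValidationError("ticks/x/y length mismatch")
        if len(self.ticks) and np.any(np.diff(self.ticks) != 1):
            raise ValidationError("ticks must be contiguous (gaps encoded as NaN)")
        if np.any(np.isnan(self.x) != np.isnan(self.y)):
            raise ValidationError("x and y must be missing together")
        if self.n_observed < 2:
            raise ValidationError("trajectory needs at least 2 observed fixes")

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of observed (non-missing) fixes."""
        return ~np.isnan(self.x)

    @property
    def n_observed(self) -> int:
        return int(np.count_nonzero(~np.isnan(self.x)))

    @property
    def n_ticks(self) -> int:
        return len(self.ticks)

    @property
    def first_observed_xy(self) -> tuple[float, float]:
        i = int(np.flatnonzero(self.observed)[0])
        return float(self.x[i]), float(self.y[i])

    @property
    def last_observed_tick(self) -> int:
        return int(self.ticks[np.flatnonzero(self.observed)[-1]])

    def validate_geometry(self, geometry: NestGeometry) -> None:
        obs = self.observed
        ok = geometry.contains(self.x[obs], self.y[obs])
        if not np.all(ok):
            bad = np.flatnonzero(~ok)[0]
            t = self.ticks[obs][bad]
            raise ValidationError(
                f"coordinate outside nest for {self.colony_id}/{self.ant_id} "
                f"at tick {t}"
            )


@dataclass(frozen=True)
class GridSpec:
    """Regular square grid over the nest, origin at the nest corner (0, 0).

    Cells are half-open ``[k*c, (k+1)*c)``; points on the far nest edges are
    clamped into the last row/column, so every in-nest point maps to exactly
    one site.  Boundary cells may be partial when the cell size does not
    divide the nest dimensions.
    """

    cell_size: float
    n_cols: int
    n_rows: int

    @property
    def n_sites(self) -> int:
        return self.n_cols * self.n_rows

    def flatten(self, col, row) -> np.ndarray:
        return np.asarray(row, dtype=int) * self.n_cols + np.asarray(col, dtype=int)

    def unflatten(self, site) -> tuple[np.ndarray, np.ndarray]:
        site = np.asarray(site, dtype=int)
        return site % self.n_cols, site // self.n_cols

    def point_to_site(self, x, y) -> np.ndarray:
        """Map coordinates to flat site indices (NaN-safe: NaN -> MISSING)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        with np.errstate(invalid="ignore"):
            col = np.clip(np.floor(x / self.cell_size), 0, self.n_cols - 1)
            row = np.clip(np.floor(y / self.cell_size), 0, self.n_rows - 1)
        flat = np.where(
            np.isnan(x), MISSING, (row * self.n_cols + col)
        )
        return flat.astype(int)

    def cell_center(self, site) -> tuple[np.ndarray, np.ndarray]:
        col, row = self.unflatten(site)
        return (col + 0.5) * self.cell_size, (row + 0.5) * self.cell_size


@dataclass
class SiteSequence:
    """Per-tick flat site index of one trajectory; MISSING where the fix is."""

    colony_id: str
    ant_id: str
    caste: str
    ticks: np.ndarray
    sites: np.ndarray
    grid: GridSpec
    tick_minutes: float = 10.0

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=int)
        if len(self.sites) != len(self.ticks):
            raise ValidationError("site sequence length mismatch")

    @property
    def observed(self) -> np.ndarray:
        return self.sites != MISSING


@dataclass
class BroodCensus:
    """Snapshots of brood item positions, taken every few hours.

    ``items`` is a DataFrame with columns census_tick, stage, x_mm, y_mm.
    Brood moves slowly (workers occasionally carry items), so lookups use
    the latest census at or before the query tick.
    """

    colony_id: str
    items: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"census_tick", "stage", "x_mm", "y_mm"}
        if not required.issubset(self.items.columns):
            raise ValidationError(f"brood census needs columns {sorted(required)}")
        bad = set(self.items["stage"]) - set(BROOD_STAGES)
        if bad:
            raise ValidationError(f"unknown brood stages {sorted(bad)}")
        self.items = self.items.sort_values("census_tick", kind="stable").reset_index(
            drop=True
        )

    @property
    def census_ticks(self) -> np.ndarray:
        return np.unique(self.items["census_tick"].to_numpy())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

TRAJ_COLUMNS = ["colony", "ant", "tick", "x_mm", "y_mm", "caste"]
BROOD_COLUMNS = ["colony", "census_tick", "stage", "x_mm", "y_mm"]


def read_trajectories(
    path: str | Path, geometry: NestGeometry, tick_minutes: float = 10.0
) -> list[Trajectory]:
    """Read trajectories from long CSV (colony,ant,tick,x_mm,y_mm,caste).

    Empty x/y fields denote missing fixes.  Each (colony, ant) becomes one
    Trajectory whose tick axis is made contiguous from the minimum to the
    maximum tick present for that ant; ticks absent from the file are filled
    as missing.  Trajectories with fewer than two observed fixes are skipped
    with a warning.
    """
    df = pd.read_csv(path, dtype={"colony": str, "ant": str, "caste": str})
    missing_cols = set(TRAJ_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"trajectory CSV lacks columns {sorted(missing_cols)}")
    dup = df.duplicated(subset=["colony", "ant", "tick"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate fix for colony={row['colony']} ant={row['ant']} "
            f"tick={row['tick']}"
        )
    out: list[Trajectory] = []
    for (colony, ant), g in df.groupby(["colony", "ant"], sort=True):
        castes = g["caste"].dropna().unique()
        if len(castes) != 1:
            raise ValidationError(f"inconsistent caste for {colony}/{ant}")
        lo, hi = int(g["tick"].min()), int(g["tick"].max())
        ticks = np.arange(lo, hi + 1)
        x = np.full(len(ticks), np.nan)
        y = np.full(len(ticks), np.nan)
        idx = g["tick"].to_numpy(dtype=int) - lo
        x[idx] = g["x_mm"].to_numpy(dtype=float)
        y[idx] = g["y_mm"].to_numpy(dtype=float)
        if np.count_nonzero(~np.isnan(x)) < 2:
            warnings.warn(
                f"skipping {colony}/{ant}: fewer than 2 observed fixes",
                stacklevel=2,
            )
            continue
        traj = Trajectory(
            colony_id=str(colony),
            ant_id=str(ant),
            caste=str(castes[0]),
            ticks=ticks,
            x=x,
            y=y,
            tick_minutes=tick_minutes,
        )
        traj.validate_geometry(geometry)
        out.append(traj)
    return out


def write_trajectories(trajectories: Iterable[Trajectory], path: str | Path) -> None:
    """Write trajectories to the long CSV format (inverse of the reader)."""
    rows = []
    for t in trajectories:
        rows.append(
            pd.DataFrame(
                {
                    "colony": t.colony_id,
                    "ant": t.ant_id,
                    "tick": t.ticks,
                    "x_mm": t.x,
                    "y_mm": t.y,
                    "caste": t.caste,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.6g")


def read_brood(path: str | Path) -> dict[str, BroodCensus]:
    """Read brood censuses (colony,census_tick,stage,x_mm,y_mm) per colony."""
    df = pd.read_csv(path, dtype={"colony": str, "stage": str})
    missing_cols = set(BROOD_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"brood CSV lacks columns {sorted(missing_cols)}")
    return {
        str(colony): BroodCensus(
            colony_id=str(colony), items=g.drop(columns="colony").reset_index(drop=True)
        )
        for colony, g in df.groupby("colony", sort=True)
    }


def write_brood(censuses: Mapping[str, BroodCensus], path: str | Path) -> None:
    rows = []
    for colony, census in censuses.items():
        g = census.items.copy()
        g.insert(0, "colony", colony)
        rows.append(g)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Gridding
# ---------------------------------------------------------------------------


def make_grid(geometry: NestGeometry, cell_size: float = 3.0) -> GridSpec:
    """Build a regular grid covering the nest; boundary cells may be partial."""
    if cell_size <= 0:
        raise ValidationError("cell size must be positive")
    if cell_size > min(geometry.width, geometry.height):
        raise ValidationError("cell size exceeds the nest's smaller dimension")
    return GridSpec(
        cell_size=float(cell_size),
        n_cols=math.ceil(geometry.width / cell_size),
        n_rows=math.ceil(geometry.height / cell_size),
    )


def assign_sites(traj: Trajectory, grid: GridSpec) -> SiteSequence:
    """Map a trajectory's fixes onto grid sites (half-open cell convention)."""
    return SiteSequence(
        colony_id=traj.colony_id,
        ant_id=traj.ant_id,
        caste=traj.caste,
        ticks=traj.ticks,
        sites=grid.point_to_site(traj.x, traj.y),
        grid=grid,
        tick_minutes=traj.tick_minutes,
    )


def brood_counts_at(
    site: int, tick: int, census: BroodCensus, grid: GridSpec
) -> dict[str, int]:
    """Per-stage brood counts at a site, from the latest census at or before
    ``tick`` (the first census is used for earlier ticks)."""
    if census.items.empty:
        raise ValidationError("brood census is empty")
    ticks = census.census_ticks
    chosen = ticks[ticks <= tick]
    use_tick = int(chosen[-1]) if len(chosen) else int(ticks[0])
    snap = census.items[census.items["census_tick"] == use_tick]
    sites = grid.point_to_site(snap["x_mm"].to_numpy(), snap["y_mm"].to_numpy())
    counts = {stage: 0 for stage in BROOD_STAGES}
    for stage in BROOD_STAGES:
        counts[stage] = int(np.count_nonzero(sites[snap["stage"] == stage] == site))
    return counts


def brood_site_table(census: BroodCensus, grid: GridSpec) -> pd.DataFrame:
    """Precomputed (census_tick, site) -> per-stage counts table.

    Convenience for bulk lookups (one row per census tick and occupied site);
    semantics identical to :func:`brood_counts_at`.
    """
    snap = census.items.copy()
    snap["site"] = grid.point_to_site(
        snap["x_mm"].to_numpy(), snap["y_mm"].to_numpy()
    )
    table = (
        snap.groupby(["census_tick", "site", "stage"], sort=True)
        .size()
        .unstack("stage", fill_value=0)
    )
    for stage in BROOD_STAGES:
        if stage not in table.columns:
            table[stage] = 0
    return table[list(BROOD_STAGES)].reset_index()


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Geometry and analysis parameters for a full pipeline run."""

    nest_width_mm: float = 50.0
    nest_height_mm: float = 35.0
    entrance_x_mm: float = 25.0
    entrance_y_mm: float = 0.0
    cell_size_mm: float = 3.0
    tick_minutes: float = 10.0
    n_null_reps: int = 10_000
    alpha: float = 0.05
    min_coverage: int = 50
    seed: int = 0
    community_gamma: float = 1.0
    community_method: str = "spinglass"
    cox_ties: str = "efron"
    cox_variance: str = "robust"
    extra: dict = field(default_factory=dict)

    @property
    def geometry(self) -> NestGeometry:
        return NestGeometry(
            width=self.nest_width_mm,
            height=self.nest_height_mm,
            entrance_xy=(self.entrance_x_mm, self.entrance_y_mm),
        )

    @property
    def grid(self) -> GridSpec:
        return make_grid(self.geometry, self.cell_size_mm)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs, extra=extra)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: getattr(self, k) for k in self.__dataclass_fields__ if k != "extra"
        }
        data.update(self.extra)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
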