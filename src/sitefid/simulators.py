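"""Synthetic trajectory and colony generation with known bias structure.

Three walker archetypes are available:

* ``unbiased`` -- a correlated random walk inside the nest: gamma step
  lengths, von Mises turning angles, boundary handled by rejection.
* ``biased`` -- the same walk with each heading pulled towards a fixed
  attractor point: the new heading is the circular interpolation between
  the correlated-walk heading and the bearing to the attractor, with mixing
  weight w in [0, 1].  w = 0 reduces exactly to the unbiased walk (same
  draws, same path); w = 1 is a beeline towards the attractor.  A biased
  walker concentrates its visits without necessarily covering less area,
  which is what defeats area-based fidelity tests.
* ``satw`` -- a self-attracting walk on the analysis grid: each tick the
  walker moves among its current cell and the four lattice neighbours with
  probability proportional to exp(u * visits(cell)), and the occupied
  cell's count is then incremented.  u = 0 is an unreinforced neighbourhood
  walk; u > 0 makes familiar cells progressively stickier, producing the
  long-dwell/fast-return association probed by the survival model.

``generate_colony`` assembles whole colonies (queen plus workers drawn from
a mixture of archetypes, missing fixes, brood censuses) in the package's
CSV formats, with per-ant ground-truth labels for benchmarking detectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import (
    BROOD_STAGES,
    BroodCensus,
    GridSpec,
    NestGeometry,
    Trajectory,
    make_grid,
    write_brood,
    write_trajectories,
)

__all__ = [
    "WalkerSpec",
    "SyntheticColony",
    "simulate_unbiased_walk",
    "simulate_biased_walk",
    "simulate_satw",
    "generate_colony",
    "write_colony",
]

#: default observation length: 48 h of 10-min fixes (fix at t=0 included)
DEFAULT_T = 289
#: default missing-fix fraction, matching within-nest tracking conditions
DEFAULT_GAP_FRACTION = 0.106


@dataclass(frozen=True)
class WalkerSpec:
    """Parameters of one synthetic walker.

    Step lengths are gamma(shape, scale) in mm per 10-min tick; turning
    angles are von Mises(0, kappa).  ``w`` is the attractor mixing weight
    (biased model), ``u`` the reinforcement strength (satw model).
    """

    model: str = "unbiased"
    step_shape: float = 1.5
    step_scale: float = 1.5
    kappa: float = 1.0
    w: float = 0.0
    attractor: tuple[float, float] | None = None
    u: float = 0.0
    T: int = DEFAULT_T
    gap_fraction: float = DEFAULT_GAP_FRACTION

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("bias weight w must lie in [0, 1]")
        if self.u < 0:
            raise ValueError("reinforcement u must be >= 0")
        if not 0.0 <= self.gap_fraction < 1.0:
            raise ValueError("gap fraction must lie in [0, 1)")
        if self.model not in ("unbiased", "biased", "satw"):
            raise ValueError(f"unknown walker model {self.model!r}")


def _apply_gaps(x, y, gap_fraction, rng):
    """Mask a random subset of interior ticks as missing."""
    T = len(x)
    if gap_fraction <= 0 or T < 4:
        return x, y
    n_gaps = int(round(gap_fraction * T))
    # keep the first and last fixes observed so every walk remains analysable
    candidates = np.arange(1, T - 1)
    drop = rng.choice(candidates, size=min(n_gaps, len(candidates)), replace=False)
    x = x.copy()
    y = y.copy()
    x[drop] = np.nan
    y[drop] = np.nan
    return x, y


def _walk(
    spec: WalkerSpec,
    geometry: NestGeometry,
    rng: np.random.Generator,
    start: tuple[float, float] | None,
    max_rejects: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated random walk, optionally heading-biased towards an attractor.

    The biased heading is the circular interpolation
    atan2((1-w) sin h + w sin b, (1-w) cos h + w cos b) between the
    correlated-walk heading h and the bearing to the attractor b.
    """
    w = spec.w if spec.model == "biased" else 0.0
    if spec.model == "biased":
        if spec.attractor is None:
            raise ValueError("biased walker needs an attractor")
        ax, ay = spec.attractor
        if not bool(geometry.contains(ax, ay)):
            raise ValueError("attractor outside nest")
    if start is None:
        start = (
            rng.uniform(0, geometry.width),
            rng.uniform(0, geometry.height),
        )
    x = np.empty(spec.T)
    y = np.empty(spec.T)
    x[0], y[0] = start
    heading = rng.uniform(-np.pi, np.pi)
    for t in range(1, spec.T):
        for attempt in range(max_rejects + 1):
            step = rng.gamma(spec.step_shape, spec.step_scale)
            if attempt < max_rejects:
                turn = rng.vonmises(0.0, spec.kappa)
            else:
                turn = rng.uniform(-np.pi, np.pi)
            h = heading + turn
            if w > 0:
                bearing = math.atan2(ay - y[t - 1], ax - x[t - 1])
                h = math.atan2(
                    (1 - w) * math.sin(h) + w * math.sin(bearing),
                    (1 - w) * math.cos(h) + w * math.cos(bearing),
                )
            px = x[t - 1] + step * math.cos(h)
            py = y[t - 1] + step * math.sin(h)
            if bool(geometry.contains(px, py)):
                break
        else:
            raise RuntimeError(f"walker trapped at ({x[t-1]}, {y[t-1]})")
        x[t], y[t] = px, py
        heading = h
    return x, y


def _as_trajectory(spec, x, y, rng, colony_id, ant_id, caste, tick_minutes):
    x, y = _apply_gaps(x, y, spec.gap_fraction, rng)
    return Trajectory(
        colony_id=colony_id,
        ant_id=ant_id,
        caste=caste,
        ticks=np.arange(len(x)),
        x=x,
        y=y,
        tick_minutes=tick_minutes,
    )


def simulate_unbiased_walk(
    spec: WalkerSpec,
    geometry: NestGeometry,
    rng: np.random.Generator,
    start: tuple[float, float] | None = None,
    colony_id: str = "sim",
    ant_id: str = "walker",
    caste: str = "worker",
    tick_minutes: float = 10.0,
) -> Trajectory:
    """Spatially unbiased correlated random walk inside the nest."""
    x, y = _walk(replace(spec, model="unbiased"), geometry, rng, start)
    return _as_trajectory(spec, x, y, rng, colony_id, ant_id, caste, tick_minutes)


def simulate_biased_walk(
    spec: WalkerSpec,
    geometry: NestGeometry,
    rng: np.random.Generator,
    start: tuple[float, float] | None = None,
    colony_id: str = "sim",
    ant_id: str = "walker",
    caste: str = "worker",
    tick_minutes: float = 10.0,
) -> Trajectory:
    """Correlated walk with headings pulled towards the attractor point."""
    if spec.model != "biased":
        raise ValueError("spec.model must be 'biased'")
    x, y = _walk(spec, geometry, rng, start)
    return _as_trajectory(spec, x, y, rng, colony_id, ant_id, caste, tick_minutes)


def simulate_satw(
    spec: WalkerSpec,
    geometry: NestGeometry,
    grid: GridSpec,
    rng: np.random.Generator,
    start_cell: tuple[int, int] | None = None,
    colony_id: str = "sim",
    ant_id: str = "walker",
    caste: str = "worker",
    tick_minutes: float = 10.0,
) -> Trajectory:
    """Self-attracting walk on the grid lattice.

    Each tick the walker chooses among its current cell and the 4-neighbour
    cells (clipped at the walls) with probability proportional to
    exp(u * visits); the chosen cell's visit count is then incremented, so
    dwelling in place reinforces a cell just as re-entering it does.
    Output coordinates are the cell centre jittered uniformly within the
    cell.
    """
    if spec.model != "satw":
        raise ValueError("spec.model must be 'satw'")
    visits = np.zeros((grid.n_cols, grid.n_rows))
    if start_cell is None:
        col = int(rng.integers(0, grid.n_cols))
        row = int(rng.integers(0, grid.n_rows))
    else:
        col, row = start_cell
    cols = np.empty(spec.T, dtype=int)
    rows = np.empty(spec.T, dtype=int)
    for t in range(spec.T):
        cols[t], rows[t] = col, row
        visits[col, row] += 1
        neigh = [(col, row)]
        for dc, dr in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            c, r = col + dc, row + dr
            if 0 <= c < grid.n_cols and 0 <= r < grid.n_rows:
                neigh.append((c, r))
        logits = np.array([spec.u * visits[c, r] for c, r in neigh])
        logits -= logits.max()
        probs = np.exp(logits)
        probs /= probs.sum()
        col, row = neigh[int(rng.choice(len(neigh), p=probs))]
    # jitter inside the (possibly partial) cell
    cx = np.minimum((cols + rng.uniform(0, 1, spec.T)) * grid.cell_size,
                    geometry.width)
    cy = np.minimum((rows + rng.uniform(0, 1, spec.T)) * grid.cell_size,
                    geometry.height)
    return _as_trajectory(spec, cx, cy, rng, colony_id, ant_id, caste, tick_minutes)


# ---------------------------------------------------------------------------
# Whole-colony synthesis
# ---------------------------------------------------------------------------


@dataclass
class ColonyConfig:
    """Mixture and shape of a synthetic colony dataset.

    Defaults emulate a 48-h observation of one queen plus 15 workers in a
    50 x 35 mm nest at 10-min fixes with ~10% missing fixes.  The worker
    mixture mirrors the broad within-nest division of labour: brood-tending
    workers biased towards the brood pile, entrance-zone workers biased
    towards the entrance, and spatially indifferent walkers.
    """

    n_colonies: int = 1
    n_workers: int = 15
    T: int = DEFAULT_T
    gap_fraction: float = DEFAULT_GAP_FRACTION
    cell_size_mm: float = 3.0
    tick_minutes: float = 10.0
    # worker mixture weights (normalized): archetype -> share
    mixture: dict = field(
        default_factory=lambda: {
            "biased_brood": 5,
            "biased_entrance": 5,
            "unbiased": 5,
        }
    )
    queen_w: float = 0.5
    worker_w: float = 0.4
    satw_u: float = 2.0
    brood_per_stage: tuple = (20, 15, 15, 10)
    n_censuses: int = 7  # every 8 h over 48 h


@dataclass
class SyntheticColony:
    geometry: NestGeometry
    trajectories: list[Trajectory]
    census: BroodCensus
    truth: pd.DataFrame


def _brood_census(
    colony_id: str,
    config: ColonyConfig,
    geometry: NestGeometry,
    rng: np.random.Generator,
) -> tuple[BroodCensus, tuple[float, float]]:
    """Brood clustered near the nest centre-back, away from the entrance,
    drifting slightly between censuses."""
    ex, ey = geometry.entrance_xy
    cx = geometry.width / 2
    cy = geometry.height * (0.65 if ey == 0 else 0.35)
    centroid = (cx, cy)
    census_ticks = np.linspace(
        0, config.T - 1, config.n_censuses
    ).astype(int)
    rows = []
    for tick in census_ticks:
        for stage, count in zip(BROOD_STAGES, config.brood_per_stage):
            xs = np.clip(rng.normal(cx, 4.0, count), 0, geometry.width)
            ys = np.clip(rng.normal(cy, 4.0, count), 0, geometry.height)
            for x, y in zip(xs, ys):
                rows.append(
                    {
                        "census_tick": int(tick),
                        "stage": stage,
                        "x_mm": float(x),
                        "y_mm": float(y),
                    }
                )
    return (
        BroodCensus(colony_id=colony_id, items=pd.DataFrame(rows)),
        centroid,
    )


def generate_colony(
    config: ColonyConfig | None = None,
    seed: int = 0,
    geometry: NestGeometry | None = None,
) -> list[SyntheticColony]:
    """Generate synthetic colonies in the package's data model.

    Per colony: a brood census, a queen (biased walker attracted to the
    brood centroid) and ``n_workers`` workers drawn from the configured
    archetype mixture.  Ground-truth labels are collected in ``truth``.
    """
    config = config or ColonyConfig()
    geometry = geometry or NestGeometry(width=50.0, height=35.0)
    grid = make_grid(geometry, config.cell_size_mm)
    weights = {k: float(v) for k, v in config.mixture.items()}
    total = sum(weights.values())
    if total <= 0 or any(v < 0 for v in weights.values()):
        raise ValueError("invalid mixture weights")
    archetypes = sorted(weights)
    probs = np.array([weights[a] / total for a in archetypes])
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    colonies = []
    for c in range(config.n_colonies):
        colony_id = f"C{c+1:02d}"
        census, brood_centroid = _brood_census(colony_id, config, geometry, rng)
        ex, ey = geometry.entrance_xy
        entrance_attractor = (
            min(max(ex, 2.0), geometry.width - 2.0),
            min(max(ey, 2.0), geometry.height - 2.0),
        )
        trajectories = []
        truth_rows = []
        base = WalkerSpec(T=config.T, gap_fraction=config.gap_fraction)
        queen_spec = replace(
            base, model="biased", w=config.queen_w, attractor=brood_centroid
        )
        trajectories.append(
            simulate_biased_walk(
                queen_spec,
                geometry,
                rng,
                start=brood_centroid,
                colony_id=colony_id,
                ant_id="Q",
                caste="queen",
                tick_minutes=config.tick_minutes,
            )
        )
        truth_rows.append(
            {"colony": colony_id, "ant": "Q", "model": "biased_brood",
             "w": config.queen_w, "u": 0.0}
        )
        draws = rng.choice(len(archetypes), size=config.n_workers, p=probs)
        for i, a in enumerate(draws, start=1):
            archetype = archetypes[a]
            ant_id = f"W{i:02d}"
            if archetype == "unbiased":
                spec = base
                traj = simulate_unbiased_walk(
                    spec, geometry, rng, colony_id=colony_id, ant_id=ant_id,
                    tick_minutes=config.tick_minutes,
                )
                w, u = 0.0, 0.0
            elif archetype == "biased_brood":
                spec = replace(
                    base, model="biased", w=config.worker_w,
                    attractor=brood_centroid,
                )
                traj = simulate_biased_walk(
                    spec, geometry, rng, colony_id=colony_id, ant_id=ant_id,
                    tick_minutes=config.tick_minutes,
                )
                w, u = config.worker_w, 0.0
            elif archetype == "biased_entrance":
                spec = replace(
                    base, model="biased", w=config.worker_w,
                    attractor=entrance_attractor,
                )
                traj = simulate_biased_walk(
                    spec, geometry, rng, colony_id=colony_id, ant_id=ant_id,
                    tick_minutes=config.tick_minutes,
                )
                w, u = config.worker_w, 0.0
            elif archetype == "satw":
                spec = replace(base, model="satw", u=config.satw_u)
                traj = simulate_satw(
                    spec, geometry, grid, rng, colony_id=colony_id,
                    ant_id=ant_id, tick_minutes=config.tick_minutes,
                )
                w, u = 0.0, config.satw_u
            else:
                raise ValueError(f"unknown archetype {archetype!r}")
            trajectories.append(traj)
            truth_rows.append(
                {"colony": colony_id, "ant": ant_id, "model": archetype,
                 "w": w, "u": u}
            )
        colonies.append(
            SyntheticColony(
                geometry=geometry,
                trajectories=trajectories,
                census=census,
                truth=pd.DataFrame(truth_rows),
            )
        )
    return colonies


def write_colony(colonies: Sequence[SyntheticColony], out_dir: str | Path) -> None:
    """Write traj.csv, brood.csv and truth.csv for a set of colonies."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_traj = [t for c in colonies for t in c.trajectories]
    write_trajectories(all_traj, out / "traj.csv")
    write_brood({c.census.colony_id: c.census for c in colonies}, out / "brood.csv")
    pd.concat([c.truth for c in colonies], ignore_index=True).to_csv(
        out / "truth.csv", index=False
    )
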