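"""Spatially unbiased null trajectories.

The Random Walk (RW) null rebuilds a trajectory by resampling, with
replacement, the empirical step-length and turn-angle distributions of the
original walk, subject to three constraints: the synthetic walk starts at the
original's first observed coordinate, every proposed step that would leave
the nest is discarded and redrawn, and the original's missing-fix pattern is
re-imposed on the synthetic walk.  The result keeps the small-scale movement
statistics of the original but carries none of its spatial preferences, so
an ensemble of RW replicates is an absolute standard for "no site fidelity".

The Location Shuffling (LS) null -- drawing coordinates at random from the
pooled fixes of all colony members -- is retained as a comparison baseline;
it destroys the step/turn structure (over-long jumps, heading reversals) and
is not used for inference here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_data import NestGeometry, Trajectory

__all__ = [
    "StepSet",
    "SyntheticTrajectory",
    "RWEnsemble",
    "extract_steps",
    "simulate_rw_null",
    "simulate_ls_null",
    "build_ensemble",
]

TWO_PI = 2.0 * np.pi


def _wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    out = np.mod(-np.asarray(theta) + np.pi, TWO_PI)
    return np.pi - out


@dataclass(frozen=True)
class StepSet:
    """Empirical step lengths (mm) and signed turn angles (rad) of one walk.

    A step joins two consecutively observed ticks; displacements bridging a
    gap are excluded.  A turn is the signed heading change between two
    consecutive steps, defined only where both steps exist (a gap breaks the
    sequence).
    """

    step_lengths: np.ndarray
    turn_angles: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.step_lengths < 0):
            raise ValueError("negative step length")
        if len(self.turn_angles) and (
            np.any(self.turn_angles <= -np.pi - 1e-12)
            or np.any(self.turn_angles > np.pi + 1e-12)
        ):
            raise ValueError("turn angle outside (-pi, pi]")


@dataclass
class SyntheticTrajectory(Trajectory):
    """A null-model realization; same shape and gap pattern as its source."""

    model: str = "RW"
    source_ant: str = ""
    replicate: int = 0
    seed: int | None = None


def extract_steps(traj: Trajectory) -> StepSet:
    """Empirical step-length and turn-angle distributions of a trajectory."""
    obs = traj.observed
    x, y = traj.x, traj.y
    # consecutive observed pairs
    pair = obs[:-1] & obs[1:]
    if not np.any(pair):
        raise ValueError("no two consecutive observed fixes: no steps")
    dx = x[1:] - x[:-1]
    dy = y[1:] - y[:-1]
    steps = np.hypot(dx, dy)[pair]
    # turns need two consecutive steps
    headings = np.arctan2(dy, dx)
    triple = pair[:-1] & pair[1:]
    turns = _wrap_angle(headings[1:] - headings[:-1])[triple]
    return StepSet(step_lengths=steps, turn_angles=turns)


def extract_paired_steps(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Paired (step length, preceding turn) draws for joint resampling.

    Each turn at a junction is paired with the step leaving that junction;
    only junctions with both steps observed contribute.
    """
    obs = traj.observed
    dx = traj.x[1:] - traj.x[:-1]
    dy = traj.y[1:] - traj.y[:-1]
    pair = obs[:-1] & obs[1:]
    headings = np.arctan2(dy, dx)
    triple = pair[:-1] & pair[1:]
    if not np.any(triple):
        raise ValueError("no consecutive step pairs: cannot pair steps and turns")
    turns = _wrap_angle(headings[1:] - headings[:-1])[triple]
    out_steps = np.hypot(dx, dy)[1:][triple]
    return out_steps, turns


def _rw_walk_batch(
    traj: Trajectory,
    geometry: NestGeometry,
    rng: np.random.Generator,
    n_reps: int,
    joint: bool = False,
    max_rejects: int = 1000,
) -> np.ndarray:
    """Simulate ``n_reps`` RW null walks at once; returns (R, T, 2) coords.

    The walk is generated over the full tick range (continuous through gap
    ticks); the caller masks it with the source's missing pattern.  All
    replicates advance in lock-step, with per-replicate rejection redraws for
    proposals leaving the nest; after ``max_rejects`` rejected proposals at
    one step the turn angle is redrawn uniformly (which always succeeds in a
    convex nest for step lengths observed inside it).
    """
    steps = extract_steps(traj)
    eps = steps.step_lengths
    thetas = steps.turn_angles
    if joint:
        eps_paired, thetas_paired = extract_paired_steps(traj)
    n_steps = traj.n_ticks - 1
    x0, y0 = traj.first_observed_xy

    pos = np.empty((n_reps, 2))
    pos[:, 0] = x0
    pos[:, 1] = y0
    heading = rng.uniform(-np.pi, np.pi, size=n_reps)
    out = np.empty((n_reps, n_steps + 1, 2))
    out[:, 0, :] = pos

    have_turns = len(thetas) > 0
    for t in range(n_steps):
        pending = np.arange(n_reps)
        new_pos = np.empty_like(pos)
        new_heading = heading.copy()
        attempts = 0
        while len(pending):
            m = len(pending)
            if joint and have_turns and attempts < max_rejects:
                k = rng.integers(0, len(thetas_paired), size=m)
                e = eps_paired[k]
                th = thetas_paired[k]
            else:
                e = eps[rng.integers(0, len(eps), size=m)]
                if attempts >= max_rejects or not have_turns:
                    th = rng.uniform(-np.pi, np.pi, size=m)
                else:
                    th = thetas[rng.integers(0, len(thetas), size=m)]
            h = _wrap_angle(heading[pending] + th)
            px = pos[pending, 0] + e * np.cos(h)
            py = pos[pending, 1] + e * np.sin(h)
            ok = geometry.contains(px, py)
            sel = pending[ok]
            new_pos[sel, 0] = px[ok]
            new_pos[sel, 1] = py[ok]
            new_heading[sel] = h[ok]
            pending = pending[~ok]
            attempts += 1
            if attempts > max_rejects + 100:
                raise RuntimeError(
                    f"step irrecoverably trapped at positions {pos[pending][:3]}"
                )
        pos = new_pos
        heading = new_heading
        out[:, t + 1, :] = pos
    return out


def _masked_synthetic(
    traj: Trajectory, coords: np.ndarray, model: str, replicate: int, seed
) -> SyntheticTrajectory:
    x = coords[:, 0].copy()
    y = coords[:, 1].copy()
    gap = ~traj.observed
    x[gap] = np.nan
    y[gap] = np.nan
    return SyntheticTrajectory(
        colony_id=traj.colony_id,
        ant_id=traj.ant_id,
        caste=traj.caste,
        ticks=traj.ticks.copy(),
        x=x,
        y=y,
        tick_minutes=traj.tick_minutes,
        model=model,
        source_ant=traj.ant_id,
        replicate=replicate,
        seed=seed,
    )


def simulate_rw_null(
    traj: Trajectory,
    geometry: NestGeometry,
    rng: np.random.Generator,
    joint: bool = False,
    max_rejects: int = 1000,
) -> SyntheticTrajectory:
    """One RW null realization of ``traj`` (see module docstring)."""
    coords = _rw_walk_batch(
        traj, geometry, rng, n_reps=1, joint=joint, max_rejects=max_rejects
    )[0]
    return _masked_synthetic(traj, coords, "RW", 0, None)


def simulate_ls_null(
    colony: Sequence[Trajectory],
    ant_id: str,
    rng: np.random.Generator,
) -> SyntheticTrajectory:
    """Location-shuffling null: coordinates drawn from pooled colony fixes.

    The pool includes all colony members (the focal ant among them); every
    observed tick of the focal ant receives an independent uniform draw with
    replacement, and its gap pattern is preserved.
    """
    if len(colony) < 2:
        raise ValueError("LS null needs at least 2 trajectories in the colony")
    target = next((t for t in colony if t.ant_id == ant_id), None)
    if target is None:
        raise ValueError(f"ant {ant_id!r} not in colony")
    pool_x = np.concatenate([t.x[t.observed] for t in colony])
    pool_y = np.concatenate([t.y[t.observed] for t in colony])
    if len(pool_x) == 0:
        raise ValueError("empty coordinate pool")
    x = np.full(target.n_ticks, np.nan)
    y = np.full(target.n_ticks, np.nan)
    obs = target.observed
    idx = rng.integers(0, len(pool_x), size=int(obs.sum()))
    x[obs] = pool_x[idx]
    y[obs] = pool_y[idx]
    out = _masked_synthetic(target, np.column_stack([x, y]), "LS", 0, None)
    return out


@dataclass
class RWEnsemble:
    """R null-model replicates of one trajectory, stored as dense arrays.

    ``coords`` has shape (R, T, 2) with NaN at the source's missing ticks.
    """

    source: Trajectory
    coords: np.ndarray
    seed: int

    @property
    def n_reps(self) -> int:
        return self.coords.shape[0]

    def replicate(self, r: int) -> SyntheticTrajectory:
        return _masked_synthetic(self.source, self.coords[r], "RW", r, self.seed)

    def __iter__(self):
        return (self.replicate(r) for r in range(self.n_reps))


def build_ensemble(
    traj: Trajectory,
    geometry: NestGeometry,
    n_reps: int,
    seed: int,
    joint: bool = False,
    max_rejects: int = 1000,
) -> RWEnsemble:
    """Generate an ensemble of ``n_reps`` RW null replicates of ``traj``.

    Replicates are simulated in lock-step from a single generator seeded by
    ``seed``, so the ensemble is exactly reproducible given (seed, n_reps).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    coords = _rw_walk_batch(
        traj, geometry, rng, n_reps=n_reps, joint=joint, max_rejects=max_rejects
    )
    gap = ~traj.observed
    coords[:, gap, :] = np.nan
    return RWEnsemble(source=traj, coords=coords, seed=seed)
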