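"""Synthetic circular-arena spatial-memory task.

Simulates the behavioral side of a virtual-navigation experiment: an agent
walking freely inside a circular arena (distances in virtual meters, vm;
1 vm = 62.5 Unreal engine units), and a feedback phase in which five object
locations are repeatedly placed from memory (5 objects x 6 repetitions = 30
feedback trials per session). Task performance is the Euclidean distance
error between the true and the remembered location, averaged within a trial;
learning is the first-minus-last-trial difference of log errors. A
Monte-Carlo chance distribution replaces every response with an area-uniform
draw from the arena disk.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._circular import heading_to_unit, wrap_degrees

UNREAL_UNITS_PER_VM = 62.5


@dataclasses.dataclass(frozen=True)
class ArenaSpec:
    """Circular arena geometry.

    Parameters
    ----------
    radius_vm : float
        Arena radius in virtual meters (vm).
    unreal_units_per_vm : float
        Engine-unit conversion; 1 vm = 62.5 Unreal units.
    cue_positions : tuple of (x, y) pairs, optional
        Cosmetic distal/local cue locations; not used by any computation.
    """

    radius_vm: float
    unreal_units_per_vm: float = UNREAL_UNITS_PER_VM
    cue_positions: tuple = ()

    def __post_init__(self):
        if not self.radius_vm > 0:
            raise ValueError("radius_vm must be positive")
        if not self.unreal_units_per_vm > 0:
            raise ValueError("unreal_units_per_vm must be positive")

    def contains(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.hypot(pts[:, 0], pts[:, 1]) <= self.radius_vm


@dataclasses.dataclass(frozen=True)
class ObjectSet:
    """The five to-be-remembered object locations."""

    positions: np.ndarray  # (5, 2), vm
    names: tuple

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.shape != (5, 2):
            raise ValueError("an ObjectSet holds exactly 5 two-dimensional positions")
        if len(self.names) != 5:
            raise ValueError("an ObjectSet holds exactly 5 names")

    @classmethod
    def random(cls, arena: ArenaSpec, seed=None, margin: float = 0.1) -> "ObjectSet":
        """Five positions drawn area-uniform inside (1 - margin) x radius."""
        rng = np.random.default_rng(seed)
        pos = sample_arena_uniform(
            ArenaSpec(arena.radius_vm * (1.0 - margin)), 5, rng
        )
        return cls(pos, tuple(f"object_{i}" for i in range(5)))


@dataclasses.dataclass
class Trajectory:
    """Uniformly sampled navigation path.

    Attributes
    ----------
    t : array of float
        Seconds from session start, strictly increasing with uniform step dt.
    x, y : array of float
        Position in vm.
    heading : array of float
        Movement direction in degrees on [0, 360).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.heading = wrap_degrees(self.heading)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.heading) == n):
            raise ValueError("t, x, y, heading must have equal length")
        if n >= 2:
            steps = np.diff(self.t)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise ValueError("t must be strictly increasing and uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        """Session duration in seconds (n samples x dt)."""
        return len(self.t) * self.dt

    @property
    def speed(self) -> np.ndarray:
        """Per-sample speed (vm/s) from forward differences; last value repeated."""
        dx = np.diff(self.x)
        dy = np.diff(self.y)
        sp = np.hypot(dx, dy) / self.dt
        if len(sp) == 0:
            return np.zeros(len(self.t))
        return np.concatenate([sp, sp[-1:]])

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {"t": self.t, "x": self.x, "y": self.y, "heading": self.heading}
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "Trajectory":
        df = pd.read_csv(path, sep="\t")
        return cls(
            df["t"].to_numpy(),
            df["x"].to_numpy(),
            df["y"].to_numpy(),
            df["heading"].to_numpy(),
        )


@dataclasses.dataclass
class FeedbackTrial:
    """One repetition of the feedback phase: all five objects placed once."""

    trial_index: int  # 1-based repetition number
    object_order: np.ndarray  # permutation of 0..4
    true_locations: np.ndarray  # (5, 2) in object order shown
    responses: np.ndarray  # (5, 2); NaN rows = missing (timeout)
    response_times: np.ndarray  # seconds

    def __post_init__(self):
        order = np.asarray(self.object_order)
        if sorted(order.tolist()) != [0, 1, 2, 3, 4]:
            raise ValueError("object_order must be a permutation of the 5 objects")

    def to_dict(self) -> dict:
        return {
            "trial_index": int(self.trial_index),
            "object_order": np.asarray(self.object_order).tolist(),
            "true_locations": np.asarray(self.true_locations).tolist(),
            "responses": np.asarray(self.responses).tolist(),
            "response_times": np.asarray(self.response_times).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeedbackTrial":
        return cls(
            d["trial_index"],
            np.asarray(d["object_order"]),
            np.asarray(d["true_locations"], dtype=float),
            np.asarray(d["responses"], dtype=float),
            np.asarray(d["response_times"], dtype=float),
        )


@dataclasses.dataclass
class BehaviorSummary:
    """Per-trial distance errors of one session, plus the learning change."""

    trial_errors: np.ndarray  # mean distance error per trial, vm
    log_trial_errors: np.ndarray  # natural log
    learning_change: float  # log(first) - log(last); positive = improvement


def trials_to_json(trials: Sequence[FeedbackTrial], path) -> None:
    Path(path).write_text(json.dumps([t.to_dict() for t in trials], indent=1))


def trials_from_json(path) -> list:
    return [FeedbackTrial.from_dict(d) for d in json.loads(Path(path).read_text())]


def sample_arena_uniform(arena: ArenaSpec, n: int, rng) -> np.ndarray:
    """Area-uniform points on the arena disk.

    Radius is R*sqrt(u) for uniform u; sampling the radius uniformly instead
    would over-represent the center and bias chance distance errors.
    """
    rng = np.random.default_rng(rng)
    r = arena.radius_vm * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def simulate_trajectory(
    arena: ArenaSpec,
    duration: float,
    dt: float = 0.1,
    turn_volatility: float = 40.0,
    mean_speed: float = 2.0,
    seed=None,
    initial_heading: float | None = None,
    speed_jitter: float = 0.15,
    wall_margin: float = 0.05,
) -> Trajectory:
    """Simulate free navigation as a wrapped-Gaussian heading random walk.

    The heading performs a Brownian walk with scale ``turn_volatility``
    (degrees per sqrt-second); position integrates speed along the heading.
    Near the wall (within ``wall_margin`` x radius of it) the agent steers
    smoothly toward the arena center, so every sample stays inside the disk.

    Parameters
    ----------
    duration, dt : float
        Session length and sampling step, seconds. n = round(duration / dt).
    turn_volatility : float
        Heading diffusion, deg / sqrt(s). 0 gives straight-line walking.
    mean_speed : float
        Average walking speed, vm/s; per-step speeds get multiplicative
        log-normal jitter of scale ``speed_jitter`` (0 disables).
    seed : int or numpy Generator
        Identical seeds give identical trajectories.
    initial_heading : float, optional
        Starting heading in degrees; drawn uniformly when omitted.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if mean_speed < 0:
        raise ValueError("mean_speed must be nonnegative")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    R = arena.radius_vm
    safe_r = R * (1.0 - wall_margin)

    heading = np.empty(n)
    x = np.empty(n)
    y = np.empty(n)
    h = rng.uniform(0.0, 360.0) if initial_heading is None else float(initial_heading)
    # start near the center, as the task replaces the player there
    px, py = 0.05 * R * rng.standard_normal(2)
    px, py = np.clip([px, py], -safe_r / 2, safe_r / 2)
    sqrt_dt = np.sqrt(dt)
    for i in range(n):
        heading[i] = h % 360.0
        x[i] = px
        y[i] = py
        speed = mean_speed
        if speed_jitter > 0 and mean_speed > 0:
            speed = mean_speed * np.exp(
                speed_jitter * rng.standard_normal() - 0.5 * speed_jitter**2
            )
        ux, uy = heading_to_unit(h)
        nx, ny = px + speed * ux * dt, py + speed * uy * dt
        if np.hypot(nx, ny) > safe_r:
            # steer toward center: blend heading with the inward direction
            inward = np.rad2deg(np.arctan2(-py, -px))
            delta = (inward - h + 180.0) % 360.0 - 180.0
            h = h + np.clip(delta, -25.0, 25.0)
            ux, uy = heading_to_unit(h)
            nx, ny = px + speed * ux * dt, py + speed * uy * dt
            if np.hypot(nx, ny) > R:  # pathological corner: stay put this step
                nx, ny = px, py
        px, py = nx, ny
        h = h + turn_volatility * sqrt_dt * rng.standard_normal()
    t = np.arange(n) * dt
    return Trajectory(t, x, y, heading)


def simulate_feedback_phase(
    arena: ArenaSpec,
    objects: ObjectSet,
    memory_noise_sd: float,
    n_repetitions: int = 6,
    seed=None,
    noise_decay: float = 0.75,
    omission_prob: float = 0.0,
) -> list:
    """Simulate the feedback phase: 5 objects x ``n_repetitions`` placements.

    Responses are the true location plus isotropic Gaussian noise whose sd
    decays geometrically across repetitions, sd_k = memory_noise_sd *
    noise_decay**k (k = 0-based repetition), emulating learning; responses
    landing outside the arena are radially clipped to the wall. Each object
    is independently missing (timeout) with probability ``omission_prob``.
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    if memory_noise_sd < 0:
        raise ValueError("memory_noise_sd must be nonnegative")
    if not 0.0 <= omission_prob < 1.0:
        raise ValueError("omission_prob must be in [0, 1)")
    rng = np.random.default_rng(seed)
    trials = []
    for k in range(n_repetitions):
        order = rng.permutation(5)
        true = objects.positions[order]
        sd = memory_noise_sd * noise_decay**k
        resp = true + sd * rng.standard_normal((5, 2))
        radii = np.hypot(resp[:, 0], resp[:, 1])
        over = radii > arena.radius_vm
        if np.any(over):
            # nextafter keeps the clipped point inside despite rounding
            scale = np.nextafter(arena.radius_vm, 0.0) / radii[over]
            resp[over] *= scale[:, None]
        missing = rng.uniform(size=5) < omission_prob
        resp[missing] = np.nan
        rt = rng.uniform(3.0, 45.0, size=5)
        rt[missing] = 60.0
        trials.append(FeedbackTrial(k + 1, order, true, resp, rt))
    return trials


def distance_error(response, true_location) -> float:
    """Euclidean distance (vm) between a placement and the true location."""
    r = np.asarray(response, dtype=float)
    t = np.asarray(true_location, dtype=float)
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(t))):
        raise ValueError("distance_error requires finite points")
    return float(np.hypot(*(r - t)))


def trial_error(trial: FeedbackTrial) -> float:
    """Mean distance error over the non-missing responses of one trial.

    Returns NaN when every response is missing (all timeouts); callers must
    treat that trial as excluded, never as a zero error.
    """
    resp = np.asarray(trial.responses, dtype=float)
    true = np.asarray(trial.true_locations, dtype=float)
    present = np.all(np.isfinite(resp), axis=1)
    if not np.any(present):
        return float("nan")
    d = np.hypot(*(resp[present] - true[present]).T)
    return float(d.mean())


def summarize_behavior(trials: Sequence[FeedbackTrial]) -> BehaviorSummary:
    errors = np.array([trial_error(t) for t in trials])
    with np.errstate(divide="ignore"):
        log_errors = np.log(errors)
    return BehaviorSummary(errors, log_errors, learning_change_from_errors(errors))


def learning_change_from_errors(trial_errors) -> float:
    """log(first-trial error) - log(last-trial error); positive = improvement."""
    errors = np.asarray(trial_errors, dtype=float)
    first, last = errors[0], errors[-1]
    if not (np.isfinite(first) and np.isfinite(last)):
        return float("nan")
    if first <= 0 or last <= 0:
        raise ValueError("learning change needs strictly positive errors (log)")
    return float(np.log(first) - np.log(last))


def learning_change(behavior: BehaviorSummary) -> float:
    return learning_change_from_errors(behavior.trial_errors)


def chance_distribution(
    arena: ArenaSpec,
    participants: Sequence[Sequence[FeedbackTrial]],
    n_locations: int = 100_000,
    n_sims: int = 1000,
    seed=None,
) -> np.ndarray:
    """Monte-Carlo chance distribution of per-trial group-mean distance errors.

    A pool of ``n_locations`` area-uniform arena locations is sampled once;
    the task is then simulated ``n_sims`` times with every (non-missing)
    response of every participant replaced by a random draw from that pool.

    Returns
    -------
    ndarray of shape (n_trials, n_sims)
        Row j holds the ``n_sims`` group-mean errors for trial j+1.
    """
    if n_locations < 1 or n_sims < 1:
        raise ValueError("n_locations and n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    pool = sample_arena_uniform(arena, n_locations, rng)
    n_trials = max(len(tr) for tr in participants)
    out = np.full((n_trials, n_sims), np.nan)
    for j in range(n_trials):
        # collect (participant, object true location) records for this trial
        targets = []  # per-participant (m_i, 2) arrays of present objects
        for trial_set in participants:
            if j >= len(trial_set):
                continue
            tr = trial_set[j]
            present = np.all(np.isfinite(np.asarray(tr.responses, dtype=float)), axis=1)
            if np.any(present):
                targets.append(np.asarray(tr.true_locations, dtype=float)[present])
        if not targets:
            continue
        counts = [len(tg) for tg in targets]
        flat = np.concatenate(targets)  # (m_total, 2)
        idx = rng.integers(0, n_locations, size=(n_sims, len(flat)))
        d = np.hypot(
            pool[idx, 0] - flat[None, :, 0], pool[idx, 1] - flat[None, :, 1]
        )  # (n_sims, m_total)
        # mean within participant, then across participants
        bounds = np.cumsum([0] + counts)
        per_part = np.stack(
            [d[:, bounds[i] : bounds[i + 1]].mean(axis=1) for i in range(len(counts))]
        )
        out[j] = per_part.mean(axis=0)
    return out
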