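"""From trajectories to classifier examples.

Walking direction is discretized into six equal 60-degree bins tiling the
circle. A direction event is a maximal run of consecutive trajectory samples
that stay in one bin while moving at least at a minimum speed, lasting at
least one second. Each event is mapped to the fMRI volumes whose acquisition
windows it overlaps, shifted two volumes later to compensate hemodynamic
lag; the voxel patterns of those volumes are averaged into a single
classifier example labelled with the event's bin center.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from ._circular import wrap_degrees
from .bold import CleanedRun
from .task import Trajectory

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class DirectionBinning:
    """Equal partition of the circle into ``n_bins`` half-open bins.

    With the default 6 bins the edges are 0, 60, ..., 300 and the labels are
    the bin centers 30, 90, ..., 330 degrees; a heading h falls in the bin
    [edge, edge + width) containing h mod 360.
    """

    n_bins: int = 6

    def __post_init__(self):
        if self.n_bins < 2 or 360 % self.n_bins != 0:
            raise ValueError("n_bins must divide 360")

    @property
    def bin_width(self) -> float:
        return 360.0 / self.n_bins

    @property
    def edges(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_width

    @property
    def centers(self) -> np.ndarray:
        return self.edges + self.bin_width / 2.0


def bin_direction(heading, binning: DirectionBinning = DirectionBinning()):
    """Map heading(s) to bin-center label(s); bins are half-open [edge, edge+w)."""
    h = wrap_degrees(heading)
    idx = np.floor(h / binning.bin_width).astype(int)
    idx = np.minimum(idx, binning.n_bins - 1)  # guard h == 360.0 - eps rounding
    labels = binning.centers[idx]
    if np.ndim(heading) == 0:
        return float(labels)
    return labels


@dataclasses.dataclass
class DirectionEvent:
    """A maximal interval of consistent walking within one direction bin."""

    onset: float  # seconds
    duration: float  # seconds
    bin_label: float  # bin center, degrees
    volume_indices: np.ndarray | None = None  # filled by events_to_examples


@dataclasses.dataclass
class ExampleSet:
    """Examples x voxels pattern matrix with labels and onsets."""

    X: np.ndarray
    y: np.ndarray  # bin-center labels, degrees
    onsets: np.ndarray  # seconds
    classes: np.ndarray  # all bin centers of the binning, degrees
    session_id: str = ""
    n_dropped: int = 0  # events lost past the end of the run

    def __post_init__(self):
        if len(self.y) != len(self.X) or len(self.onsets) != len(self.X):
            raise ValueError("X, y and onsets must agree in length")

    @property
    def class_counts(self) -> dict:
        return {float(c): int(np.sum(self.y == c)) for c in self.classes}

    def save(self, path_prefix) -> None:
        import json
        from pathlib import Path

        prefix = Path(path_prefix)
        np.savez_compressed(
            prefix.with_suffix(".npz"),
            X=self.X, y=self.y, onsets=self.onsets, classes=self.classes,
        )
        prefix.with_suffix(".json").write_text(
            json.dumps({"session_id": self.session_id, "n_dropped": self.n_dropped})
        )

    @classmethod
    def load(cls, path_prefix) -> "ExampleSet":
        import json
        from pathlib import Path

        prefix = Path(path_prefix)
        arrays = np.load(prefix.with_suffix(".npz"))
        meta = json.loads(prefix.with_suffix(".json").read_text())
        return cls(
            arrays["X"], arrays["y"], arrays["onsets"], arrays["classes"],
            meta["session_id"], meta["n_dropped"],
        )


def extract_events(
    traj: Trajectory,
    binning: DirectionBinning = DirectionBinning(),
    min_duration: float = 1.0,
    min_speed: float = 0.05,
) -> list:
    """Segment a trajectory into direction events.

    A sample belongs to a run when its bin equals its neighbours' and its
    instantaneous speed is at least ``min_speed`` (standing still is not
    walking). Maximal runs shorter than ``min_duration`` are discarded.
    """
    if len(traj.t) == 0:
        return []
    dt = traj.dt if len(traj.t) > 1 else 0.0
    bins = bin_direction(traj.heading, binning)
    moving = traj.speed >= min_speed
    events = []
    i = 0
    n = len(traj.t)
    while i < n:
        if not moving[i]:
            i += 1
            continue
        j = i + 1
        while j < n and moving[j] and bins[j] == bins[i]:
            j += 1
        duration = (j - i) * dt
        if duration >= min_duration:
            events.append(DirectionEvent(float(traj.t[i]), duration, float(bins[i])))
        i = j
    return events


def events_to_tsv(events: Sequence[DirectionEvent], path) -> None:
    """Write events as a BIDS-style events table (onset, duration, trial_type)."""
    pd.DataFrame(
        {
            "onset": [e.onset for e in events],
            "duration": [e.duration for e in events],
            "trial_type": [e.bin_label for e in events],
        }
    ).to_csv(path, sep="\t", index=False)


def events_from_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [
        DirectionEvent(float(r.onset), float(r.duration), float(r.trial_type))
        for r in df.itertuples()
    ]


def events_to_examples(
    events: Sequence[DirectionEvent],
    run: CleanedRun,
    TR: float | None = None,
    lag_TRs: int = 2,
    binning: DirectionBinning = DirectionBinning(),
    session_id: str = "",
    anchor: str = "onset",
) -> ExampleSet:
    """Average each event's lag-shifted volumes into one classifier example.

    An event covering [onset, onset + duration) uses every volume whose
    acquisition window overlaps that interval, shifted ``lag_TRs`` volumes
    later; multi-volume events are averaged into a single pattern. Events
    whose shifted volumes run past the end of the run are dropped (counted
    in ``n_dropped``). ``anchor='midpoint'`` shifts relative to the event
    midpoint instead of its onset.
    """
    if TR is None:
        TR = run.TR
    if anchor not in ("onset", "midpoint"):
        raise ValueError("anchor must be 'onset' or 'midpoint'")
    eps = 1e-9
    rows, labels, onsets = [], [], []
    n_dropped = 0
    for ev in events:
        start, dur = ev.onset, ev.duration
        if anchor == "midpoint":
            start = start + dur / 2.0
            dur = 0.0
        first = int(np.floor(start / TR))
        last = int(np.floor(max(start + dur - eps, start) / TR))
        vols = np.arange(first, last + 1) + lag_TRs
        if vols[-1] >= run.n_volumes or vols[0] < 0:
            n_dropped += 1
            continue
        ev.volume_indices = vols
        rows.append(run.data[vols].mean(axis=0))
        labels.append(ev.bin_label)
        onsets.append(ev.onset)
    if n_dropped:
        logger.info("dropped %d event(s) past the end of the run", n_dropped)
    X = np.array(rows) if rows else np.empty((0, run.data.shape[1]))
    return ExampleSet(
        X,
        np.array(labels, dtype=float),
        np.array(onsets, dtype=float),
        binning.centers,
        session_id,
        n_dropped,
    )


def check_class_distribution(
    es: ExampleSet, min_per_class: int = 3, k_folds: int = 3
) -> tuple[bool, dict]:
    """Gate a session before decoding.

    Passes iff every direction bin has at least ``min_per_class`` examples
    AND every contiguous temporal fold contains at least one example of
    every bin. Sessions failing the check are excluded from decoding, the
    synthetic mirror of participant exclusion for unmet direction-coverage
    requirements.
    """
    if len(es.X) == 0:
        return False, {"reason": "empty example set"}
    counts = es.class_counts
    diagnostic: dict = {"class_counts": counts}
    if any(c < min_per_class for c in counts.values()):
        diagnostic["reason"] = f"a class has fewer than {min_per_class} examples"
        return False, diagnostic
    order = np.argsort(es.onsets, kind="stable")
    folds = np.array_split(order, k_folds)
    for f, members in enumerate(folds):
        present = set(np.unique(es.y[members]))
        if present != set(es.classes.tolist()):
            diagnostic["reason"] = f"fold {f} is missing at least one class"
            return False, diagnostic
    diagnostic["reason"] = "ok"
    return True, diagnostic
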