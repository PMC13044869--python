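"""Sound-preference assay metrics.

The assay maps auditory conditions onto eight arena fields (the mapping is
re-shuffled between sessions), and quantifies preference by

* length of stay: cumulative time spent in each condition's fields, and
* the Preference Index,
  PI = Pr(Goal = X | Start != X) - Pr(Goal != X | Start = X),
  a movement-based statistic that is 0 at chance and insensitive to
  immobility (freezing, sleep).

Because the field-condition mapping changes every session, Start/Goal are
conditioned at the *condition* level: a session counts as Start = X when the
condition mapped to the start field is X.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import DegenerateDataError, ParameterError


@dataclass(frozen=True)
class SessionRecord:
    """One session: start/goal fields plus the session's field->condition map."""

    start_field: int
    goal_field: int
    mapping: tuple[str, ...]
    session_duration: float = 20.0

    def __post_init__(self):
        n = len(self.mapping)
        for f in (self.start_field, self.goal_field):
            if not 0 <= f < n:
                raise ParameterError(f"field index {f} outside 0..{n - 1}")

    @property
    def start_condition(self) -> str:
        return self.mapping[self.start_field]

    @property
    def goal_condition(self) -> str:
        return self.mapping[self.goal_field]


@dataclass
class OccupancySeries:
    """Timestamped field indices over one session."""

    times: np.ndarray  # sample timestamps, seconds, increasing
    fields: np.ndarray  # field index per sample
    session_duration: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.fields = np.asarray(self.fields, dtype=int)
        if self.times.size != self.fields.size:
            raise ParameterError("times and fields must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("timestamps must be increasing")


def length_of_stay(
    occupancies: Sequence[OccupancySeries],
    mappings: Sequence[tuple[str, ...]],
) -> dict[str, float]:
    """Cumulative dwell time per condition across sessions.

    Each sample's dwell is the interval to the next sample; the first sample
    also covers the stretch from the session start, and the last extends to
    the session end, so totals sum to the summed session durations.  Dwell is
    attributed to the condition the sample's field maps to in that session.
    """
    if len(occupancies) != len(mappings):
        raise ParameterError("one mapping per session required")
    totals: dict[str, float] = {}
    for occ, mapping in zip(occupancies, mappings):
        n_fields = len(mapping)
        if np.any(occ.fields >= n_fields) or np.any(occ.fields < 0):
            raise ParameterError("occupancy sample maps to no condition")
        edges = np.concatenate([[0.0], occ.times[1:], [occ.session_duration]])
        dwell = np.diff(edges)
        if np.any(dwell < 0):
            raise ParameterError("occupancy extends past the session duration")
        for f, d in zip(occ.fields, dwell):
            cond = mapping[int(f)]
            totals[cond] = totals.get(cond, 0.0) + float(d)
    return totals


def preference_index(sessions: Sequence[SessionRecord], condition: str) -> float:
    """PI = Pr(Goal = X | Start != X) - Pr(Goal != X | Start = X).

    Conditioning is at the condition level (fields collapsed through each
    session's mapping).  Raises if either conditioning set is empty, naming
    the inestimable probability.
    """
    start_in = np.array([s.start_condition == condition for s in sessions])
    goal_in = np.array([s.goal_condition == condition for s in sessions])
    n_out = int((~start_in).sum())
    n_in = int(start_in.sum())
    if n_out == 0:
        raise DegenerateDataError(
            f"Pr(Goal = {condition} | Start != {condition}) inestimable: "
            "no session starts outside the condition"
        )
    if n_in == 0:
        raise DegenerateDataError(
            f"Pr(Goal != {condition} | Start = {condition}) inestimable: "
            "no session starts inside the condition"
        )
    p_attract = float(goal_in[~start_in].sum()) / n_out
    p_leave = float((~goal_in)[start_in].sum()) / n_in
    return p_attract - p_leave


def preference_index_by_animal(
    sessions_per_animal: Iterable[Sequence[SessionRecord]], condition: str
) -> np.ndarray:
    """Per-animal PI values (one per animal), the default estimation level."""
    return np.array(
        [preference_index(s, condition) for s in sessions_per_animal]
    )


def occupancy_heatmap(
    trajectory: np.ndarray,
    n_bins: int = 20,
    bounds: tuple[float, float, float, float] = (0.0, 1.0, 0.0, 1.0),
) -> np.ndarray:
    """Percent-time occupancy grid (default 20 x 20), summing to 100.

    ``trajectory`` is an (n, 2) array of x/y positions inside ``bounds``
    (x_lo, x_hi, y_lo, y_hi); samples are weighted equally.
    """
    xy = np.asarray(trajectory, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] == 0:
        raise ParameterError("trajectory must be a non-empty (n, 2) array")
    x_lo, x_hi, y_lo, y_hi = bounds
    if np.any(xy[:, 0] < x_lo) or np.any(xy[:, 0] > x_hi) or np.any(
        xy[:, 1] < y_lo
    ) or np.any(xy[:, 1] > y_hi):
        raise ParameterError("trajectory leaves the arena bounds")
    grid, _, _ = np.histogram2d(
        xy[:, 0],
        xy[:, 1],
        bins=n_bins,
        range=[[x_lo, x_hi], [y_lo, y_hi]],
    )
    return grid / xy.shape[0] * 100.0


def pseudo_log_display(grid: np.ndarray, sigma: float = 0.001) -> np.ndarray:
    """Pseudo-logarithmic display transform (base 10) for occupancy heatmaps.

    Rendering option only; not part of the occupancy metric.
    """
    return np.arcsinh(np.asarray(grid, dtype=float) / (2.0 * sigma)) / np.log(10.0)
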