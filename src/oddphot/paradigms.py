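"""Auditory stimulus paradigm generators.

Eight paradigms are supported, all returning a :class:`StimulusSequence` of
:class:`StimulusEvent` records on a common time base (seconds, 64-bit floats
on an integer sample grid to avoid drift):

* single presentation (``gen_simple``) — long white noise, offset-to-onset ISI
* multiple duration (``gen_simple`` per duration, or via the CLI)
* dynamic-change / constant-change (``gen_change``) — mid-stimulus intensity
  decrements
* single brief presentation (``gen_simple`` with 100-ms bursts)
* repetitive presentation (``gen_repetitive``) — short-SOA bursts with a
  pause inserted after every block of stimuli
* oddball (``gen_oddball``) — standard/deviant band-limited noise with an
  exact deviant ratio, a minimum standard run between deviants, and a role
  swap after a fixed number of deviants
* many-standards control (``gen_many_standards``) — equiprobable bands, the
  one physically matching the oddball deviant labelled ``deviant_equivalent``

``select_analysis_standards`` implements the n-back pairing rule used to pick
a temporally buffered standard for each deviant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InfeasibleDesignError, ParameterError

logger = logging.getLogger(__name__)

#: Valid event roles.
ROLES = ("standard", "deviant", "deviant_equivalent", "plain")

#: Default oddball band pair (Hz intervals), 500-Hz-wide noises.
STANDARD_BAND = (2250.0, 2750.0)
DEVIANT_BAND = (3250.0, 3750.0)

#: Many-standards band centers: 1000..5500 Hz in 500-Hz steps (10 bands),
#: each with the same 500-Hz width as the oddball bands.
MANY_STANDARDS_BANDS = tuple(
    (c - 250.0, c + 250.0) for c in np.arange(1000.0, 5500.0 + 1, 500.0)
)

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusEvent:
    """One auditory stimulus.

    ``band`` is a closed Hz interval ``(lo, hi)``; ``None`` is the reserved
    broadband (white noise) marker.  Two-stage events carry a second intensity
    and a change time strictly inside the stimulus.
    """

    onset: float
    duration: float
    intensity: float
    intensity2: float | None = None
    change_time: float | None = None  # s after onset
    band: tuple[float, float] | None = None
    role: str = "plain"
    trial_index: int = 0

    def __post_init__(self):
        if self.onset < 0:
            raise ParameterError(f"onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ParameterError(f"duration must be > 0, got {self.duration}")
        if self.role not in ROLES:
            raise ParameterError(f"unknown role {self.role!r}")
        if (self.intensity2 is None) != (self.change_time is None):
            raise ParameterError(
                "two-stage events need both intensity2 and change_time"
            )
        if self.change_time is not None and not (
            0.0 < self.change_time < self.duration
        ):
            raise ParameterError(
                "change_time must lie strictly inside (0, duration)"
            )

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    @property
    def change_magnitude(self) -> float | None:
        """Signed dB step at the mid-stimulus change (None if single-stage)."""
        if self.intensity2 is None:
            return None
        return self.intensity2 - self.intensity


@dataclass(frozen=True)
class StimulusSequence:
    """Ordered stimulus events plus paradigm metadata."""

    events: tuple[StimulusEvent, ...]
    paradigm: str
    soa: float | None = None
    seed: int | None = None

    def __post_init__(self):
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ParameterError("events must be strictly ordered by onset")

    def __len__(self) -> int:
        return len(self.events)

    def roles(self) -> list[str]:
        return [e.role for e in self.events]

    @property
    def duration(self) -> float:
        """Time from t=0 to the offset of the last event."""
        return self.events[-1].offset if self.events else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.events:
            lo, hi = (np.nan, np.nan) if e.band is None else e.band
            rows.append(
                dict(
                    onset_s=e.onset,
                    duration_s=e.duration,
                    intensity_db=e.intensity,
                    intensity2_db=np.nan if e.intensity2 is None else e.intensity2,
                    change_s=np.nan if e.change_time is None else e.change_time,
                    band_lo_hz=lo,
                    band_hi_hz=hi,
                    role=e.role,
                    trial_index=e.trial_index,
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "onset_s",
                "duration_s",
                "intensity_db",
                "intensity2_db",
                "change_s",
                "band_lo_hz",
                "band_hi_hz",
                "role",
                "trial_index",
            ],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, paradigm: str = "loaded", soa: float | None = None
    ) -> "StimulusSequence":
        events = []
        for _, r in df.iterrows():
            band = None
            if np.isfinite(r["band_lo_hz"]):
                band = (float(r["band_lo_hz"]), float(r["band_hi_hz"]))
            i2 = None if pd.isna(r["intensity2_db"]) else float(r["intensity2_db"])
            ct = None if pd.isna(r["change_s"]) else float(r["change_s"])
            events.append(
                StimulusEvent(
                    onset=float(r["onset_s"]),
                    duration=float(r["duration_s"]),
                    intensity=float(r["intensity_db"]),
                    intensity2=i2,
                    change_time=ct,
                    band=band,
                    role=str(r["role"]),
                    trial_index=int(r["trial_index"]),
                )
            )
        return cls(events=tuple(events), paradigm=paradigm, soa=soa)

    @classmethod
    def from_csv(cls, path, **kw) -> "StimulusSequence":
        return cls.from_frame(pd.read_csv(path), **kw)


@dataclass(frozen=True)
class OddballSpec:
    """Design parameters of the oddball paradigm."""

    standard_band: tuple[float, float] = STANDARD_BAND
    deviant_band: tuple[float, float] = DEVIANT_BAND
    deviant_prob: float = 0.10
    min_standard_run: int = 4
    n_deviants_per_block: int = 300
    swap_roles: bool = True
    stimulus_duration: float = 0.150
    soa: float = 0.800
    n_blocks: int = 2

    def __post_init__(self):
        if not 0.0 < self.deviant_prob < 1.0:
            raise ParameterError("deviant_prob must lie in (0, 1)")
        if self.min_standard_run < 1:
            raise ParameterError("min_standard_run must be >= 1")
        if self.n_deviants_per_block < 0:
            raise ParameterError("n_deviants_per_block must be >= 0")
        if self.soa <= 0 or self.stimulus_duration <= 0:
            raise ParameterError("soa and stimulus_duration must be > 0")


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _snap(t: float, rate: float) -> float:
    """Snap a time to the integer sample grid at `rate` (drift-free base)."""
    return round(t * rate) / rate


TIME_BASE_HZ = 10_000.0  # internal grid for stimulus onsets (0.1 ms)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def gen_simple(
    duration_s: float,
    intensity_db: float,
    n_events: int,
    isi_s: float,
    seed: int | None = None,
    band: tuple[float, float] | None = None,
    role: str = "plain",
) -> StimulusSequence:
    """Regularly repeated single presentations.

    ``isi_s`` is the offset-to-next-onset gap, so successive onsets are
    ``duration_s + isi_s`` apart.
    """
    if duration_s <= 0 or isi_s < 0:
        raise ParameterError("duration_s must be > 0 and isi_s >= 0")
    if n_events <= 0:
        raise ParameterError(f"n_events must be positive, got {n_events}")
    period = duration_s + isi_s
    events = tuple(
        StimulusEvent(
            onset=_snap(i * period, TIME_BASE_HZ),
            duration=duration_s,
            intensity=intensity_db,
            band=band,
            role=role,
            trial_index=i,
        )
        for i in range(n_events)
    )
    return StimulusSequence(events=events, paradigm="simple", soa=None, seed=seed)


def gen_change(
    mode: str,
    initial_levels_db: Sequence[float],
    second_levels_db: Sequence[float],
    change_time_s: float = 3.0,
    duration_s: float = 6.0,
    n_reps: int = 10,
    seed: int | None = None,
    isi_s: float = 3.0,
) -> StimulusSequence:
    """Mid-stimulus intensity-change paradigms.

    ``dynamic`` mode fixes the initial level (one value) and varies the
    second-stage level; ``constant`` mode pairs each initial level with its
    own second-stage level (a fixed decrement in the reference design).
    Conditions are interleaved in randomized order per seed.  Only decrements
    (or zero steps, flagged as no-change controls) are supported.
    """
    if mode not in ("dynamic", "constant"):
        raise ParameterError(f"mode must be 'dynamic' or 'constant', got {mode!r}")
    if not 0.0 < change_time_s < duration_s:
        raise ParameterError("change_time_s must lie strictly inside the stimulus")
    if n_reps <= 0:
        raise ParameterError("n_reps must be positive")

    initial = list(np.atleast_1d(np.asarray(initial_levels_db, dtype=float)))
    second = list(np.atleast_1d(np.asarray(second_levels_db, dtype=float)))
    if mode == "dynamic":
        if len(initial) != 1:
            raise ParameterError("dynamic mode takes a single initial level")
        conditions = [(initial[0], s) for s in second]
    else:
        if len(initial) != len(second):
            raise ParameterError(
                "constant mode pairs each initial level with one second level"
            )
        conditions = list(zip(initial, second))
        steps = {round(s - i, 9) for i, s in conditions}
        if len(steps) > 1:
            raise ParameterError(
                f"constant mode requires a single fixed step, got {sorted(steps)}"
            )
    for lo, hi in ((s, i) for i, s in conditions):
        if lo > hi:
            raise ParameterError(
                "intensity increments are unsupported (decrements only): "
                f"{hi} -> {lo} dB SPL"
            )

    rng = np.random.default_rng(seed)
    order = np.concatenate([rng.permutation(len(conditions)) for _ in range(n_reps)])
    period = duration_s + isi_s
    events = []
    for k, ci in enumerate(order):
        i_db, s_db = conditions[ci]
        if s_db == i_db:
            logger.info("event %d is a no-change control (%g -> %g dB)", k, i_db, s_db)
        events.append(
            StimulusEvent(
                onset=_snap(k * period, TIME_BASE_HZ),
                duration=duration_s,
                intensity=i_db,
                intensity2=s_db,
                change_time=change_time_s,
                band=None,
                role="plain",
                trial_index=k,
            )
        )
    return StimulusSequence(
        events=tuple(events), paradigm=f"{mode}_change", soa=None, seed=seed
    )


def gen_repetitive(
    soa_s: float,
    n_per_condition: int,
    pause_every: int = 10,
    pause_s: float = 2.0,
    seed: int | None = None,
    duration_s: float = 0.100,
    intensity_db: float = 80.0,
    pause_replaces_soa: bool = False,
) -> StimulusSequence:
    """Short-SOA repetitive bursts with a pause inserted after every block.

    By default the pause is *added* to the nominal SOA (the interval from the
    last stimulus of a block to the first of the next is ``soa_s + pause_s``);
    set ``pause_replaces_soa`` for the replacing convention.
    """
    if soa_s <= 0 or pause_s < 0 or duration_s <= 0:
        raise ParameterError("soa_s, duration_s must be > 0 and pause_s >= 0")
    if pause_every < 1:
        raise ParameterError("pause_every must be >= 1")
    if n_per_condition <= 0:
        raise ParameterError("n_per_condition must be positive")
    events = []
    for k in range(n_per_condition):
        n_pauses = k // pause_every
        extra = n_pauses * (pause_s - soa_s if pause_replaces_soa else pause_s)
        events.append(
            StimulusEvent(
                onset=_snap(k * soa_s + extra, TIME_BASE_HZ),
                duration=duration_s,
                intensity=intensity_db,
                band=None,
                role="plain",
                trial_index=k,
            )
        )
    return StimulusSequence(
        events=tuple(events), paradigm="repetitive", soa=soa_s, seed=seed
    )


def _oddball_roles(
    n_deviants: int, n_standards: int, min_run: int, rng: np.random.Generator
) -> list[str]:
    """Pseudo-random role order with >= min_run standards before each deviant.

    Base gaps of ``min_run`` standards precede every deviant (including the
    first, so the sequence opens context-valid); the remaining standards are
    scattered uniformly over the ``n_deviants + 1`` gaps.
    """
    extras = n_standards - min_run * n_deviants
    if extras < 0:
        raise InfeasibleDesignError(
            f"{n_deviants} deviants with min run {min_run} need "
            f">= {min_run * n_deviants} standards, got {n_standards}"
        )
    gap_extra = rng.multinomial(extras, np.full(n_deviants + 1, 1.0 / (n_deviants + 1)))
    roles: list[str] = []
    for i in range(n_deviants):
        roles.extend(["standard"] * (min_run + int(gap_extra[i])))
        roles.append("deviant")
    roles.extend(["standard"] * int(gap_extra[-1]))
    return roles


def gen_oddball(spec: OddballSpec = OddballSpec(), seed: int | None = None) -> StimulusSequence:
    """Oddball sequence with exact deviant ratio and role swap between blocks.

    Each block holds exactly ``n_deviants_per_block`` deviants in
    ``n_deviants_per_block / deviant_prob`` events (block-wise exact-ratio
    construction), with at least ``min_standard_run`` standards before every
    deviant.  After each block, the standard and deviant frequency bands are
    exchanged (if ``swap_roles``); role labels always follow context, not
    physical band.
    """
    n_dev = spec.n_deviants_per_block
    if n_dev == 0:
        # degenerate all-standard sequence: one "block" of standards
        n_total = round(1.0 / spec.deviant_prob)
        roles_blocks = [["standard"] * n_total]
    else:
        total_f = n_dev / spec.deviant_prob
        n_total = round(total_f)
        if abs(total_f - n_total) > 1e-9:
            raise InfeasibleDesignError(
                f"{n_dev} deviants at probability {spec.deviant_prob} does not "
                "give an integer block length"
            )
        if spec.deviant_prob > 1.0 / (spec.min_standard_run + 1):
            raise InfeasibleDesignError(
                f"deviant_prob {spec.deviant_prob} exceeds "
                f"1/(min_standard_run+1) = {1.0 / (spec.min_standard_run + 1):.4f}"
            )
        rng = np.random.default_rng(seed)
        roles_blocks = [
            _oddball_roles(n_dev, n_total - n_dev, spec.min_standard_run, rng)
            for _ in range(spec.n_blocks)
        ]

    events = []
    k = 0
    for b, roles in enumerate(roles_blocks):
        swapped = spec.swap_roles and (b % 2 == 1)
        band_of = {
            "standard": spec.deviant_band if swapped else spec.standard_band,
            "deviant": spec.standard_band if swapped else spec.deviant_band,
        }
        for role in roles:
            events.append(
                StimulusEvent(
                    onset=_snap(k * spec.soa, TIME_BASE_HZ),
                    duration=spec.stimulus_duration,
                    intensity=80.0,
                    band=band_of[role],
                    role=role,
                    trial_index=k,
                )
            )
            k += 1
    return StimulusSequence(
        events=tuple(events), paradigm="oddball", soa=spec.soa, seed=seed
    )


def gen_many_standards(
    bands: Sequence[tuple[float, float]] = MANY_STANDARDS_BANDS,
    prob_each: Sequence[float] | None = None,
    n_events: int = 3000,
    deviant_equivalent_band: tuple[float, float] = DEVIANT_BAND,
    seed: int | None = None,
    stimulus_duration: float = 0.150,
    soa: float = 0.800,
) -> StimulusSequence:
    """Many-standards control: equiprobable bands, balanced shuffle.

    Each band appears with its exact target count; events whose band equals
    ``deviant_equivalent_band`` are labelled ``deviant_equivalent``.
    """
    bands = [tuple(map(float, b)) for b in bands]
    if prob_each is None:
        prob_each = [1.0 / len(bands)] * len(bands)
    prob_each = list(map(float, prob_each))
    if abs(sum(prob_each) - 1.0) > 1e-9:
        raise ParameterError("band probabilities must sum to 1")
    de_band = tuple(map(float, deviant_equivalent_band))
    if de_band not in bands:
        raise ParameterError("deviant_equivalent_band must be one of the bands")
    if n_events <= 0:
        raise ParameterError("n_events must be positive")

    rng = np.random.default_rng(seed)
    counts = np.array([int(np.floor(p * n_events)) for p in prob_each])
    remainder = n_events - counts.sum()
    if remainder:
        logger.warning(
            "n_events=%d not divisible by band design; distributing %d "
            "remainder events uniformly at random",
            n_events,
            remainder,
        )
        lucky = rng.choice(len(bands), size=remainder, replace=False)
        counts[lucky] += 1
    labels = np.repeat(np.arange(len(bands)), counts)
    labels = labels[rng.permutation(n_events)]

    events = tuple(
        StimulusEvent(
            onset=_snap(k * soa, TIME_BASE_HZ),
            duration=stimulus_duration,
            intensity=80.0,
            band=bands[li],
            role="deviant_equivalent" if bands[li] == de_band else "plain",
            trial_index=k,
        )
        for k, li in enumerate(labels)
    )
    return StimulusSequence(
        events=events, paradigm="many_standards", soa=soa, seed=seed
    )


def select_analysis_standards(
    seq: StimulusSequence, offset_trials: int = 3
) -> list[tuple[int, int]]:
    """Pair each deviant with the standard ``offset_trials`` before it.

    Deviants whose n-back position is out of range or not a standard are
    skipped (logged).  Returns ``(deviant_index, standard_index)`` pairs in
    trial order.
    """
    if offset_trials < 1:
        raise ParameterError("offset_trials must be >= 1")
    roles = seq.roles()
    pairs = []
    for i, role in enumerate(roles):
        if role != "deviant":
            continue
        j = i - offset_trials
        if j < 0:
            logger.info("deviant at trial %d skipped: %d-back out of range", i, offset_trials)
            continue
        if roles[j] != "standard":
            logger.info(
                "deviant at trial %d skipped: %d-back trial holds role %r",
                i,
                offset_trials,
                roles[j],
            )
            continue
        pairs.append((i, j))
    return pairs
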