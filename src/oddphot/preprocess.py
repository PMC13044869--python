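"""Two-channel fluorescence preprocessing.

The processing chain is: least-squares regression of the isosbestic channel
onto the excitation channel, dF/F against the fitted reference,
z-normalization (whole-session or a local peri-event window), and
event-aligned epoch extraction with a 2-s pre-onset baseline.

dF/F = (F_excitation - F_fitted) / F_fitted, where F_fitted is the linear
image of the isosbestic channel.  Because the isosbestic channel tracks
bleaching, drift and common-mode motion artifacts but not ligand binding,
this referencing removes shared artifacts while preserving the
sensor-specific signal.  No detrending or filtering beyond the isosbestic
reference is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateDataError,
    NonPositiveReferenceError,
    ParameterError,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class PhotometryRecording:
    """Uniformly sampled excitation + isosbestic channels with events."""

    time: np.ndarray
    excitation: np.ndarray
    isosbestic: np.ndarray
    sampling_rate: float
    events: "object | None" = None  # StimulusSequence, onsets in recording time

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.excitation = np.asarray(self.excitation, dtype=float)
        self.isosbestic = np.asarray(self.isosbestic, dtype=float)
        if not (self.time.size == self.excitation.size == self.isosbestic.size):
            raise ParameterError("channels and time must have equal length")
        if self.time.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise ParameterError("time must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "excitation": self.excitation,
                "isosbestic": self.isosbestic,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("time_s", data=self.time)
            f.create_dataset("excitation", data=self.excitation)
            f.create_dataset("isosbestic", data=self.isosbestic)
            f.attrs["sampling_rate"] = self.sampling_rate
            if self.events is not None:
                g = f.create_group("events")
                df = self.events.to_frame()
                for col in df.columns:
                    data = df[col].to_numpy()
                    if data.dtype == object:
                        data = data.astype("S")
                    g.create_dataset(col, data=data)

    @classmethod
    def from_csv(cls, path, sampling_rate: float | None = None):
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        if sampling_rate is None:
            sampling_rate = 1.0 / np.median(np.diff(t))
        return cls(
            time=t,
            excitation=df["excitation"].to_numpy(),
            isosbestic=df["isosbestic"].to_numpy(),
            sampling_rate=float(sampling_rate),
        )

    @classmethod
    def from_hdf5(cls, path):
        import h5py

        from .paradigms import StimulusSequence

        with h5py.File(path, "r") as f:
            events = None
            if "events" in f:
                g = f["events"]
                cols = {}
                for name in g:
                    data = g[name][...]
                    if data.dtype.kind == "S":
                        data = data.astype(str)
                    cols[name] = data
                events = StimulusSequence.from_frame(pd.DataFrame(cols))
            return cls(
                time=f["time_s"][...],
                excitation=f["excitation"][...],
                isosbestic=f["isosbestic"][...],
                sampling_rate=float(f.attrs["sampling_rate"]),
                events=events,
            )


@dataclass
class DffTrace:
    time: np.ndarray
    dff: np.ndarray
    slope: float
    intercept: float
    sampling_rate: float


@dataclass
class ZTrace:
    """Normalized trace.  ``normalization`` is ``"global_session"`` or
    ``("local_window", t0, t1)``; mean/sd are the values used, so extracted
    z features can be mapped back to dF/F units."""

    time: np.ndarray
    z: np.ndarray
    normalization: object
    mean: float
    sd: float
    sampling_rate: float
    #: unbiased (n-1) sd convention, recorded for output metadata
    sd_ddof: int = 1


@dataclass
class EpochSet:
    """Event-aligned windows (trial x time); t=0 at the alignment sample."""

    t_rel: np.ndarray  # (n_time,)
    data: np.ndarray  # (n_trials, n_time)
    roles: list[str]
    trial_indices: list[int]
    onsets: np.ndarray  # alignment times in recording coordinates
    durations: np.ndarray
    baselines: np.ndarray  # 2-s (or configured) pre-onset means
    window: tuple[float, float]
    sampling_rate: float
    n_dropped: int = 0

    def __len__(self):
        return self.data.shape[0]

    def mean(self) -> np.ndarray:
        return self.data.mean(axis=0)

    def to_long_frame(self) -> pd.DataFrame:
        n_tr, n_t = self.data.shape
        return pd.DataFrame(
            {
                "trial": np.repeat(self.trial_indices, n_t),
                "role": np.repeat(self.roles, n_t),
                "t_rel_s": np.tile(self.t_rel, n_tr),
                "z": self.data.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def fit_isosbestic(
    excitation: np.ndarray, isosbestic: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Least-squares regression of the isosbestic onto the excitation channel.

    Returns ``(slope, intercept, fitted)`` with
    ``fitted = slope * isosbestic + intercept`` minimizing the squared error
    against the excitation channel.  A constant isosbestic channel falls back
    to an intercept-only fit (fitted = mean of excitation), logged.
    """
    x = np.asarray(isosbestic, dtype=float)
    y = np.asarray(excitation, dtype=float)
    if x.size != y.size:
        raise ParameterError("channel length mismatch")
    if x.size < 2:
        raise ParameterError("need at least 2 samples")
    if np.ptp(x) == 0.0:
        logger.warning(
            "isosbestic channel is constant; falling back to intercept-only fit"
        )
        inter = float(y.mean())
        return 0.0, inter, np.full_like(y, inter)
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept), slope * x + intercept


def compute_dff(
    excitation: np.ndarray,
    fitted: np.ndarray,
    time: np.ndarray | None = None,
    sampling_rate: float = np.nan,
    slope: float = np.nan,
    intercept: float = np.nan,
) -> DffTrace:
    """dF/F = (excitation - fitted) / fitted, pointwise.

    Raises :class:`NonPositiveReferenceError` naming the first offending
    sample if the fitted reference is not strictly positive.
    """
    exc = np.asarray(excitation, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    bad = np.nonzero(fit <= 0)[0]
    if bad.size:
        raise NonPositiveReferenceError(int(bad[0]))
    if time is None:
        time = np.arange(exc.size) * (
            1.0 / sampling_rate if np.isfinite(sampling_rate) else 1.0
        )
    return DffTrace(
        time=np.asarray(time, dtype=float),
        dff=(exc - fit) / fit,
        slope=slope,
        intercept=intercept,
        sampling_rate=sampling_rate,
    )


def preprocess_recording(rec: PhotometryRecording) -> DffTrace:
    """Convenience chain: isosbestic fit then dF/F for a recording."""
    slope, intercept, fitted = fit_isosbestic(rec.excitation, rec.isosbestic)
    return compute_dff(
        rec.excitation,
        fitted,
        time=rec.time,
        sampling_rate=rec.sampling_rate,
        slope=slope,
        intercept=intercept,
    )


def zscore(
    dff: DffTrace,
    mode: str = "global_session",
    window: tuple[float, float] | None = None,
) -> ZTrace:
    """z-normalize a dF/F trace.

    ``global_session`` normalizes by mean/sd over the whole recording;
    ``local_window`` normalizes the samples inside ``window`` (seconds, in
    recording time) by that window's own mean/sd and returns only that
    window.  The local mode normalizes the whole window once, so a deviant
    and its paired n-back standard share one reference frame.  Unbiased
    (n-1) sd.
    """
    x = dff.dff
    t = dff.time
    if mode == "global_session":
        seg, tseg = x, t
        norm = "global_session"
    elif mode == "local_window":
        if window is None:
            raise ParameterError("local_window mode requires a window")
        t0, t1 = window
        if t0 < t[0] - 0.5 / dff.sampling_rate or t1 > t[-1] + 0.5 / dff.sampling_rate:
            raise ParameterError("local window extends outside the recording")
        m = (t >= t0) & (t <= t1)
        seg, tseg = x[m], t[m]
        norm = ("local_window", float(t0), float(t1))
    else:
        raise ParameterError(f"unknown z-score mode {mode!r}")
    mu = float(seg.mean())
    sd = float(seg.std(ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateDataError("zero-variance segment; z-score undefined")
    return ZTrace(
        time=tseg,
        z=(seg - mu) / sd,
        normalization=norm,
        mean=mu,
        sd=sd,
        sampling_rate=dff.sampling_rate,
    )


def extract_epochs(
    ztrace: ZTrace,
    events,
    window: tuple[float, float] = (-2.0, 8.0),
    baseline_s: float = 2.0,
) -> EpochSet:
    """Cut event-aligned epochs from a normalized trace.

    Alignment uses the nearest sample to each onset (no sub-sample
    interpolation); epochs are half-open sample intervals of identical
    length.  ``baselines`` holds the mean of the ``baseline_s`` seconds
    preceding each onset (NaN where the pre-onset stretch is unavailable).
    Events whose window falls outside the trace are dropped with a log entry.
    """
    rate = ztrace.sampling_rate
    t = ztrace.time
    z = ztrace.z
    i_lo = int(round(window[0] * rate))
    i_hi = int(round(window[1] * rate))
    if i_hi <= i_lo:
        raise ParameterError("empty epoch window")
    n_t = i_hi - i_lo + 1
    t_rel = np.arange(i_lo, i_hi + 1) / rate

    evs = events.events if hasattr(events, "events") else list(events)
    rows, roles, trials, onsets, durs, bases = [], [], [], [], [], []
    n_dropped = 0
    nb = int(round(baseline_s * rate))
    for ev in evs:
        ia = int(round((ev.onset - t[0]) * rate))
        a, b = ia + i_lo, ia + i_hi
        if a < 0 or b >= t.size:
            n_dropped += 1
            logger.info(
                "event at t=%.3f s dropped: window [%g, %g] s outside recording",
                ev.onset,
                window[0],
                window[1],
            )
            continue
        rows.append(z[a : b + 1])
        roles.append(ev.role)
        trials.append(ev.trial_index)
        onsets.append(ev.onset)
        durs.append(ev.duration)
        b0, b1 = ia - nb, ia
        bases.append(float(z[b0:b1].mean()) if b0 >= 0 and nb > 0 else np.nan)
    data = np.array(rows) if rows else np.empty((0, n_t))
    return EpochSet(
        t_rel=t_rel,
        data=data,
        roles=roles,
        trial_indices=trials,
        onsets=np.array(onsets),
        durations=np.array(durs),
        baselines=np.array(bases),
        window=tuple(window),
        sampling_rate=rate,
        n_dropped=n_dropped,
    )


def local_epoch_pairs(
    dff: DffTrace,
    events,
    pairs: Sequence[tuple[int, int]],
    soa: float,
    half_window_s: float = 3.2,
    exclude_anchor_cycle: bool = True,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Locally normalized deviant/standard epoch pairs.

    For each ``(deviant_index, standard_index)`` pair, the +/-``half_window_s``
    stretch around the deviant onset is z-normalized once, and one SOA-long
    epoch is cut for the deviant and for its paired standard (which lies
    inside the same window for the default 3-back rule at 0.8-s SOA).

    With ``exclude_anchor_cycle`` (default), the window mean/sd are estimated
    with the anchoring event's own SOA cycle masked out, so the response
    being measured does not influence its own normalization; this keeps the
    normalization statistically identical between an oddball window (which
    contains an enhanced deviant) and a many-standards window (which does
    not).  Returns ``(t_rel, deviant_epoch, standard_epoch)`` tuples; pairs
    whose window leaves the recording are dropped with a log entry.
    """
    evs = events.events if hasattr(events, "events") else list(events)
    rate = dff.sampling_rate
    x = dff.dff
    t_start = dff.time[0]
    out = []
    n_soa = int(round(soa * rate))
    n_half = int(round(half_window_s * rate))
    t_rel = np.arange(n_soa) / rate
    for di, si in pairs:
        dev, std = evs[di], evs[si]
        ia = int(round((dev.onset - t_start) * rate))
        lo, hi = ia - n_half, ia + n_half
        if lo < 0 or hi >= x.size:
            logger.info("pair (%d, %d) dropped: local window outside recording", di, si)
            continue
        if std.onset < dev.onset - half_window_s:
            logger.info(
                "pair (%d, %d) dropped: paired standard outside local window", di, si
            )
            continue
        seg = x[lo : hi + 1]
        if exclude_anchor_cycle:
            keep = np.ones(seg.size, dtype=bool)
            keep[ia - lo : ia - lo + n_soa] = False
            ref = seg[keep]
        else:
            ref = seg
        mu = ref.mean()
        sd = ref.std(ddof=1)
        if sd == 0.0:
            raise DegenerateDataError("zero-variance local window")
        zseg = (seg - mu) / sd
        idev = ia - lo
        istd = int(round((std.onset - t_start) * rate)) - lo
        out.append((t_rel, zseg[idev : idev + n_soa], zseg[istd : istd + n_soa]))
    return out
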