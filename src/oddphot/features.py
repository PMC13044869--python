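"""Response-component feature extraction.

The stimulus-locked dopamine response is summarized by four components, each
measured in a fixed window relative to its anchoring event (half-open
windows, ties broken by the earliest sample):

* onset-positive peak: maximum z in (0, 300] ms after stimulus onset
* onset-negative trough: minimum z in (0, 800] ms after onset
* offset-positive peak: maximum z in (0, 800] ms after stimulus offset
* intra-stimulus dip: mean z during the final min(1 s, duration) of the
  stimulus

plus the drop-positive transient (maximum z in (0, 800] ms after a
mid-stimulus intensity decrement), the peak-to-trough span within an SOA
window (the response measure under continuous stimulation), the 2-s
pre-onset baseline, relative amplitudes measured from the immediately
preceding state, and two anatomical summaries (onset/offset ratio and the
projection of recording sites onto a ventromedial-to-dorsolateral axis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, MissingWindowError, ParameterError

# analysis windows, seconds
ONSET_POSITIVE_WINDOW = (0.0, 0.300)
ONSET_NEGATIVE_WINDOW = (0.0, 0.800)
OFFSET_POSITIVE_WINDOW = (0.0, 0.800)
DROP_POSITIVE_WINDOW = (0.0, 0.800)
DIP_FINAL_S = 1.0

#: axis for recording-site projection: ventromedial (ML 0.0, DV 8.0) to
#: dorsolateral (ML 8.0, DV 1.5), mm
PROJECTION_ORIGIN = (0.0, 8.0)
PROJECTION_TIP = (8.0, 1.5)

COMPONENT_NAMES = (
    "onset_positive",
    "onset_negative",
    "intra_dip",
    "offset_positive",
)


@dataclass
class ResponseFeatures:
    """Per-trial (or trial-averaged) component amplitudes and latencies.

    Amplitudes are raw z at the extremum (signed; troughs negative); use
    ``abs()`` downstream for absolute-amplitude comparisons.  Relative
    amplitudes are measured from the immediately preceding state:
    onset-negative relative to the onset-positive peak, offset-positive
    relative to the intra-stimulus dip.
    """

    onset_positive: tuple[float, float]  # (amplitude z, latency ms)
    onset_negative: tuple[float, float]
    offset_positive: tuple[float, float] | None
    intra_dip: float
    baseline_at_onset: float
    onset_negative_rel: float
    offset_positive_rel: float | None
    drop_positive: tuple[float, float] | None = None
    peak_to_trough: float | None = None

    def amplitude(self, name: str) -> float:
        if name == "intra_dip":
            return self.intra_dip
        v = getattr(self, name)
        if v is None:
            raise MissingWindowError(f"component {name} absent")
        return v[0]


def _window_extremum(
    t: np.ndarray, z: np.ndarray, lo: float, hi: float, kind: str, name: str
) -> tuple[float, float]:
    """Extremum in the half-open window (lo, hi]; earliest sample on ties."""
    m = (t > lo) & (t <= hi)
    if not m.any() or t[-1] < hi - 0.5 * np.median(np.diff(t)):
        raise MissingWindowError(
            f"epoch does not cover the {name} window ({lo*1e3:.0f}, {hi*1e3:.0f}] ms"
        )
    zw, tw = z[m], t[m]
    i = int(np.argmax(zw) if kind == "max" else np.argmin(zw))
    return float(zw[i]), float((tw[i] - lo) * 1e3)


def component_features(
    t_rel: np.ndarray,
    z: np.ndarray,
    duration: float,
    baseline_s: float = 2.0,
) -> ResponseFeatures:
    """Extract the four response components from one onset-aligned epoch.

    ``t_rel`` is seconds relative to stimulus onset; the epoch must cover
    (0, 0.8] s after the stimulus offset for the offset-positive component
    (skipped for stimuli too brief to carry one would raise; the window is
    required whenever ``duration`` allows it).  ``baseline_at_onset`` is the
    mean over [-baseline_s, 0) when covered, else NaN.
    """
    t = np.asarray(t_rel, dtype=float)
    z = np.asarray(z, dtype=float)
    if t.size != z.size:
        raise ParameterError("time and signal must have equal length")

    op = _window_extremum(t, z, *ONSET_POSITIVE_WINDOW, "max", "onset-positive")
    on = _window_extremum(t, z, *ONSET_NEGATIVE_WINDOW, "min", "onset-negative")

    dip_w = min(DIP_FINAL_S, duration)
    m = (t >= duration - dip_w) & (t <= duration)
    if not m.any():
        raise MissingWindowError("epoch does not cover the intra-stimulus dip window")
    dip = float(z[m].mean())

    off = _window_extremum(
        t,
        z,
        duration + OFFSET_POSITIVE_WINDOW[0],
        duration + OFFSET_POSITIVE_WINDOW[1],
        "max",
        "offset-positive",
    )
    off = (off[0], off[1])

    mb = (t >= -baseline_s) & (t < 0)
    baseline = float(z[mb].mean()) if mb.any() else np.nan

    return ResponseFeatures(
        onset_positive=op,
        onset_negative=on,
        offset_positive=off,
        intra_dip=dip,
        baseline_at_onset=baseline,
        onset_negative_rel=on[0] - op[0],
        offset_positive_rel=off[0] - dip,
    )


def drop_positive(
    t_rel: np.ndarray, z: np.ndarray, change_time: float
) -> tuple[float, float]:
    """Drop-positive transient: maximum z in (0, 800] ms after the change.

    ``change_time`` is seconds after stimulus onset (on the epoch's t=0
    scale).  Returns (amplitude z, latency ms after the change).
    """
    t = np.asarray(t_rel, dtype=float)
    z = np.asarray(z, dtype=float)
    return _window_extremum(
        t,
        z,
        change_time + DROP_POSITIVE_WINDOW[0],
        change_time + DROP_POSITIVE_WINDOW[1],
        "max",
        "drop-positive",
    )


def peak_to_trough(t_rel: np.ndarray, z: np.ndarray, soa: float) -> float:
    """max - min of the signal within the [onset, onset + SOA) window."""
    t = np.asarray(t_rel, dtype=float)
    z = np.asarray(z, dtype=float)
    m = (t >= 0) & (t < soa)
    if not m.any():
        raise MissingWindowError("epoch does not cover the SOA window")
    zw = z[m]
    return float(zw.max() - zw.min())


def onset_offset_ratio(onset_amp: float, offset_amp: float) -> float:
    """onset-positive / (onset-positive + offset-positive), in [0, 1].

    Negative inputs (noisy trials) are clamped at zero before the ratio.
    """
    a = max(float(onset_amp), 0.0)
    b = max(float(offset_amp), 0.0)
    if a + b == 0.0:
        raise DegenerateDataError("both amplitudes zero; ratio undefined")
    return a / (a + b)


def project_site(ml_mm: float, dv_mm: float) -> float:
    """Scalar projection (mm) of a recording site onto the shell-core axis.

    The axis runs from ventromedial (ML 0.0, DV 8.0) to dorsolateral
    (ML 8.0, DV 1.5); the origin projects to 0.
    """
    if not (np.isfinite(ml_mm) and np.isfinite(dv_mm)):
        raise ParameterError("coordinates must be finite")
    ox, oy = PROJECTION_ORIGIN
    tx, ty = PROJECTION_TIP
    ax, ay = tx - ox, ty - oy
    norm = float(np.hypot(ax, ay))
    return ((ml_mm - ox) * ax + (dv_mm - oy) * ay) / norm


def trial_stability(
    trials: list[ResponseFeatures], n_edge: int = 2
) -> pd.DataFrame:
    """First-vs-last trial means per component, for paired testing.

    Returns a one-row-per-component frame with the mean over the first
    ``n_edge`` and last ``n_edge`` trials.  Requires at least ``2 * n_edge``
    trials.
    """
    if len(trials) < 2 * n_edge:
        raise ParameterError(
            f"need at least {2 * n_edge} trials, got {len(trials)}"
        )
    rows = []
    for comp in COMPONENT_NAMES:
        vals = np.array([tr.amplitude(comp) for tr in trials])
        rows.append(
            dict(
                component=comp,
                first_mean=float(vals[:n_edge].mean()),
                last_mean=float(vals[-n_edge:].mean()),
            )
        )
    return pd.DataFrame(rows)


def features_table(
    subject: int, epochs, durations: np.ndarray | None = None
) -> pd.DataFrame:
    """Tidy per-trial feature table (subject, trial, role, component,
    amplitude, latency) from an :class:`oddphot.preprocess.EpochSet`."""
    rows = []
    for i in range(len(epochs)):
        dur = float(epochs.durations[i]) if durations is None else float(durations[i])
        f = component_features(epochs.t_rel, epochs.data[i], dur)
        for comp in COMPONENT_NAMES:
            if comp == "intra_dip":
                amp, lat = f.intra_dip, np.nan
            else:
                amp, lat = getattr(f, comp)
            rows.append(
                dict(
                    subject=subject,
                    trial=epochs.trial_indices[i],
                    role=epochs.roles[i],
                    component=comp,
                    amplitude=amp,
                    latency_ms=lat,
                )
            )
    return pd.DataFrame(rows)
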