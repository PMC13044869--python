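"""End-to-end experiment orchestration on synthetic cohorts.

``run_oddball_experiment`` reproduces the deviance-detection contrast:
for each synthetic subject it generates an oddball sequence (and optionally
a many-standards control), renders two-channel recordings, preprocesses with
local z-normalization around each deviant, pairs deviants with their 3-back
standards, quantifies responses as the peak-to-trough span within the SOA
window, and runs Wilcoxon + Bayesian paired tests on the
deviant/standard/deviant-equivalent contrasts.

``run_component_characterization`` reproduces the component analyses on a
synthetic cohort: grand-average responses to sustained white noise with
trial-stability contrasts, the stimulus-duration series for the
offset-positive component, intensity-change (drop-positive) series, and the
SOA series with baseline-at-onset and peak-to-trough measures.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ParameterError
from .features import component_features, drop_positive, peak_to_trough, trial_stability
from .paradigms import (
    OddballSpec,
    StimulusSequence,
    gen_change,
    gen_many_standards,
    gen_oddball,
    gen_repetitive,
    gen_simple,
    select_analysis_standards,
)
from .preprocess import extract_epochs, local_epoch_pairs, preprocess_recording, zscore
from .stats import TestResult, bayes_paired_t, friedman, spearman, wilcoxon_signed_rank
from .synth import (
    KernelParams,
    NoiseParams,
    SensorParams,
    render_recording,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentConfig:
    """Synthetic-cohort experiment configuration.

    The cohort default (n = 21 subjects) mirrors the oddball cohort size.
    ``deviants_per_block`` scales the recording length (the reference design
    uses 300 per block; smaller values keep simulations desk-sized while
    preserving the design's structure).  ``deviant_gain`` multiplies the
    value-encoding components for deviant-role events; ``ms_gain`` plays the
    same role for the deviant-equivalent in the many-standards control
    (1.0 encodes no rule-violation enhancement).  ``subject_sd`` is the sd of
    a log-normal inter-subject response-gain factor.
    """

    n_subjects: int = 21
    deviants_per_block: int = 30
    n_blocks: int = 2
    deviant_gain: float = 1.5
    ms_gain: float = 1.0
    include_ms: bool = True
    subject_sd: float = 0.2
    pair_offset: int = 3
    local_half_window_s: float = 3.2
    kernel: KernelParams = KernelParams()
    sensor: SensorParams = SensorParams()
    noise: NoiseParams = NoiseParams()
    # characterization problem sizes
    n_trials: int = 10
    durations: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 3.0, 5.0)
    soas: tuple[float, ...] = (0.8, 0.6, 0.4, 0.2)
    n_repetitive: int = 50
    seed: int = 0


@dataclass
class ContrastTable:
    """Per-subject peak-to-trough means and the group contrasts."""

    per_subject: pd.DataFrame  # columns: subject, dev, std [, ms]
    tests: dict[str, TestResult]
    config: ExperimentConfig


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-subject seeds below 2**31."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def _mean_p2t(pairs_zt, soa: float) -> tuple[float, float]:
    dev = [peak_to_trough(t, zd, soa) for t, zd, _ in pairs_zt]
    std = [peak_to_trough(t, zs, soa) for t, _, zs in pairs_zt]
    return float(np.mean(dev)), float(np.mean(std))


def _subject_oddball(
    config: ExperimentConfig, spec: OddballSpec, seed: int, subject_gain: float
) -> tuple[float, float]:
    """One subject's mean deviant / standard peak-to-trough (local z)."""
    seq = gen_oddball(spec, seed=seed)
    kernel = replace(config.kernel, deviant_gain=config.deviant_gain)
    rec, _ = render_recording(
        seq,
        kernel=kernel,
        sensor=config.sensor,
        noise=config.noise,
        seed=seed,
        subject_gain=subject_gain,
    )
    dff = preprocess_recording(rec)
    pairs = select_analysis_standards(rec.events, config.pair_offset)
    pairs_zt = local_epoch_pairs(
        dff, rec.events, pairs, spec.soa, config.local_half_window_s
    )
    if not pairs_zt:
        raise ParameterError("no valid deviant/standard pairs in recording")
    return _mean_p2t(pairs_zt, spec.soa)


def _subject_many_standards(
    config: ExperimentConfig, spec: OddballSpec, seed: int, subject_gain: float
) -> float:
    """Mean deviant-equivalent peak-to-trough in the many-standards control."""
    n_events = round(spec.n_deviants_per_block / spec.deviant_prob) * spec.n_blocks
    seq = gen_many_standards(
        n_events=n_events,
        deviant_equivalent_band=spec.deviant_band,
        seed=seed,
        stimulus_duration=spec.stimulus_duration,
        soa=spec.soa,
    )
    if config.ms_gain != 1.0:
        # model a hypothetical rarity effect: render deviant-equivalents with
        # the ms gain by giving them deviant role for rendering only
        render_seq = StimulusSequence(
            events=tuple(
                replace(e, role="deviant") if e.role == "deviant_equivalent" else e
                for e in seq.events
            ),
            paradigm=seq.paradigm,
            soa=seq.soa,
            seed=seq.seed,
        )
        kernel = replace(config.kernel, deviant_gain=config.ms_gain)
    else:
        render_seq = seq
        kernel = config.kernel
    rec, _ = render_recording(
        render_seq,
        kernel=kernel,
        sensor=config.sensor,
        noise=config.noise,
        seed=seed + 1,
        subject_gain=subject_gain,
    )
    dff = preprocess_recording(rec)
    de_idx = [i for i, e in enumerate(seq.events) if e.role == "deviant_equivalent"]
    # reuse the pairing plumbing with each event paired to itself
    pairs_zt = local_epoch_pairs(
        dff,
        rec.events,
        [(i, i) for i in de_idx],
        spec.soa,
        config.local_half_window_s,
    )
    if not pairs_zt:
        raise ParameterError("no valid deviant-equivalent epochs in recording")
    return float(np.mean([peak_to_trough(t, z, spec.soa) for t, z, _ in pairs_zt]))


def run_oddball_experiment(
    config: ExperimentConfig = ExperimentConfig(),
) -> ContrastTable:
    """Oddball vs many-standards contrast on one synthetic cohort.

    Returns per-subject mean peak-to-trough for deviant (Dev), 3-back
    standard (Std) and, if enabled, the many-standards deviant-equivalent
    (MS), plus Wilcoxon and JZS Bayes-factor results for the pairwise
    contrasts.
    """
    spec = OddballSpec(
        n_deviants_per_block=config.deviants_per_block, n_blocks=config.n_blocks
    )
    seeds = _child_seeds(config.seed, 2 * config.n_subjects)
    rng = np.random.default_rng(int(seeds[-1]))
    gains = (
        np.exp(rng.normal(0.0, config.subject_sd, size=config.n_subjects))
        if config.subject_sd > 0
        else np.ones(config.n_subjects)
    )

    rows = []
    for s in range(config.n_subjects):
        try:
            dev, std = _subject_oddball(config, spec, int(seeds[s]), gains[s])
            row = dict(subject=s, dev=dev, std=std)
            if config.include_ms:
                row["ms"] = _subject_many_standards(
                    config, spec, int(seeds[config.n_subjects + s]), gains[s]
                )
            rows.append(row)
        except ParameterError as err:
            raise ParameterError(f"subject {s}: {err}") from err
    table = pd.DataFrame(rows)

    tests: dict[str, TestResult] = {}
    w = wilcoxon_signed_rank(table["dev"], table["std"])
    b = bayes_paired_t(table["dev"], table["std"])
    w.bf10 = b.bf10
    tests["dev_vs_std"] = w
    if config.include_ms:
        for name, a_col, b_col in (
            ("dev_vs_ms", "dev", "ms"),
            ("std_vs_ms", "std", "ms"),
        ):
            wt = wilcoxon_signed_rank(table[a_col], table[b_col])
            wt.bf10 = bayes_paired_t(table[a_col], table[b_col]).bf10
            tests[name] = wt
    return ContrastTable(per_subject=table, tests=tests, config=config)


# ---------------------------------------------------------------------------
# Component characterization
# ---------------------------------------------------------------------------


def _render_and_epochs(config, seq, seed, window=(-2.0, 8.0)):
    rec, truth = render_recording(
        seq, kernel=config.kernel, sensor=config.sensor, noise=config.noise, seed=seed
    )
    dff = preprocess_recording(rec)
    zt = zscore(dff, mode="global_session")
    return extract_epochs(zt, rec.events, window=window), truth


def run_component_characterization(
    config: ExperimentConfig = ExperimentConfig(),
) -> dict:
    """Component analyses on a synthetic cohort.

    Returns a dict of tidy tables: ``grand_average`` (time, mean z),
    ``components`` (per subject, per component amplitude/latency from
    trial-averaged epochs), ``stability`` (first-two vs last-two trial means
    with paired tests), ``durations`` (offset-positive vs stimulus duration,
    with a Friedman test), ``intensity_change`` (drop-positive vs decrement
    magnitude, with Friedman on the change conditions and the
    injected-vs-extracted Spearman), and ``soa`` (baseline at onset and
    peak-to-trough per SOA, with Friedman on peak-to-trough).
    """
    seeds = _child_seeds(config.seed, 4 * config.n_subjects + 4)
    results: dict = {"tests": {}}

    # --- sustained white noise: components and stability -------------------
    comp_rows, stab_frames, grand = [], [], []
    for s in range(config.n_subjects):
        seq = gen_simple(6.0, 80.0, config.n_trials, 3.0)
        epochs, _ = _render_and_epochs(config, seq, int(seeds[s]))
        grand.append(epochs.mean())
        avg = epochs.data.mean(axis=0)
        f = component_features(epochs.t_rel, avg, 6.0)
        for comp in ("onset_positive", "onset_negative", "offset_positive"):
            amp, lat = getattr(f, comp)
            comp_rows.append(
                dict(subject=s, component=comp, amplitude=amp, latency_ms=lat)
            )
        comp_rows.append(
            dict(subject=s, component="intra_dip", amplitude=f.intra_dip, latency_ms=np.nan)
        )
        trials = [
            component_features(epochs.t_rel, epochs.data[i], 6.0)
            for i in range(len(epochs))
        ]
        sf = trial_stability(trials)
        sf.insert(0, "subject", s)
        stab_frames.append(sf)
    t_rel = np.arange(
        int(round(-2.0 * config.noise.sampling_rate)),
        int(round(8.0 * config.noise.sampling_rate)) + 1,
    ) / config.noise.sampling_rate
    results["grand_average"] = pd.DataFrame(
        {"t_rel_s": t_rel, "z": np.mean(grand, axis=0)}
    )
    results["components"] = pd.DataFrame(comp_rows)
    stability = pd.concat(stab_frames, ignore_index=True)
    results["stability"] = stability
    for comp, grp in stability.groupby("component"):
        results["tests"][f"stability_{comp}"] = wilcoxon_signed_rank(
            grp["first_mean"], grp["last_mean"]
        )

    # --- stimulus-duration series ------------------------------------------
    dur_rows = []
    for s in range(config.n_subjects):
        for d_i, dur in enumerate(config.durations):
            seq = gen_simple(dur, 80.0, config.n_trials, 3.0)
            epochs, _ = _render_and_epochs(
                config, seq, int(seeds[config.n_subjects + s]) + d_i, window=(-2.0, dur + 1.0)
            )
            avg = epochs.data.mean(axis=0)
            f = component_features(epochs.t_rel, avg, dur)
            dur_rows.append(
                dict(subject=s, duration_s=dur, offset_positive=f.offset_positive[0])
            )
    durations = pd.DataFrame(dur_rows)
    results["durations"] = durations
    wide = durations.pivot(index="subject", columns="duration_s", values="offset_positive")
    results["tests"]["duration_offset_positive"] = friedman(wide.to_numpy())

    # --- intensity-change series (dynamic-change paradigm) ------------------
    seconds = (80.0, 60.0, 40.0, 20.0)
    chg_rows = []
    for s in range(config.n_subjects):
        seq = gen_change(
            "dynamic", [80.0], seconds, 3.0, 6.0, config.n_trials,
            seed=int(seeds[2 * config.n_subjects + s]),
        )
        epochs, _ = _render_and_epochs(
            config, seq, int(seeds[2 * config.n_subjects + s])
        )
        by_cond: dict[float, list[float]] = {sec: [] for sec in seconds}
        for row_i in range(len(epochs)):
            ev = seq.events[epochs.trial_indices[row_i]]
            amp, _ = drop_positive(epochs.t_rel, epochs.data[row_i], ev.change_time)
            by_cond[ev.intensity2].append(amp)
        for sec in seconds:
            chg_rows.append(
                dict(
                    subject=s,
                    second_db=sec,
                    decrement_db=80.0 - sec,
                    drop_positive=float(np.mean(by_cond[sec])),
                )
            )
    change = pd.DataFrame(chg_rows)
    results["intensity_change"] = change
    active = change[change["decrement_db"] > 0]
    wide = active.pivot(index="subject", columns="decrement_db", values="drop_positive")
    results["tests"]["dynamic_change_drop"] = friedman(wide.to_numpy())
    means = active.groupby("decrement_db")["drop_positive"].mean()
    r, _ = spearman(means.index.to_numpy(), means.to_numpy())
    results["drop_monotonicity_spearman_r"] = r

    # --- SOA series ----------------------------------------------------------
    soa_rows = []
    for s in range(config.n_subjects):
        for k_i, soa in enumerate(config.soas):
            seq = gen_repetitive(soa, config.n_repetitive, 10, 2.0)
            epochs, _ = _render_and_epochs(
                config,
                seq,
                int(seeds[3 * config.n_subjects + s]) + k_i,
                window=(-0.0, soa),
            )
            onset_idx = int(np.argmin(np.abs(epochs.t_rel)))
            base = epochs.data[:, onset_idx].mean()
            p2t = float(
                np.mean(
                    [peak_to_trough(epochs.t_rel, epochs.data[i], soa)
                     for i in range(len(epochs))]
                )
            )
            soa_rows.append(
                dict(subject=s, soa_s=soa, baseline_at_onset=float(base), peak_to_trough=p2t)
            )
    soa_df = pd.DataFrame(soa_rows)
    results["soa"] = soa_df
    wide = soa_df.pivot(index="subject", columns="soa_s", values="peak_to_trough")
    results["tests"]["soa_peak_to_trough"] = friedman(wide.to_numpy())
    return results


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

#: structural requirements of a report summary (shipped schema)
REPORT_SUMMARY_SCHEMA = {
    "required": {
        "package_version": str,
        "seed": (int, type(None)),
        "config_hash": str,
        "tables": dict,
        "tests": dict,
    }
}


def validate_report_summary(summary: dict) -> None:
    """Raise ParameterError if a summary violates the shipped schema."""
    for key, typ in REPORT_SUMMARY_SCHEMA["required"].items():
        if key not in summary:
            raise ParameterError(f"report summary missing key {key!r}")
        if not isinstance(summary[key], typ):
            raise ParameterError(f"report summary key {key!r} has wrong type")
    for name, meta in summary["tables"].items():
        if not isinstance(meta, dict) or "n_rows" not in meta:
            raise ParameterError(f"table entry {name!r} malformed")


def write_report(
    tables: dict[str, pd.DataFrame],
    path,
    tests: dict[str, TestResult] | None = None,
    config: ExperimentConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Write delimited-text tables plus a JSON summary to a directory.

    Every run logs the config hash, seed, and package version into the
    summary.  Returns the summary dict (also written as ``summary.json``).
    """
    from pathlib import Path

    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)

    cfg_repr = repr(config) if config is not None else ""
    summary = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(cfg_repr.encode()).hexdigest()[:16],
        "tables": {name: {"n_rows": int(len(df))} for name, df in tables.items()},
        "tests": {
            name: {
                "statistic": t.statistic,
                "p_value": t.p_value,
                "n": t.n,
                "bf10": t.bf10,
                "method": t.method,
            }
            for name, t in (tests or {}).items()
        },
    }
    validate_report_summary(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    logger.info("report written to %s (config %s)", out, summary["config_hash"])
    return summary
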