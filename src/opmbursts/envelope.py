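"""Beta-envelope contrast-to-noise analysis.

The beta-band virtual electrode for the whole experiment is Hilbert
transformed; the modulus of the analytic signal is the instantaneous
oscillatory amplitude ("Hilbert envelope").  Baseline mean and SD are taken
from the last 8 s of the interspersed rest trials, and the envelope is
expressed as CNR(t) = 100 * (env(t) - mu_b) / sigma_b, i.e. the change from
baseline as a percentage of the baseline standard deviation.  CNR time
courses are averaged over 16 s trials split by attention cue, and epoched
around probe stimuli (-180 ms to +650 ms) in four cue x stimulated-hand
categories with target/bad-response probes excluded and trial counts
equalised by random subsampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.fft import next_fast_len

from .paradigm import TRIAL_DURATION_S

PROBE_EPOCH_WINDOW_S = (-0.180, 0.650)
BASELINE_LAST_S = 8.0


@dataclass
class EnvelopeTimecourse:
    samples: np.ndarray
    fs: float
    region: str = ""
    band: str = ""


@dataclass
class BaselineStats:
    mu_b: float
    sigma_b: float
    n_baseline_samples: int


@dataclass
class CNRCondition:
    condition: str
    times: np.ndarray            # trial- or probe-relative s
    mean: np.ndarray             # mean CNR timecourse (%)
    per_trial: np.ndarray        # (n_trials, n_samples)


def hilbert_envelope(x: np.ndarray, fs: float, region: str = "",
                     band: str = "") -> EnvelopeTimecourse:
    """Modulus of the analytic signal of a continuous band-limited series.

    Must be applied to the whole unsegmented recording (epoching first would
    corrupt the envelope at every segment edge).
    """
    x = np.asarray(x, float)
    if x.ndim != 1:
        raise ValueError("expected a single continuous time course; "
                         "segmented input is not allowed")
    if len(x) < fs:
        raise ValueError("time course must be at least 1 s long")
    n = len(x)
    analytic = signal.hilbert(x, N=next_fast_len(n))[:n]
    return EnvelopeTimecourse(samples=np.abs(analytic), fs=fs, region=region, band=band)


def baseline_stats(env: EnvelopeTimecourse, trial_labels: pd.DataFrame,
                   kept: np.ndarray | None = None,
                   last_s: float = BASELINE_LAST_S) -> BaselineStats:
    """Envelope mean/SD over the last ``last_s`` seconds of kept rest trials."""
    if kept is None:
        kept = np.ones(len(trial_labels), dtype=bool)
    rest = trial_labels[np.asarray(kept) & trial_labels.is_rest.to_numpy()]
    if not len(rest):
        raise ValueError("no kept rest trials to estimate the baseline from")
    chunks = []
    for start in rest.start_s:
        i0 = int(round((start + TRIAL_DURATION_S - last_s) * env.fs))
        i1 = int(round((start + TRIAL_DURATION_S) * env.fs))
        chunks.append(env.samples[i0:i1])
    samples = np.concatenate(chunks)
    return BaselineStats(mu_b=float(samples.mean()), sigma_b=float(samples.std()),
                         n_baseline_samples=len(samples))


def cnr(env: EnvelopeTimecourse, baseline: BaselineStats) -> np.ndarray:
    """CNR(t) = 100 * (env(t) - mu_b) / sigma_b, in percent."""
    if baseline.sigma_b <= 0:
        raise ValueError("degenerate baseline: sigma_b must be positive")
    return 100.0 * (env.samples - baseline.mu_b) / baseline.sigma_b


def average_trials(series: np.ndarray, fs: float, trial_labels: pd.DataFrame,
                   condition: str, kept: np.ndarray | None = None) -> CNRCondition:
    """Average a continuous (CNR) time course over one cue condition's trials.

    ``condition`` is "cue_left" or "cue_right"; trials are cut on 16 s
    boundaries from ``trial_labels`` (start_s, cue columns).
    """
    if kept is None:
        kept = np.ones(len(trial_labels), dtype=bool)
    cue = condition.removeprefix("cue_")
    sel = trial_labels[np.asarray(kept)
                       & (~trial_labels.is_rest).to_numpy()
                       & (trial_labels.cue == cue).to_numpy()]
    if not len(sel):
        raise ValueError(f"no kept trials for condition {condition!r}")
    n_per = int(round(TRIAL_DURATION_S * fs))
    rows = []
    for start in sel.start_s:
        i0 = int(round(start * fs))
        rows.append(series[i0:i0 + n_per])
    per_trial = np.stack(rows)
    times = np.arange(n_per) / fs
    return CNRCondition(condition=condition, times=times,
                        mean=per_trial.mean(axis=0), per_trial=per_trial)


def epoch_probes(series: np.ndarray, fs: float, events: pd.DataFrame,
                 window: tuple[float, float] = PROBE_EPOCH_WINDOW_S,
                 kept_trials: set[int] | None = None) -> dict[str, np.ndarray]:
    """Epoch a continuous series around qualifying probe stimuli.

    Categories: attend_{cue}_stim_{hand} for cue, hand in {left, right}.
    Target probes and probes with a (simulated) incorrect button press are
    excluded; epochs are half-open [onset+a, onset+b) windows.
    """
    a, b = window
    n_per = int(round((b - a) * fs))
    cats: dict[str, list[np.ndarray]] = {
        f"attend_{c}_stim_{h}": [] for c in ("left", "right") for h in ("left", "right")
    }
    probes = events[events.trial_type.str.startswith("probe_")]
    cue_by_trial = (
        events[events.trial_type.str.startswith("cue_")]
        .set_index("trial_index").trial_type.str.removeprefix("cue_")
    )
    n_total = len(series)
    for _, p in probes.iterrows():
        if bool(p.is_target) or bool(p.bad_response):
            continue
        if kept_trials is not None and int(p.trial_index) not in kept_trials:
            continue
        cue = cue_by_trial.loc[int(p.trial_index)]
        i0 = int(round((p.onset + a) * fs))
        if i0 < 0 or i0 + n_per > n_total:
            warnings.warn(f"probe at {p.onset:.2f} s too close to the recording "
                          "edge; epoch dropped", RuntimeWarning)
            continue
        cats[f"attend_{cue}_stim_{p.hand}"].append(series[i0:i0 + n_per])
    return {k: (np.stack(v) if v else np.empty((0, n_per))) for k, v in cats.items()}


def equalise_trial_counts(
    epoch_sets: dict[str, np.ndarray], rng: np.random.Generator | int
) -> dict[str, np.ndarray]:
    """Randomly discard epochs so every set has the minimum count (seeded)."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if any(len(v) == 0 for v in epoch_sets.values()):
        raise ValueError("every epoch set must contain at least one epoch")
    n_min = min(len(v) for v in epoch_sets.values())
    out = {}
    for key in epoch_sets:   # fixed iteration order keeps this seeded-deterministic
        v = epoch_sets[key]
        idx = np.sort(rng.choice(len(v), size=n_min, replace=False))
        out[key] = v[idx]
    return out


def window_average(timecourse: np.ndarray, fs: float,
                   window: tuple[float, float], t0: float = 0.0) -> float:
    """Mean over the half-open window [a, b) of a trial/probe-relative series.

    ``t0`` is the time of the first sample (e.g. -0.180 for probe epochs).
    """
    a, b = window
    i0 = int(round((a - t0) * fs))
    i1 = int(round((b - t0) * fs))
    if not 0 <= i0 < i1 <= len(np.atleast_2d(timecourse)[0]):
        raise ValueError(f"window {window} outside the epoch time grid")
    tc = np.asarray(timecourse, float)
    return float(tc[..., i0:i1].mean())
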