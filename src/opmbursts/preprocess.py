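"""Sensor-space quality control and interference suppression.

Implements the standard wearable-magnetometer cleanup chain: Welch spectra,
noise-floor based bad-channel rejection (median amplitude spectral density
above ~16 fT/sqrt(Hz) in 5-150 Hz, or a dead channel), segmentation into 16 s
trials, rejection of trials whose pooled standard deviation exceeds three
times that of the combined data, and homogeneous field correction (HFC) -
projection of the data out of the subspace spanned by the spatially uniform
field components measurable through the channel orientation geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .containers import RawRecording
from .paradigm import TARGET_WINDOW_S, TRIAL_DURATION_S


@dataclass
class PSDResult:
    freqs: np.ndarray           # Hz
    psd: np.ndarray             # (n_channels, n_freqs), T^2/Hz
    channel_names: list[str]

    @property
    def asd_fT(self) -> np.ndarray:
        """Amplitude spectral density in fT/sqrt(Hz)."""
        return np.sqrt(self.psd) * 1e15


@dataclass
class TrialMatrix:
    data: np.ndarray            # (n_trials, n_channels, n_samples)
    labels: pd.DataFrame        # per-trial: trial_index, is_rest, cue, start_s
    kept: np.ndarray            # bool mask, False = rejected
    fs: float

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def welch_psd(recording: RawRecording, segment_s: float = 2.0,
              overlap_fraction: float = 0.5) -> PSDResult:
    """One-sided Welch power spectral density (Hann taper)."""
    nperseg = int(round(segment_s * recording.fs))
    if nperseg < 8:
        raise ValueError("segment too short: need segment_s * fs >= 8 samples")
    if recording.n_samples < nperseg:
        raise ValueError("recording shorter than one Welch segment")
    freqs, psd = signal.welch(
        recording.data, fs=recording.fs, window="hann", nperseg=nperseg,
        noverlap=int(round(overlap_fraction * nperseg)), axis=-1,
    )
    return PSDResult(freqs=freqs, psd=psd, channel_names=list(recording.channel_names))


def detect_bad_channels(psd: PSDResult, floor_limit: float = 16.0,
                        band: tuple[float, float] = (5.0, 150.0)) -> list[str]:
    """Channels whose median in-band ASD exceeds ``floor_limit`` fT/sqrt(Hz),
    plus channels with an identically zero spectrum."""
    sel = (psd.freqs >= band[0]) & (psd.freqs <= band[1])
    if not np.any(sel):
        raise ValueError("band contains no PSD frequencies")
    med = np.median(psd.asd_fT[:, sel], axis=1)
    dead = np.all(psd.psd == 0, axis=1)
    flags = (med > floor_limit) | dead
    return [name for name, f in zip(psd.channel_names, flags) if f]


def mark_bad_channels(recording: RawRecording, bad_names: list[str]) -> RawRecording:
    bad = recording.bad.copy()
    for name in bad_names:
        bad[recording.channel_names.index(name)] = True
    return recording.copy_with(bad=bad)


def _trial_starts(events: pd.DataFrame) -> pd.DataFrame:
    """Per-trial start times/labels recovered from a BIDS-style events table."""
    rows = []
    for idx, grp in events.groupby("trial_index", sort=True):
        rest = grp[grp.trial_type == "rest"]
        if len(rest):
            rows.append(dict(trial_index=idx, is_rest=True, cue="n/a",
                             start_s=float(rest.iloc[0].onset)))
            continue
        tgt = grp[grp.trial_type == "target"]
        cue_row = grp[grp.trial_type.str.startswith("cue_")]
        if not len(tgt) or not len(cue_row):
            raise ValueError(f"trial {idx}: events lack target/cue rows")
        rows.append(dict(trial_index=idx, is_rest=False,
                         cue=cue_row.iloc[0].trial_type.removeprefix("cue_"),
                         start_s=float(tgt.iloc[0].onset) - TARGET_WINDOW_S[0]))
    return pd.DataFrame(rows, columns=["trial_index", "is_rest", "cue", "start_s"])


def segment_trials(recording: RawRecording, events: pd.DataFrame | None = None,
                   trial_duration_s: float = TRIAL_DURATION_S) -> TrialMatrix:
    """Cut the continuous recording on trial boundaries (half-open windows)."""
    events = recording.events if events is None else events
    n_per = int(round(trial_duration_s * recording.fs))
    if events is None or not len(events):
        return TrialMatrix(
            data=np.empty((0, recording.n_channels, n_per)),
            labels=pd.DataFrame(columns=["trial_index", "is_rest", "cue", "start_s"]),
            kept=np.zeros(0, dtype=bool), fs=recording.fs,
        )
    labels = _trial_starts(events)
    segs = []
    for start in labels.start_s:
        i0 = int(round(start * recording.fs))
        if i0 < 0 or i0 + n_per > recording.n_samples:
            raise ValueError(f"trial at {start} s extends past the recording")
        segs.append(recording.data[:, i0:i0 + n_per])
    return TrialMatrix(data=np.stack(segs), labels=labels,
                       kept=np.ones(len(segs), dtype=bool), fs=recording.fs)


def reject_bad_trials(trials: TrialMatrix, k: float = 3.0,
                      good_channels: np.ndarray | None = None) -> TrialMatrix:
    """Reject trials whose pooled SD exceeds ``k`` x the combined-data SD.

    The SD is pooled over channels and samples; rest blocks are included.
    Returns a new TrialMatrix with an updated kept mask.
    """
    if trials.n_trials < 1:
        raise ValueError("need at least one trial")
    if good_channels is None or np.all(good_channels):
        data = trials.data
    else:
        data = trials.data[:, good_channels, :]
    combined_sd = data.std()
    per_trial_sd = data.std(axis=(1, 2))
    kept = trials.kept & ~(per_trial_sd > k * combined_sd)
    return TrialMatrix(data=trials.data, labels=trials.labels, kept=kept, fs=trials.fs)


def homogeneous_field_correction(
    recording: RawRecording,
) -> tuple[RawRecording, np.ndarray]:
    """Project spatially uniform field components out of the data.

    The homogeneous model matrix S (n_good_channels x 3) holds each good
    channel's measurement-axis unit vector; the data are replaced by
    (I - S S+) X.  Returns the corrected recording and the removed component
    (same shape as the good-channel data).  Bad channels pass through
    untouched.
    """
    good = recording.good
    if good.sum() < 4:
        raise ValueError("HFC needs >= 4 good channels")
    S = recording.axes[good]
    sv = np.linalg.svd(S, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        warnings.warn("homogeneous model is rank deficient; projecting onto the "
                      "achievable subspace", RuntimeWarning)
    all_good = bool(good.all())
    X = recording.data if all_good else recording.data[good]
    removed = S @ np.linalg.lstsq(S, X, rcond=None)[0]
    if all_good:
        corrected = X - removed
    else:
        corrected = recording.data.copy()
        corrected[good] = X - removed
    return recording.copy_with(data=corrected, hfc_applied=True), removed
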