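"""Burst detection and metrics from HMM state posteriors.

State posteriors are binarised at 2/3 (strictly above threshold = active;
since rows sum to one, at most one state is active at a time).  The burst
state is the one whose binary timecourse correlates best with the beta
envelope.  Maximal runs of the burst state become burst events carrying
duration and the peak broadband Hilbert-envelope amplitude; trial-segmented
binaries yield the burst probability (fraction of trials bursting at each
trial-relative time point), and a state-weighted multitaper estimate gives
each state's power spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

BINARISE_THRESHOLD = 2.0 / 3.0
CUE_BURST_WINDOW_S = (4.0, 6.0)      # trial-relative
PROBE_BURST_WINDOW_S = (0.0, 1.1)    # probe-relative


@dataclass(frozen=True)
class BurstEvent:
    onset_s: float
    offset_s: float
    peak_amplitude: float

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("burst offset must follow its onset")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class BurstProbability:
    times: np.ndarray          # trial-relative s
    prob: np.ndarray           # fraction of trials with a burst, in [0, 1]
    n_trials: int


def binarise(gamma: np.ndarray, threshold: float = BINARISE_THRESHOLD) -> np.ndarray:
    """State k active at t iff posterior[t, k] > threshold; (T, K) bool."""
    gamma = np.asarray(gamma, float)
    return gamma > threshold


def select_burst_state(binary: np.ndarray, beta_env: np.ndarray) -> int:
    """State whose binary timecourse correlates highest with the beta envelope.

    Degenerate (constant) state timecourses are excluded with a warning; a
    constant envelope, or all states degenerate, is an error.  Ties break to
    the lowest state index.
    """
    binary = np.asarray(binary, float)
    env = np.asarray(beta_env, float)
    if binary.shape[0] != env.shape[0]:
        raise ValueError("binary timecourses and envelope must share a time grid")
    if env.std() == 0:
        raise ValueError("beta envelope is constant; correlation undefined")
    corrs = np.full(binary.shape[1], -np.inf)
    for k in range(binary.shape[1]):
        if binary[:, k].std() == 0:
            warnings.warn(f"state {k} timecourse is constant; excluded from "
                          "burst-state selection", RuntimeWarning)
            continue
        corrs[k] = np.corrcoef(binary[:, k], env)[0, 1]
    if np.all(np.isinf(corrs)):
        raise ValueError("all state timecourses are constant; correlation undefined")
    return int(np.argmax(corrs))


def burst_events(burst_binary: np.ndarray, fs: float, envelope: np.ndarray,
                 t0: float = 0.0) -> list[BurstEvent]:
    """Maximal runs of the burst state as events with peak envelope amplitude."""
    b = np.asarray(burst_binary, bool).astype(int)
    if len(b) != len(envelope):
        raise ValueError("binary series and envelope must be aligned")
    edges = np.diff(np.concatenate(([0], b, [0])))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return [
        BurstEvent(onset_s=t0 + i0 / fs, offset_s=t0 + i1 / fs,
                   peak_amplitude=float(np.max(envelope[i0:i1])))
        for i0, i1 in zip(starts, stops)
    ]


def burst_probability(trial_binaries: np.ndarray, fs: float) -> BurstProbability:
    """Fraction of trials with the burst state active at each time point."""
    tb = np.asarray(trial_binaries, bool)
    if tb.ndim != 2 or tb.shape[0] < 1:
        raise ValueError("need a (n_trials, n_samples) binary array with >= 1 trial")
    return BurstProbability(times=np.arange(tb.shape[1]) / fs,
                            prob=tb.mean(axis=0), n_trials=tb.shape[0])


def burst_count_in_window(events: list[BurstEvent],
                          window: tuple[float, float]) -> int:
    """Bursts fully encapsulated (onset >= a and offset < b) in the window."""
    a, b = window
    return sum(1 for e in events if e.onset_s >= a and e.offset_s < b)


def _dpss_tapers(n: int, nw: float, n_tapers: int) -> np.ndarray:
    return signal.windows.dpss(n, nw, Kmax=n_tapers)


def multitaper_psd(x: np.ndarray, fs: float, win_s: float = 1.0,
                   step_s: float = 0.5, nw: float = 4.0,
                   n_tapers: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window DPSS multitaper PSD, averaged over windows."""
    freqs, S, _ = _windowed_multitaper(x, fs, win_s, step_s, nw, n_tapers)
    return freqs, S.mean(axis=0)


def _windowed_multitaper(x, fs, win_s, step_s, nw, n_tapers):
    x = np.asarray(x, float)
    n_win = int(round(win_s * fs))
    step = int(round(step_s * fs))
    if len(x) < n_win:
        raise ValueError("series shorter than one taper window")
    n_tapers = int(2 * nw - 1) if n_tapers is None else n_tapers
    tapers = _dpss_tapers(n_win, nw, n_tapers)       # (n_tapers, n_win)
    starts = np.arange(0, len(x) - n_win + 1, step)
    freqs = np.fft.rfftfreq(n_win, d=1.0 / fs)
    S = np.empty((len(starts), len(freqs)))
    for i, s in enumerate(starts):
        seg = x[s:s + n_win]
        spec = np.fft.rfft(tapers * seg, axis=1)
        S[i] = (np.abs(spec) ** 2).mean(axis=0) / fs
    return freqs, S, starts


def statewise_multitaper(
    x: np.ndarray, fs: float, gamma: np.ndarray, win_s: float = 1.0,
    step_s: float = 0.5, nw: float = 4.0, n_tapers: int | None = None,
    fmax: float = 48.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Occupancy-weighted multitaper spectrum for each HMM state.

    Each sliding window's multitaper spectrum contributes to state k with
    weight equal to the state's mean posterior occupancy over the window.
    Returns (freqs, spectra (K, n_freqs), valid (K,) bool); a state that is
    never occupied gets a NaN spectrum and valid=False rather than a
    fabricated estimate.
    """
    gamma = np.asarray(gamma, float)
    if gamma.shape[0] != len(x):
        raise ValueError("posterior and series must share a time grid")
    freqs, S, starts = _windowed_multitaper(x, fs, win_s, step_s, nw, n_tapers)
    n_win = int(round(win_s * fs))
    K = gamma.shape[1]
    occ = np.stack([gamma[s:s + n_win].mean(axis=0) for s in starts])  # (W, K)
    sel = freqs <= fmax
    spectra = np.full((K, sel.sum()), np.nan)
    valid = np.zeros(K, dtype=bool)
    for k in range(K):
        w = occ[:, k]
        if w.sum() <= 0:
            warnings.warn(f"state {k} never occupied; spectrum left empty",
                          RuntimeWarning)
            continue
        spectra[k] = (w[:, None] * S[:, sel]).sum(axis=0) / w.sum()
        valid[k] = True
    return freqs[sel], spectra, valid
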