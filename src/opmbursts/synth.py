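"""Ground-truthed synthetic OPM-MEG recordings.

Generates triaxial sensor arrays on a helmet surface, analytic
spherical-conductor lead fields, burst-driven source dynamics locked to the
task schedule, white sensor noise, and spatially uniform low-frequency
interference drift.  Every dataset retains its exact injected sources and
burst intervals, so downstream stages can be validated against ground truth.

The source dynamics follow the burst phenomenology of sensorimotor cortex:
transient oscillatory packets with an alpha-band carrier and a beta-band
component (pan-spectral bursts), whose occurrence rate drops during attended
cue/probe windows and during tactile stimulation, riding on 1/f background
activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal

from .containers import RawRecording
from .paradigm import (
    CUE_WINDOW_S,
    PROBE_ONSETS_S,
    TARGET_WINDOW_S,
    Schedule,
    schedule_to_events,
)

MU0_OVER_4PI = 1e-7  # T·m/A

AXIS_SUFFIXES = ("rad", "tan1", "tan2")


@dataclass
class SensorArray:
    """Triaxial OPM array: one radial + two tangential axes per sensor."""

    positions: np.ndarray       # (n_sensors, 3) m, head-centred
    axes: np.ndarray            # (n_sensors, 3, 3): [radial, tan1, tan2] rows
    channel_names: list[str]

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]

    @property
    def n_channels(self) -> int:
        return 3 * self.n_sensors

    @property
    def channel_positions(self) -> np.ndarray:
        return np.repeat(self.positions, 3, axis=0)

    @property
    def channel_axes(self) -> np.ndarray:
        return self.axes.reshape(-1, 3)


@dataclass
class SourceModel:
    """N source regions inside a homogeneous spherical conductor."""

    centroids: np.ndarray       # (n_regions, 3) m
    labels: list[str]
    conductor_radius: float = 0.09
    conductor_centre: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.conductor_centre = np.asarray(self.conductor_centre, dtype=float)
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("region labels must be unique")
        r = np.linalg.norm(self.centroids - self.conductor_centre, axis=1)
        if np.any(r >= self.conductor_radius):
            raise ValueError("all centroids must lie strictly inside the conductor")

    @property
    def n_regions(self) -> int:
        return self.centroids.shape[0]


@dataclass
class BurstSpec:
    """Generative law for one region's burst dynamics.

    Rates are events/s; duration_law holds (mu, sigma) of a log-normal in
    seconds; amplitude is the dipole moment scale (A·m); carrier mixes an
    alpha-band sinusoid with a beta-band component so bursts are pan-spectral.
    Factors <= 1 multiply the burst rate during attended cue/probe windows
    (attended_rate_factor) and during tactile stimulation
    (stim_suppression_factor).
    """

    baseline_rate: float = 1.2
    duration_law: tuple[float, float] = (np.log(0.25), 0.4)
    amplitude: float = 20e-9
    carrier: tuple[float, float] = (1.0, 0.6)     # (alpha weight, beta weight)
    alpha_freq: float = 10.0
    beta_freq: float = 21.0
    attended_rate_factor: float = 0.65
    stim_suppression_factor: float = 0.5
    background_sd_frac: float = 0.25   # 1/f background SD as fraction of amplitude
    stim_response_s: float = 0.30      # suppression window after each stimulus onset

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0 or self.amplitude < 0:
            raise ValueError("rates and amplitudes must be positive")
        for f in (self.attended_rate_factor, self.stim_suppression_factor):
            if not 0.0 <= f <= 1.0:
                raise ValueError("rate factors must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    recording: RawRecording
    schedule: Schedule
    truth_sources: np.ndarray            # (n_regions, n_samples), A·m
    truth_bursts: dict[str, np.ndarray]  # label -> (n_bursts, 2) [onset, offset] s
    truth_orientations: np.ndarray       # (n_regions, 3) unit dipole orientations
    source_model: SourceModel
    array: SensorArray


def build_helmet_array(
    n_sensors: int,
    helmet_radius: float = 0.12,
    rng: np.random.Generator | int = 0,
    centre: np.ndarray | None = None,
) -> SensorArray:
    """Quasi-uniform triaxial sensors on the upper hemisphere.

    Positions follow a Fibonacci lattice on the z > 0 hemisphere with a small
    seeded jitter; each sensor measures along one radial and two tangential
    orthonormal axes.
    """
    if n_sensors < 1:
        raise ValueError("n_sensors must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    centre = np.zeros(3) if centre is None else np.asarray(centre, float)

    golden = (1 + np.sqrt(5)) / 2
    k = np.arange(n_sensors)
    z = 0.15 + 0.85 * (k + 0.5) / n_sensors          # keep above the helmet rim
    phi = 2 * np.pi * k / golden
    rho = np.sqrt(1 - z**2)
    unit = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)

    # small tangential jitter, re-normalised onto the helmet sphere
    jitter = rng.normal(scale=0.01, size=unit.shape)
    unit = unit + jitter - (np.sum(jitter * unit, axis=1, keepdims=True)) * unit
    unit /= np.linalg.norm(unit, axis=1, keepdims=True)
    positions = centre + helmet_radius * unit

    axes = np.empty((n_sensors, 3, 3))
    names: list[str] = []
    for i in range(n_sensors):
        radial = unit[i]
        ref = np.array([0.0, 0.0, 1.0])
        if abs(radial @ ref) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        t1 = ref - (ref @ radial) * radial
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(radial, t1)
        theta = rng.uniform(0, 2 * np.pi)   # random in-plane tangential frame
        axes[i, 0] = radial
        axes[i, 1] = np.cos(theta) * t1 + np.sin(theta) * t2
        axes[i, 2] = -np.sin(theta) * t1 + np.cos(theta) * t2
        names.extend(f"S{i:03d}-{sfx}" for sfx in AXIS_SUFFIXES)
    return SensorArray(positions=positions, axes=axes, channel_names=names)


def sphere_lead_field(
    source_pos: np.ndarray,
    source_moment: np.ndarray,
    sensor_pos: np.ndarray,
    sensor_axis: np.ndarray,
    conductor_centre: np.ndarray | None = None,
    conductor_radius: float | None = None,
) -> float:
    """Field of a current dipole in a homogeneous spherical conductor.

    Analytic external solution for the magnetic field of a primary current
    dipole (moment in A·m) inside a conducting sphere, projected onto the
    sensor's measurement axis; the volume-current contribution is included in
    closed form.  Radial dipoles are magnetically silent.
    """
    centre = np.zeros(3) if conductor_centre is None else np.asarray(conductor_centre, float)
    r0 = np.asarray(source_pos, float) - centre
    r = np.asarray(sensor_pos, float) - centre
    q = np.asarray(source_moment, float)
    if conductor_radius is not None:
        if np.linalg.norm(r0) >= conductor_radius:
            raise ValueError("source must lie strictly inside the conductor")
        if np.linalg.norm(r) <= conductor_radius:
            raise ValueError("sensor must lie strictly outside the conductor")
    b = _sphere_dipole_field(r0, q, r)
    return float(b @ np.asarray(sensor_axis, float))


def _sphere_dipole_field(r0: np.ndarray, q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """B(r) for dipole q at r0, sphere centred at the origin."""
    a_vec = r - r0
    a = np.linalg.norm(a_vec)
    rn = np.linalg.norm(r)
    if a < 1e-12 or rn < 1e-12:
        raise ValueError("degenerate sensor/source geometry")
    ar = a_vec @ r
    F = a * (rn * a + rn**2 - r0 @ r)
    gradF = (a**2 / rn + ar / a + 2 * a + 2 * rn) * r - (a + 2 * rn + ar / a) * r0
    qxr0 = np.cross(q, r0)
    return MU0_OVER_4PI / F**2 * (F * qxr0 - (qxr0 @ r) * gradF)


def _sphere_dipole_field_many(r0: np.ndarray, q: np.ndarray,
                              r: np.ndarray) -> np.ndarray:
    """Vectorised _sphere_dipole_field over sensor positions r (n, 3)."""
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    ar = np.einsum("ij,ij->i", a_vec, r)
    F = a * (rn * a + rn**2 - r @ r0)
    c1 = a**2 / rn + ar / a + 2 * a + 2 * rn
    c2 = a + 2 * rn + ar / a
    gradF = c1[:, None] * r - c2[:, None] * r0
    qxr0 = np.cross(q, r0)
    return MU0_OVER_4PI / F[:, None]**2 * (
        F[:, None] * qxr0 - (r @ qxr0)[:, None] * gradF)


def region_lead_field(
    source_model: SourceModel, array: SensorArray, region: int | str
) -> np.ndarray:
    """(n_channels, 3) lead field for unit dipole moments along x, y, z."""
    if isinstance(region, str):
        region = source_model.labels.index(region)
    pos = source_model.centroids[region] - source_model.conductor_centre
    if np.linalg.norm(pos) >= source_model.conductor_radius:
        raise ValueError("source must lie strictly inside the conductor")
    cpos = array.channel_positions - source_model.conductor_centre
    caxes = array.channel_axes
    L = np.empty((array.n_channels, 3))
    for j in range(3):
        q = np.zeros(3)
        q[j] = 1.0
        B = _sphere_dipole_field_many(pos, q, cpos)
        L[:, j] = np.einsum("ij,ij->i", B, caxes)
    return L


_BASE_REGIONS = [
    ("left_postcentral", (-0.042, -0.019, 0.055)),
    ("right_postcentral", (0.042, -0.019, 0.055)),
    ("occipital", (0.0, -0.060, 0.025)),
    ("frontal", (0.0, 0.060, 0.030)),
    ("left_temporal", (-0.058, 0.005, 0.010)),
    ("right_temporal", (0.058, 0.005, 0.010)),
]

#: region label -> the hand whose stimulation/attention drives it
REGION_HANDS = {"left_postcentral": "right", "right_postcentral": "left"}


def make_source_model(n_regions: int = 6, conductor_radius: float = 0.09) -> SourceModel:
    """Default synthetic parcellation; always includes both postcentral regions."""
    if n_regions < 2:
        raise ValueError("need at least the two postcentral regions")
    labels = [n for n, _ in _BASE_REGIONS[:n_regions]]
    pts = [p for _, p in _BASE_REGIONS[:n_regions]]
    golden = (1 + np.sqrt(5)) / 2
    for k in range(len(_BASE_REGIONS), n_regions):
        z = 0.2 + 0.6 * ((k + 0.5) / n_regions)
        phi = 2 * np.pi * k / golden
        rho = np.sqrt(1 - z**2)
        pts.append(tuple(0.065 * np.array([rho * np.cos(phi), rho * np.sin(phi), z])))
        labels.append(f"region_{k:02d}")
    return SourceModel(centroids=np.array(pts), labels=labels,
                       conductor_radius=conductor_radius)


def _rate_factors(schedule: Schedule, spec: BurstSpec, region_hand: str | None,
                  t: np.ndarray) -> np.ndarray:
    """Multiplicative burst-rate factor at times t (experiment clock)."""
    f = np.ones_like(t)
    for trial in schedule.trials:
        if trial.is_rest:
            continue
        rel = t - trial.start_s
        in_trial = (rel >= 0) & (rel < trial.duration_s)
        if not np.any(in_trial):
            continue
        if region_hand is not None and trial.cue == region_hand:
            # attention directed to this region's hand: cue window + probe span
            att = in_trial & (
                ((rel >= CUE_WINDOW_S[0]) & (rel < CUE_WINDOW_S[1]))
                | ((rel >= PROBE_ONSETS_S[0]) & (rel < PROBE_ONSETS_S[-1] + 1.1))
            )
            f[att] *= spec.attended_rate_factor
        if region_hand is not None:
            # target patterns are presented to both hands
            stim = in_trial & (rel >= TARGET_WINDOW_S[0]) & (rel < TARGET_WINDOW_S[1])
            f[stim] *= spec.stim_suppression_factor
            for p in trial.probes:
                if p.hand == region_hand:
                    w = in_trial & (rel >= p.onset_s) & (rel < p.onset_s + spec.stim_response_s)
                    f[w] *= spec.stim_suppression_factor
    return f


def _one_over_f_background(n: int, fs: float, sd: float,
                           rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(freqs, 1.0))   # power ~ 1/f above 1 Hz
    x = np.fft.irfft(spec * shape, n=n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def simulate_source_timecourse(
    schedule: Schedule,
    spec: BurstSpec,
    fs: float,
    rng: np.random.Generator | int,
    region_hand: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One region's source dynamics plus its exact burst intervals.

    Burst onsets follow an inhomogeneous Poisson process (thinning of a
    homogeneous process at the baseline rate); ``region_hand`` selects the
    hand this region responds to ("other" regions pass None and receive no
    task modulation).  Returns (timecourse[A·m], intervals (n, 2) seconds).
    """
    if fs < 200:
        raise ValueError("fs must be >= 200 Hz")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    duration = schedule.total_duration_s
    n = int(round(duration * fs))
    x = _one_over_f_background(n, fs, spec.background_sd_frac * spec.amplitude, rng)

    n_cand = rng.poisson(spec.baseline_rate * duration)
    onsets = np.sort(rng.uniform(0, duration, size=n_cand))
    keep = rng.random(n_cand) < _rate_factors(schedule, spec, region_hand, onsets)
    onsets = onsets[keep]

    wa, wb = spec.carrier
    intervals = []
    for onset in onsets:
        dur = float(np.clip(rng.lognormal(*spec.duration_law), 0.08, 1.2))
        i0 = int(round(onset * fs))
        npk = int(round(dur * fs))
        if i0 + npk > n:
            npk = n - i0
            if npk < int(0.05 * fs):
                continue
        tt = np.arange(npk) / fs
        fa = rng.normal(spec.alpha_freq, 0.8)
        fb = rng.normal(spec.beta_freq, 1.5)
        packet = wa * np.sin(2 * np.pi * fa * tt + rng.uniform(0, 2 * np.pi))
        packet += wb * np.sin(2 * np.pi * fb * tt + rng.uniform(0, 2 * np.pi))
        x[i0:i0 + npk] += spec.amplitude * _tukey_cached(npk) * packet
        intervals.append((i0 / fs, (i0 + npk) / fs))
    return x, np.array(intervals).reshape(-1, 2)


@lru_cache(maxsize=1024)
def _tukey_cached(n: int) -> np.ndarray:
    return signal.windows.tukey(n, alpha=0.5)


def _uniform_drift(n: int, fs: float, amplitude: float,
                   rng: np.random.Generator) -> np.ndarray:
    """(3, n) slowly varying uniform field vector, band-limited below 2 Hz."""
    walks = np.cumsum(rng.standard_normal((3, n)), axis=1)
    sos = signal.butter(4, 2.0, btype="low", fs=fs, output="sos")
    walks = signal.sosfiltfilt(sos, walks, axis=1)
    sd = walks.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return amplitude * walks / sd


def _tangential_orientation(source_model: SourceModel, region: int,
                            rng: np.random.Generator) -> np.ndarray:
    radial = source_model.centroids[region] - source_model.conductor_centre
    nr = np.linalg.norm(radial)
    radial = radial / nr if nr > 0 else np.array([0.0, 0.0, 1.0])
    v = rng.standard_normal(3)
    v -= (v @ radial) * radial
    return v / np.linalg.norm(v)


def simulate_recording(
    schedule: Schedule,
    source_model: SourceModel,
    array: SensorArray,
    specs: BurstSpec | dict[str, BurstSpec],
    noise_sd: float = 1.5e-13,
    drift_amplitude: float = 5e-12,
    fs: float = 1200.0,
    rng: np.random.Generator | int = 0,
) -> SyntheticDataset:
    """Compose source dynamics, lead fields, sensor noise and uniform drift.

    Sensor data = sum over regions of (lead field · orientation) x source(t)
    + white noise (sd ``noise_sd`` tesla) + a spatially uniform drift field
    projected onto each channel axis.  Dipole orientations are tangential
    (the spherical conductor is blind to radial moments) and retained as
    ground truth along with sources and burst intervals.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    n = int(round(schedule.total_duration_s * fs))
    if n == 0:
        raise ValueError("schedule has zero duration")
    n_regions = source_model.n_regions

    sources = np.zeros((n_regions, n))
    orientations = np.zeros((n_regions, 3))
    bursts: dict[str, np.ndarray] = {}
    gains = np.empty((array.n_channels, n_regions))   # lead field . orientation
    for ridx, label in enumerate(source_model.labels):
        spec = specs[label] if isinstance(specs, dict) else specs
        hand = REGION_HANDS.get(label)
        x, iv = simulate_source_timecourse(schedule, spec, fs, rng, region_hand=hand)
        u = _tangential_orientation(source_model, ridx, rng)
        gains[:, ridx] = region_lead_field(source_model, array, ridx) @ u
        sources[ridx] = x
        orientations[ridx] = u
        bursts[label] = iv
    data = gains @ sources

    if noise_sd > 0:
        data += rng.normal(scale=noise_sd, size=data.shape)
    if drift_amplitude > 0:
        b = _uniform_drift(n, fs, drift_amplitude, rng)
        data += array.channel_axes @ b

    events = schedule_to_events(schedule)
    recording = RawRecording(
        data=data, fs=fs, channel_names=list(array.channel_names),
        positions=array.channel_positions, axes=array.channel_axes, events=events,
    )
    return SyntheticDataset(
        recording=recording, schedule=schedule, truth_sources=sources,
        truth_bursts=bursts, truth_orientations=orientations,
        source_model=source_model, array=array,
    )
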