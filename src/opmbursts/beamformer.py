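"""LCMV beamformer virtual electrodes.

Band-filters the sensor data (zero-phase Butterworth), computes a
band-specific data covariance regularised by the Tikhonov method (5% of the
largest eigenvalue added to the diagonal), selects for each source region the
dipole orientation with the largest beamformer output power, and projects the
sensor data through unit-gain linearly-constrained minimum-variance weights
w = C^-1 l / (l^T C^-1 l) to obtain one source time course ("virtual
electrode") per region and band.  With a spherical conductor the radial lead
field column is null, so the orientation search runs in the tangential plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, signal

from .containers import RawRecording
from .synth import SensorArray, SourceModel, region_lead_field

BROADBAND = (1.0, 48.0)
BETA_BAND = (13.0, 30.0)
TIKHONOV_FRACTION = 0.05


@dataclass
class BandCovariance:
    band: tuple[float, float]
    C: np.ndarray                # regularised covariance
    C_raw: np.ndarray            # before regularisation
    regularisation: float        # scalar added to the diagonal
    n_samples_used: int


@dataclass
class VirtualElectrodeSet:
    band: tuple[float, float]
    data: np.ndarray             # (n_regions, n_samples)
    orientations: np.ndarray     # (n_regions, 3) unit vectors
    weights: np.ndarray          # (n_regions, n_good_channels)
    labels: list[str]
    fs: float

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]


def band_filter(recording: RawRecording, band: tuple[float, float]) -> RawRecording:
    """Zero-phase 4th-order Butterworth band-pass."""
    f_lo, f_hi = band
    if not 0 < f_lo < f_hi < recording.fs / 2:
        raise ValueError(f"invalid band edges {band} for fs={recording.fs}")
    sos = signal.butter(4, band, btype="bandpass", fs=recording.fs, output="sos")
    return recording.copy_with(data=signal.sosfiltfilt(sos, recording.data, axis=-1))


def band_covariance(filtered: RawRecording, band: tuple[float, float],
                    sample_mask: np.ndarray | None = None) -> BandCovariance:
    """Tikhonov-regularised covariance of the good channels.

    ``sample_mask`` restricts the estimate to samples surviving trial
    rejection.
    """
    X = filtered.data if filtered.good.all() else filtered.data[filtered.good]
    if sample_mask is not None and not sample_mask.all():
        X = X[:, sample_mask]
    C = np.cov(X)
    return tikhonov_regularise(C, band=band, n_samples=X.shape[1])


def tikhonov_regularise(C: np.ndarray, band: tuple[float, float] = BROADBAND,
                        n_samples: int = 0) -> BandCovariance:
    """C + 0.05 * lambda_max(C) * I."""
    C = np.asarray(C, float)
    if not np.allclose(C, C.T, atol=1e-10 * max(1.0, np.abs(C).max())):
        raise ValueError("covariance must be symmetric")
    lam_max = float(np.max(linalg.eigvalsh(C)))
    reg = TIKHONOV_FRACTION * lam_max
    return BandCovariance(band=tuple(band), C=C + reg * np.eye(C.shape[0]),
                          C_raw=C, regularisation=reg, n_samples_used=n_samples)


def _solve_spd(C: np.ndarray, B: np.ndarray) -> np.ndarray:
    cho = linalg.cho_factor(C, lower=True)
    return linalg.cho_solve(cho, B)


def optimal_orientation(L: np.ndarray, C_reg: np.ndarray,
                        null_tol: float = 1e-8) -> np.ndarray:
    """Dipole orientation maximising beamformer output power.

    Output power for unit-gain weights is 1 / (u^T L^T C^-1 L u); the maximiser
    is the smallest-eigenvalue eigenvector of L^T C^-1 L, restricted to the
    subspace where the lead field is non-null (the tangential plane for a
    spherical conductor).  Sign fixed so the first non-zero component is
    positive.
    """
    L = np.asarray(L, float)
    sv = linalg.svdvals(L)
    if sv[0] <= 0:
        raise ValueError("lead field is identically zero")
    # basis of the effective (non-silent) moment subspace
    _, s, Vt = linalg.svd(L, full_matrices=False)
    V = Vt[s > null_tol * s[0]].T            # (3, m)
    if V.shape[1] == 0:
        raise ValueError("lead field effectively rank 0")
    M = (L @ V).T @ _solve_spd(C_reg, L @ V)   # m x m
    vals, vecs = linalg.eigh(M)
    u = V @ vecs[:, 0]
    u /= np.linalg.norm(u)
    nz = np.flatnonzero(np.abs(u) > 1e-12)
    if len(nz) and u[nz[0]] < 0:
        u = -u
    return u


def lcmv_weights(l: np.ndarray, C_reg: np.ndarray) -> np.ndarray:
    """Unit-gain LCMV weights w = C^-1 l / (l^T C^-1 l)."""
    l = np.asarray(l, float)
    if np.linalg.norm(l) == 0:
        raise ValueError("lead field vector is zero")
    Cinv_l = _solve_spd(C_reg, l)
    return Cinv_l / (l @ Cinv_l)


def reconstruct_virtual_electrodes(
    recording: RawRecording,
    source_model: SourceModel,
    array: SensorArray,
    band: tuple[float, float],
    sample_mask: np.ndarray | None = None,
) -> VirtualElectrodeSet:
    """Full per-band chain: filter, covariance, orientation, weights, project.

    When the recording has been homogeneous-field corrected, the same
    uniform-field projector is applied to the lead fields so that source and
    data models live in the same subspace (and beamformer weights carry no
    uniform-field component).
    """
    filtered = band_filter(recording, band)
    cov = band_covariance(filtered, band, sample_mask=sample_mask)
    good = recording.good
    X = filtered.data if good.all() else filtered.data[good]

    P = None
    if recording.hfc_applied:
        S = recording.axes[good]
        P = np.eye(S.shape[0]) - S @ np.linalg.pinv(S)

    n_regions = source_model.n_regions
    ve = np.empty((n_regions, X.shape[1]))
    orientations = np.empty((n_regions, 3))
    weights = np.empty((n_regions, X.shape[0]))
    for r in range(n_regions):
        L = region_lead_field(source_model, array, r)[good]
        if P is not None:
            L = P @ L
        u = optimal_orientation(L, cov.C)
        w = lcmv_weights(L @ u, cov.C)
        ve[r] = w @ X
        orientations[r] = u
        weights[r] = w
    return VirtualElectrodeSet(band=tuple(band), data=ve, orientations=orientations,
                               weights=weights, labels=list(source_model.labels),
                               fs=recording.fs)
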