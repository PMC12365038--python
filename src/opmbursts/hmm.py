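"""Time-delay-embedded Gaussian hidden Markov model.

The broadband (1-48 Hz) virtual electrode is (optionally) downsampled,
embedded in a centred window of ``n_lags`` consecutive samples (so states
capture spectral as well as amplitude structure), optionally PCA-reduced, and
modelled by a K-state HMM with full-covariance Gaussian emissions.  Fitting is
maximum-likelihood EM (Baum-Welch) with seeded k-means restarts; state
posteriors come from the scaled forward-backward recursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import linalg, signal

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class TDEConfig:
    n_lags: int = 15
    target_fs: float | None = 100.0   # None = keep the input rate
    pca_dims: int | None = None

    def __post_init__(self) -> None:
        if self.n_lags < 1 or self.n_lags % 2 == 0:
            raise ValueError("n_lags must be odd and >= 1")


@dataclass
class EmbeddedSeries:
    X: np.ndarray                 # (T', d) embedded (possibly PCA-reduced) rows
    fs: float                     # rate of the embedded grid
    n_lags: int
    t0_s: float                   # time of the first embedded row
    pca_components: np.ndarray | None = None
    pca_mean: np.ndarray | None = None

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.X.shape[0]) / self.fs


@dataclass
class GaussianHMM:
    pi: np.ndarray                # (K,)
    A: np.ndarray                 # (K, K), rows sum to 1
    means: np.ndarray             # (K, d)
    covs: np.ndarray              # (K, d, d)
    x_mean: np.ndarray            # column standardisation applied before fitting
    x_sd: np.ndarray
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True

    @property
    def n_states(self) -> int:
        return len(self.pi)


@dataclass
class StatePosterior:
    gamma: np.ndarray             # (T, K) marginal state probabilities
    loglik: float


def downsample(x: np.ndarray, fs: float, target_fs: float) -> tuple[np.ndarray, float]:
    """Anti-aliased rational resampling (polyphase FIR)."""
    if target_fs > fs:
        raise ValueError("target_fs must not exceed the input rate")
    frac = Fraction(target_fs / fs).limit_denominator(1000)
    if frac == 1:
        return np.asarray(x, float), fs
    y = signal.resample_poly(x, frac.numerator, frac.denominator)
    return y, fs * frac.numerator / frac.denominator


def embed(x: np.ndarray, fs: float, cfg: TDEConfig) -> EmbeddedSeries:
    """Centred time-delay embedding; row t spans x[t-h .. t+h], h=(n_lags-1)/2."""
    x = np.asarray(x, float)
    fs_ds = fs
    if cfg.target_fs is not None and cfg.target_fs < fs:
        x, fs_ds = downsample(x, fs, cfg.target_fs)
    if len(x) <= cfg.n_lags:
        raise ValueError("series shorter than the embedding window")
    h = (cfg.n_lags - 1) // 2
    X = np.lib.stride_tricks.sliding_window_view(x, cfg.n_lags).copy()
    comps = mean = None
    if cfg.pca_dims is not None and cfg.pca_dims < cfg.n_lags:
        mean = X.mean(axis=0)
        Xc = X - mean
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        # deterministic sign: largest-magnitude loading positive
        for row in Vt:
            if row[np.argmax(np.abs(row))] < 0:
                row *= -1
        comps = Vt[: cfg.pca_dims]
        X = Xc @ comps.T
    return EmbeddedSeries(X=X, fs=fs_ds, n_lags=cfg.n_lags, t0_s=h / fs_ds,
                          pca_components=comps, pca_mean=mean)


# ---------------------------------------------------------------------------
# scaled forward-backward recursion (numpy fallback + optional numba fast path)

def _fb_vec(pi: np.ndarray, A: np.ndarray, B: np.ndarray):
    T, K = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    xi = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta[t + 1]
        beta[t] = (A @ bb) / c[t + 1]
        xi += np.outer(alpha[t], bb) * A / c[t + 1]
    gamma = alpha * beta
    for t in range(T):
        gamma[t] /= gamma[t].sum()
    return gamma, xi, np.log(c).sum()


def _fb_loops(pi: np.ndarray, A: np.ndarray, B: np.ndarray):
    # allocation-free inner loops; same recursion as _fb_vec
    T, K = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    s = 0.0
    for j in range(K):
        alpha[0, j] = pi[j] * B[0, j]
        s += alpha[0, j]
    c[0] = s
    for j in range(K):
        alpha[0, j] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(K):
            a = 0.0
            for i in range(K):
                a += alpha[t - 1, i] * A[i, j]
            a *= B[t, j]
            alpha[t, j] = a
            s += a
        c[t] = s
        for j in range(K):
            alpha[t, j] /= s
    beta = np.empty((T, K))
    for j in range(K):
        beta[T - 1, j] = 1.0
    xi = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        ct = c[t + 1]
        for i in range(K):
            b = 0.0
            for j in range(K):
                bb = B[t + 1, j] * beta[t + 1, j]
                b += A[i, j] * bb
                xi[i, j] += alpha[t, i] * A[i, j] * bb / ct
            beta[t, i] = b / ct
    gamma = alpha * beta
    for t in range(T):
        s = 0.0
        for j in range(K):
            s += gamma[t, j]
        for j in range(K):
            gamma[t, j] /= s
    return gamma, xi, np.log(c).sum()


try:  # pragma: no cover - fast path exercised when numba is installed
    from numba import njit

    _fb_jit = njit(cache=False)(_fb_loops)
    _fb_jit(np.array([0.5, 0.5]), np.eye(2), np.ones((3, 2)))  # force compile
    _FB_IMPLS = {"numba": _fb_jit, "numpy": _fb_vec}
    _fb_core = _fb_jit
except Exception:  # pragma: no cover
    _FB_IMPLS = {"numpy": _fb_vec}
    _fb_core = _fb_vec


def _log_emissions(Z: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    T, d = Z.shape
    K = len(means)
    logB = np.empty((T, K))
    for k in range(K):
        L = np.linalg.cholesky(covs[k])
        sol = linalg.solve_triangular(L, (Z - means[k]).T, lower=True,
                                      check_finite=False)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        logB[:, k] = -0.5 * (d * _LOG2PI + logdet + np.einsum("ij,ij->j", sol, sol))
    return logB


def _fb_from_log(pi: np.ndarray, A: np.ndarray, logB: np.ndarray):
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])
    gamma, xi, logc = _fb_core(pi, A, B)
    return gamma, xi, logc + float(shift.sum())


def forward_backward(model: GaussianHMM, X: np.ndarray) -> StatePosterior:
    """Marginal state posteriors and total log-likelihood for an embedded series."""
    Z = (np.asarray(X, float) - model.x_mean) / model.x_sd
    if Z.shape[1] != model.means.shape[1]:
        raise ValueError("model dimensionality does not match the data")
    logB = _log_emissions(Z, model.means, model.covs)
    gamma, _, loglik = _fb_from_log(model.pi, model.A, logB)
    return StatePosterior(gamma=gamma, loglik=loglik)


def _floor_cov(C: np.ndarray, floor: float) -> np.ndarray:
    C = 0.5 * (C + C.T)
    vals, vecs = np.linalg.eigh(C)
    return (vecs * np.maximum(vals, floor)) @ vecs.T


def _em_run(Z: np.ndarray, K: int, seed: int, tol: float, max_iter: int):
    from sklearn.cluster import KMeans

    T, d = Z.shape
    sub = Z if T <= 20000 else Z[:: T // 20000 + 1]
    km = KMeans(n_clusters=K, n_init=1, random_state=seed).fit(sub)
    means = km.cluster_centers_.copy()
    base_cov = np.cov(Z.T).reshape(d, d)
    floor = 1e-6 * float(np.trace(base_cov) / d)
    covs = np.array([_floor_cov(base_cov, floor) for _ in range(K)])
    pi = np.full(K, 1.0 / K)
    A = np.full((K, K), 0.05 / max(K - 1, 1))
    np.fill_diagonal(A, 0.95)

    trace = []
    converged = False
    for _ in range(max_iter):
        logB = _log_emissions(Z, means, covs)
        gamma, xi, loglik = _fb_from_log(pi, A, logB)
        trace.append(loglik)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol * (abs(trace[-2]) + 1e-12):
            converged = True
            break
        pi = gamma[0] / gamma[0].sum()
        A = xi / xi.sum(axis=1, keepdims=True)
        Ng = gamma.sum(axis=0)
        means = (gamma.T @ Z) / Ng[:, None]
        for k in range(K):
            diff = Z - means[k]
            Ck = (gamma[:, k][:, None] * diff).T @ diff / Ng[k]
            covs[k] = _floor_cov(Ck, floor)
    return pi, A, means, covs, np.array(trace), converged


def fit_hmm(X: np.ndarray, K: int = 3, n_restarts: int = 3, tol: float = 1e-6,
            max_iter: int = 100, rng: np.random.Generator | int = 0) -> GaussianHMM:
    """Baum-Welch fit with seeded k-means restarts; best log-likelihood wins.

    Columns of X are z-scored before fitting (scale stored in the model, and
    re-applied by forward_backward).  Covariances are floored at 1e-6 of the
    mean data variance to prevent collapse.  Restart ties break toward the
    lowest restart index.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] <= 10 * K:
        raise ValueError("too few rows to fit the HMM")
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0)
    x_sd[x_sd == 0] = 1.0
    Z = (X - x_mean) / x_sd

    seeds = rng.integers(0, 2**31 - 1, size=n_restarts)
    best = None
    for seed in seeds:
        pi, A, means, covs, trace, conv = _em_run(Z, K, int(seed), tol, max_iter)
        if best is None or trace[-1] > best[4][-1]:
            best = (pi, A, means, covs, trace, conv)
    pi, A, means, covs, trace, conv = best
    if not conv:
        import warnings
        warnings.warn("EM did not converge within max_iter; returning best-so-far",
                      RuntimeWarning)
    return GaussianHMM(pi=pi, A=A, means=means, covs=covs, x_mean=x_mean,
                       x_sd=x_sd, loglik_trace=trace, converged=conv)
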