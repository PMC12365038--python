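"""Across-subject inference for the attention contrasts.

Paired per-subject condition values are compared with the Wilcoxon sign-rank
test (exact two-sided p by enumeration of the sign-flip distribution for up
to 25 effective pairs, tie- and continuity-corrected normal approximation
above), and each family of tests is corrected with the Benjamini-Hochberg
step-up procedure at a 5% false discovery rate.  The standard design runs an
envelope family of 4 tests (2 hemispheres x cue/probe windows) and a
burst-metric family of 12 (count, amplitude, duration x 2 windows x 2
hemispheres).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

EXACT_MAX_N = 25
DEFAULT_Q = 0.05


@dataclass
class TestResult:
    name: str
    statistic: float            # W+ = sum of positive-difference ranks
    p_value: float
    n_effective: int
    method: str                 # "exact" | "normal"
    direction: int              # sign of the median difference (A - B)
    rejected: bool | None = None
    family: str = ""


def _signed_midranks(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    return ranks, np.sign(d)


def _exact_signrank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided p from the exact null distribution of W+.

    Under the null each difference's sign is an independent fair coin; the
    distribution of 2*W+ (doubled so midranks become integers) is built by
    the generating-polynomial convolution over the doubled ranks.
    """
    doubled = np.rint(2 * ranks).astype(int)
    counts = np.zeros(doubled.sum() + 1)
    counts[0] = 1.0
    for dr in doubled:
        shifted = np.zeros_like(counts)
        shifted[dr:] = counts[:-dr] if dr else counts
        counts = counts + shifted if dr else 2 * counts
    total = counts.sum()
    w2 = int(np.rint(2 * w_plus))
    cdf = counts[: w2 + 1].sum() / total
    sf = counts[w2:].sum() / total
    return float(min(1.0, 2.0 * min(cdf, sf)))


def _normal_signrank_p(ranks: np.ndarray, w_plus: float) -> float:
    n = len(ranks)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    dev = w_plus - mean
    z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


def wilcoxon_signrank(a: np.ndarray, b: np.ndarray, name: str = "") -> TestResult:
    """Paired two-sided Wilcoxon sign-rank test on a - b.

    Zero differences are dropped before ranking; ties get midranks.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all paired differences are zero; test degenerate")
    ranks, signs = _signed_midranks(d)
    w_plus = float(ranks[signs > 0].sum())
    if len(d) <= EXACT_MAX_N:
        p, method = _exact_signrank_p(ranks, w_plus), "exact"
    else:
        p, method = _normal_signrank_p(ranks, w_plus), "normal"
    return TestResult(name=name, statistic=w_plus, p_value=p, n_effective=len(d),
                      method=method, direction=int(np.sign(np.median(d))))


def bh_fdr(p_values: np.ndarray, q: float = DEFAULT_Q) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level q."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return rejected


ENVELOPE_FAMILY = [("left", "cue"), ("right", "cue"), ("left", "probe"), ("right", "probe")]
BURST_METRICS = ("count", "amplitude", "duration")


def _paired_values(df: pd.DataFrame, sel: dict) -> tuple[np.ndarray, np.ndarray]:
    sub = df
    for col, val in sel.items():
        sub = sub[sub[col] == val]
    n_before = sub.subject.nunique()
    sub = sub.dropna(subset=["attended", "nonattended"])
    n_dropped = n_before - len(sub)
    if n_dropped > 0:
        warnings.warn(f"{sel}: {n_dropped} subject(s) dropped pairwise "
                      "(missing condition)", RuntimeWarning)
    return sub.attended.to_numpy(), sub.nonattended.to_numpy()


def attention_contrast_report(envelope_df: pd.DataFrame, burst_df: pd.DataFrame,
                              q: float = DEFAULT_Q,
                              merge_families: bool = False) -> pd.DataFrame:
    """Run the 4-test envelope family and 12-test burst family, BH-corrected.

    Both inputs are tidy per-subject tables with columns
    (subject, hemisphere, window, [metric,] attended, nonattended);
    each family is corrected separately at FDR ``q`` unless
    ``merge_families`` is set.  Returns one row per test.
    """
    results: list[TestResult] = []
    for hemi, window in ENVELOPE_FAMILY:
        a, b = _paired_values(envelope_df, dict(hemisphere=hemi, window=window))
        r = wilcoxon_signrank(a, b, name=f"envelope_{hemi}_{window}")
        r.family = "envelope"
        results.append(r)
    for metric in BURST_METRICS:
        for window in ("cue", "probe"):
            for hemi in ("left", "right"):
                a, b = _paired_values(
                    burst_df, dict(hemisphere=hemi, window=window, metric=metric))
                r = wilcoxon_signrank(a, b, name=f"burst_{metric}_{hemi}_{window}")
                r.family = "bursts"
                results.append(r)

    rows = pd.DataFrame(
        dict(test=r.name, family=r.family, n=r.n_effective, W=r.statistic,
             p=r.p_value, method=r.method, direction=r.direction)
        for r in results
    )
    rows["bh_rejected"] = False
    families = [rows.index] if merge_families else [
        rows.index[rows.family == f] for f in rows.family.unique()
    ]
    for idx in families:
        rows.loc[idx, "bh_rejected"] = bh_fdr(rows.loc[idx, "p"].to_numpy(), q=q)
    return rows
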