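"""Nonlinear gait descriptors: entropy-family regularity measures and
recurrence quantification analysis (RQA).

* ApEn (Pincus): Φ^m(r) − Φ^{m+1}(r), self-matches included, Chebyshev
  distance, tolerance r·SD of the series.
* SampEn (Richman–Moorman): −ln(A/B), self-matches excluded; m-length and
  (m+1)-length templates both drawn from the first N−m positions.
* MSE: SampEn of non-overlapping coarse-grained versions of the series at
  scales 1..6, with the tolerance fixed from the scale-1 SD; the curve is
  summarized by its trapezoidal area (complexity index) and least-squares
  slope. White noise loses entropy with scale; 1/f noise keeps it high.
* RQA: delay embedding (dim 5, delay 10) of the z-scored series, recurrence
  threshold at 40% of the maximum pairwise Euclidean distance, a Theiler
  window (= delay) around the line of identity, diagonal structures of
  length ≥ 2. Reports recurrence rate, determinism, diagonal-length Shannon
  entropy (nats) and MaxLine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "EntropySpec",
    "RqaSpec",
    "RqaResult",
    "apen",
    "sampen",
    "coarse_grain",
    "mse",
    "rqa",
]


@dataclass
class EntropySpec:
    m: int = 2                      # embedding (template) length
    r: float = 0.25                 # tolerance as fraction of series SD
    mse_scales: tuple = tuple(range(1, 7))

    def validate(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be > 0")
        if any(s < 1 for s in self.mse_scales):
            raise ValueError("MSE scales must be >= 1")

    @classmethod
    def for_length(cls, n: int, min_points: int = 150, **kwargs) -> "EntropySpec":
        """Spec whose MSE scale range keeps >= ``min_points`` coarse samples.

        The default 1..6 instantiates this rule for ~1000-sample (10 s walk)
        series; longer series support a wider scale range and a sharper
        white-vs-1/f complexity contrast.
        """
        tau_max = max(n // min_points, 1)
        return cls(mse_scales=tuple(range(1, tau_max + 1)), **kwargs)


@dataclass
class RqaSpec:
    embedding_dim: int = 5
    delay: int = 10                 # samples
    radius_fraction: float = 0.40   # of the maximum pairwise distance
    min_diag_length: int = 2
    theiler_window: int | None = None  # defaults to `delay`

    def validate(self) -> None:
        if self.embedding_dim < 1 or self.delay < 1:
            raise ValueError("embedding_dim and delay must be >= 1")
        if not (0 < self.radius_fraction <= 1):
            raise ValueError("radius_fraction must be in (0, 1]")

    @property
    def theiler(self) -> int:
        return self.delay if self.theiler_window is None else self.theiler_window


@dataclass
class RqaResult:
    recurrence_rate: float
    determinism: float
    entropy: float                  # nats, diagonal-length distribution
    maxline: int                    # samples
    degenerate: bool = False


def _embed(x: np.ndarray, dim: int, delay: int = 1) -> np.ndarray:
    n = len(x) - (dim - 1) * delay
    if n < 1:
        raise ValueError("series too short for this embedding")
    return np.stack([x[i * delay : i * delay + n] for i in range(dim)], axis=1)


def _check_length(x: np.ndarray, m: int) -> np.ndarray:
    x = np.asarray(x, float).ravel()
    if len(x) < 10 * (m + 1):
        raise ValueError(f"series length {len(x)} < 10·(m+1); too short")
    return x


def apen(x: np.ndarray, spec: EntropySpec | None = None) -> float:
    """Approximate entropy (self-matches included ⇒ always defined)."""
    spec = spec or EntropySpec()
    spec.validate()
    x = _check_length(x, spec.m)
    tol = spec.r * x.std()

    def phi(m: int) -> float:
        X = _embed(x, m)
        D = cdist(X, X, metric="chebyshev")
        C = (D <= tol).mean(axis=1)  # self-match included
        return float(np.mean(np.log(C)))

    return phi(spec.m) - phi(spec.m + 1)


def sampen(
    x: np.ndarray,
    spec: EntropySpec | None = None,
    tol: float | None = None,
) -> float:
    """Sample entropy −ln(A/B); NaN (flagged) when no matches exist.

    ``tol`` overrides the r·SD tolerance (used by MSE to hold the scale-1
    tolerance fixed across coarse-grained series).
    """
    spec = spec or EntropySpec()
    spec.validate()
    x = _check_length(x, spec.m)
    if tol is None:
        tol = spec.r * x.std()
    m = spec.m
    n_templates = len(x) - m  # both m- and (m+1)-templates from these starts
    Xm = _embed(x, m)[:n_templates]
    Xm1 = _embed(x, m + 1)
    iu = np.triu_indices(n_templates, k=1)
    B = int((cdist(Xm, Xm, metric="chebyshev")[iu] <= tol).sum())
    A = int((cdist(Xm1, Xm1, metric="chebyshev")[iu] <= tol).sum())
    if B == 0 or A == 0:
        warnings.warn("sample entropy undefined (no template matches)", stacklevel=2)
        return np.nan
    return float(-np.log(A / B))


def coarse_grain(x: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping window means; output length floor(n/tau)."""
    x = np.asarray(x, float).ravel()
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if tau > len(x):
        raise ValueError("tau exceeds series length")
    if tau == 1:
        return x.copy()
    n = len(x) // tau
    return x[: n * tau].reshape(n, tau).mean(axis=1)


def mse(
    x: np.ndarray, spec: EntropySpec | None = None
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Multiscale entropy curve with its area and slope summaries.

    Returns (scales_used, sampen_values, area, slope). The tolerance is
    fixed at r·SD of the scale-1 series. If SampEn becomes undefined at
    some scale the curve is truncated there (area over available scales).
    """
    spec = spec or EntropySpec()
    spec.validate()
    x = np.asarray(x, float).ravel()
    tol = spec.r * x.std()
    scales, values = [], []
    for tau in sorted(spec.mse_scales):
        cg = coarse_grain(x, tau)
        if len(cg) < 10 * (spec.m + 1):
            warnings.warn(f"MSE curve truncated at scale {tau} (series too short)", stacklevel=2)
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val = sampen(cg, spec, tol=tol)
        if not np.isfinite(val):
            warnings.warn(f"MSE curve truncated at scale {tau} (SampEn undefined)", stacklevel=2)
            break
        scales.append(tau)
        values.append(val)
    scales_arr = np.array(scales, float)
    values_arr = np.array(values, float)
    if len(values_arr) == 0:
        return scales_arr, values_arr, np.nan, np.nan
    if len(values_arr) == 1:
        return scales_arr, values_arr, 0.0, 0.0
    area = float(np.trapezoid(values_arr, scales_arr))
    slope = float(np.polyfit(scales_arr, values_arr, 1)[0])
    return scales_arr, values_arr, area, slope


def _diag_run_lengths(diag: np.ndarray) -> list[int]:
    if not diag.any():
        return []
    padded = np.concatenate([[0], diag.view(np.int8), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return (ends - starts).tolist()


def rqa(x: np.ndarray, spec: RqaSpec | None = None) -> RqaResult:
    """Recurrence quantification of one (z-scored, delay-embedded) series."""
    spec = spec or RqaSpec()
    spec.validate()
    x = np.asarray(x, float).ravel()
    min_len = (spec.embedding_dim - 1) * spec.delay + 10
    if len(x) < min_len:
        raise ValueError(f"series length {len(x)} < {min_len} for this embedding")
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else x - x.mean()
    X = _embed(z, spec.embedding_dim, spec.delay)
    n = len(X)
    D = cdist(X, X)
    dmax = D.max()
    theiler = spec.theiler
    if dmax == 0:
        warnings.warn("degenerate embedding: all points identical", stacklevel=2)
        return RqaResult(1.0, 1.0, 0.0, max(n - theiler - 1, 0), degenerate=True)
    R = D <= spec.radius_fraction * dmax

    # pairs with |i-j| > theiler only (upper triangle; counts doubled)
    total_rec = 0
    diag_lengths: list[int] = []
    for k in range(theiler + 1, n):
        diag = np.diagonal(R, offset=k)
        total_rec += int(diag.sum())
        diag_lengths.extend(_diag_run_lengths(diag))
    n_allowed = n * n - sum(
        2 * (n - k) for k in range(1, theiler + 1)
    ) - n  # minus near-diagonal band and the LOI
    rr = 2 * total_rec / n_allowed if n_allowed > 0 else np.nan

    if total_rec == 0:
        return RqaResult(0.0, 0.0, 0.0, 0, degenerate=False)
    long_lengths = [l for l in diag_lengths if l >= spec.min_diag_length]
    det = sum(long_lengths) / total_rec
    if long_lengths:
        _, counts = np.unique(long_lengths, return_counts=True)
        p = counts / counts.sum()
        ent = float(-(p * np.log(p)).sum())
        maxline = int(max(long_lengths))
    else:
        ent, maxline = 0.0, 0
    return RqaResult(float(rr), float(det), ent, maxline)
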