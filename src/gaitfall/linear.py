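"""Linear gait descriptors: spatiotemporal parameters, RMS, harmonic ratios.

All temporal parameters derive from the detected event table (first/last
stride excluded). Conventions:

* gait cycle time (GCT): ipsilateral HC→HC interval;
* step time: HC→contralateral HC;
* single-stance (support) time per foot: that foot's HC→TO interval;
* swing time per foot: TO→next ipsilateral HC;
* double support: sum of the two double-support periods inside one cycle;
* CV = SD/mean × 100 (sample SD, n−1);
* walking velocity: distance / walk duration, in cm/s;
* RMS on mean-removed walk-window accelerations; normalized RMS divides each
  axis RMS by the Euclidean norm of the three (so the squares sum to 1);
* harmonic ratio: per-stride Fourier amplitudes, Σ even / Σ odd harmonics
  1..20 for AP and V, inverted for ML; higher = smoother gait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .events import GaitEventTable

__all__ = [
    "SpatiotemporalSeries",
    "spatiotemporal",
    "summarize",
    "velocity_features",
    "rms_features",
    "harmonic_ratio",
]


@dataclass
class SpatiotemporalSeries:
    """Per-stride temporal gait parameters (seconds), NaN where a toe-off
    was undetected in the contributing cycle."""

    gait_cycle_time: np.ndarray      # both feet's ipsilateral HC→HC intervals
    step_time: np.ndarray
    swing_L: np.ndarray
    swing_R: np.ndarray
    stance_L: np.ndarray             # single-stance (HC→TO, same foot)
    stance_R: np.ndarray
    double_support: np.ndarray


def spatiotemporal(table: GaitEventTable) -> SpatiotemporalSeries:
    ev = table.included.reset_index(drop=True)
    if len(ev) < 3:
        raise ValueError("need at least one included stride")
    t = ev["hc_time"].to_numpy()
    sides = ev["side"].to_numpy()
    to = ev["to_time"].to_numpy()

    step = np.diff(t)
    gct, swing = {"L": [], "R": []}, {"L": [], "R": []}
    stance = {"L": [], "R": []}
    dst = []
    for i in range(len(ev) - 2):
        s = sides[i]
        gct[s].append(t[i + 2] - t[i])
        # TO of foot s follows the contralateral HC at i+1
        to_s = to[i + 1]
        stance[s].append(to_s - t[i] if np.isfinite(to_s) else np.nan)
        swing[s].append(t[i + 2] - to_s if np.isfinite(to_s) else np.nan)
        # two double-support periods in this cycle
        ds1 = to[i] - t[i] if np.isfinite(to[i]) else np.nan
        ds2 = to[i + 1] - t[i + 1] if np.isfinite(to[i + 1]) else np.nan
        dst.append(ds1 + ds2)
    return SpatiotemporalSeries(
        gait_cycle_time=np.array(gct["L"] + gct["R"]),
        step_time=step,
        swing_L=np.array(swing["L"]),
        swing_R=np.array(swing["R"]),
        stance_L=np.array(stance["L"]),
        stance_R=np.array(stance["R"]),
        double_support=np.array(dst),
    )


def summarize(values: np.ndarray) -> tuple[float, float, float]:
    """(mean, sample SD, CV in percent) over finite entries.

    SD/CV are NaN with fewer than two finite values; CV is NaN (flagged)
    when the mean is zero.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return np.nan, np.nan, np.nan
    mean = float(v.mean())
    if len(v) < 2:
        return mean, np.nan, np.nan
    sd = float(v.std(ddof=1))
    if mean == 0:
        warnings.warn("CV undefined for zero-mean series", stacklevel=2)
        return mean, sd, np.nan
    return mean, sd, 100.0 * sd / mean


def velocity_features(
    table: GaitEventTable, walk_distance: float, walk_duration: float
) -> dict[str, float]:
    """Walking velocity (cm/s) and times to velocity quartiles (s).

    The quartile times are operationalized through the cumulative distance
    profile: each detected step advances the participant by an equal share
    of the walk distance, and the reported time is the elapsed walk time at
    which 25/50/75% of the distance has been covered (linear interpolation
    between heel contacts).
    """
    if walk_duration <= 0:
        raise ValueError("walk duration must be positive")
    velocity = 100.0 * walk_distance / walk_duration
    ev = table.events
    t = ev["hc_time"].to_numpy()
    t0 = t[0]
    cum = np.linspace(0.0, walk_distance, len(t))
    out = {"Velocity": velocity}
    for name, q in (
        ("Time2FirstQuartile_Velocity", 0.25),
        ("Time2Median_Velocity", 0.50),
        ("Time2ThirdQuartile_Velocity", 0.75),
    ):
        out[name] = float(np.interp(q * walk_distance, cum, t) - t0)
    return out


def rms_features(ap: np.ndarray, ml: np.ndarray, v: np.ndarray) -> dict[str, float]:
    """RMS and normalized RMS of the mean-removed walk-window axes."""
    out = {}
    rms = {}
    for name, sig in (("AP", ap), ("ML", ml), ("V", v)):
        s = np.asarray(sig, float)
        s = s - s.mean()
        rms[name] = float(np.sqrt(np.mean(s * s)))
        out[f"RMS_{name}"] = rms[name]
    norm = float(np.sqrt(sum(r * r for r in rms.values())))
    if norm == 0:
        warnings.warn("all-zero signals: normalized RMS undefined", stacklevel=2)
        for name in rms:
            out[f"RMSR_{name}"] = np.nan
    else:
        for name in rms:
            out[f"RMSR_{name}"] = rms[name] / norm
    return out


def harmonic_ratio(
    axis_signal: np.ndarray,
    time: np.ndarray,
    table: GaitEventTable,
    axis: str,
    n_harmonics: int = 10,
    resample_points: int = 1024,
    cap: float = 100.0,
) -> float:
    """Stride-averaged harmonic ratio for one axis.

    Each included stride segment is linearly resampled to a common length so
    harmonic h is Fourier bin h; amplitudes of even harmonics 2..20 are
    summed against odd 1..19 (AP, V) or inverted (ML). A vanishing
    denominator caps the ratio at ``cap``.
    """
    if axis not in ("AP", "ML", "V"):
        raise ValueError("axis must be AP, ML or V")
    ev = table.included.reset_index(drop=True)
    t_hc = ev["hc_time"].to_numpy()
    sig = np.asarray(axis_signal, float)
    time = np.asarray(time, float)
    ratios = []
    for i in range(len(t_hc) - 2):
        if i % 2:  # one stride per ipsilateral pair, non-overlapping
            continue
        mask_t = np.linspace(t_hc[i], t_hc[i + 2], resample_points, endpoint=False)
        seg = np.interp(mask_t, time, sig)
        seg = seg - seg.mean()
        amps = np.abs(np.fft.rfft(seg))
        even = amps[2 : 2 * n_harmonics + 1 : 2].sum()
        odd = amps[1 : 2 * n_harmonics : 2].sum()
        num, den = (even, odd) if axis in ("AP", "V") else (odd, even)
        if den <= 1e-12 * max(num, 1e-300):
            warnings.warn("harmonic-ratio denominator ~0; capped", stacklevel=2)
            ratios.append(cap)
        else:
            ratios.append(min(num / den, cap))
    return float(np.mean(ratios)) if ratios else np.nan
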