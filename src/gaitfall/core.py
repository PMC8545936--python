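"""Core containers for trunk-worn IMU walk recordings and gait ground truth.

A recording is one 10-m walk trial: tri-axial trunk acceleration
(anteroposterior AP, mediolateral ML, vertical V, in m/s²) plus the vertical
angular velocity (deg/s), sampled uniformly, with 5 s of quiet standing
padding the walk on both sides. ``walk_start``/``walk_end`` mark the walking
window inside the record.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TrunkRecording",
    "GroundTruth",
    "TrialRejected",
    "read_trial_csv",
    "write_trial_csv",
    "read_manifest",
    "write_manifest",
    "row_hashes",
]


class TrialRejected(ValueError):
    """Raised when a trial cannot yield usable gait events/features."""


@dataclass
class TrunkRecording:
    """One synchronized trunk-IMU walk trial."""

    time: np.ndarray            # s, strictly increasing at 1/fs
    accel_ap: np.ndarray        # m/s²
    accel_ml: np.ndarray        # m/s²
    accel_v: np.ndarray         # m/s² (includes gravity offset)
    gyro_v: np.ndarray          # deg/s, vertical axis
    sampling_rate: float        # Hz
    walk_start: float           # s
    walk_end: float             # s
    walk_distance: float = 10.0  # m, protocol constant

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("accel_ap", "accel_ml", "accel_v", "gyro_v"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != time length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not (self.time[0] <= self.walk_start < self.walk_end <= self.time[-1] + 1e-9):
            raise ValueError("walk window must lie within the record span")

    @property
    def n_samples(self) -> int:
        return len(self.time)

    def walk_slice(self) -> slice:
        """Index slice covering the walking window."""
        i0 = int(np.searchsorted(self.time, self.walk_start))
        i1 = int(np.searchsorted(self.time, self.walk_end, side="right"))
        return slice(i0, i1)

    def walk_signals(self, demean: bool = True) -> dict[str, np.ndarray]:
        """Walk-window AP/ML/V and resultant signals, mean-removed by default."""
        sl = self.walk_slice()
        ap = self.accel_ap[sl]
        ml = self.accel_ml[sl]
        v = self.accel_v[sl]
        res = np.sqrt(ap * ap + ml * ml + v * v)
        out = {"AP": ap, "ML": ml, "V": v, "Res": res}
        if demean:
            out = {k: s - s.mean() for k, s in out.items()}
        return out


@dataclass
class GroundTruth:
    """Generator-known gait events for one synthetic walk (detector oracle)."""

    hc_times: np.ndarray        # s, strictly increasing, alternating feet
    to_times: np.ndarray        # s, toe-offs (one per HC except the last)
    hc_sides: np.ndarray        # 'L'/'R' per HC
    true_stride_times: np.ndarray  # s, the stride durations actually drawn

    def __post_init__(self) -> None:
        if np.any(np.diff(self.hc_times) <= 0):
            raise ValueError("hc_times must be strictly increasing")
        sides = np.asarray(self.hc_sides)
        if len(sides) != len(self.hc_times):
            raise ValueError("hc_sides length mismatch")
        if len(sides) > 1 and np.any(sides[1:] == sides[:-1]):
            raise ValueError("hc_sides must alternate")


# ---------------------------------------------------------------------------
# CSV interchange (one trial per file; cohort manifest alongside)

_TRIAL_COLUMNS = ["t", "ax_ap", "ax_ml", "ax_v", "gz"]


def write_trial_csv(rec: TrunkRecording, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "t": rec.time,
            "ax_ap": rec.accel_ap,
            "ax_ml": rec.accel_ml,
            "ax_v": rec.accel_v,
            "gz": rec.gyro_v,
        }
    )
    with open(path, "w") as fh:
        fh.write(
            f"# fs={rec.sampling_rate} walk_start={rec.walk_start} "
            f"walk_end={rec.walk_end} walk_distance={rec.walk_distance}\n"
        )
        df.to_csv(fh, index=False, float_format="%.6f")


def read_trial_csv(path: str | Path) -> TrunkRecording:
    with open(path) as fh:
        header = fh.readline()
        meta = {}
        if header.startswith("#"):
            for tok in header[1:].split():
                k, _, v = tok.partition("=")
                meta[k] = float(v)
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    missing = [c for c in _TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV missing columns: {missing}")
    t = df["t"].to_numpy(float)
    fs = meta.get("fs", 1.0 / np.median(np.diff(t)))
    return TrunkRecording(
        time=t,
        accel_ap=df["ax_ap"].to_numpy(float),
        accel_ml=df["ax_ml"].to_numpy(float),
        accel_v=df["ax_v"].to_numpy(float),
        gyro_v=df["gz"].to_numpy(float),
        sampling_rate=fs,
        walk_start=meta.get("walk_start", t[0]),
        walk_end=meta.get("walk_end", t[-1]),
        walk_distance=meta.get("walk_distance", 10.0),
    )


def write_manifest(rows: list[dict], path: str | Path) -> None:
    """Cohort manifest: participant_id, trial_id, file, label."""
    pd.DataFrame(rows, columns=["participant_id", "trial_id", "file", "label"]).to_csv(
        path, index=False
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant_id", "trial_id", "file", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    return df


def row_hashes(X: np.ndarray) -> set[str]:
    """SHA-256 per row of a float matrix (rounded to 12 decimals).

    Used by the pipeline's blind-test isolation audit: every matrix consumed
    by a fit-type operation is hashed row-wise, and held-out rows must never
    appear among fit inputs.
    """
    X = np.asarray(X, float)
    out = set()
    for row in np.atleast_2d(X):
        out.add(hashlib.sha256(np.round(row, 12).tobytes()).hexdigest())
    return out
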