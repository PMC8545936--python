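"""Synthetic trunk-IMU walk and cohort generator with known gait ground truth.

Emulates the statistical structure a sternum-worn IMU sees during a 10-m
walk at 100 Hz: stride-periodic harmonics (AP and V dominated by even stride
harmonics — two oscillations per stride; ML by odd harmonics — one per
stride), stride-time variability, a white/pink (1/f) noise mixture, a
push-off transient in AP at every toe-off, and a smooth vertical angular
velocity whose sign tracks the stance side. Five seconds of quiet standing
pad the walk on both ends, matching the walking protocol the analysis
assumes.

Every generated walk carries a :class:`~gaitfall.core.GroundTruth` with the
exact heel-contact/toe-off schedule, so the whole downstream stack (event
detection → descriptors → classifier) can be validated by parameter
recovery rather than against withheld human data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import GroundTruth, TrunkRecording, write_manifest, write_trial_csv

__all__ = [
    "WalkSpec",
    "FallerEffect",
    "CohortSpec",
    "Participant",
    "Cohort",
    "generate_walk",
    "generate_cohort",
    "pink_noise",
]

GRAVITY = 9.81

# Default per-axis stride-harmonic amplitudes (m/s²), harmonics 1..10.
# AP/V even-dominant (step periodicity), ML odd-dominant (stride periodicity).
_DEFAULT_HARMONICS = {
    "AP": [0.15, 0.55, 0.05, 0.18, 0.02, 0.08, 0.01, 0.04, 0.005, 0.02],
    "V": [0.20, 1.00, 0.08, 0.30, 0.03, 0.12, 0.015, 0.05, 0.01, 0.02],
    "ML": [0.45, 0.08, 0.18, 0.03, 0.08, 0.015, 0.04, 0.01, 0.02, 0.005],
}

# Axis → indices (1-based harmonics) that dominate; the faller smoothness
# attenuation acts on these.
_DOMINANT = {"AP": (2, 4, 6, 8, 10), "V": (2, 4, 6, 8, 10), "ML": (1, 3, 5, 7, 9)}


@dataclass
class WalkSpec:
    """Parameters of one synthetic walk trial."""

    sampling_rate: float = 100.0        # Hz
    walk_distance: float = 10.0         # m
    mean_speed: float = 1.0             # m/s
    mean_stride_time: float = 1.1       # s
    stride_time_cv: float = 3.0         # percent
    step_asymmetry: float = 0.01        # fraction of stride time added to 1st step
    swing_fraction: float = 0.40        # of gait cycle (per foot)
    double_support_fraction: float = 0.20  # of gait cycle (both DS periods)
    harmonic_amplitudes: dict = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_HARMONICS.items()}
    )
    noise_sd: float = 0.12              # m/s², per acceleration axis
    pink_noise_fraction: float = 0.30   # share of noise variance that is 1/f
    standing_pad: float = 5.0           # s of quiet standing each side
    to_bump_amplitude: float = 1.0      # m/s², AP push-off transient at TO
    to_bump_width: float = 0.025        # s (Gaussian sigma)
    gyro_amplitude: float = 30.0        # deg/s
    gyro_noise_sd: float = 1.0          # deg/s

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not (0 < self.stride_time_cv < 100):
            raise ValueError("stride_time_cv must be in (0, 100) percent")
        if self.swing_fraction + self.double_support_fraction >= 1:
            raise ValueError("swing + double-support fractions must be < 1")
        if not (0 <= self.pink_noise_fraction <= 1):
            raise ValueError("pink_noise_fraction must be in [0, 1]")
        if self.mean_speed <= 0 or self.walk_distance <= 0:
            raise ValueError("speed and distance must be positive")


@dataclass
class FallerEffect:
    """Shifts applied to a walk spec to produce the faller gait phenotype.

    Encodes the qualitative picture of at-risk gait: more stride-time
    variability, altered temporal complexity of the acceleration signal,
    reduced smoothness (attenuated dominant harmonics), and slower walking.
    """

    stride_cv_multiplier: float = 1.5
    pink_fraction_shift: float = 0.2
    harmonic_ratio_attenuation: float = 0.7
    speed_shift: float = -0.1           # m/s

    def __post_init__(self) -> None:
        if self.stride_cv_multiplier <= 0 or self.harmonic_ratio_attenuation <= 0:
            raise ValueError("multipliers must be > 0")

    @classmethod
    def neutral(cls) -> "FallerEffect":
        return cls(1.0, 0.0, 1.0, 0.0)

    def apply(self, spec: WalkSpec) -> WalkSpec:
        amps = {k: list(v) for k, v in spec.harmonic_amplitudes.items()}
        for axis, dom in _DOMINANT.items():
            for h in dom:
                amps[axis][h - 1] *= self.harmonic_ratio_attenuation
        return dataclasses.replace(
            spec,
            stride_time_cv=spec.stride_time_cv * self.stride_cv_multiplier,
            pink_noise_fraction=float(
                np.clip(spec.pink_noise_fraction + self.pink_fraction_shift, 0.0, 1.0)
            ),
            mean_speed=max(spec.mean_speed + self.speed_shift, 0.2),
            harmonic_amplitudes=amps,
        )


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise by spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # keep DC finite; removed below anyway
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _mixed_noise(n: int, sd: float, pink_frac: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        # keep RNG stream advancing identically whether or not noise is on
        rng.standard_normal(n)
        pink_noise(n, rng)
        return np.zeros(n)
    w = rng.standard_normal(n)
    p = pink_noise(n, rng)
    return sd * (np.sqrt(1.0 - pink_frac) * w + np.sqrt(pink_frac) * p)


def generate_walk(
    spec: WalkSpec,
    faller_effect: FallerEffect | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[TrunkRecording, GroundTruth]:
    """Generate one walk trial and its exact gait-event schedule.

    The signal is built on a piecewise-linear stride phase anchored at the
    heel contacts, so every sine harmonic has its maximum slope exactly at
    each HC — the landmark the CWT event detector looks for in real trunk
    data. Toe-offs are marked by a negative Gaussian transient in AP.
    """
    if faller_effect is not None:
        spec = faller_effect.apply(spec)
    spec.validate()
    rng = np.random.default_rng(seed)
    fs = spec.sampling_rate
    dt = 1.0 / fs

    walk_time = spec.walk_distance / spec.mean_speed
    n_strides = int(round(walk_time / spec.mean_stride_time))
    if n_strides < 3:
        raise ValueError(
            f"walk of {spec.walk_distance} m at {spec.mean_speed} m/s yields "
            f"{n_strides} strides (< 3); not a usable walk"
        )

    # Stride durations and the alternating heel-contact schedule.
    sd_stride = spec.mean_stride_time * spec.stride_time_cv / 100.0
    stride_times = rng.normal(spec.mean_stride_time, sd_stride, n_strides)
    stride_times = np.clip(stride_times, 0.4 * spec.mean_stride_time, None)
    c = 0.5 + spec.step_asymmetry  # first-step share of the stride

    lead = 0.25 * spec.mean_stride_time
    t_first_hc = spec.standing_pad + lead
    # ipsilateral HC grid (foot A) + contralateral offsets (foot B); the
    # step-phase jitter (sd = half the stride sd) gives the second foot the
    # same stride-time CV as the first instead of an averaged, smaller one
    hc_a = t_first_hc + np.concatenate([[0.0], np.cumsum(stride_times)])
    step_jitter = rng.normal(0.0, 0.5 * sd_stride, n_strides)
    hc_b = hc_a[:-1] + np.clip(c * stride_times + step_jitter,
                               0.15 * stride_times, 0.85 * stride_times)
    hc_times = np.sort(np.concatenate([hc_a, hc_b]))

    first_side = "R" if rng.random() < 0.5 else "L"
    other = "L" if first_side == "R" else "R"
    hc_sides = np.array([first_side, other] * len(hc_times))[: len(hc_times)]

    # Toe-off of the contralateral foot follows each HC by half the
    # double-support fraction of the local stride.
    stride_of_event = np.clip(np.searchsorted(hc_a, hc_times, side="right") - 1, 0, n_strides - 1)
    ds_half = 0.5 * spec.double_support_fraction
    to_times = hc_times[:-1] + ds_half * stride_times[stride_of_event[:-1]]

    t_last_hc = hc_a[-1]
    walk_start = spec.standing_pad
    walk_end = t_last_hc + lead
    total = walk_end + spec.standing_pad
    n = int(round(total * fs))
    time = np.arange(n) * dt

    # Piecewise-linear stride phase through (hc_i, i/2), extended a quarter
    # stride before the first and after the last HC.
    phase_knots_t = np.concatenate([[walk_start], hc_times, [walk_end]])
    phase_knots_p = np.concatenate([[-0.25], np.arange(len(hc_times)) / 2.0, [len(hc_times) / 2.0 - 0.5 + 0.25]])
    phase = np.interp(time, phase_knots_t, phase_knots_p)

    in_walk = (time >= walk_start) & (time <= walk_end)
    env = np.zeros(n)
    env[in_walk] = 1.0
    ramp_in = in_walk & (time < t_first_hc)
    env[ramp_in] = np.sin(0.5 * np.pi * (time[ramp_in] - walk_start) / lead) ** 2
    ramp_out = in_walk & (time > t_last_hc)
    env[ramp_out] = np.cos(0.5 * np.pi * (time[ramp_out] - t_last_hc) / lead) ** 2

    def harmonic_signal(axis: str) -> np.ndarray:
        amps = spec.harmonic_amplitudes[axis]
        sig = np.zeros(n)
        for h, a in enumerate(amps, start=1):
            if a:
                sig += a * np.sin(2.0 * np.pi * h * phase)
        return sig * env

    ap = harmonic_signal("AP")
    ml = harmonic_signal("ML")
    v = harmonic_signal("V")

    # AP push-off transient at each toe-off (sharp local minimum).
    if spec.to_bump_amplitude:
        sig_w = spec.to_bump_width
        for t_to in to_times:
            i0 = max(int((t_to - 5 * sig_w) * fs), 0)
            i1 = min(int((t_to + 5 * sig_w) * fs) + 1, n)
            seg = time[i0:i1]
            ap[i0:i1] -= (
                spec.to_bump_amplitude
                * np.exp(-0.5 * ((seg - t_to) / sig_w) ** 2)
                * env[i0:i1]
            )

    pf = spec.pink_noise_fraction
    ap = ap + _mixed_noise(n, spec.noise_sd, pf, rng)
    ml = ml + _mixed_noise(n, spec.noise_sd, pf, rng)
    v = v + GRAVITY + _mixed_noise(n, spec.noise_sd, pf, rng)

    # Vertical angular velocity: smooth, sign-alternating with stance side,
    # equal to ±gyro_amplitude exactly at each HC. side 'R' ↔ positive sign.
    step_idx = np.clip(np.searchsorted(hc_times, time, side="right") - 1, 0, len(hc_times) - 1)
    signs = np.where(hc_sides == "R", 1.0, -1.0)[step_idx]
    step_frac = np.clip(2.0 * (phase - step_idx / 2.0), 0.0, 1.0)
    gyro = spec.gyro_amplitude * signs * np.cos(np.pi * step_frac) * env
    # before the first HC the sign is the first side's, ramping up with env
    pre = in_walk & (time < t_first_hc)
    gyro[pre] = spec.gyro_amplitude * (1.0 if first_side == "R" else -1.0) * env[pre]
    gyro = gyro + (spec.gyro_noise_sd * rng.standard_normal(n) if spec.gyro_noise_sd else 0.0)

    rec = TrunkRecording(
        time=time,
        accel_ap=ap,
        accel_ml=ml,
        accel_v=v,
        gyro_v=gyro,
        sampling_rate=fs,
        walk_start=walk_start,
        walk_end=walk_end,
        walk_distance=spec.walk_distance,
    )
    truth = GroundTruth(
        hc_times=hc_times,
        to_times=to_times,
        hc_sides=hc_sides,
        true_stride_times=stride_times,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortSpec:
    """A labeled faller / non-faller cohort with train and blind-test splits."""

    n_train: int = 127
    n_test: int = 44
    faller_fraction_train: float = 25 / 127
    faller_fraction_test: float = 9 / 44
    effect: FallerEffect = field(default_factory=FallerEffect)
    seed: int = 0
    base_walk: WalkSpec = field(default_factory=WalkSpec)
    n_trials: int = 2

    def validate(self) -> None:
        if self.n_train < 0 or self.n_test < 0:
            raise ValueError("cohort counts must be >= 0")
        for f in (self.faller_fraction_train, self.faller_fraction_test):
            if not (0 <= f <= 1):
                raise ValueError("faller fractions must be in [0, 1]")


@dataclass
class Participant:
    participant_id: str
    label: int                     # 1 = faller
    split: str                     # 'train' | 'test'
    trials: list                   # [(TrunkRecording, GroundTruth), ...]


@dataclass
class Cohort:
    spec: CohortSpec
    participants: list

    @property
    def train(self) -> list:
        return [p for p in self.participants if p.split == "train"]

    @property
    def test(self) -> list:
        return [p for p in self.participants if p.split == "test"]


def _participant_spec(
    base: WalkSpec, rng: np.random.Generator
) -> WalkSpec:
    """Draw between-participant gait heterogeneity around the base spec.

    Spreads chosen so that the faller effect shifts distributions by roughly
    0.7–1.2 within-class SDs per affected feature: separable but overlapping
    classes, as in real cohorts.
    """
    amps = {k: list(v) for k, v in base.harmonic_amplitudes.items()}
    amp_factor = rng.lognormal(0.0, 0.25)
    for axis, dom in _DOMINANT.items():
        for h in dom:
            amps[axis][h - 1] *= amp_factor
    return dataclasses.replace(
        base,
        mean_speed=float(np.clip(rng.normal(base.mean_speed, 0.10), 0.4, None)),
        mean_stride_time=float(np.clip(rng.normal(base.mean_stride_time, 0.08), 0.7, 1.6)),
        stride_time_cv=float(np.clip(base.stride_time_cv * rng.lognormal(0.0, 0.4), 0.5, 30.0)),
        pink_noise_fraction=float(np.clip(rng.normal(base.pink_noise_fraction, 0.15), 0.02, 0.95)),
        noise_sd=float(np.clip(rng.normal(base.noise_sd, 0.03), 0.05, None)),
        step_asymmetry=float(np.clip(rng.normal(0.01, 0.008), 0.0, 0.05)),
        harmonic_amplitudes=amps,
    )


def generate_cohort(cspec: CohortSpec) -> Cohort:
    """Generate the full labeled cohort, reproducibly from ``cspec.seed``.

    Exactly ``round(n · fraction)`` fallers per split; fallers get the
    :class:`FallerEffect` applied on top of their individual gait parameters.
    """
    cspec.validate()
    root = np.random.SeedSequence(cspec.seed)
    participants: list[Participant] = []
    pid = 0
    for split, n, frac in (
        ("train", cspec.n_train, cspec.faller_fraction_train),
        ("test", cspec.n_test, cspec.faller_fraction_test),
    ):
        n_fallers = int(round(n * frac))
        if split == "train" and cspec.n_train > 0 and (n_fallers == 0 or n_fallers == n):
            import warnings

            warnings.warn(
                "training split has a single class; downstream training will reject it",
                stacklevel=2,
            )
        split_ss, label_ss = np.random.SeedSequence((cspec.seed, pid, 7)).spawn(2)
        label_rng = np.random.default_rng(label_ss)
        labels = np.zeros(n, dtype=int)
        labels[label_rng.permutation(n)[:n_fallers]] = 1
        part_seeds = split_ss.spawn(max(n, 1))
        for i in range(n):
            pid += 1
            ss = part_seeds[i]
            param_ss, *trial_ss = ss.spawn(1 + cspec.n_trials)
            spec_i = _participant_spec(cspec.base_walk, np.random.default_rng(param_ss))
            effect = cspec.effect if labels[i] == 1 else None
            trials = [
                generate_walk(spec_i, faller_effect=effect, seed=tss)
                for tss in trial_ss
            ]
            participants.append(
                Participant(
                    participant_id=f"P{pid:04d}", label=int(labels[i]),
                    split=split, trials=trials,
                )
            )
    return Cohort(spec=cspec, participants=participants)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write per-trial CSVs plus a cohort manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort.participants:
        for j, (rec, _) in enumerate(p.trials, start=1):
            fname = f"{p.participant_id}_t{j}.csv"
            write_trial_csv(rec, out / fname)
            rows.append(
                {
                    "participant_id": p.participant_id,
                    "trial_id": j,
                    "file": fname,
                    "label": p.label,
                    "split": p.split,
                }
            )
    import pandas as pd

    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
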