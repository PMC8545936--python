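"""The 58-descriptor gait feature vector and its extraction.

One feature vector per participant: each 10-m trial is processed through
event detection and the linear/nonlinear descriptor blocks, and the two
trials are averaged. Feature names and their linear/nonlinear category
follow the published descriptor list verbatim (including its binning of
RMS_AP with the nonlinear block); ApEn/SampEn of the resultant are emitted
as auxiliary columns outside the 58.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import TrialRejected, TrunkRecording, read_manifest, read_trial_csv
from .events import CwtSpec, FilterSpec, GaitEventTable, detect_events
from .linear import harmonic_ratio, rms_features, spatiotemporal, summarize, velocity_features
from .nonlinear import EntropySpec, RqaSpec, apen, mse, rqa, sampen

# (name, category) in the published table's order; category 'L' or 'NL'.
FEATURES: list[tuple[str, str]] = [
    ("RQA_AP_Ent", "NL"), ("MSE_AP_area", "NL"), ("RSwT_sdTotal", "L"),
    ("StepTime_mean", "L"), ("RSwt_cv", "L"), ("Velocity", "L"),
    ("LSwT_cv", "L"), ("DST_cv", "L"), ("LSST_mean", "L"),
    ("Time2FirstQuartile_Velocity", "L"), ("Time2Median_Velocity", "L"),
    ("RMS_AP", "NL"), ("DST_sdTotal", "L"), ("HR_ML", "L"), ("RMS_ML", "L"),
    ("Time2ThirdQuartile_Velocity", "L"), ("RQA_ML_MaxLine", "NL"),
    ("GCTime_cv", "L"), ("RQA_Res_MaxLine", "NL"), ("RSST_mean", "L"),
    ("RQA_V_MaxLine", "NL"), ("MSE_AP_slope", "NL"), ("LSwT_mean", "L"),
    ("RQA_AP_Det", "NL"), ("MSE_ML_area", "NL"), ("StepTime_sdTotal", "L"),
    ("RQA_V_Rec", "NL"), ("RSST_sdTotal", "L"), ("MSE_Res_slope", "NL"),
    ("RQA_AP_Rec", "NL"), ("RMSR_V", "L"), ("DST_mean", "L"),
    ("GCTime_sdTotal", "L"), ("LSwT_sdTotal", "L"), ("RMSR_AP", "L"),
    ("RQA_V_Ent", "NL"), ("MSE_Res_area", "NL"), ("RQA_ML_Rec", "NL"),
    ("LSST_sdTotal", "L"), ("StepTime_cv", "L"), ("HR_V", "L"),
    ("RSwT_mean", "L"), ("RMSR_ML", "L"), ("MSE_ML_slope", "NL"),
    ("MSE_V_slope", "NL"), ("GCTime_mean", "L"), ("RMS_V", "L"),
    ("MSE_V_area", "NL"), ("RQA_Res_Ent", "NL"), ("RQA_Res_Det", "NL"),
    ("RQA_AP_MaxLine", "NL"), ("RQA_V_Det", "NL"), ("RSST_cv", "L"),
    ("RQA_ML_Det", "NL"), ("RQA_ML_Ent", "NL"), ("LSST_cv", "L"),
    ("RQA_Res_Rec", "NL"), ("HR_AP", "L"),
]

FEATURE_NAMES = [n for n, _ in FEATURES]
LINEAR_FEATURES = [n for n, c in FEATURES if c == "L"]
NONLINEAR_FEATURES = [n for n, c in FEATURES if c == "NL"]
AUXILIARY_FEATURES = ["ApEn_Res", "SampEn_Res"]

assert len(FEATURE_NAMES) == 58 and len(LINEAR_FEATURES) == 33


def extract_trial_features(
    rec: TrunkRecording,
    fspec: FilterSpec | None = None,
    cspec: CwtSpec | None = None,
    espec: EntropySpec | None = None,
    rspec: RqaSpec | None = None,
    table: GaitEventTable | None = None,
    include_auxiliary: bool = True,
) -> dict[str, float]:
    """All 58 descriptors (plus auxiliary entropies) for one trial.

    Raises :class:`TrialRejected` when too few strides are detected.
    """
    espec = espec or EntropySpec()
    rspec = rspec or RqaSpec()
    if table is None:
        table = detect_events(rec, fspec, cspec)
    out: dict[str, float] = {}

    st = spatiotemporal(table)
    for prefix, series in (
        ("GCTime", st.gait_cycle_time),
        ("StepTime", st.step_time),
        ("DST", st.double_support),
        ("LSwT", st.swing_L),
        ("RSwT", st.swing_R),
        ("LSST", st.stance_L),
        ("RSST", st.stance_R),
    ):
        mean, sd, cv = summarize(series)
        out[f"{prefix}_mean"] = mean
        out[f"{prefix}_sdTotal"] = sd
        out[f"{prefix}_cv"] = cv
    # the published list spells the right-swing CV with a lowercase t
    out["RSwt_cv"] = out.pop("RSwT_cv")

    out.update(
        velocity_features(table, rec.walk_distance, rec.walk_end - rec.walk_start)
    )

    sigs = rec.walk_signals(demean=True)
    out.update(rms_features(sigs["AP"], sigs["ML"], sigs["V"]))

    sl = rec.walk_slice()
    t_walk = rec.time[sl]
    for axis, full in (("AP", rec.accel_ap), ("ML", rec.accel_ml), ("V", rec.accel_v)):
        out[f"HR_{axis}"] = harmonic_ratio(full[sl], t_walk, table, axis)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for axis in ("AP", "ML", "V", "Res"):
            sig = sigs[axis]
            _, _, area, slope = mse(sig, espec)
            out[f"MSE_{axis}_area"] = area
            out[f"MSE_{axis}_slope"] = slope
            r = rqa(sig, rspec)
            out[f"RQA_{axis}_Rec"] = r.recurrence_rate
            out[f"RQA_{axis}_Det"] = r.determinism
            out[f"RQA_{axis}_Ent"] = r.entropy
            out[f"RQA_{axis}_MaxLine"] = float(r.maxline)
        if include_auxiliary:
            out["ApEn_Res"] = apen(sigs["Res"], espec)
            out["SampEn_Res"] = sampen(sigs["Res"], espec)

    missing = [k for k in FEATURE_NAMES if k not in out]
    if missing:
        raise RuntimeError(f"descriptor block incomplete: {missing}")
    return out


def participant_features(
    trial_features: list[dict[str, float]],
) -> dict[str, float]:
    """Average descriptor dicts across a participant's trials (NaN-aware)."""
    if not trial_features:
        raise ValueError("no trials to aggregate")
    keys = trial_features[0].keys()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return {
            k: float(np.nanmean([tf[k] for tf in trial_features])) for k in keys
        }


def extract_cohort_features(
    participants,
    include_auxiliary: bool = False,
    on_reject: str = "drop",
    **specs,
) -> pd.DataFrame:
    """Feature table (one row per participant) from in-memory cohort data.

    Returns a DataFrame indexed by participant id with the 58 descriptor
    columns plus ``label`` and ``split``. Participants whose every trial is
    rejected are dropped with a warning (or re-raised if on_reject='raise').
    """
    rows = {}
    meta = {}
    for p in participants:
        feats = []
        for rec, _ in p.trials:
            try:
                feats.append(
                    extract_trial_features(rec, include_auxiliary=include_auxiliary, **specs)
                )
            except TrialRejected as exc:
                warnings.warn(
                    f"{p.participant_id}: trial rejected ({exc})", stacklevel=2
                )
        if not feats:
            if on_reject == "raise":
                raise TrialRejected(f"{p.participant_id}: all trials rejected")
            warnings.warn(f"{p.participant_id}: dropped (no usable trials)", stacklevel=2)
            continue
        rows[p.participant_id] = participant_features(feats)
        meta[p.participant_id] = (p.label, p.split)
    df = pd.DataFrame.from_dict(rows, orient="index")
    cols = FEATURE_NAMES + [c for c in df.columns if c not in FEATURE_NAMES]
    df = df[cols]
    df["label"] = [meta[i][0] for i in df.index]
    df["split"] = [meta[i][1] for i in df.index]
    df.index.name = "participant_id"
    return df


def extract_manifest_features(
    manifest_path: str | Path, include_auxiliary: bool = False, **specs
) -> pd.DataFrame:
    """Feature table from a cohort manifest CSV on disk."""
    manifest = read_manifest(manifest_path)
    base = Path(manifest_path).parent

    class _P:  # adapter matching the Participant interface
        def __init__(self, pid, label, split, trials):
            self.participant_id, self.label, self.split, self.trials = (
                pid, label, split, trials,
            )

    participants = []
    for pid, grp in manifest.groupby("participant_id", sort=True):
        trials = [(read_trial_csv(base / f), None) for f in grp["file"]]
        split = grp["split"].iloc[0] if "split" in grp else "train"
        participants.append(_P(pid, int(grp["label"].iloc[0]), split, trials))
    return extract_cohort_features(
        participants, include_auxiliary=include_auxiliary, **specs
    )
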