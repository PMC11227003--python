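"""Survey cleaning, outcome binarization, time-block assignment and
patient-inclusion rules.

Surveys are rows of a DataFrame with columns ``survey_id, patient_id,
timestamp_s, pas_vocal, pas_motor, pas_aggr, pas_resist, rass``.  PAS items
are observer ratings on a 0-4 scale; RASS is carried through but not
modeled.  Outcomes are derived, never stored independently:

* ``agitated``        = 1 iff the PAS total (sum of the four items) > 0
* ``motor_agitated``  = 1 iff the motor item > 0
* ``verbal_agitated`` = 1 iff the vocalization item > 0

``time_group`` partitions the 24 h clock into 1: 8-12 h, 2: 12-16 h,
3: 16-20 h, 4: 20-8 h (wrap-around), used as a categorical fixed effect to
absorb sundowning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

PAS_ITEMS = ("pas_vocal", "pas_motor", "pas_aggr", "pas_resist")
OUTCOMES = ("agitated", "motor_agitated", "verbal_agitated")

DUPLICATE_GAP_S = 300.0  # "within 5 min of the previous"


def deduplicate(surveys: pd.DataFrame) -> pd.DataFrame:
    """Drop any survey occurring strictly within 5 min of the previously
    *retained* survey of the same patient (sequential scan in time order;
    the earlier survey is kept).  Idempotent."""
    kept_idx: list = []
    for _, grp in surveys.sort_values(["patient_id", "timestamp_s"]).groupby(
            "patient_id", sort=False):
        last = -np.inf
        for idx, t in zip(grp.index, grp["timestamp_s"].to_numpy()):
            if t - last >= DUPLICATE_GAP_S or not np.isfinite(last):
                kept_idx.append(idx)
                last = t
    return surveys.loc[sorted(kept_idx)]


def binarize_outcomes(surveys: pd.DataFrame) -> pd.DataFrame:
    """Derive the three binary outcomes from the PAS items."""
    df = surveys.copy()
    total = sum(df[item] for item in PAS_ITEMS)
    df["agitated"] = (total > 0).astype(int)
    df["motor_agitated"] = (df["pas_motor"] > 0).astype(int)
    df["verbal_agitated"] = (df["pas_vocal"] > 0).astype(int)
    return df


def assign_time_group(timestamp_s):
    """Map timestamps (s since midnight of day 1) to clock blocks 1-4.

    Half-open blocks [8,12) -> 1, [12,16) -> 2, [16,20) -> 3, the rest
    (20-24 and 0-8, the overnight block) -> 4.  Accepts scalars or arrays.
    """
    hour = (np.asarray(timestamp_s, dtype=float) % 86400.0) / 3600.0
    group = np.full(hour.shape, 4, dtype=int)
    group[(hour >= 8) & (hour < 12)] = 1
    group[(hour >= 12) & (hour < 16)] = 2
    group[(hour >= 16) & (hour < 20)] = 3
    if group.ndim == 0:
        return int(group)
    return group


def apply_inclusion_rules(feature_table: pd.DataFrame,
                          min_surveys: int = 2) -> pd.DataFrame:
    """Per modality, drop patients contributing fewer than 2 kept surveys.

    Exclusion in one modality leaves the patient's other modalities intact.
    Expects one row per (survey, modality, series, feature) of *kept*
    windows.
    """
    counts = (feature_table.groupby(["modality", "patient_id"])["survey_id"]
              .nunique().rename("n_surveys").reset_index())
    ok = counts[counts["n_surveys"] >= min_surveys][["modality", "patient_id"]]
    return feature_table.merge(ok, on=["modality", "patient_id"], how="inner")


def select_visualization_subset(feature_table: pd.DataFrame,
                                surveys: pd.DataFrame,
                                n_patients: int = 5) -> list:
    """Patients with consistent data availability: at least two agitated
    surveys of each type (motor, verbal) and two non-agitated surveys with
    kept windows in every sensor modality.  Deterministic ordering (by the
    number of kept surveys, descending, then patient id); at most
    ``n_patients`` returned.
    """
    if feature_table.empty or surveys.empty:
        warnings.warn("empty cohort: visualization subset is empty")
        return []
    kept = (feature_table[["survey_id", "patient_id", "modality"]]
            .drop_duplicates()
            .merge(surveys[["survey_id", "motor_agitated", "verbal_agitated",
                            "agitated"]], on="survey_id"))
    modalities = sorted(kept["modality"].unique())
    eligible = []
    for pid, grp in kept.groupby("patient_id"):
        ok = True
        for m in modalities:
            g = grp[grp["modality"] == m]
            if ((g["motor_agitated"] == 1).sum() < 2
                    or (g["verbal_agitated"] == 1).sum() < 2
                    or (g["agitated"] == 0).sum() < 2):
                ok = False
                break
        if ok:
            eligible.append((len(grp), pid))
    eligible.sort(key=lambda e: (-e[0], e[1]))
    return [pid for _, pid in eligible[:n_patients]]
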