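"""Summary surfaces of the analysis: agitation proportion per time block,
coefficient/significance table, and median standardized-difference
breakdowns by agitation type and by patient.

All outputs are deterministic tabular data (the canonical artifact); plot
rendering is left to the consumer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MODALITY_ORDER = ("acc", "eda", "hr", "st")


def proportion_by_time_group(surveys: pd.DataFrame) -> pd.DataFrame:
    """Per patient and clock block: agitated / total among kept surveys.

    Blocks in which a patient has no surveys are reported missing (NaN),
    never zero.  Wide format: one row per patient, columns block 1-4.
    """
    out = {}
    for pid, grp in surveys.groupby("patient_id"):
        row = {}
        for block in (1, 2, 3, 4):
            sub = grp[grp["time_group"] == block]
            row[block] = sub["agitated"].mean() if len(sub) else np.nan
        out[pid] = row
    df = pd.DataFrame.from_dict(out, orient="index").sort_index()
    df.index.name = "patient_id"
    df.columns = [f"block{b}" for b in df.columns]
    return df


def _median_or_nan(x: pd.Series) -> float:
    return float(x.median()) if len(x) else np.nan


def median_difference_table(analysis: pd.DataFrame,
                            grouping: str = "agitation_type",
                            patient_subset: list | None = None
                            ) -> pd.DataFrame:
    """Median standardized feature value in a group minus the median among
    non-agitated surveys (the reference at 0); no significance tests and no
    confounder adjustment, by design.

    grouping='agitation_type': motor-agitated and verbal-agitated groups vs
    all non-agitated surveys ('both'-type surveys enter both groups; flagged
    in the ``n_*`` metadata).  grouping='patient': all-agitated vs
    non-agitated per patient, usually on the visualization subset.
    Untruncated values are reported; groups with n < 2 are flagged.
    """
    if grouping not in ("agitation_type", "patient"):
        raise ValueError("grouping must be 'agitation_type' or 'patient'")
    df = analysis
    if patient_subset is not None:
        df = df[df["patient_id"].isin(patient_subset)]
    rows = []
    for (series, feature), grp in df.groupby(["series", "feature"]):
        ref = grp[grp["agitated"] == 0]["z"]
        if grouping == "agitation_type":
            for kind, col in (("motor", "motor_agitated"),
                              ("verbal", "verbal_agitated")):
                agi = grp[grp[col] == 1]["z"]
                rows.append({
                    "grouping": "agitation_type", "group": kind,
                    "series": series, "feature": feature,
                    "median_difference": _median_or_nan(agi) - _median_or_nan(ref),
                    "n_group": len(agi), "n_reference": len(ref),
                    "low_n": len(agi) < 2 or len(ref) < 2,
                })
        else:
            for pid, pgrp in grp.groupby("patient_id"):
                agi = pgrp[pgrp["agitated"] == 1]["z"]
                pref = pgrp[pgrp["agitated"] == 0]["z"]
                rows.append({
                    "grouping": "patient", "group": pid,
                    "series": series, "feature": feature,
                    "median_difference": _median_or_nan(agi) - _median_or_nan(pref),
                    "n_group": len(agi), "n_reference": len(pref),
                    "low_n": len(agi) < 2 or len(pref) < 2,
                })
    cols = ["grouping", "group", "series", "feature", "median_difference",
            "n_group", "n_reference", "low_n"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["series", "feature", "group"], ignore_index=True)


def significance_stars(p: float) -> str:
    """Star coding: * p<.05, ** p<.01, *** p<.001; empty otherwise."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def coefficient_table(fits: pd.DataFrame) -> pd.DataFrame:
    """Per (modality, series, feature, outcome): beta, SE, p and stars,
    grouped by modality in the fixed order acc, eda, hr, st — the
    machine-readable data behind a forest-style coefficient plot."""
    df = fits.copy()
    df["stars"] = df["p"].map(significance_stars)
    df["modality"] = pd.Categorical(df["modality"], MODALITY_ORDER,
                                    ordered=True)
    df = df.sort_values(["modality", "series", "feature", "outcome"],
                        ignore_index=True)
    df["modality"] = df["modality"].astype(str)
    return df
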