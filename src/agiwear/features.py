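"""Minimal statistical features per kept window and within-patient z-scoring.

Each kept window yields min, max, median, mean and sample SD of its series;
skin-temperature windows additionally yield the OLS slope (degC/min) to
capture drift in this slow-varying signal.  Features are then centered and
scaled within each patient, so model coefficients read as log-odds per
within-patient SD.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BASIC_FEATURES = ("min", "max", "median", "mean", "sd")

#: Feature names per modality series as they enter the models.
SERIES_FEATURES = {
    "acc_magnitude": BASIC_FEATURES,
    "hr": BASIC_FEATURES,
    "eda_full": BASIC_FEATURES,
    "eda_tonic": BASIC_FEATURES,
    "eda_phasic": BASIC_FEATURES,
    "st": BASIC_FEATURES + ("slope",),
}


def extract_features(values: np.ndarray, times: np.ndarray | None = None,
                     with_slope: bool = False) -> dict[str, float]:
    """Summary statistics of one window series, NaN samples excluded.

    ``sd`` is the sample standard deviation (denominator n-1).  ``slope`` is
    the ordinary-least-squares slope of value against time in degC/min and
    requires ``times`` (seconds).  Raises on fewer than 2 finite samples.
    """
    v = np.asarray(values, dtype=float)
    mask = np.isfinite(v)
    if mask.sum() < 2:
        raise ValueError("feature extraction needs at least 2 samples")
    x = v[mask]
    out = {
        "min": float(x.min()),
        "max": float(x.max()),
        "median": float(np.median(x)),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)),
    }
    if with_slope:
        if times is None:
            raise ValueError("slope requires sample times")
        t = np.asarray(times, dtype=float)[mask] / 60.0  # minutes
        if np.ptp(t) == 0:
            out["slope"] = 0.0
        else:
            out["slope"] = float(np.polyfit(t, x, 1)[0])
    return out


def standardize_within_patient(table: pd.DataFrame,
                               value_col: str = "value",
                               out_col: str = "z",
                               group_cols: tuple[str, ...] = (
                                   "patient_id", "series", "feature"),
                               ) -> pd.DataFrame:
    """Add within-patient z-scores per feature: z = (x - mean_i) / sd_i.

    ``sd`` uses denominator n-1 over all of that patient's kept windows for
    the series/feature (agitated and non-agitated pooled).  Zero-variance or
    single-observation groups get missing z, excluding that feature from the
    patient's model rows.
    """
    df = table.copy()
    grp = df.groupby(list(group_cols))[value_col]
    mean = grp.transform("mean")
    sd = grp.transform("std")  # pandas std is ddof=1
    z = (df[value_col] - mean) / sd
    z[~np.isfinite(z)] = np.nan
    df[out_col] = z
    return df
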