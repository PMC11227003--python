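"""Modality-specific preprocessing and quality gates for ACC, HR and ST windows.

Rules, with their defaults, live in :class:`QcRuleSet`:

* heart rate (0.5 Hz): gaps shorter than 10 s are filled with a centered
  rolling 10 s median; remaining *interior* gaps are filled by cubic spline
  interpolation; leading/trailing gaps stay missing (no surrounding data).
  A window is dropped when >= 50% of its slots are missing *before*
  imputation.
* skin temperature (1 Hz): a sample is valid when present and within
  20-40 degC (closed interval); the window is dropped when the valid
  fraction is <= 50%.
* acceleration (32 Hz): per-sample magnitude sqrt(x^2+y^2+z^2); no quality
  threshold is applied — only fully empty windows are dropped.

Verdicts are monotone in missingness: removing valid samples never flips a
dropped window back to kept.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import InterpolatedUnivariateSpline

from .streams import FeatureWindow


@dataclass
class QcRuleSet:
    """Window quality thresholds; defaults follow the analysis protocol."""

    hr_roll_median_s: float = 10.0
    hr_spline_order: int = 3
    missing_drop_fraction: float = 0.5   # HR: dropped iff missing >= this
    st_min: float = 20.0                 # degC, inclusive
    st_max: float = 40.0                 # degC, inclusive
    st_valid_min_fraction: float = 0.5   # ST: dropped iff valid <= this

    def __post_init__(self) -> None:
        if not (0.0 < self.missing_drop_fraction <= 1.0):
            raise ValueError("missing_drop_fraction must be in (0, 1]")
        if not (0.0 < self.st_valid_min_fraction <= 1.0):
            raise ValueError("st_valid_min_fraction must be in (0, 1]")
        if self.st_min >= self.st_max:
            raise ValueError("st_min must be < st_max")


def acc_magnitude(x, y, z):
    """Magnitude of acceleration sqrt(x^2 + y^2 + z^2), in g.

    NaN inputs propagate (missing samples); infinite inputs are rejected.
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    for v in (x, y, z):
        if np.any(np.isinf(v)):
            raise ValueError("non-finite (infinite) acceleration input")
    return np.sqrt(x * x + y * y + z * z)


def _missing_runs(missing: np.ndarray):
    """Yield (start, stop) index pairs of consecutive-missing runs."""
    idx = np.flatnonzero(missing)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    return list(zip(starts.tolist(), stops.tolist()))


def impute_hr_window(window: FeatureWindow, rules: QcRuleSet | None = None
                     ) -> FeatureWindow:
    """Fill HR gaps: rolling 10 s median for short gaps, cubic spline for the
    rest; leading/trailing gaps are left missing.

    Never alters valid samples.  Records ``meta['imputed_fraction']`` and
    ``meta['pre_missing_fraction']``.
    """
    rules = rules or QcRuleSet()
    v = window.values.astype(float).copy()
    n = v.size
    period = 1.0 / window.sampling_rate
    missing0 = ~np.isfinite(v)
    pre_missing_fraction = float(missing0.mean())

    half = int(round(rules.hr_roll_median_s / 2.0 / period))  # samples each side
    out = v.copy()
    # pass 1: short interior gaps (< rolling window length) -> centered
    # rolling median; gaps touching the window edge have no surrounding data
    # on one side and stay missing
    for start, stop in _missing_runs(missing0):
        gap_s = (stop - start) * period
        if gap_s < rules.hr_roll_median_s and start > 0 and stop < n:
            for i in range(start, stop):
                lo, hi = max(0, i - half), min(n, i + half + 1)
                neigh = v[lo:hi]
                neigh = neigh[np.isfinite(neigh)]
                if neigh.size:
                    out[i] = np.median(neigh)
    # pass 2: remaining interior gaps -> cubic spline through valid samples;
    # extrapolation is forbidden, so leading/trailing gaps stay missing.
    still = ~np.isfinite(out)
    valid_idx = np.flatnonzero(np.isfinite(v))
    if still.any() and valid_idx.size > rules.hr_spline_order:
        first, last = valid_idx[0], valid_idx[-1]
        interior = still & (np.arange(n) > first) & (np.arange(n) < last)
        if interior.any():
            spl = InterpolatedUnivariateSpline(
                valid_idx.astype(float), v[valid_idx], k=rules.hr_spline_order
            )
            out[interior] = spl(np.flatnonzero(interior).astype(float))
    imputed = np.isfinite(out) & missing0
    meta = dict(window.meta)
    meta["pre_missing_fraction"] = pre_missing_fraction
    meta["imputed_fraction"] = float(imputed.mean())
    return replace(window, values=out, meta=meta)


def hr_window_verdict(window: FeatureWindow, rules: QcRuleSet | None = None
                      ) -> FeatureWindow:
    """Drop an HR window iff its pre-imputation missing fraction is >= 50%."""
    rules = rules or QcRuleSet()
    frac = window.meta.get("pre_missing_fraction", window.missing_fraction())
    if frac >= rules.missing_drop_fraction:
        return window.dropped("hr_missing_ge_50pct")
    return window


def st_window_verdict(window: FeatureWindow, rules: QcRuleSet | None = None
                      ) -> FeatureWindow:
    """Drop an ST window iff the fraction of present, in-range (20-40 degC,
    closed) samples is <= 50%."""
    rules = rules or QcRuleSet()
    v = window.values
    valid = np.isfinite(v) & (v >= rules.st_min) & (v <= rules.st_max)
    if valid.mean() <= rules.st_valid_min_fraction:
        return window.dropped("st_valid_le_50pct")
    return window


def st_valid_mask(window: FeatureWindow, rules: QcRuleSet | None = None
                  ) -> np.ndarray:
    rules = rules or QcRuleSet()
    v = window.values
    return np.isfinite(v) & (v >= rules.st_min) & (v <= rules.st_max)


def acc_window_series(window: FeatureWindow) -> FeatureWindow:
    """Per-sample acceleration magnitude; no quality gate beyond non-emptiness.

    Returns a single-channel window whose values are magnitudes (NaN where
    any axis is missing), dropped with reason ``no_data`` when empty.
    """
    xyz = window.values
    mag = acc_magnitude(xyz[:, 0], xyz[:, 1], xyz[:, 2])
    out = replace(window, values=mag)
    if not np.isfinite(mag).any():
        return out.dropped("no_data")
    return out
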