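"""Sensor stream containers, columnar I/O, and survey-centered window extraction.

A :class:`SensorStream` is a uniformly sampled single- or tri-channel time
series for one patient and one modality.  Missing samples are explicit
(``NaN``), never silently dropped rows, so "proportion missing" is well
defined for downstream quality control.

Timestamps are seconds since local midnight of the first study day (float);
the analysis only ever uses local clock time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Nominal sampling rate per modality, Hz.  EDA may alternatively be carried
#: at 8 Hz (the post-filter rate); see :data:`EDA_RATES`.
MODALITY_RATES = {
    "acc": 32.0,
    "hr": 0.5,
    "eda": 256.0,
    "st": 1.0,
    "ambient": 1.0,
}

EDA_RATES = (256.0, 8.0)

#: Fixed analysis window length: 6 minutes centered on survey submission.
WINDOW_DURATION_S = 360.0
WINDOW_HALF_S = WINDOW_DURATION_S / 2.0

MODALITIES = tuple(MODALITY_RATES)


class StreamFormatError(ValueError):
    """Raised for malformed stream files or invariant violations."""


def _expected_rate(modality: str, sampling_rate: float) -> None:
    if modality not in MODALITY_RATES:
        raise StreamFormatError(f"unknown modality: {modality!r}")
    allowed = EDA_RATES if modality == "eda" else (MODALITY_RATES[modality],)
    if not any(abs(sampling_rate - r) <= 0.01 * r for r in allowed):
        raise StreamFormatError(
            f"sampling rate {sampling_rate} Hz not valid for modality {modality!r} "
            f"(expected one of {allowed})"
        )


@dataclass
class SensorStream:
    """Uniformly sampled time series for one patient/modality.

    ``values`` has shape ``(n,)`` for single-channel modalities and ``(n, 3)``
    for tri-axial acceleration; NaN marks a missing sample.
    """

    patient_id: str
    modality: str
    sampling_rate: float
    t0: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _expected_rate(self.modality, self.sampling_rate)
        if self.modality == "acc":
            if self.values.ndim != 2 or self.values.shape[1] != 3:
                raise StreamFormatError("acc streams must have exactly 3 channels")
        else:
            if self.values.ndim != 1:
                raise StreamFormatError(
                    f"{self.modality} streams must be single-channel"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def t_end(self) -> float:
        """Time just past the last sample (exclusive end of coverage)."""
        return self.t0 + self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate


@dataclass
class FeatureWindow:
    """The 6-min slice of one stream around one survey.

    ``values`` always holds exactly ``n_slots = duration * rate`` sample
    slots on the stream's own grid; slots outside the recording span are NaN,
    so emptiness and missingness are indistinguishable to QC, by design.
    """

    survey_id: str
    patient_id: str
    modality: str
    t_center: float
    sampling_rate: float
    times: np.ndarray
    values: np.ndarray
    duration: float = WINDOW_DURATION_S
    quality_verdict: str = "kept"
    drop_reason: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_slots(self) -> int:
        return self.values.shape[0]

    def n_present(self) -> int:
        v = self.values
        finite = np.isfinite(v)
        if v.ndim == 2:
            finite = finite.all(axis=1)
        return int(finite.sum())

    def missing_fraction(self) -> float:
        return 1.0 - self.n_present() / self.n_slots

    def dropped(self, reason: str) -> "FeatureWindow":
        return replace(self, quality_verdict="dropped", drop_reason=reason)


def extract_window(stream: SensorStream, t_center: float,
                   survey_id: str = "") -> FeatureWindow:
    """Extract the half-open 6-min window ``[t_center-180, t_center+180)``.

    The slot grid is aligned with the stream's sample grid and always has
    ``round(duration * rate)`` entries; slots before the first or after the
    last recorded sample are NaN.  Side-effect free on the stream.
    """
    rate = stream.sampling_rate
    n_slots = int(round(WINDOW_DURATION_S * rate))
    # first stream index whose time is >= t_center - 180 (tolerate fp jitter)
    k0 = int(np.ceil((t_center - WINDOW_HALF_S - stream.t0) * rate - 1e-9))
    idx = k0 + np.arange(n_slots)
    times = stream.t0 + idx / rate
    if stream.values.ndim == 2:
        values = np.full((n_slots, 3), np.nan)
    else:
        values = np.full(n_slots, np.nan)
    inside = (idx >= 0) & (idx < stream.n_samples)
    values[inside] = stream.values[idx[inside]]
    return FeatureWindow(
        survey_id=survey_id,
        patient_id=stream.patient_id,
        modality=stream.modality,
        t_center=float(t_center),
        sampling_rate=rate,
        times=times,
        values=values,
    )


# ---------------------------------------------------------------------------
# Columnar text dialect: header row, `timestamp_s,value` or `timestamp_s,x,y,z`,
# missing = empty field, UTF-8, "." decimal separator.
# ---------------------------------------------------------------------------

def write_stream(stream: SensorStream, path: str | Path, fmt: str = "csv") -> None:
    """Write a stream in the columnar dialect (CSV, or parquet with pyarrow)."""
    path = Path(path)
    t = stream.times()
    if stream.modality == "acc":
        df = pd.DataFrame(
            {"timestamp_s": t, "x": stream.values[:, 0],
             "y": stream.values[:, 1], "z": stream.values[:, 2]}
        )
    else:
        df = pd.DataFrame({"timestamp_s": t, "value": stream.values})
    if fmt == "csv":
        df.to_csv(path, index=False, float_format="%.6f")
    elif fmt == "parquet":
        df.to_parquet(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_stream(path: str | Path, modality: str, patient_id: str = "",
                fmt: str | None = None) -> SensorStream:
    """Read a stream file, inferring the sampling rate from the timestamps.

    Raises :class:`StreamFormatError` on malformed rows, non-monotone or
    non-uniform timestamps (tolerance 1% of the sample period), or a channel
    count inconsistent with the modality.
    """
    path = Path(path)
    if fmt is None:
        fmt = "parquet" if path.suffix == ".parquet" else "csv"
    if fmt == "parquet":
        df = pd.read_parquet(path)
    else:
        try:
            df = pd.read_csv(path)
        except (pd.errors.ParserError, UnicodeDecodeError) as exc:
            raise StreamFormatError(f"malformed stream file {path}: {exc}") from exc
    if "timestamp_s" not in df.columns:
        raise StreamFormatError(f"{path}: missing timestamp_s column")
    t = df["timestamp_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise StreamFormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise StreamFormatError(f"{path}: timestamps not strictly increasing")
    period = float(np.median(dt))
    if np.any(np.abs(dt - period) > 0.01 * period):
        raise StreamFormatError(f"{path}: non-uniform timestamps beyond 1% tolerance")
    rate = 1.0 / period
    cols = [c for c in df.columns if c != "timestamp_s"]
    if modality == "acc":
        if cols != ["x", "y", "z"]:
            raise StreamFormatError(
                f"{path}: acc stream needs x,y,z columns, got {cols}"
            )
        values = df[["x", "y", "z"]].to_numpy(dtype=float)
    else:
        if cols != ["value"]:
            raise StreamFormatError(
                f"{path}: {modality} stream needs a single value column, got {cols}"
            )
        values = df["value"].to_numpy(dtype=float)
    # snap rate to nominal to avoid float drift from the text round-trip
    _expected_rate(modality, rate)
    allowed = EDA_RATES if modality == "eda" else (MODALITY_RATES[modality],)
    rate = min(allowed, key=lambda r: abs(r - rate))
    return SensorStream(patient_id=patient_id, modality=modality,
                        sampling_rate=rate, t0=float(t[0]), values=values)
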