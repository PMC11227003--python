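"""End-to-end orchestration: surveys -> windows -> QC -> features ->
standardization -> analysis table -> mixed models.

The pipeline can either consume a materialized :class:`~agiwear.cohort.Cohort`
or stream a :class:`~agiwear.cohort.SimConfig` patient-day by patient-day
(generating, windowing and discarding each day's streams) so week-long
cohorts at device sampling rates never need to fit in memory at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohort as coh
from . import eda as eda_mod
from .features import extract_features, standardize_within_patient
from .glmm import run_feature_screen
from .qc import (QcRuleSet, acc_window_series, hr_window_verdict,
                 impute_hr_window, st_valid_mask, st_window_verdict)
from .streams import extract_window

WEARABLE_MODALITIES = ("acc", "hr", "eda", "st")


@dataclass
class PipelineSettings:
    """Every threshold of the analysis in one place."""

    qc: QcRuleSet = field(default_factory=QcRuleSet)
    eda_quality: eda_mod.EdaQualityRules = field(
        default_factory=eda_mod.EdaQualityRules)
    kernel: eda_mod.BatemanKernel = field(default_factory=eda_mod.BatemanKernel)
    decompose_max_iter: int = 20
    standardize_confounders: bool = True
    min_surveys_per_patient: int = 2


def _eda_to_8hz(window_values: np.ndarray, rate: float) -> np.ndarray:
    """Bring an EDA window to the 8 Hz analysis rate, keeping missingness.

    At the device rate the signal is Savitzky-Golay filtered and decimated;
    NaN stretches are bridged for filtering and re-marked missing on the
    8 Hz grid so the quality rules see them.
    """
    v = np.asarray(window_values, dtype=float)
    if rate == 8.0:
        return v.copy()
    step = int(round(rate / 8.0))
    miss = ~np.isfinite(v)
    miss8 = miss.reshape(-1, step).any(axis=1)
    if miss.all():
        return np.full(v.size // step, np.nan)
    if miss.any():
        idx = np.arange(v.size)
        v = v.copy()
        v[miss] = np.interp(idx[miss], idx[~miss], v[~miss])
    out = eda_mod.filter_and_downsample(v, rate_in=rate)
    out[miss8] = np.nan
    return out


def process_survey_windows(streams: dict, survey: pd.Series,
                           settings: PipelineSettings):
    """All per-modality work for one survey: extract the 6-min windows,
    apply QC, and return (feature_rows, audit_rows, confounder_values)."""
    t = float(survey["timestamp_s"])
    sid = str(survey["survey_id"])
    pid = str(survey["patient_id"])
    frows: list[dict] = []
    audit: list[dict] = []
    conf = {"ambient_mean": np.nan, "acc_sd": np.nan}

    def add_features(series: str, modality: str, values, times=None,
                     with_slope=False):
        feats = extract_features(values, times=times, with_slope=with_slope)
        for name, val in feats.items():
            frows.append({"survey_id": sid, "patient_id": pid,
                          "modality": modality, "series": series,
                          "feature": name, "value": val})
        return feats

    # ambient mean over the same 6-min window (confounder only)
    if "ambient" in streams:
        w = extract_window(streams["ambient"], t, sid)
        finite = w.values[np.isfinite(w.values)]
        if finite.size:
            conf["ambient_mean"] = float(finite.mean())

    for modality in WEARABLE_MODALITIES:
        if modality not in streams:
            continue
        w = extract_window(streams[modality], t, sid)
        verdict, reason = "kept", None
        try:
            if modality == "acc":
                w2 = acc_window_series(w)
                verdict, reason = w2.quality_verdict, w2.drop_reason
                if verdict == "kept":
                    feats = add_features("acc_magnitude", "acc", w2.values)
                    conf["acc_sd"] = feats["sd"]
            elif modality == "hr":
                w2 = impute_hr_window(w, settings.qc)
                w2 = hr_window_verdict(w2, settings.qc)
                verdict, reason = w2.quality_verdict, w2.drop_reason
                if verdict == "kept":
                    add_features("hr", "hr", w2.values)
            elif modality == "eda":
                sig8 = _eda_to_8hz(w.values, w.sampling_rate)
                quality = eda_mod.quality_indicator(sig8, settings.eda_quality)
                verdict = eda_mod.eda_window_verdict(quality,
                                                     settings.eda_quality)
                reason = None if verdict == "kept" else "eda_quality_lt_50pct"
                if verdict == "kept":
                    mask = eda_mod.segment_quality_mask(sig8,
                                                        settings.eda_quality)
                    cleaned = eda_mod.interpolate_artifacts(sig8, mask)
                    tonic, phasic, _, info = eda_mod.decompose(
                        cleaned, settings.kernel,
                        max_iter=settings.decompose_max_iter, strict=False)
                    add_features("eda_full", "eda", cleaned)
                    add_features("eda_tonic", "eda", tonic)
                    add_features("eda_phasic", "eda", phasic)
                    if not info["converged"]:
                        reason = "decomposition_not_converged"
            elif modality == "st":
                w2 = st_window_verdict(w, settings.qc)
                verdict, reason = w2.quality_verdict, w2.drop_reason
                if verdict == "kept":
                    valid = st_valid_mask(w2, settings.qc)
                    add_features("st", "st", np.where(valid, w2.values, np.nan),
                                 times=w2.times, with_slope=True)
        except ValueError:
            verdict, reason = "dropped", "too_few_samples"
        audit.append({"survey_id": sid, "patient_id": pid,
                      "modality": modality, "verdict": verdict,
                      "drop_reason": reason})
    return frows, audit, conf


def prepare_surveys(raw_surveys: pd.DataFrame) -> pd.DataFrame:
    """Survey-side preprocessing: deduplicate, binarize, assign time blocks."""
    from .surveys import assign_time_group, binarize_outcomes, deduplicate

    s = deduplicate(raw_surveys)
    s = binarize_outcomes(s)
    s = s.copy()
    s["time_group"] = assign_time_group(s["timestamp_s"].to_numpy())
    return s.reset_index(drop=True)


@dataclass
class PipelineResult:
    surveys: pd.DataFrame          # cleaned surveys with outcomes/time_group
    features: pd.DataFrame         # long: survey x series x feature, raw + z
    analysis: pd.DataFrame         # model-ready long table
    audit: pd.DataFrame            # per survey x modality verdicts
    fits: pd.DataFrame | None = None


def _iter_patient_days(source) -> tuple:
    """Yield (patient_id, day, streams, surveys_raw) from a Cohort or a
    SimConfig (streaming generation)."""
    if isinstance(source, coh.Cohort):
        surveys = source.surveys
        keys = sorted({(p, d) for (p, d, _m) in source.streams})
        for pid, day in keys:
            streams = {m: s for (p, d, m), s in source.streams.items()
                       if p == pid and d == day}
            day_surveys = surveys[
                (surveys["patient_id"] == pid)
                & (surveys["timestamp_s"] // coh.DAY_S == day)]
            yield pid, day, streams, day_surveys
    else:
        config: coh.SimConfig = source
        seeds = coh.day_seedseqs(config)
        for pid in coh.patient_ids(config):
            for day in range(config.days_per_patient):
                streams, _eps, surveys = coh.generate_patient_day(
                    config, pid, day, seeds[(pid, day)],
                    acc_windows_only=True)
                yield pid, day, streams, surveys


def preprocess(source, settings: PipelineSettings | None = None
               ) -> PipelineResult:
    """Windows + QC + features + within-patient standardization + inclusion
    rules for a cohort (materialized or streamed from a config)."""
    from .surveys import apply_inclusion_rules

    settings = settings or PipelineSettings()
    all_surveys: list[pd.DataFrame] = []
    frames: list[dict] = []
    audits: list[dict] = []
    confs: list[dict] = []
    for pid, day, streams, raw in _iter_patient_days(source):
        if raw.empty:
            continue
        day_surveys = prepare_surveys(raw)
        all_surveys.append(day_surveys)
        for _, survey in day_surveys.iterrows():
            frows, audit, conf = process_survey_windows(streams, survey,
                                                        settings)
            frames.extend(frows)
            audits.extend(audit)
            conf.update(survey_id=survey["survey_id"],
                        patient_id=survey["patient_id"])
            confs.append(conf)
    surveys = pd.concat(all_surveys, ignore_index=True)
    conf_df = pd.DataFrame(confs)
    if settings.standardize_confounders and not conf_df.empty:
        for col in ("ambient_mean", "acc_sd"):
            conf_df = standardize_within_patient(
                conf_df, value_col=col, out_col=col + "_z",
                group_cols=("patient_id",))
    surveys = surveys.merge(conf_df, on=["survey_id", "patient_id"],
                            how="left")
    features = pd.DataFrame(frames)
    audit = pd.DataFrame(audits)
    if not features.empty:
        features = standardize_within_patient(features)
        features = apply_inclusion_rules(
            features, min_surveys=settings.min_surveys_per_patient)
    analysis = build_analysis_table(features, surveys, settings)
    return PipelineResult(surveys=surveys, features=features,
                          analysis=analysis, audit=audit)


def build_analysis_table(features: pd.DataFrame, surveys: pd.DataFrame,
                         settings: PipelineSettings | None = None
                         ) -> pd.DataFrame:
    """Join standardized features with outcomes, time blocks and
    standardized confounders into the model-ready long table."""
    settings = settings or PipelineSettings()
    if features.empty:
        return pd.DataFrame()
    suffix = "_z" if settings.standardize_confounders else ""
    cols = ["survey_id", "time_group", "agitated", "motor_agitated",
            "verbal_agitated"]
    ren = {}
    for c in ("ambient_mean", "acc_sd"):
        src = c + suffix
        if src in surveys.columns:
            cols.append(src)
            ren[src] = c
    out = features.merge(surveys[cols].rename(columns=ren), on="survey_id")
    return out


def run(source, settings: PipelineSettings | None = None,
        outcomes: tuple = ("agitated", "motor_agitated", "verbal_agitated"),
        features_subset: dict | None = None) -> PipelineResult:
    """Full pipeline: preprocessing plus the per-feature GLMM screen."""
    result = preprocess(source, settings)
    if not result.analysis.empty:
        result.fits = run_feature_screen(result.analysis, outcomes=outcomes,
                                         series_features=features_subset)
    return result
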