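"""Fully synthetic ward cohort: sensor streams, ambient temperature, survey
schedule, and ground-truth agitation episodes.

The generator emulates a dementia-ward study: ~30 patients wearing a wrist
device for ~1 week, nine pseudorandom survey prompts per day between 08:45
and 20:45 with a minimum 50-min spread (plus spontaneous surveys during
observed episodes), and agitation episodes whose hazard rises across the
day (sundowning).  During an episode, autonomic activation raises the EDA
tonic level and SCR rate and the heart rate, lowers distal skin
temperature, and (for motor-type episodes) raises acceleration variability.

Episodes follow a piecewise-constant-rate Poisson process over the four
clock blocks; durations are lognormal with a 6-min median (sigma_log 0.5).
Streams cover the daily wear period 08:00-21:00 — every possible survey
window lies inside it — one stream per patient/modality/day, so uniform
sampling holds within each stream.

Determinism: one master seed spawns independent per-patient-day substreams,
so an identical :class:`SimConfig` yields a byte-identical cohort.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import uniform_filter1d

from .eda import BatemanKernel
from .streams import SensorStream

DAY_S = 86400.0
PROMPT_START_S = 8 * 3600 + 45 * 60      # 08:45
PROMPT_END_S = 20 * 3600 + 45 * 60       # 20:45
PROMPT_MIN_GAP_S = 50 * 60               # minimum spread of 50 min
PROMPTS_PER_DAY = 9
WEAR_START_S = 8 * 3600.0                # daily wear period 08:00-21:00
WEAR_END_S = 21 * 3600.0

EPISODE_MEDIAN_S = 360.0                 # 6-min median duration
EPISODE_SIGMA_LOG = 0.5

#: time-block boundaries in hours, matching the analysis blocks 1-4
BLOCK_HOURS = ((8, 12), (12, 16), (16, 20), (20, 32))  # block 4 wraps to 08:00


@dataclass
class EffectProfile:
    """Autonomic-activation deltas planted during agitation episodes.

    Sign conventions: skin temperature falls (delta_st <= 0 by default);
    everything else rises.  Motor episodes scale the movement/HR deltas up,
    verbal episodes scale the EDA deltas up; 'both' episodes get both
    scalings.
    """

    delta_tonic_level: float = 1.0       # uS
    delta_phasic_rate: float = 4.0       # extra SCR peaks/min
    delta_hr: float = 10.0               # beats/min
    delta_st: float = -1.5               # degC (negative)
    delta_acc_sd: float = 0.15           # g of extra magnitude SD
    motor_movement_scale: float = 1.5    # motor: movement/HR deltas x this
    verbal_eda_scale: float = 1.5        # verbal: EDA deltas x this
    verbal_movement_scale: float = 0.25  # verbal episodes move little

    def scales(self, ep_type: str) -> dict:
        """Per-modality multipliers for one episode type."""
        move = eda = 1.0
        if ep_type in ("motor", "both"):
            move *= self.motor_movement_scale
        if ep_type == "verbal":
            move *= self.verbal_movement_scale
        if ep_type in ("verbal", "both"):
            eda *= self.verbal_eda_scale
        return {"acc": move, "hr": move if ep_type != "verbal" else 1.0,
                "eda": eda, "st": 1.0}

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite effect field {name}")


@dataclass
class MissingnessConfig:
    """Per-modality missingness and per-survey nonwear."""

    hr_missing_prob: float = 0.15        # stationary missing fraction
    hr_burst_mean_s: float = 20.0        # mean missing-burst length
    nonwear_prob: float = 0.10           # per survey: all wearables blanked

    def __post_init__(self) -> None:
        for p in (self.hr_missing_prob, self.nonwear_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic ward cohort."""

    n_patients: int = 30
    days_per_patient: int = 7
    seed: int = 0
    episode_base_rate: float = 1.1       # episodes/hour before multipliers
    sundowning_multipliers: tuple = (0.5, 1.0, 1.5, 2.0)
    motor_fraction: float = 0.45
    verbal_fraction: float = 0.25
    both_fraction: float = 0.25          # residual 0.05 = untyped, discarded
    spontaneous_rate: float = 0.15       # prob of a spontaneous survey/episode
    effect_profile: EffectProfile = field(default_factory=EffectProfile)
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    acc_hz: float = 32.0
    hr_hz: float = 0.5
    eda_hz: float = 256.0                # device rate; 8.0 = post-filter rate
    st_hz: float = 1.0
    ambient_hz: float = 1.0
    kernel: BatemanKernel = field(default_factory=BatemanKernel)
    eda_kernel_mismatch: bool = False    # generate SCRs with perturbed taus
    scr_base_rate_per_min: float = 2.0
    hr_baseline_bpm: float = 72.0
    tonic_baseline_us: float = 2.0
    st_baseline_c: float = 32.5
    ambient_baseline_c: float = 22.0

    def __post_init__(self) -> None:
        fr = (self.motor_fraction, self.verbal_fraction, self.both_fraction)
        if any(not 0.0 <= f <= 1.0 for f in fr) or sum(fr) > 1.0 + 1e-12:
            raise ValueError("episode-type fractions must be in [0,1] and sum <= 1")
        if any(m <= 0 for m in self.sundowning_multipliers) \
                or len(self.sundowning_multipliers) != 4:
            raise ValueError("need 4 positive sundowning multipliers")
        if self.episode_base_rate < 0:
            raise ValueError("episode_base_rate must be >= 0")
        if self.eda_hz not in (256.0, 8.0):
            raise ValueError("eda_hz must be 256 or 8")


@dataclass
class EpisodeTruth:
    """Ground-truth agitation episode (generator bookkeeping)."""

    patient_id: str
    start: float
    end: float
    type: str  # motor | verbal | both

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("episode end must be after start")


def generate_prompt_schedule(rng: np.random.Generator,
                             day_offset_s: float = 0.0) -> np.ndarray:
    """Nine pseudorandom prompt times in [08:45, 20:45] with pairwise gaps
    >= 50 min, by rejection sampling (vectorized batches; the constraint is
    feasible: 9 x 50 min = 400 min < 720 min span)."""
    lo, hi = PROMPT_START_S, PROMPT_END_S
    while True:
        cand = rng.uniform(lo, hi, size=(4096, PROMPTS_PER_DAY))
        cand.sort(axis=1)
        ok = np.flatnonzero((np.diff(cand, axis=1) >= PROMPT_MIN_GAP_S).all(axis=1))
        if ok.size:
            return cand[ok[0]] + day_offset_s


def _block_of_hour(hour: float) -> int:
    h = hour % 24.0
    if 8 <= h < 12:
        return 0
    if 12 <= h < 16:
        return 1
    if 16 <= h < 20:
        return 2
    return 3


def simulate_episodes(config: SimConfig, rng: np.random.Generator,
                      patient_id: str, day_index: int) -> list[EpisodeTruth]:
    """Agitation episodes for one patient-day from an inhomogeneous Poisson
    process: rate = episode_base_rate x sundowning_multiplier(block), over
    the full 24 h clock (block 4 spans 20:00-08:00).  Durations are
    lognormal around a 6-min median; overlapping episodes are thinned (later
    start dropped); the untyped residual fraction is discarded.
    """
    day0 = day_index * DAY_S
    raw: list[tuple[float, float, str]] = []
    type_probs = np.array([config.motor_fraction, config.verbal_fraction,
                           config.both_fraction])
    none_prob = max(0.0, 1.0 - type_probs.sum())
    probs = np.concatenate([type_probs, [none_prob]])
    types = np.array(["motor", "verbal", "both", "none"])
    for block, (h0, h1) in enumerate(BLOCK_HOURS):
        rate_per_s = (config.episode_base_rate
                      * config.sundowning_multipliers[block] / 3600.0)
        span = (h1 - h0) * 3600.0
        n = rng.poisson(rate_per_s * span)
        if n == 0:
            continue
        starts = day0 + h0 * 3600.0 + rng.uniform(0.0, span, size=n)
        durations = rng.lognormal(np.log(EPISODE_MEDIAN_S),
                                  EPISODE_SIGMA_LOG, size=n)
        ep_types = rng.choice(types, size=n, p=probs)
        for s, d, t in zip(starts, durations, ep_types):
            if t != "none":
                raw.append((float(s), float(s + d), str(t)))
    raw.sort()
    episodes: list[EpisodeTruth] = []
    last_end = -np.inf
    for s, e, t in raw:
        if s >= last_end:  # enforce non-overlap: keep earlier episode
            episodes.append(EpisodeTruth(patient_id, s, e, t))
            last_end = e
    return episodes


def emit_surveys(episodes: list[EpisodeTruth], schedule: np.ndarray,
                 spontaneous_rate: float, rng: np.random.Generator,
                 patient_id: str, day_index: int) -> pd.DataFrame:
    """Score prompted surveys from episode overlap at the prompt time and add
    spontaneous surveys (fired at episode midpoints with probability
    ``spontaneous_rate``).

    PAS items are 0-4: the motor/vocalization item is > 0 iff an episode of
    that type overlaps; aggression occasionally accompanies any episode
    (it feeds only the overall outcome).
    """
    rows = []

    def overlapping(t: float):
        return [ep for ep in episodes if ep.start <= t < ep.end]

    def score(t: float, prompted: bool):
        eps = overlapping(t)
        motor = any(ep.type in ("motor", "both") for ep in eps)
        verbal = any(ep.type in ("verbal", "both") for ep in eps)
        sev = int(rng.integers(1, 5)) if eps else 0
        pas_aggr = int(rng.integers(1, 4)) if eps and rng.random() < 0.15 else 0
        rows.append({
            "patient_id": patient_id,
            "timestamp_s": float(t),
            "pas_vocal": sev if verbal else 0,
            "pas_motor": sev if motor else 0,
            "pas_aggr": pas_aggr,
            "pas_resist": 0,
            "rass": min(4, sev) if eps else int(rng.integers(-1, 1)),
            "prompted": prompted,
        })

    for t in schedule:
        score(float(t), True)
    for ep in episodes:
        mid = 0.5 * (ep.start + ep.end)
        in_day = WEAR_START_S <= (mid % DAY_S) <= WEAR_END_S
        if in_day and rng.random() < spontaneous_rate:
            score(mid, False)
    df = pd.DataFrame(rows).sort_values("timestamp_s", ignore_index=True)
    df["survey_id"] = [f"{patient_id}-d{day_index}-{k}" for k in range(len(df))]
    return df


def _episode_mask(t0: float, rate: float, n: int,
                  episodes: list[EpisodeTruth], weight_fn) -> np.ndarray:
    """Per-sample episode weight (0 outside episodes), by index slices."""
    w = np.zeros(n)
    for ep in episodes:
        i0 = max(0, int(np.ceil((ep.start - t0) * rate)))
        i1 = min(n, int(np.ceil((ep.end - t0) * rate)))
        if i1 > i0:
            w[i0:i1] = np.maximum(w[i0:i1], weight_fn(ep))
    return w


def _ar1(n: int, phi: float, innov_sd: float,
         rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise via a recursive filter."""
    from scipy.signal import lfilter

    eps = rng.normal(0.0, innov_sd, n)
    eps[0] = rng.normal(0.0, innov_sd / np.sqrt(1.0 - phi * phi))
    return lfilter([1.0], [1.0, -phi], eps)


def _burst_missing_mask(n: int, missing_prob: float, burst_len: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Two-state (clean/missing) alternating-renewal mask with geometric
    segment lengths, stationary missing fraction ``missing_prob`` and mean
    missing-burst length ``burst_len`` samples."""
    if missing_prob <= 0.0:
        return np.zeros(n, dtype=bool)
    if missing_prob >= 1.0:
        return np.ones(n, dtype=bool)
    burst_len = max(burst_len, 1.0)
    clean_len = burst_len * (1.0 - missing_prob) / missing_prob
    est = int(n / (burst_len + clean_len)) + 10
    while True:
        n_seg = 2 * est
        clean = rng.geometric(min(1.0, 1.0 / clean_len), size=n_seg)
        miss = rng.geometric(min(1.0, 1.0 / burst_len), size=n_seg)
        lengths = np.empty(2 * n_seg, dtype=np.int64)
        lengths[0::2], lengths[1::2] = clean, miss
        if lengths.sum() >= n:
            break
        est *= 2
    bounds = np.cumsum(lengths)
    mask = np.zeros(n, dtype=bool)
    starts = np.concatenate(([0], bounds[:-1]))
    for s, e, is_missing in zip(starts, bounds,
                                np.arange(2 * n_seg) % 2 == 1):
        if s >= n:
            break
        if is_missing:
            mask[s:min(e, n)] = True
    # random phase: start mid-process so the first sample is not always clean
    if rng.random() < missing_prob:
        mask = np.roll(mask, rng.integers(0, n))
    return mask


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    return uniform_filter1d(x, size=max(1, width), mode="nearest")


def synthesize_streams(config: SimConfig, episodes: list[EpisodeTruth],
                       patient_id: str, day_index: int,
                       rng: np.random.Generator,
                       acc_noise_rng: np.random.Generator | None = None,
                       acc_base_rng: np.random.Generator | None = None,
                       survey_times: np.ndarray | None = None,
                       acc_windows_only: bool = False
                       ) -> dict[str, SensorStream]:
    """Per-modality streams for one patient-day (wear period 08:00-21:00).

    Baselines: ACC magnitude ~ 1 g gravity plus posture noise; HR with a
    diurnal drift and AR(1) variability; EDA = smooth tonic + Bateman-kernel
    SCR train (quantized to ADC steps at 256 Hz); ST near 31-34 degC coupled
    negatively to the ambient-temperature deviation.  EffectProfile deltas
    are added during episodes with smoothed onsets.  HR burst missingness is
    applied last (nonwear blanking happens at the cohort level, per survey).

    High-rate ACC activity noise is drawn per survey window from
    ``acc_noise_rng`` in survey-time order, so the streamed analysis mode
    (``acc_windows_only=True``, which materializes ACC only inside the 6-min
    survey windows) produces sample-identical window contents to the full
    stream written to disk.
    """
    eff = config.effect_profile
    day0 = day_index * DAY_S
    t_start, t_end = day0 + WEAR_START_S, day0 + WEAR_END_S
    span = t_end - t_start
    streams: dict[str, SensorStream] = {}
    if survey_times is None:
        survey_times = np.empty(0)

    def times(rate: float) -> np.ndarray:
        return t_start + np.arange(int(round(span * rate))) / rate

    # --- ambient temperature (ward sensor; diurnal peak mid-afternoon) ----
    t_amb = times(config.ambient_hz)
    hour = (t_amb % DAY_S) / 3600.0
    ambient = (config.ambient_baseline_c
               + 1.5 * np.sin((hour - 9.0) / 24.0 * 2 * np.pi)
               + _smooth(rng.normal(0, 0.6, t_amb.size),
                         int(600 * config.ambient_hz)))
    streams["ambient"] = SensorStream(patient_id, "ambient",
                                      config.ambient_hz, t_start, ambient)

    # --- accelerometer: gravity + posture drift + activity noise ---------
    # Episode weight and posture drift are cheap 1 Hz processes interpolated
    # to 32 Hz; the white activity noise is drawn per survey window from the
    # dedicated rng (full-day background noise only when writing streams).
    rate_acc = config.acc_hz
    n_acc = int(round(span * rate_acc))
    if acc_noise_rng is None:
        acc_noise_rng = rng
    n1 = int(round(span))  # 1 Hz support grid
    w1 = _episode_mask(t_start, 1.0, n1, episodes,
                       lambda ep: eff.scales(ep.type)["acc"])
    w1 = _smooth(w1, 10)
    t1 = t_start + np.arange(n1)
    posture1 = np.empty((n1, 3))
    for axis in range(3):
        p = _smooth(rng.normal(0, 1, n1), 300)
        posture1[:, axis] = p * (0.05 / max(p.std(), 1e-9))
    base_sd = 0.03

    def acc_block(i0: int, i1: int, noise_rng: np.random.Generator
                  ) -> np.ndarray:
        """ACC samples for stream indices [i0, i1) (i0 may be negative)."""
        tt = t_start + np.arange(i0, i1) / rate_acc
        sd = base_sd + eff.delta_acc_sd * np.interp(tt, t1, w1)
        out = noise_rng.normal(0.0, 1.0, (i1 - i0, 3)) * sd[:, None]
        for axis, g0 in enumerate((0.0, 0.0, 1.0)):
            out[:, axis] += g0 + np.interp(tt, t1, posture1[:, axis])
        return out

    xyz = np.full((n_acc, 3), np.nan)
    if not acc_windows_only:
        xyz[:] = acc_block(0, n_acc, acc_base_rng or rng)
    margin = int(rate_acc)  # one second of slack around each window
    for t in np.sort(survey_times):
        i0 = int(np.floor((t - 180.0 - t_start) * rate_acc)) - margin
        i1 = i0 + int(round(362.0 * rate_acc)) + 2 * margin
        block = acc_block(i0, i1, acc_noise_rng)
        lo, hi = max(i0, 0), min(i1, n_acc)
        if hi > lo:
            xyz[lo:hi] = block[lo - i0:hi - i0]
    streams["acc"] = SensorStream(patient_id, "acc", rate_acc, t_start, xyz)

    # --- heart rate at 0.5 Hz with burst missingness ----------------------
    t_hr = times(config.hr_hz)
    n_hr = t_hr.size
    hour = (t_hr % DAY_S) / 3600.0
    w_hr = _episode_mask(t_start, config.hr_hz, n_hr, episodes,
                         lambda ep: eff.scales(ep.type)["hr"])
    w_hr = _smooth(w_hr, int(20 * config.hr_hz))
    hr = (config.hr_baseline_bpm
          + 3.0 * np.sin((hour - 16.0) / 24.0 * 2 * np.pi)
          + _ar1(n_hr, 0.97, 0.8, rng) + eff.delta_hr * w_hr)
    m = config.missingness
    missing = _burst_missing_mask(n_hr, m.hr_missing_prob,
                                  m.hr_burst_mean_s * config.hr_hz, rng)
    hr[missing] = np.nan
    streams["hr"] = SensorStream(patient_id, "hr", config.hr_hz, t_start, hr)

    # --- EDA: tonic + SCR train, at device (256 Hz) or post-filter (8 Hz) -
    gen_rate = 8.0
    n_eda = int(round(span * gen_rate))
    t_eda = times(gen_rate)
    hour = (t_eda % DAY_S) / 3600.0
    w_eda = _episode_mask(t_start, gen_rate, n_eda, episodes,
                          lambda ep: eff.scales(ep.type)["eda"])
    w_eda_s = _smooth(w_eda, int(30 * gen_rate))
    # slow tonic wander generated on a 1 Hz support grid, then interpolated
    wander1 = _smooth(rng.normal(0, 0.4, n1), 120)
    tonic = (config.tonic_baseline_us
             + 0.3 * np.sin((hour - 14.0) / 24.0 * 2 * np.pi)
             + np.interp(t_eda, t1, wander1)
             + eff.delta_tonic_level * w_eda_s)
    tonic = np.maximum(tonic, 0.1)
    # SCR events: Poisson with base rate + planted extra rate in episodes
    rate_per_sample = (config.scr_base_rate_per_min
                       + eff.delta_phasic_rate * w_eda) / 60.0 / gen_rate
    events = np.flatnonzero(rng.random(n_eda) < rate_per_sample)
    amps = rng.lognormal(np.log(0.3), 0.4, events.size)
    kernel = config.kernel
    if config.eda_kernel_mismatch:
        kernel = replace(kernel, tau_rise=kernel.tau_rise * 1.3,
                         tau_decay=kernel.tau_decay * 1.3)
    h = kernel.sample(gen_rate)
    phasic = np.zeros(n_eda)
    for i, a in zip(events, amps):  # sparse scatter-add of SCR kernels
        hi = min(n_eda, i + h.size)
        phasic[i:hi] += a * h[:hi - i]
    eda8 = tonic + phasic
    if config.eda_hz == 256.0:
        # device-rate signal: linear upsample + ADC quantization steps
        t256 = times(256.0)
        eda = np.interp(t256, t_eda, eda8)
        eda = np.round(eda * 128.0) / 128.0
        streams["eda"] = SensorStream(patient_id, "eda", 256.0, t_start, eda)
    else:
        streams["eda"] = SensorStream(patient_id, "eda", 8.0, t_start, eda8)

    # --- skin temperature at 1 Hz, coupled to ambient ---------------------
    t_st = times(config.st_hz)
    n_st = t_st.size
    w_st = _episode_mask(t_start, config.st_hz, n_st, episodes,
                         lambda ep: 1.0)
    w_st = _smooth(w_st, int(60 * config.st_hz))
    amb_at_st = np.interp(t_st, t_amb, ambient)
    st = (config.st_baseline_c + rng.normal(0, 0.5)
          - 0.3 * (amb_at_st - config.ambient_baseline_c)
          + _smooth(rng.normal(0, 0.8, n_st), int(900 * config.st_hz))
          + eff.delta_st * w_st)
    streams["st"] = SensorStream(patient_id, "st", config.st_hz, t_start, st)
    return streams


def apply_nonwear(streams: dict[str, SensorStream], survey_times: np.ndarray,
                  nonwear_prob: float, rng: np.random.Generator,
                  half_window_s: float = 180.0) -> list[float]:
    """Blank all wearable modalities in the 6-min window around a random
    subset of surveys (device off the wrist); ambient is a ward sensor and
    is unaffected.  Returns the affected survey times."""
    affected = []
    for t in survey_times:
        if rng.random() < nonwear_prob:
            affected.append(float(t))
            for mod, stream in streams.items():
                if mod == "ambient":
                    continue
                i0 = int(np.ceil((t - half_window_s - stream.t0)
                                 * stream.sampling_rate - 1e-9))
                i1 = int(np.ceil((t + half_window_s - stream.t0)
                                 * stream.sampling_rate - 1e-9))
                stream.values[max(i0, 0):max(i1, 0)] = np.nan
    return affected


@dataclass
class Cohort:
    """Materialized synthetic cohort."""

    config: SimConfig
    streams: dict            # (patient_id, day_index, modality) -> SensorStream
    surveys: pd.DataFrame
    episodes: pd.DataFrame


def patient_ids(config: SimConfig) -> list[str]:
    return [f"P{i + 1:02d}" for i in range(config.n_patients)]


def _child_seed(ss: np.random.SeedSequence, i: int) -> np.random.SeedSequence:
    """Stateless child derivation (SeedSequence.spawn mutates its parent)."""
    return np.random.SeedSequence(entropy=ss.entropy,
                                  spawn_key=ss.spawn_key + (i,))


def day_seedseqs(config: SimConfig):
    """Deterministic per-(patient, day) seed sequences from the master seed."""
    out = {}
    for pi, pid in enumerate(patient_ids(config)):
        for day in range(config.days_per_patient):
            out[(pid, day)] = np.random.SeedSequence(
                entropy=config.seed, spawn_key=(pi, day))
    return out


def generate_patient_day(config: SimConfig, patient_id: str, day_index: int,
                         seedseq: np.random.SeedSequence,
                         acc_windows_only: bool = False):
    """All data for one patient-day: (streams, episodes, surveys).

    Each generator stage draws from its own spawned substream, so the
    survey-window contents are identical whether ACC is materialized for
    the whole day or only inside the windows the analysis consumes.
    """
    k_main, k_stream, k_accw, k_accbase, k_nonwear = (
        _child_seed(seedseq, i) for i in range(5))
    rng = np.random.default_rng(k_main)
    rng_stream = np.random.default_rng(k_stream)
    rng_accw = np.random.default_rng(k_accw)
    rng_accbase = np.random.default_rng(k_accbase)
    rng_nonwear = np.random.default_rng(k_nonwear)
    schedule = generate_prompt_schedule(rng, day_offset_s=day_index * DAY_S)
    episodes = simulate_episodes(config, rng, patient_id, day_index)
    surveys = emit_surveys(episodes, schedule, config.spontaneous_rate, rng,
                           patient_id, day_index)
    streams = synthesize_streams(config, episodes, patient_id, day_index,
                                 rng_stream, acc_noise_rng=rng_accw,
                                 acc_base_rng=rng_accbase,
                                 survey_times=surveys["timestamp_s"].to_numpy(),
                                 acc_windows_only=acc_windows_only)
    apply_nonwear(streams, surveys["timestamp_s"].to_numpy(),
                  config.missingness.nonwear_prob, rng_nonwear)
    return streams, episodes, surveys


def generate_cohort(config: SimConfig) -> Cohort:
    """Materialize the full cohort (use for small configs; the analysis
    pipeline streams patient-days without holding everything in memory)."""
    seeds = day_seedseqs(config)
    all_streams = {}
    all_surveys = []
    all_episodes = []
    for pid in patient_ids(config):
        for day in range(config.days_per_patient):
            streams, episodes, surveys = generate_patient_day(
                config, pid, day, seeds[(pid, day)])
            for mod, s in streams.items():
                all_streams[(pid, day, mod)] = s
            all_surveys.append(surveys)
            all_episodes.extend(episodes)
    surveys = pd.concat(all_surveys, ignore_index=True)
    episodes = pd.DataFrame(
        [{"patient_id": e.patient_id, "start": e.start, "end": e.end,
          "type": e.type} for e in all_episodes])
    return Cohort(config=config, streams=all_streams, surveys=surveys,
                  episodes=episodes)


# ---------------------------------------------------------------------------
# Disk layout: one file per patient/modality/day + surveys + episode truth
# + a manifest recording config and seed.
# ---------------------------------------------------------------------------

def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["sundowning_multipliers"] = list(d["sundowning_multipliers"])
    return d


def write_cohort(cohort: Cohort, outdir: str | Path, fmt: str = "csv") -> None:
    """Write the cohort: columnar stream files (CSV, or parquet for the
    compressed option), surveys.csv, episodes.csv, manifest.yaml."""
    from .streams import write_stream

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = "parquet" if fmt == "parquet" else "csv"
    for (pid, day, mod), stream in cohort.streams.items():
        write_stream(stream, outdir / f"{pid}_{mod}_day{day}.{ext}", fmt=fmt)
    cohort.surveys.to_csv(outdir / "surveys.csv", index=False)
    cohort.episodes.to_csv(outdir / "episodes.csv", index=False)
    manifest = {"config": _config_dict(cohort.config), "format": fmt,
                "seed": cohort.config.seed}
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest))


def read_cohort(indir: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`."""
    from .streams import read_stream

    indir = Path(indir)
    manifest = yaml.safe_load((indir / "manifest.yaml").read_text())
    cfg_d = dict(manifest["config"])
    cfg_d["sundowning_multipliers"] = tuple(cfg_d["sundowning_multipliers"])
    cfg_d["effect_profile"] = EffectProfile(**cfg_d["effect_profile"])
    cfg_d["missingness"] = MissingnessConfig(**cfg_d["missingness"])
    cfg_d["kernel"] = BatemanKernel(**cfg_d["kernel"])
    config = SimConfig(**cfg_d)
    ext = "parquet" if manifest.get("format") == "parquet" else "csv"
    streams = {}
    for path in sorted(indir.glob(f"*_day*.{ext}")):
        pid, mod, day_part = path.stem.split("_")
        day = int(day_part.removeprefix("day"))
        streams[(pid, day, mod)] = read_stream(path, mod, patient_id=pid)
    surveys = pd.read_csv(indir / "surveys.csv")
    episodes = pd.read_csv(indir / "episodes.csv")
    return Cohort(config=config, streams=streams, surveys=surveys,
                  episodes=episodes)
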