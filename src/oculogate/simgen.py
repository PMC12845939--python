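"""Synthetic-data generators for the whole screening pipeline.

Everything the pipeline consumes is generated here, fully seeded: cohorts of
participants with group-structured oculomotor feature distributions, pupil and
gaze traces realising those features, synthetic eye images with ground-truth
circle geometry, and rater matrices for the stimulus corpus.

The default cohort reproduces the study conditions: 242 participants of whom
81 carry a depressive response pattern, feature-level group contrasts taken
from the reported descriptive statistics (pupil dilation amplitude to negative
and positive stimuli, fixation duration, saccade velocity), 90-120 Hz traces
in 5 s baseline / 8 s stimulus / 5 s rest blocks, and three reference sessions
per participant recorded in rested, tired and stressed states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .irisid import EyeImage

__all__ = [
    "CohortConfig",
    "PupilKernelParams",
    "GazeKernelParams",
    "IrisIdentityParams",
    "RatingProfile",
    "RatingMatrix",
    "Block",
    "BlockSchedule",
    "Stimulus",
    "Session",
    "Participant",
    "Cohort",
    "FEATURE_EFFECTS",
    "pupil_kernel",
    "generate_cohort",
    "simulate_pupil_trace",
    "simulate_gaze_trace",
    "simulate_session_trace",
    "simulate_iris_image",
    "generate_rating_matrix",
    "main_sequence_velocity",
]

# Latent feature table: (feature, group) -> (mean, sd).  PDA (% of baseline)
# and FD (ms), SV (deg/s) use the reported group statistics; PDV (%/s), SA
# (deg), GDE (bits), EMA (unitless) and CL (ms) have no reported
# distributions and use declared defaults (see docs/methods.md).
FEATURE_EFFECTS: dict[tuple[str, str], tuple[float, float]] = {
    ("PDA_neg", "control"): (18.4, 6.7),
    ("PDA_neg", "depressed"): (27.9, 8.3),
    ("PDA_pos", "control"): (6.2, 4.1),
    ("PDA_pos", "depressed"): (-1.3, 5.0),
    ("FD", "control"): (280.0, 40.0),
    ("FD", "depressed"): (345.0, 52.0),
    ("SV", "control"): (320.0, 45.0),
    ("SV", "depressed"): (276.0, 51.0),
    ("PDV_neg", "control"): (12.0, 4.0),
    ("PDV_neg", "depressed"): (17.0, 5.0),
    ("PDV_pos", "control"): (4.0, 2.5),
    ("PDV_pos", "depressed"): (0.5, 2.5),
    ("SA", "control"): (8.0, 2.0),
    ("SA", "depressed"): (7.0, 2.2),
    ("GDE", "control"): (4.2, 0.6),
    ("GDE", "depressed"): (3.6, 0.7),
    ("EMA", "control"): (0.08, 0.04),
    ("EMA", "depressed"): (0.12, 0.06),
    ("CL", "control"): (400.0, 50.0),
    ("CL", "depressed"): (430.0, 60.0),
}

REFERENCE_STATES = ("rested", "tired", "stressed")


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    n_total: int = 242
    n_depressed: int = 81
    feature_effects: dict = field(default_factory=lambda: dict(FEATURE_EFFECTS))
    inter_feature_rho: float = 0.25
    stimuli_per_session: tuple[int, int] = (3, 3)  # (positive, negative)
    within_frac: float = 0.30  # within-participant SD as fraction of between SD
    sampling_rate: float = 100.0
    baseline_s: float = 5.0
    stimulus_s: float = 8.0
    rest_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_depressed <= self.n_total:
            raise ValueError("need 0 <= n_depressed <= n_total")
        if not 0.0 <= self.inter_feature_rho < 1.0:
            raise ValueError(
                "inter_feature_rho must lie in [0, 1) for a positive-definite "
                "equicorrelation matrix"
            )
        if not 90.0 <= self.sampling_rate <= 120.0:
            raise ValueError("sampling_rate must lie in [90, 120] Hz")
        for name in ("baseline_s", "stimulus_s", "rest_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for (feat, grp), (mu, sd) in self.feature_effects.items():
            if sd <= 0:
                raise ValueError(f"SD for ({feat}, {grp}) must be > 0")


@dataclass
class PupilKernelParams:
    """Event-related pupil response: gamma-family impulse kernel
    h(t) = (t/t_max)^n * exp(n * (1 - t/t_max)), unit peak at t_max."""

    baseline_diameter: float = 4.0  # mm
    amplitude: float = 18.4  # % of baseline at the kernel peak
    latency_ms: float = 400.0
    peak_time_ms: float = 930.0
    shape_n: float = 10.1
    noise_sd: float = 0.02  # mm
    blink_rate_per_min: float = 0.0
    blink_duration_ms: float = 150.0

    def __post_init__(self) -> None:
        if not 1.5 <= self.baseline_diameter <= 9.0:
            raise ValueError("baseline_diameter must lie in [1.5, 9] mm")
        if self.peak_time_ms <= 0:
            raise ValueError("peak_time_ms must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GazeKernelParams:
    """Fixation/saccade alternation with a saturating-exponential main
    sequence v_peak(A) = vmax * (1 - exp(-A / a0))."""

    fixation_mean_ms: float = 280.0
    fixation_sd_ms: float = 60.0
    saccade_amp_mean_deg: float = 8.0
    saccade_amp_sd_deg: float = 2.0
    vmax: float = 500.0
    a0: float = 12.0
    noise_sd_deg: float = 0.05
    position_spread_deg: float = 6.0  # SD of fixation targets around centre
    extent_deg: tuple[float, float] = (20.0, 12.0)  # display half-extent (x, y)

    def __post_init__(self) -> None:
        for name in ("fixation_mean_ms", "fixation_sd_ms", "saccade_amp_mean_deg",
                     "saccade_amp_sd_deg", "vmax", "a0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fixation_mean_ms < 50:
            raise ValueError("fixation_mean_ms must be at least 50 ms")
        if self.noise_sd_deg < 0:
            raise ValueError("noise_sd_deg must be non-negative")


@dataclass
class IrisIdentityParams:
    identity_seed: int = 0
    n_radial: int = 64
    n_angular: int = 256
    band_low: float = 3.0  # cycles around the annulus
    band_high: float = 24.0
    pupil_radius_base: float = 40.0  # px at zero dilation
    limbus_radius: float = 100.0
    image_size: int = 256
    dilation_range: tuple[float, float] = (0.10, 0.40)
    intra_noise_sd: float = 0.02  # intensity units
    rotation_jitter_deg: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.dilation_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("dilation_range must satisfy 0 <= lo <= hi < 1")
        if self.pupil_radius_base * (1 + hi) >= self.limbus_radius:
            raise ValueError("pupil must stay inside the limbus at max dilation")


@dataclass
class RatingProfile:
    """Item-truth spread and rater noise for the valence/arousal matrices."""

    truth_mean: float = 5.0
    valence_truth_sd: float = 2.0
    arousal_truth_sd: float = 2.0
    rater_sd: float = 1.0


@dataclass
class RatingMatrix:
    item_ids: list[str]
    valence: np.ndarray  # items x raters, int 1..9
    arousal: np.ndarray

    def __post_init__(self) -> None:
        for plane in (self.valence, self.arousal):
            if plane.shape[1] < 2:
                raise ValueError("need at least 2 raters")
            if not np.isin(plane, np.arange(1, 10)).all():
                raise ValueError("ratings must be integers in 1..9")


# ---------------------------------------------------------------------------
# schedules, sessions, cohort containers
# ---------------------------------------------------------------------------

@dataclass
class Block:
    onset_ms: int  # stimulus onset
    baseline_ms: int = 5000
    stimulus_ms: int = 8000
    rest_ms: int = 5000
    valence: str = "none"

    @property
    def start_ms(self) -> int:
        return self.onset_ms - self.baseline_ms

    @property
    def end_ms(self) -> int:
        return self.onset_ms + self.stimulus_ms + self.rest_ms


@dataclass
class BlockSchedule:
    participant_id: str
    state: str
    blocks: list[Block]

    def __post_init__(self) -> None:
        last_end = -1
        for b in sorted(self.blocks, key=lambda b: b.start_ms):
            if b.start_ms < last_end:
                raise ValueError("blocks must not overlap")
            last_end = b.end_ms

    @property
    def duration_ms(self) -> int:
        return max(b.end_ms for b in self.blocks) if self.blocks else 0


@dataclass
class Stimulus:
    index: int
    valence: str  # 'pos' | 'neg'
    features: dict[str, float]


@dataclass
class Session:
    session_id: str
    state: str  # 'rested' | 'tired' | 'stressed' | 'screening'
    stimuli: list[Stimulus]
    schedule: BlockSchedule | None = None
    trace: pd.DataFrame | None = None

    def session_features(self) -> dict[str, float]:
        """Per-session feature values: means over this session's stimuli."""
        keys = self.stimuli[0].features.keys()
        return {k: float(np.nanmean([s.features[k] for s in self.stimuli]))
                for k in keys}


@dataclass
class Participant:
    pid: str
    group: str  # 'control' | 'depressed'
    latent: dict[str, float]
    reference_latent: dict[str, float]
    reference_sessions: list[Session]
    screening_session: Session


@dataclass
class Cohort:
    config: CohortConfig
    participants: list[Participant]

    @property
    def labels(self) -> pd.Series:
        return pd.Series({p.pid: p.group for p in self.participants})

    def feature_frame(self) -> pd.DataFrame:
        """Participant-level screening features: per-valence means over the
        screening stimuli, in the layout the screening models consume."""
        rows = []
        for p in self.participants:
            feats: dict[str, float] = {}
            for val in ("pos", "neg"):
                sel = [s.features for s in p.screening_session.stimuli if s.valence == val]
                for key in ("PDA", "PDV"):
                    feats[f"{key}_{val}"] = float(np.nanmean([f[key] for f in sel]))
            neg = [s.features for s in p.screening_session.stimuli if s.valence == "neg"]
            allst = [s.features for s in p.screening_session.stimuli]
            feats["FD"] = float(np.nanmean([f["FD"] for f in neg]))
            feats["SV"] = float(np.nanmean([f["SV"] for f in allst]))
            feats["SA"] = float(np.nanmean([f["SA"] for f in allst]))
            feats["GDE"] = float(np.nanmean([f["GDE"] for f in allst]))
            feats["EMA"] = float(np.nanmean([f["EMA"] for f in allst]))
            rows.append({"participant_id": p.pid, "group": p.group, **feats})
        return pd.DataFrame(rows).set_index("participant_id")


# ---------------------------------------------------------------------------
# pupil kernel and traces
# ---------------------------------------------------------------------------

def pupil_kernel(t_ms: np.ndarray, peak_time_ms: float = 930.0,
                 shape_n: float = 10.1) -> np.ndarray:
    """Unit-peak gamma-family pupil impulse response, h(t_max) = 1."""
    t = np.asarray(t_ms, dtype=float)
    x = np.clip(t / peak_time_ms, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(x > 0, np.exp(shape_n * (np.log(np.where(x > 0, x, 1.0))
                                              + 1.0 - x)), 0.0)
    return h


def _substream(seed: int, *tags: int) -> np.random.Generator:
    """Named substream of the root seed (keeps all derived seeds < 2**31)."""
    ss = np.random.SeedSequence(entropy=int(seed) % (2 ** 31), spawn_key=tags)
    return np.random.default_rng(ss)


def simulate_pupil_trace(params: PupilKernelParams, schedule: BlockSchedule,
                         seed: int = 0, sampling_rate: float = 100.0,
                         amplitudes: dict[int, float] | None = None) -> pd.DataFrame:
    """Pupil diameter trace for a block schedule.

    d(t) = B * (1 + sum_k (a_k/100) * h(t - onset_k - latency)) + noise, with
    blinks inserted as missing (NaN) runs.  ``amplitudes`` optionally overrides
    the kernel amplitude per block index.
    """
    if not schedule.blocks:
        raise ValueError("schedule has no blocks")
    dt_ms = 1000.0 / sampling_rate
    n = int(round(schedule.duration_ms / dt_ms)) + 1
    t = np.arange(n) * dt_ms
    if schedule.duration_ms > t[-1] + dt_ms:
        raise ValueError("schedule extends beyond the trace duration")
    d = np.full(n, float(params.baseline_diameter))
    for i, b in enumerate(schedule.blocks):
        amp = params.amplitude if amplitudes is None else amplitudes.get(i, params.amplitude)
        h = pupil_kernel(t - b.onset_ms - params.latency_ms,
                         params.peak_time_ms, params.shape_n)
        d += params.baseline_diameter * (amp / 100.0) * h
    rng = _substream(seed, 1)
    if params.noise_sd > 0:
        d = d + rng.normal(0.0, params.noise_sd, size=n)
    valid = np.ones(n, dtype=bool)
    if params.blink_rate_per_min > 0:
        n_blinks = rng.poisson(params.blink_rate_per_min * t[-1] / 60000.0)
        for _ in range(n_blinks):
            s = rng.uniform(0.0, t[-1])
            m = (t >= s) & (t < s + params.blink_duration_ms)
            valid[m] = False
    d = np.where(valid, d, np.nan)
    return pd.DataFrame({"t_ms": t, "pupil_mm": d, "valid": valid.astype(int)})


def main_sequence_velocity(amplitude_deg: float, vmax: float = 500.0,
                           a0: float = 12.0) -> float:
    """Saccadic main sequence: peak velocity for a given amplitude."""
    return float(vmax * (1.0 - math.exp(-amplitude_deg / a0)))


def simulate_gaze_trace(params: GazeKernelParams, schedule: BlockSchedule,
                        seed: int = 0, sampling_rate: float = 100.0,
                        saccade_rate_hz: float | None = None) -> pd.DataFrame:
    """Gaze position trace: alternating fixations and saccades.

    Fixations hold a target position with Gaussian positional noise; saccades
    move between targets with a raised-cosine velocity profile whose peak
    follows the main sequence.  ``saccade_rate_hz = 0`` yields a single
    fixation covering the whole trace.
    """
    dt_ms = 1000.0 / sampling_rate
    n = int(round(schedule.duration_ms / dt_ms)) + 1
    t = np.arange(n) * dt_ms
    rng = _substream(seed, 2)
    ex, ey = params.extent_deg
    x = np.empty(n)
    y = np.empty(n)
    pos = np.array([rng.normal(0, params.position_spread_deg) * 0.5,
                    rng.normal(0, params.position_spread_deg) * 0.3])
    events: list[dict] = []
    i = 0
    single_fix = saccade_rate_hz == 0.0
    while i < n:
        fix_dur = max(50.0, rng.normal(params.fixation_mean_ms, params.fixation_sd_ms))
        if single_fix:
            fix_dur = t[-1] + dt_ms
        n_fix = max(1, int(round(fix_dur / dt_ms)))
        j = min(n, i + n_fix)
        x[i:j] = pos[0]
        y[i:j] = pos[1]
        events.append({"kind": "fixation", "start_ms": t[i],
                       "end_ms": t[min(j, n) - 1]})
        i = j
        if i >= n:
            break
        # saccade to a new target at the main-sequence amplitude
        amp = max(0.5, rng.normal(params.saccade_amp_mean_deg, params.saccade_amp_sd_deg))
        ang = rng.uniform(0, 2 * np.pi)
        target = pos + amp * np.array([np.cos(ang), np.sin(ang)])
        # keep targets on the display
        target[0] = float(np.clip(target[0], -ex, ex))
        target[1] = float(np.clip(target[1], -ey, ey))
        amp_eff = float(np.hypot(*(target - pos)))
        if amp_eff < 1e-6:
            continue
        v_peak = main_sequence_velocity(amp_eff, params.vmax, params.a0)
        # raised-cosine velocity profile: mean velocity = v_peak / 2
        sac_dur_ms = max(2 * dt_ms, 1000.0 * amp_eff / (v_peak / 2.0))
        n_sac = max(2, int(round(sac_dur_ms / dt_ms)))
        k = min(n, i + n_sac)
        phase = (np.arange(k - i) + 1) / n_sac  # position fraction via raised cosine
        frac = phase - np.sin(2 * np.pi * phase) / (2 * np.pi)
        x[i:k] = pos[0] + (target[0] - pos[0]) * frac
        y[i:k] = pos[1] + (target[1] - pos[1]) * frac
        events.append({"kind": "saccade", "start_ms": t[i], "end_ms": t[min(k, n) - 1],
                       "amplitude_deg": amp_eff, "peak_velocity": v_peak})
        i = k
        pos = target
    if params.noise_sd_deg > 0:
        x = x + rng.normal(0, params.noise_sd_deg, n)
        y = y + rng.normal(0, params.noise_sd_deg, n)
    df = pd.DataFrame({"t_ms": t, "gaze_x_deg": x, "gaze_y_deg": y})
    df.attrs["events"] = events
    return df


def make_schedule(participant_id: str, state: str, n_pos: int, n_neg: int,
                  rng: np.random.Generator, baseline_ms: int = 5000,
                  stimulus_ms: int = 8000, rest_ms: int = 5000) -> BlockSchedule:
    valences = ["pos"] * n_pos + ["neg"] * n_neg
    rng.shuffle(valences)
    block_len = baseline_ms + stimulus_ms + rest_ms
    blocks = [Block(onset_ms=i * block_len + baseline_ms, baseline_ms=baseline_ms,
                    stimulus_ms=stimulus_ms, rest_ms=rest_ms, valence=v)
              for i, v in enumerate(valences)]
    return BlockSchedule(participant_id=participant_id, state=state, blocks=blocks)


def simulate_session_trace(session: Session, cfg: CohortConfig,
                           seed: int) -> pd.DataFrame:
    """Materialise a two-eye trace CSV frame realising the session's
    per-stimulus pupil amplitudes and gaze statistics."""
    sched = session.schedule
    if sched is None:
        raise ValueError("session has no schedule")
    amplitudes = {i: s.features["PDA"] for i, s in enumerate(session.stimuli)}
    mean_fd = float(np.mean([s.features["FD"] for s in session.stimuli]))
    mean_sv = float(np.mean([s.features["SV"] for s in session.stimuli]))
    mean_sv = min(mean_sv, 0.98 * 500.0)
    amp_target = -12.0 * math.log(1.0 - mean_sv / 500.0)
    pk = PupilKernelParams(amplitude=0.0, noise_sd=0.01)
    gk = GazeKernelParams(fixation_mean_ms=mean_fd, fixation_sd_ms=0.15 * mean_fd,
                          saccade_amp_mean_deg=amp_target,
                          saccade_amp_sd_deg=max(0.3, 0.1 * amp_target))
    left = simulate_pupil_trace(pk, sched, seed=seed, sampling_rate=cfg.sampling_rate,
                                amplitudes=amplitudes)
    right = simulate_pupil_trace(pk, sched, seed=seed + 1,
                                 sampling_rate=cfg.sampling_rate, amplitudes=amplitudes)
    gaze = simulate_gaze_trace(gk, sched, seed=seed, sampling_rate=cfg.sampling_rate)
    df = pd.DataFrame({
        "t_ms": left["t_ms"],
        "pupil_l_mm": left["pupil_mm"],
        "pupil_r_mm": right["pupil_mm"],
        "gaze_x_deg": gaze["gaze_x_deg"],
        "gaze_y_deg": gaze["gaze_y_deg"],
        "valid": (left["valid"] & right["valid"]).astype(int),
    })
    df.attrs["events"] = gaze.attrs.get("events", [])
    return df


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _latent_features(cfg: CohortConfig) -> list[str]:
    return sorted({feat for feat, _ in cfg.feature_effects.keys()})


def _effect_signs(cfg: CohortConfig, features: list[str]) -> np.ndarray:
    """Direction of the depression effect per feature (+1 when the depressed
    mean exceeds the control mean).  The equicorrelation is applied along
    these directions: a single severity axis loads every feature."""
    signs = np.ones(len(features))
    for i, f in enumerate(features):
        mu_c = cfg.feature_effects[(f, "control")][0]
        mu_d = cfg.feature_effects[(f, "depressed")][0]
        signs[i] = 1.0 if mu_d >= mu_c else -1.0
    return signs


def generate_cohort(cfg: CohortConfig | None = None, *,
                    with_traces: bool = False) -> Cohort:
    """Generate the full participant cohort.

    Each participant receives a latent per-feature mean drawn from the group
    distribution with effect-aligned equicorrelation ``rho`` (a shared
    severity factor), three reference sessions (rested/tired/stressed) drawn
    around the participant's own neutral response level, and one screening
    session of 3 positive + 3 negative stimuli.  Per-stimulus values add
    within-participant noise at ``within_frac`` of the between-participant SD.
    Identical seeds give bit-identical cohorts.
    """
    cfg = cfg or CohortConfig()
    features = _latent_features(cfg)
    signs = _effect_signs(cfg, features)
    rho = cfg.inter_feature_rho
    rng = _substream(cfg.seed, 0)
    n_pos, n_neg = cfg.stimuli_per_session

    participants: list[Participant] = []
    groups = ["depressed"] * cfg.n_depressed + ["control"] * (cfg.n_total - cfg.n_depressed)
    for idx, group in enumerate(groups):
        pid = f"P{idx:04d}"
        # shared severity axis: u_i = s_i * (sqrt(rho) z0 + sqrt(1-rho) z_i)
        z0 = rng.normal()
        zi = rng.normal(size=len(features))
        u = signs * (math.sqrt(rho) * z0 + math.sqrt(1.0 - rho) * zi)
        latent = {}
        ref_latent = {}
        for f, ui in zip(features, u):
            mu_g, sd_g = cfg.feature_effects[(f, group)]
            mu_c, sd_c = cfg.feature_effects[(f, "control")]
            latent[f] = mu_g + sd_g * ui
            ref_latent[f] = mu_c + sd_c * ui

        def draw(feat: str, base: dict[str, float], sd_scale: dict) -> float:
            sd = sd_scale[feat]
            return float(base[feat] + cfg.within_frac * sd * rng.normal())

        sd_ref = {f: cfg.feature_effects[(f, "control")][1] for f in features}
        sd_grp = {f: cfg.feature_effects[(f, group)][1] for f in features}

        ref_sessions = []
        for si, state in enumerate(REFERENCE_STATES):
            stimuli = []
            for k in range(n_pos + n_neg):
                val = "pos" if k < n_pos else "neg"
                stimuli.append(Stimulus(index=k, valence=val,
                                        features=_stimulus_features(
                                            val, ref_latent, draw, sd_ref)))
            sched = make_schedule(pid, state, n_pos, n_neg, rng,
                                  int(cfg.baseline_s * 1000),
                                  int(cfg.stimulus_s * 1000),
                                  int(cfg.rest_s * 1000))
            ref_sessions.append(Session(session_id=f"{pid}-ref{si}", state=state,
                                        stimuli=stimuli, schedule=sched))

        stimuli = []
        for k in range(n_pos + n_neg):
            val = "pos" if k < n_pos else "neg"
            stimuli.append(Stimulus(index=k, valence=val,
                                    features=_stimulus_features(
                                        val, latent, draw, sd_grp)))
        sched = make_schedule(pid, "screening", n_pos, n_neg, rng,
                              int(cfg.baseline_s * 1000),
                              int(cfg.stimulus_s * 1000),
                              int(cfg.rest_s * 1000))
        screening = Session(session_id=f"{pid}-screen", state="screening",
                            stimuli=stimuli, schedule=sched)

        p = Participant(pid=pid, group=group, latent=latent,
                        reference_latent=ref_latent,
                        reference_sessions=ref_sessions,
                        screening_session=screening)
        participants.append(p)

    cohort = Cohort(config=cfg, participants=participants)
    if with_traces:
        for i, p in enumerate(cohort.participants):
            for j, sess in enumerate(p.reference_sessions + [p.screening_session]):
                sess.trace = simulate_session_trace(
                    sess, cfg, seed=(cfg.seed * 97 + i * 11 + j) % (2 ** 31))
    return cohort


def _stimulus_features(valence: str, base: dict[str, float], draw,
                       sd_table: dict[str, float]) -> dict[str, float]:
    out = {}
    for key in ("PDA", "PDV"):
        out[key] = draw(f"{key}_{valence}", {f"{key}_{valence}":
                                             base[f"{key}_{valence}"]}, sd_table)
    for key in ("FD", "SV", "SA", "GDE", "EMA", "CL"):
        out[key] = draw(key, base, sd_table)
    out["FD"] = max(out["FD"], 50.0)
    out["SV"] = max(out["SV"], 0.0)
    out["SA"] = max(out["SA"], 0.1)
    out["GDE"] = float(np.clip(out["GDE"], 0.0, 6.0))
    out["EMA"] = max(out["EMA"], 0.0)
    out["CL"] = max(out["CL"], 0.0)
    return out


# ---------------------------------------------------------------------------
# iris images
# ---------------------------------------------------------------------------

def _identity_texture(params: IrisIdentityParams) -> np.ndarray:
    """Band-limited identity texture on a polar (radial x angular) grid,
    zero mean, unit SD.  Fully determined by identity_seed."""
    rng = _substream(params.identity_seed, 3)
    noise = rng.normal(size=(params.n_radial, params.n_angular))
    spec = np.fft.rfft(noise, axis=1)
    f = np.arange(spec.shape[1], dtype=float)
    band = ((f >= params.band_low) & (f <= params.band_high)).astype(float)
    tex = np.fft.irfft(spec * band[None, :], n=params.n_angular, axis=1)
    # mild radial smoothing for coherent ridges
    kernel = np.array([0.25, 0.5, 0.25])
    tex = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="same"), 0, tex)
    tex -= tex.mean()
    tex /= tex.std()
    return tex


def simulate_iris_image(id_params: IrisIdentityParams, dilation: float,
                        seed: int = 0) -> EyeImage:
    """Render a synthetic eye image at the given pupil dilation.

    Geometry: concentric pupil (dark disc, radius = pupil_radius_base *
    (1 + dilation)) and limbus circles; the annulus carries the
    identity-seeded texture mapped homogeneously between the two boundaries,
    so the same identity renders the same texture field at any dilation.
    """
    lo, hi = id_params.dilation_range
    if not lo <= dilation <= hi:
        raise ValueError(f"dilation {dilation} outside configured range [{lo}, {hi}]")
    size = id_params.image_size
    r_p = id_params.pupil_radius_base * (1.0 + dilation)
    r_l = id_params.limbus_radius
    if r_p >= r_l:
        raise ValueError("pupil radius must stay below the limbus radius")
    cx = cy = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    rr = np.hypot(xx - cx, yy - cy)
    rng = _substream(seed, 4)
    rot = math.radians(id_params.rotation_jitter_deg)
    theta = np.arctan2(yy - cy, xx - cx) + rot

    img = np.full((size, size), 0.92)  # sclera
    img[rr < r_l] = 0.5
    tex = _identity_texture(id_params)
    ann = (rr >= r_p) & (rr < r_l)
    rho = (rr[ann] - r_p) / (r_l - r_p)
    ri = rho * (id_params.n_radial - 1)
    ai = (np.mod(theta[ann], 2 * np.pi) / (2 * np.pi)) * id_params.n_angular
    from scipy.ndimage import map_coordinates
    vals = map_coordinates(tex, [ri, ai], order=1, mode="grid-wrap")
    img[ann] = 0.5 + 0.18 * vals
    img[rr < r_p] = 0.08  # pupil
    if id_params.intra_noise_sd > 0:
        img = img + rng.normal(0.0, id_params.intra_noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    gt = {"cx": cx, "cy": cy, "r_pupil": float(r_p), "r_limbus": float(r_l),
          "dilation": float(dilation), "identity_seed": id_params.identity_seed}
    return EyeImage(data=img, ground_truth=gt)


# ---------------------------------------------------------------------------
# rater matrices
# ---------------------------------------------------------------------------

def generate_rating_matrix(n_items: int = 186, n_raters: int = 3,
                           profile: RatingProfile | None = None,
                           seed: int = 0) -> RatingMatrix:
    """Valence/arousal rating matrices on the 1..9 integer scale.

    Each item has a latent truth on both scales; each rater reports
    truth + N(0, rater_sd), rounded and clipped to the scale.  With rater
    noise 0 all raters agree exactly (downstream ICC = 1)."""
    if n_raters < 2:
        raise ValueError("need at least 2 raters")
    profile = profile or RatingProfile()
    rng = _substream(seed, 5)

    def plane(truth_sd: float) -> np.ndarray:
        truth = rng.normal(profile.truth_mean, truth_sd, size=n_items)
        obs = truth[:, None] + rng.normal(0.0, profile.rater_sd,
                                          size=(n_items, n_raters))
        return np.clip(np.rint(obs), 1, 9).astype(int)

    valence = plane(profile.valence_truth_sd)
    arousal = plane(profile.arousal_truth_sd)
    ids = [f"item{i:04d}" for i in range(n_items)]
    return RatingMatrix(item_ids=ids, valence=valence, arousal=arousal)
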