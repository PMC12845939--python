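"""Trace hygiene, oculomotor event detection, and the per-stimulus feature
battery, z-scored against an individual multi-state baseline profile.

Features (per stimulus block):

* PDA  — pupil dilation amplitude, % of the pre-stimulus baseline mean
* CL   — pupil response delay, ms (censored when the pupil never responds)
* PDV  — peak dilation velocity of the percent-change signal, %/s
* FD   — mean fixation duration, ms
* SV   — mean saccade peak velocity, deg/s
* SA   — mean saccade amplitude, deg
* GDE  — gaze dispersion entropy, bits on an 8x8 spatial grid
* EMA  — left/right pupil-dilation asymmetry index, unitless

All screening is relative to the individual's own baseline profile: the
per-feature mean and SD over at least three reference sessions recorded in at
least two distinct states (rested / tired / stressed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .simgen import Block

__all__ = [
    "PreprocessConfig",
    "IVTConfig",
    "CleanTrace",
    "GazeEvent",
    "BaselineProfile",
    "FEATURE_NAMES",
    "SD_FLOOR_EPS",
    "preprocess",
    "pupil_features",
    "detect_events",
    "gaze_features",
    "asymmetry",
    "build_baseline",
    "zscore",
    "extract_session_features",
]

FEATURE_NAMES = ("PDA", "CL", "PDV", "FD", "SV", "SA", "GDE", "EMA")

# absolute SD floors per feature, in feature units
SD_FLOOR_EPS = {"PDA": 0.5, "CL": 20.0, "PDV": 0.5, "FD": 5.0,
                "SV": 5.0, "SA": 0.25, "GDE": 0.05, "EMA": 0.02}

PUPIL_RANGE_MM = (1.5, 9.0)


@dataclass
class PreprocessConfig:
    max_interp_gap_ms: float = 500.0
    pupil_smooth_ms: float = 100.0
    speed_smooth_ms: float = 20.0


@dataclass
class IVTConfig:
    velocity_threshold: float = 30.0  # deg/s
    min_fixation_ms: float = 50.0
    min_saccade_ms: float = 10.0


@dataclass
class CleanTrace:
    t_ms: np.ndarray
    pupil_l: np.ndarray  # smoothed mm, NaN where invalid
    pupil_r: np.ndarray
    pupil: np.ndarray  # two-eye mean
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    speed: np.ndarray  # deg/s
    valid: np.ndarray
    interpolated: np.ndarray
    fs: float


@dataclass
class GazeEvent:
    kind: str  # 'fixation' | 'saccade'
    start_ms: float
    end_ms: float
    amplitude_deg: float = float("nan")
    peak_velocity: float = float("nan")

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass
class BaselineProfile:
    stats: dict[str, tuple[float, float]]  # feature -> (mean, floored SD)
    n_sessions: int
    states: tuple[str, ...]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _interp_short_gaps(t: np.ndarray, x: np.ndarray, max_gap_ms: float
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate NaN runs no longer than max_gap_ms; longer runs
    stay NaN.  Returns (filled, interpolated_mask)."""
    x = x.copy()
    isnan = ~np.isfinite(x)
    interp_mask = np.zeros_like(isnan)
    if not isnan.any() or isnan.all():
        return x, interp_mask
    idx = np.arange(len(x))
    # locate NaN runs
    edges = np.diff(isnan.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if isnan[0]:
        starts.insert(0, 0)
    if isnan[-1]:
        ends.append(len(x))
    filled = np.interp(idx, idx[~isnan], x[~isnan])
    for s, e in zip(starts, ends):
        if s == 0 or e == len(x):
            continue  # edge gaps cannot be bridged
        gap_ms = t[e - 1] - t[s] + (t[1] - t[0])
        if gap_ms <= max_gap_ms:
            x[s:e] = filled[s:e]
            interp_mask[s:e] = True
    return x, interp_mask


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average that ignores NaNs (min_periods = 1)."""
    if window <= 1:
        return x.copy()
    return (pd.Series(x).rolling(window, center=True, min_periods=1)
            .mean().to_numpy())


def preprocess(raw: pd.DataFrame, cfg: PreprocessConfig | None = None) -> CleanTrace:
    """Clean a raw trace frame (columns ``t_ms, pupil_l_mm, pupil_r_mm,
    gaze_x_deg, gaze_y_deg, valid``).

    Out-of-range pupil samples and declared-invalid samples are treated as
    blinks/missing; gaps up to 500 ms are linearly interpolated, longer gaps
    stay invalid.  The pupil is smoothed with a 100 ms moving average; gaze
    speed comes from central differences with 20 ms smoothing.
    """
    cfg = cfg or PreprocessConfig()
    if len(raw) == 0:
        raise ValueError("empty trace")
    t = raw["t_ms"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time axis must be strictly increasing")
    fs = 1000.0 / float(np.median(np.diff(t)))
    if t[-1] - t[0] < 1000.0:
        raise ValueError("need at least 1 s of data")

    declared_valid = raw["valid"].to_numpy(dtype=bool) if "valid" in raw else \
        np.ones(len(raw), dtype=bool)

    eyes = {}
    masks = {}
    for col, key in (("pupil_l_mm", "l"), ("pupil_r_mm", "r")):
        if col not in raw:
            eyes[key] = np.full(len(raw), np.nan)
            masks[key] = np.zeros(len(raw), dtype=bool)
            continue
        p = raw[col].to_numpy(dtype=float)
        bad = (~np.isfinite(p)) | (p < PUPIL_RANGE_MM[0]) | (p > PUPIL_RANGE_MM[1]) \
            | (~declared_valid)
        p = np.where(bad, np.nan, p)
        p, im = _interp_short_gaps(t, p, cfg.max_interp_gap_ms)
        win = max(1, int(round(cfg.pupil_smooth_ms * fs / 1000.0)))
        sm = _moving_average(p, win)
        sm[~np.isfinite(p)] = np.nan
        eyes[key] = sm
        masks[key] = im

    pupil = np.nanmean(np.vstack([eyes["l"], eyes["r"]]), axis=0)
    valid = np.isfinite(pupil)
    interp = masks["l"] | masks["r"]

    gx = raw["gaze_x_deg"].to_numpy(dtype=float) if "gaze_x_deg" in raw else \
        np.zeros(len(raw))
    gy = raw["gaze_y_deg"].to_numpy(dtype=float) if "gaze_y_deg" in raw else \
        np.zeros(len(raw))
    gx, _ = _interp_short_gaps(t, np.where(declared_valid, gx, np.nan),
                               cfg.max_interp_gap_ms)
    gy, _ = _interp_short_gaps(t, np.where(declared_valid, gy, np.nan),
                               cfg.max_interp_gap_ms)
    dt_s = np.gradient(t) / 1000.0
    vx = np.gradient(gx) / dt_s
    vy = np.gradient(gy) / dt_s
    speed = np.hypot(vx, vy)
    win = max(1, int(round(cfg.speed_smooth_ms * fs / 1000.0)))
    speed = _moving_average(speed, win)
    speed[~np.isfinite(speed)] = np.nan

    return CleanTrace(t_ms=t, pupil_l=eyes["l"], pupil_r=eyes["r"], pupil=pupil,
                      gaze_x=gx, gaze_y=gy, speed=speed, valid=valid,
                      interpolated=interp, fs=fs)


# ---------------------------------------------------------------------------
# pupil features
# ---------------------------------------------------------------------------

def _kernel_rise_fraction(phi: float, shape_n: float = 10.1) -> float:
    """Solve h(x) = phi on (0, 1] for the unit-peak gamma kernel:
    shape_n * (ln x + 1 - x) = ln phi."""
    phi = float(np.clip(phi, 1e-12, 1.0 - 1e-12))
    target = math.log(phi) / shape_n

    def f(x: float) -> float:
        return math.log(x) + 1.0 - x - target

    return float(brentq(f, 1e-9, 1.0))


def pupil_features(clean: CleanTrace, block: Block, *, eye: str = "both",
                   search_ms: float = 10_000.0, baseline_ms: float = 3000.0,
                   min_baseline_valid: float = 0.8,
                   kernel_peak_ms: float = 930.0, kernel_shape: float = 10.1
                   ) -> dict[str, float]:
    """PDA / CL / PDV for one stimulus block.

    The baseline B is the mean smoothed diameter over the last ``baseline_ms``
    before onset.  PDA is the peak percent change over [onset, onset +
    search_ms); PDV the maximum derivative of the percent-change signal.  CL
    is a model-based onset estimate: the first sustained crossing of
    B + 1 SD(baseline), corrected by the deterministic rise-to-threshold
    interval of the canonical pupil impulse kernel (so CL tracks the true
    response latency rather than the crossing time).  CL is censored at the
    window end when the pupil never responds; a censored CL is reported as
    NaN with ``CL_censored`` = 1.
    """
    sig = {"both": clean.pupil, "l": clean.pupil_l, "r": clean.pupil_r}[eye]
    t = clean.t_ms
    base_mask = (t >= block.onset_ms - baseline_ms) & (t < block.onset_ms)
    win_mask = (t >= block.onset_ms) & (t < block.onset_ms + search_ms)
    out = {"PDA": np.nan, "CL": np.nan, "CL_censored": 0.0, "PDV": np.nan}
    if base_mask.sum() == 0 or win_mask.sum() == 0:
        out["CL_censored"] = 1.0
        return out
    base = sig[base_mask]
    frac_valid = np.isfinite(base).mean()
    if frac_valid < min_baseline_valid:
        out["CL_censored"] = 1.0
        return out
    B = float(np.nanmean(base))
    sd_b = float(np.nanstd(base, ddof=1)) if np.isfinite(base).sum() > 1 else 0.0

    d = sig[win_mask]
    tw = t[win_mask]
    if not np.isfinite(d).any():
        out["CL_censored"] = 1.0
        return out
    # signed extremal deviation: a blunted/constriction response (negative
    # amplitude) must come out negative, not as a near-zero maximum
    dev = d - B
    i_ext = int(np.nanargmax(np.abs(dev)))
    out["PDA"] = 100.0 * float(dev[i_ext]) / B
    peak = float(np.nanmax(d))

    pct = 100.0 * (d - B) / B
    dt_s = np.gradient(tw) / 1000.0
    with np.errstate(invalid="ignore"):
        deriv = np.gradient(np.nan_to_num(pct, nan=0.0)) / dt_s
    out["PDV"] = float(np.nanmax(deriv)) if np.isfinite(deriv).any() else np.nan

    thresh = B + max(sd_b, 1e-9)
    if peak <= thresh:
        out["CL_censored"] = 1.0
        return out
    # crossing attached to the main response: last up-crossing before the
    # peak, so isolated pre-response noise excursions are ignored
    dv = np.nan_to_num(d, nan=-np.inf)
    i_peak = int(np.argmax(dv))
    below = np.nonzero(dv[: i_peak + 1] <= thresh)[0]
    cross_idx = int(below[-1]) + 1 if len(below) else 0
    if cross_idx > i_peak:
        out["CL_censored"] = 1.0
        return out
    phi = (thresh - B) / max(peak - B, 1e-12)
    rise_ms = _kernel_rise_fraction(phi, kernel_shape) * kernel_peak_ms
    cl = (tw[cross_idx] - block.onset_ms) - rise_ms
    out["CL"] = float(max(cl, 0.0))
    return out


# ---------------------------------------------------------------------------
# gaze events and features
# ---------------------------------------------------------------------------

def detect_events(clean: CleanTrace, cfg: IVTConfig | None = None) -> list[GazeEvent]:
    """Velocity-threshold (I-VT) event detection.

    Samples faster than the velocity threshold form saccades (minimum 10 ms;
    shorter super-threshold fragments are folded back into fixations);
    sub-threshold samples form fixations (minimum 50 ms), with adjacent
    fragments merged.
    """
    cfg = cfg or IVTConfig()
    ok = np.isfinite(clean.speed)
    if not ok.any():
        return []
    t = clean.t_ms
    dt_ms = 1000.0 / clean.fs
    lab = np.where(np.nan_to_num(clean.speed, nan=0.0) > cfg.velocity_threshold, 1, 0)
    lab[~ok] = 0
    # collapse to runs
    runs = _runs(lab)
    # fold too-short saccades into fixations
    runs = [(0 if (k == 1 and (t[e - 1] - t[s] + dt_ms) < cfg.min_saccade_ms) else k,
             s, e) for k, s, e in runs]
    runs = _merge_adjacent(runs)
    events: list[GazeEvent] = []
    for k, s, e in runs:
        dur = t[e - 1] - t[s] + dt_ms
        if k == 0:
            if dur < cfg.min_fixation_ms:
                continue
            events.append(GazeEvent("fixation", float(t[s]), float(t[s] + dur)))
        else:
            amp = float(np.hypot(clean.gaze_x[e - 1] - clean.gaze_x[s],
                                 clean.gaze_y[e - 1] - clean.gaze_y[s]))
            pv = float(np.nanmax(clean.speed[s:e]))
            events.append(GazeEvent("saccade", float(t[s]), float(t[s] + dur),
                                    amplitude_deg=amp, peak_velocity=pv))
    return events


def _runs(lab: np.ndarray) -> list[tuple[int, int, int]]:
    out = []
    s = 0
    for i in range(1, len(lab) + 1):
        if i == len(lab) or lab[i] != lab[s]:
            out.append((int(lab[s]), s, i))
            s = i
    return out


def _merge_adjacent(runs: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    out: list[tuple[int, int, int]] = []
    for k, s, e in runs:
        if out and out[-1][0] == k:
            out[-1] = (k, out[-1][1], e)
        else:
            out.append((k, s, e))
    return out


def gaze_features(events: list[GazeEvent], clean: CleanTrace, block: Block,
                  extent: tuple[tuple[float, float], tuple[float, float]] =
                  ((-20.0, 20.0), (-12.0, 12.0)),
                  n_bins: int = 8) -> dict[str, float]:
    """FD / SV / SA / GDE over the stimulus window.

    GDE is the Shannon entropy (bits) of the distribution of valid gaze
    samples over an ``n_bins x n_bins`` equal-area grid spanning the display
    extent; 0 bits means fully concentrated gaze, log2(n_bins^2) uniform.
    """
    w0, w1 = block.onset_ms, block.onset_ms + block.stimulus_ms
    out = {"FD": np.nan, "SV": np.nan, "SA": np.nan, "GDE": np.nan}
    fix = [ev for ev in events if ev.kind == "fixation"
           and ev.start_ms < w1 and ev.end_ms > w0]
    sac = [ev for ev in events if ev.kind == "saccade"
           and ev.start_ms < w1 and ev.end_ms > w0]
    if fix:
        out["FD"] = float(np.mean([ev.duration_ms for ev in fix]))
    if sac:
        out["SV"] = float(np.mean([ev.peak_velocity for ev in sac]))
        out["SA"] = float(np.mean([ev.amplitude_deg for ev in sac]))
    m = (clean.t_ms >= w0) & (clean.t_ms < w1) & np.isfinite(clean.gaze_x) \
        & np.isfinite(clean.gaze_y)
    if m.any():
        (x0, x1), (y0, y1) = extent
        hist, _, _ = np.histogram2d(
            np.clip(clean.gaze_x[m], x0, x1 - 1e-9),
            np.clip(clean.gaze_y[m], y0, y1 - 1e-9),
            bins=n_bins, range=[[x0, x1], [y0, y1]])
        p = hist.ravel() / hist.sum()
        p = p[p > 0]
        out["GDE"] = float(-(p * np.log2(p)).sum())
    return out


def asymmetry(delta_left_mm: float, delta_right_mm: float,
              eps: float = 1e-6) -> float:
    """Eye-movement asymmetry index on absolute pupil dilation:
    EMA = |dL - dR| / max(eps, (dL + dR) / 2).  NaN when either eye is
    missing (single-eye session)."""
    if not (np.isfinite(delta_left_mm) and np.isfinite(delta_right_mm)):
        return float("nan")
    dl, dr = abs(delta_left_mm), abs(delta_right_mm)
    return float(abs(dl - dr) / max(eps, (dl + dr) / 2.0))


# ---------------------------------------------------------------------------
# baseline profiles and z-scores
# ---------------------------------------------------------------------------

def build_baseline(session_features: list[dict[str, float]],
                   states: list[str],
                   floors: dict[str, float] | None = None) -> BaselineProfile:
    """Per-feature mean/SD over reference sessions.

    Requires at least three sessions covering at least two distinct states.
    The SD is floored at max(0.05 * |mean|, feature floor) so over-consistent
    reference data cannot produce degenerate z-scores.
    """
    if len(session_features) < 3:
        raise ValueError(
            f"need at least 3 reference sessions, got {len(session_features)}")
    if len(set(states)) < 2:
        raise ValueError(
            f"need at least 2 distinct states, got {sorted(set(states))}")
    floors = floors or SD_FLOOR_EPS
    keys = set().union(*(f.keys() for f in session_features)) - {"CL_censored"}
    stats = {}
    for k in sorted(keys):
        vals = np.array([f.get(k, np.nan) for f in session_features], dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            continue
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        floor = max(0.05 * abs(mu), floors.get(k, 1e-6))
        stats[k] = (mu, max(sd, floor))
    return BaselineProfile(stats=stats, n_sessions=len(session_features),
                           states=tuple(sorted(set(states))))


def zscore(features: dict[str, float], profile: BaselineProfile) -> dict[str, float]:
    """Baseline-relative z-scores, z = (x - mean) / SD; NaN propagates."""
    out = {}
    for k, x in features.items():
        if k == "CL_censored":
            continue
        if k not in profile.stats:
            raise KeyError(f"baseline profile does not cover feature {k!r}")
        mu, sd = profile.stats[k]
        out[k] = float((x - mu) / sd) if np.isfinite(x) else float("nan")
    return out


# ---------------------------------------------------------------------------
# session-level driver
# ---------------------------------------------------------------------------

def extract_session_features(trace: pd.DataFrame, schedule,
                             pre_cfg: PreprocessConfig | None = None,
                             ivt_cfg: IVTConfig | None = None) -> list[dict]:
    """Run the full extraction for one session: preprocess, detect events,
    and compute the eight-feature vector per stimulus block."""
    clean = preprocess(trace, pre_cfg)
    events = detect_events(clean, ivt_cfg)
    rows = []
    for i, block in enumerate(schedule.blocks):
        pf = pupil_features(clean, block)
        gf = gaze_features(events, clean, block)
        dl = _eye_delta(clean, block, "l")
        dr = _eye_delta(clean, block, "r")
        row = {"stimulus_idx": i, "valence": block.valence, **pf, **gf,
               "EMA": asymmetry(dl, dr)}
        rows.append(row)
    return rows


def _eye_delta(clean: CleanTrace, block: Block, eye: str,
               baseline_ms: float = 3000.0, search_ms: float = 10_000.0) -> float:
    sig = clean.pupil_l if eye == "l" else clean.pupil_r
    t = clean.t_ms
    base = sig[(t >= block.onset_ms - baseline_ms) & (t < block.onset_ms)]
    win = sig[(t >= block.onset_ms) & (t < block.onset_ms + search_ms)]
    if not (np.isfinite(base).any() and np.isfinite(win).any()):
        return float("nan")
    dev = win - np.nanmean(base)
    return float(dev[np.nanargmax(np.abs(dev))])
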