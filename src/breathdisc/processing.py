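"""Signal processing: raw sensor traces to breathprint features.

Pipeline per channel: detrend (least-squares line removed, level kept),
low-pass smoothing, ambient-air correction against the paired ambient
sensor, then landmark detection.  Two landmarks are read per exhaled
channel: the signal peak during the slow expiration (P) and the value at
the breath-hold plateau (B).  The per-measurement feature vector is the
six peak ratios P_s / P_ref (reference = sensor 2, whose own ratio is
identically 1 and therefore dropped) plus the seven peak / breath-hold
ratios P_s / B_s.  Duplicate measurements of a subject are merged by
element-wise averaging with a discordance check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import (FEATURE_NAMES, N_SENSORS, REFERENCE_SENSOR, BreathFeatures,
                   Phase, SensorRecording)

__all__ = [
    "FeatureConfig",
    "Landmarks",
    "preprocess",
    "ambient_correct",
    "detect_landmarks",
    "extract_features",
    "merge_duplicates",
    "extract_cohort",
]

_MIN_SAMPLES = 20


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable parameters of the feature-extraction pipeline."""

    ambient_mode: str = "subtract"     # or "ratio"
    smooth_window_s: float = 0.5       # moving-average width
    reference_sensor: int = REFERENCE_SENSOR  # 1-based
    noise_k: float = 5.0               # peak must exceed baseline + k*noise
    merge_rel_tol: float = 0.20        # replicate discordance threshold

    def __post_init__(self) -> None:
        if self.ambient_mode not in ("subtract", "ratio"):
            raise ValueError("ambient_mode must be 'subtract' or 'ratio'")
        if not 1 <= self.reference_sensor <= N_SENSORS:
            raise ValueError("reference_sensor must be in 1..7")


def _detrend_keep_level(channels: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Remove the least-squares line per row, re-adding the mean level."""
    A = np.column_stack([t, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(A, channels.T, rcond=None)
    fitted = (A @ coef).T
    return channels - fitted + channels.mean(axis=-1, keepdims=True)


def _smooth(channels: np.ndarray, sample_rate: float, window_s: float) -> np.ndarray:
    w = max(1, int(round(window_s * sample_rate)))
    if w <= 1:
        return channels
    return uniform_filter1d(channels, size=w, axis=-1, mode="nearest")


def preprocess(series: np.ndarray, sample_rate: float,
               smooth_window_s: float = 0.5) -> np.ndarray:
    """Detrend and low-pass smooth one channel.

    The linear trend is removed but the mean level is kept, so a pure
    ramp collapses to its midpoint value and a constant series passes
    through unchanged.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size < _MIN_SAMPLES:
        raise ValueError(f"need a 1-D series with >= {_MIN_SAMPLES} samples")
    t = np.arange(y.size) / sample_rate
    out = _detrend_keep_level(y[None, :], t)[0]
    return _smooth(out[None, :], sample_rate, smooth_window_s)[0]


def ambient_correct(exhaled: np.ndarray, ambient: np.ndarray,
                    mode: str = "subtract",
                    eps: float = 1e-9) -> tuple[np.ndarray, list[str]]:
    """Remove ambient-air background from an exhaled channel.

    ``subtract`` (default) removes the ambient fluctuation around its
    median (common-mode rejection); ``ratio`` divides by the ambient
    signal, guarded by ``eps`` for nonpositive values (flagged).
    Returns ``(corrected, flags)``.
    """
    ex = np.asarray(exhaled, dtype=float)
    am = np.asarray(ambient, dtype=float)
    if ex.shape != am.shape:
        raise ValueError("exhaled and ambient series must have equal length")
    flags: list[str] = []
    if mode == "subtract":
        corrected = ex - (am - np.median(am, axis=-1, keepdims=True))
    elif mode == "ratio":
        if np.any(am <= 0):
            flags.append("nonpositive_ambient")
        corrected = ex / np.maximum(am, eps)
    else:
        raise ValueError("mode must be 'subtract' or 'ratio'")
    return corrected, flags


@dataclass
class Landmarks:
    """Detected peak and breath-hold landmarks of one channel."""

    peak_value: float
    peak_index: int
    hold_value: float
    hold_index: int
    qc_ok: bool = True
    flags: tuple[str, ...] = ()


def _noise_window(n: int, phase: np.ndarray | None) -> np.ndarray:
    if phase is not None and np.any(phase == Phase.TIDAL.value):
        return np.flatnonzero(phase == Phase.TIDAL.value)
    return np.arange(max(_MIN_SAMPLES // 2, n // 5))


def detect_landmarks(channel: np.ndarray,
                     phase: np.ndarray | None = None,
                     sample_rate: float = 10.0,
                     noise_k: float = 5.0) -> Landmarks:
    """Locate the expiration peak and the breath-hold plateau.

    With phase labels, P is the maximum over the expiration window and B
    the value at the last breath-hold sample.  Without phases, P is the
    global maximum and B the low-derivative plateau immediately before
    the peak's rise.  A channel whose peak does not clear the baseline
    by ``noise_k`` noise SDs fails QC (flag, not an exception).
    """
    y = np.asarray(channel, dtype=float)
    n = y.size
    flags: list[str] = []

    if phase is not None:
        exp_idx = np.flatnonzero(phase == Phase.EXPIRATION.value)
        hold_idx = np.flatnonzero(phase == Phase.HOLD.value)
        if exp_idx.size == 0 or hold_idx.size == 0:
            return Landmarks(np.nan, -1, np.nan, -1, qc_ok=False,
                             flags=("missing_phase_segment",))
        peak_index = int(exp_idx[np.argmax(y[exp_idx])])
        hold_index = int(hold_idx[-1])
    else:
        peak_index = int(np.argmax(y))
        w = max(1, int(round(0.5 * sample_rate)))
        d = uniform_filter1d(np.abs(np.gradient(y)), size=w, mode="nearest")
        # plateau = flattest point in the few seconds before the peak's rise
        w0 = max(0, peak_index - int(round(5.0 * sample_rate)))
        pre = d[w0:peak_index] if peak_index > w0 else d[:1]
        hold_index = w0 + int(np.argmin(pre))

    base_idx = _noise_window(n, phase)
    baseline = float(np.median(y[base_idx]))
    noise = _diff_noise_sd(y[None, base_idx])[0]
    peak_value = float(y[peak_index])
    hold_value = float(y[hold_index])

    prominence = peak_value - baseline
    floor = max(noise_k * noise, 1e-9 * max(1.0, abs(peak_value)))
    qc_ok = prominence > floor
    if not qc_ok:
        flags.append("no_peak_above_noise")
    return Landmarks(peak_value, peak_index, hold_value, hold_index,
                     qc_ok=qc_ok, flags=tuple(flags))


def _diff_noise_sd(channels: np.ndarray) -> np.ndarray:
    """Robust per-row noise SD from successive differences.

    Differencing removes the local trend left in the baseline window by
    whole-trace detrending, so only high-frequency noise is measured.
    """
    d = np.diff(channels, axis=-1)
    return 1.4826 * np.median(np.abs(d), axis=-1) / np.sqrt(2.0)


def _batch_landmarks(channels: np.ndarray, phase: np.ndarray | None,
                     noise_k: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised landmark detection for a (7, T) block with known phases."""
    exp_mask = phase == Phase.EXPIRATION.value
    hold_idx = np.flatnonzero(phase == Phase.HOLD.value)
    exp_idx = np.flatnonzero(exp_mask)
    P = channels[:, exp_idx].max(axis=1)
    B = channels[:, hold_idx[-1]]
    base_idx = _noise_window(channels.shape[1], phase)
    baseline = np.median(channels[:, base_idx], axis=1)
    noise = _diff_noise_sd(channels[:, base_idx])
    floor = np.maximum(noise_k * noise, 1e-9 * np.maximum(1.0, np.abs(P)))
    ok = (P - baseline) > floor
    return P, B, ok


def extract_features(recording: SensorRecording,
                     config: FeatureConfig | None = None) -> BreathFeatures:
    """Run the full per-measurement pipeline and emit the 13 features."""
    cfg = config or FeatureConfig()
    t = recording.time_s - recording.time_s[0]
    ex = _smooth(_detrend_keep_level(recording.exhaled, t),
                 recording.sample_rate_hz, cfg.smooth_window_s)
    am = _smooth(_detrend_keep_level(recording.ambient, t),
                 recording.sample_rate_hz, cfg.smooth_window_s)
    corrected, flags = ambient_correct(ex, am, mode=cfg.ambient_mode)

    if recording.phase is not None:
        P, B, ok = _batch_landmarks(corrected, recording.phase, cfg.noise_k)
        qc_ok = bool(ok.all())
        if not qc_ok:
            flags.append("no_peak_above_noise")
    else:
        P = np.empty(N_SENSORS)
        B = np.empty(N_SENSORS)
        qc_ok = True
        for s in range(N_SENSORS):
            lm = detect_landmarks(corrected[s], None,
                                  recording.sample_rate_hz, cfg.noise_k)
            P[s], B[s] = lm.peak_value, lm.hold_value
            if not lm.qc_ok:
                qc_ok = False
                flags.extend(lm.flags)

    ref = cfg.reference_sensor - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        peak_ratio = P / P[ref]
        peak_bh = P / B
    if qc_ok and (P[ref] <= 0 or np.any(B <= 0) or np.any(P <= 0)):
        qc_ok = False
        flags.append("nonpositive_landmark")
    values = np.concatenate([np.delete(peak_ratio, ref), peak_bh])
    if qc_ok and not np.all(np.isfinite(values)):
        qc_ok = False
        flags.append("nonfinite_feature")
    return BreathFeatures(subject_id=recording.subject_id,
                          replicate=recording.replicate, values=values,
                          qc_ok=qc_ok, qc_flags=tuple(dict.fromkeys(flags)))


def merge_duplicates(rep1: BreathFeatures, rep2: BreathFeatures,
                     rel_tol: float = 0.20) -> BreathFeatures:
    """Merge the duplicate measurements of one subject.

    Element-wise mean of concordant replicates; a relative difference
    above ``rel_tol`` on any feature sets a ``replicate_discordant``
    flag.  If exactly one replicate failed QC the other is used alone
    (flagged); if both failed the merged record is QC-failed and the
    subject is excluded downstream.
    """
    if rep1.subject_id != rep2.subject_id:
        raise ValueError("replicates belong to different subjects")
    if not rep1.qc_ok and not rep2.qc_ok:
        return BreathFeatures(rep1.subject_id, np.full(len(FEATURE_NAMES), np.nan),
                              replicate=None, qc_ok=False,
                              qc_flags=("both_replicates_failed",))
    if rep1.qc_ok != rep2.qc_ok:
        good = rep1 if rep1.qc_ok else rep2
        return BreathFeatures(good.subject_id, good.values.copy(),
                              replicate=None, qc_ok=True,
                              qc_flags=("single_replicate",))
    a, b = rep1.values, rep2.values
    flags: tuple[str, ...] = ()
    denom = (np.abs(a) + np.abs(b)) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(denom > 0, np.abs(a - b) / denom, 0.0)
    if np.any(rel > rel_tol):
        flags = ("replicate_discordant",)
    return BreathFeatures(rep1.subject_id, (a + b) / 2.0, replicate=None,
                          qc_ok=True, qc_flags=flags)


def extract_cohort(recordings: list[SensorRecording],
                   config: FeatureConfig | None = None):
    """Extract and merge features for a whole cohort.

    Returns a DataFrame with one row per subject: ``subject_id``, the 13
    features, ``qc_ok`` and ``qc_flags``.
    """
    import pandas as pd

    cfg = config or FeatureConfig()
    by_subject: dict[str, list[BreathFeatures]] = {}
    for rec in recordings:
        by_subject.setdefault(rec.subject_id, []).append(
            extract_features(rec, cfg))
    rows = []
    for sid, feats in by_subject.items():
        if len(feats) == 2:
            merged = merge_duplicates(feats[0], feats[1], cfg.merge_rel_tol)
        elif len(feats) == 1:
            f = feats[0]
            merged = BreathFeatures(sid, f.values.copy(), replicate=None,
                                    qc_ok=f.qc_ok,
                                    qc_flags=f.qc_flags + ("single_replicate",))
        else:
            raise ValueError(f"subject {sid} has {len(feats)} recordings")
        rows.append({"subject_id": sid,
                     **dict(zip(FEATURE_NAMES, merged.values)),
                     "qc_ok": merged.qc_ok,
                     "qc_flags": ";".join(merged.qc_flags)})
    return pd.DataFrame(rows)
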