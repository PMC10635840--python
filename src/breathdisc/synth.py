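"""Forward simulation of eNose breath recordings and study cohorts.

The generator emulates the clinical measurement: five tidal breaths, an
inspiratory capacity maneuver to total lung capacity, a 5-s breath hold,
and a slow expiration (< 0.4 L/s) to residual volume, recorded by seven
cross-reactive metal-oxide sensors sampling exhaled air while a parallel
array of the same sensors samples ambient air.

The unobserved volatile-organic-compound (VOC) mixture of a subject is
reduced to three latent components: one COPD-associated, one
cancer-associated, and one shared/ambient component.  Each sensor
responds to a weighted sum of the latent intensities through a smooth
maneuver-locked response kernel, on top of a baseline with linear drift
and white noise.  All between-class differences in the latent means
scale with a single ``effect_size`` knob, so the discriminating signal
is low-dimensional (mirroring the way a small number of principal
components carries the contrast in real breathprint data) and
``effect_size = 0`` yields an exchangeable null cohort.

Cohort-level defaults mirror the study population: 682 COPD subjects of
whom 37 develop clinically manifest lung cancer within two years, and
211 lung-cancer subjects, measured in duplicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import N_SENSORS, Phase, SensorRecording

__all__ = [
    "ManeuverParams",
    "ManeuverTrace",
    "SensorArraySpec",
    "VOCProfile",
    "CohortSpec",
    "simulate_maneuver",
    "response_kernel",
    "simulate_recording",
    "generate_cohort",
    "DEFAULT_SENSITIVITY",
    "DEFAULT_BASELINE",
    "LATENT_NAMES",
    "STAGE_FACTORS",
]

LATENT_NAMES = ("copd", "cancer", "shared")

#: Per-sensor response weights to the (copd, cancer, shared) latent VOC
#: components.  Cross-reactive but linearly independent so the cancer
#: contrast is recoverable from the array yet confined to no single sensor.
DEFAULT_SENSITIVITY = np.array(
    [
        [0.80, 0.10, 0.50],
        [0.30, 0.30, 0.60],  # sensor 2: moderate, balanced -> stable reference
        [0.10, 0.90, 0.50],
        [0.60, 0.50, 0.40],
        [0.20, 0.70, 0.60],
        [0.90, 0.30, 0.30],
        [0.40, 0.60, 0.50],
    ]
)

#: Resting signal level per sensor (arbitrary sensor units).
DEFAULT_BASELINE = np.array([10.0, 12.0, 9.0, 11.0, 10.5, 9.5, 11.5])

#: Cancer-stage severity multipliers on the cancer-associated latent
#: shift; a steep gradient reflecting tumour burden, so that early vs
#: advanced stage remains a detectable contrast within small groups.
STAGE_FACTORS = {"I": 0.5, "II": 0.75, "III": 1.25, "IV": 1.5}

#: Between-subject SD of each latent component; `effect_size` is expressed
#: in units of this SD.
LATENT_SD = 0.25
_LATENT_BASE = {"copd": 1.0, "cancer": 0.30, "shared": 1.0}
_CANCER_COPD_LATENT = 0.5  # copd component in cancer subjects without COPD
#: Double-diagnosis (cancer + comorbid COPD) subjects show an intermediate
#: breathprint: full COPD component plus an attenuated cancer shift.
_COMORBID_ATTENUATION = 0.75

_CLASS_LABELS = ("COPD", "LUNG_CANCER", "COPD_INCIDENT_CANCER")


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


@dataclass(frozen=True)
class ManeuverParams:
    """Timing of the standardised breath maneuver.

    Defaults encode the clinical protocol: 5 tidal breaths, inspiratory
    capacity maneuver, 5-s breath hold, then a slow expiration whose
    flow must stay below 0.4 L/s.
    """

    n_tidal_breaths: int = 5
    tidal_period_s: float = 4.0
    inspiration_s: float = 2.5
    breath_hold_s: float = 5.0
    expiration_s: float = 10.0
    expiratory_flow_lps: float = 0.35
    sample_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        if self.n_tidal_breaths < 0:
            raise ValueError("n_tidal_breaths must be >= 0")
        for name in ("tidal_period_s", "inspiration_s", "breath_hold_s",
                     "expiration_s", "sample_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.expiratory_flow_lps < 0.4:
            raise ValueError("expiratory_flow_lps must be in (0, 0.4) L/s")

    @property
    def total_duration_s(self) -> float:
        return (self.n_tidal_breaths * self.tidal_period_s
                + self.inspiration_s + self.breath_hold_s + self.expiration_s)

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration_s * self.sample_rate_hz))


@dataclass
class ManeuverTrace:
    """Phase-annotated airflow trace of one maneuver."""

    time_s: np.ndarray
    flow_lps: np.ndarray
    phase: np.ndarray
    params: ManeuverParams


def simulate_maneuver(params: ManeuverParams | None = None,
                      rng: np.random.Generator | None = None) -> ManeuverTrace:
    """Generate the airflow trace and per-sample phase labels.

    ``rng`` (optional) adds small per-breath tidal-amplitude variability;
    the phase structure is deterministic either way.
    """
    p = params if params is not None else ManeuverParams()
    n = p.n_samples
    t = np.arange(n) / p.sample_rate_hz

    t_tidal_end = p.n_tidal_breaths * p.tidal_period_s
    t_insp_end = t_tidal_end + p.inspiration_s
    t_hold_end = t_insp_end + p.breath_hold_s

    phase = np.full(n, Phase.EXPIRATION.value, dtype=np.int8)
    phase[t < t_hold_end] = Phase.HOLD.value
    phase[t < t_insp_end] = Phase.INSPIRATION.value
    phase[t < t_tidal_end] = Phase.TIDAL.value

    flow = np.zeros(n)
    tidal = phase == Phase.TIDAL.value
    if np.any(tidal):
        amp = np.full(p.n_tidal_breaths, 0.5)
        if rng is not None:
            amp = amp * (1.0 + 0.05 * rng.standard_normal(p.n_tidal_breaths))
        breath_idx = np.minimum(
            (t[tidal] / p.tidal_period_s).astype(int), p.n_tidal_breaths - 1)
        flow[tidal] = amp[breath_idx] * np.sin(
            2.0 * np.pi * t[tidal] / p.tidal_period_s)

    insp = phase == Phase.INSPIRATION.value
    u = (t[insp] - t_tidal_end) / p.inspiration_s
    flow[insp] = 1.2 * np.sin(np.pi * u)

    expi = phase == Phase.EXPIRATION.value
    u = (t[expi] - t_hold_end) / p.expiration_s
    # constant slow expiration with smooth 0.5-s on/off ramps
    ramp = np.minimum(1.0, np.minimum(u, 1.0 - u) * p.expiration_s / 0.5)
    flow[expi] = -p.expiratory_flow_lps * np.clip(ramp, 0.0, 1.0)

    return ManeuverTrace(time_s=t, flow_lps=flow, phase=phase, params=p)


# response-kernel shape constants: fraction of full response reached at the
# end of inspiration / breath hold, the within-expiration peak position, and
# the post-peak relaxation
_G_INSP = 0.15
_G_HOLD = 0.55
_G_PEAK_FRAC = 0.35
_G_END = 0.25
_G_DECAY = 3.0


def response_kernel(trace: ManeuverTrace) -> np.ndarray:
    """Maneuver-locked sensor response kernel g(t) in [0, 1].

    Zero during tidal breathing, rises through inspiration, flattens to a
    plateau of height ``0.55`` by the end of the breath hold (the
    breath-hold landmark), peaks at 1 early in the slow expiration and
    then relaxes.  Smoothstep segments make the plateau and peak
    well-defined landmarks at any sample rate.
    """
    p = trace.params
    t = trace.time_s
    g = np.zeros_like(t)
    t_tidal_end = p.n_tidal_breaths * p.tidal_period_s
    t_insp_end = t_tidal_end + p.inspiration_s
    t_hold_end = t_insp_end + p.breath_hold_s

    insp = trace.phase == Phase.INSPIRATION.value
    g[insp] = _G_INSP * _smoothstep((t[insp] - t_tidal_end) / p.inspiration_s)

    hold = trace.phase == Phase.HOLD.value
    g[hold] = _G_INSP + (_G_HOLD - _G_INSP) * _smoothstep(
        (t[hold] - t_insp_end) / p.breath_hold_s)

    expi = trace.phase == Phase.EXPIRATION.value
    u = (t[expi] - t_hold_end) / p.expiration_s
    rising = u < _G_PEAK_FRAC
    ge = np.empty(u.shape)
    ge[rising] = _G_HOLD + (1.0 - _G_HOLD) * _smoothstep(u[rising] / _G_PEAK_FRAC)
    ge[~rising] = _G_END + (1.0 - _G_END) * np.exp(
        -_G_DECAY * (u[~rising] - _G_PEAK_FRAC))
    g[expi] = ge
    return g


@dataclass
class SensorArraySpec:
    """Response and noise model of one 7-sensor array."""

    sensitivity_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_SENSITIVITY.copy())
    baseline_level: np.ndarray = field(
        default_factory=lambda: DEFAULT_BASELINE.copy())
    drift_rate: float = 0.01  # signal units / s, common to both arrays
    noise_sd: float = 0.05
    reference_sensor_index: int = 2  # 1-based

    def __post_init__(self) -> None:
        self.sensitivity_matrix = np.asarray(self.sensitivity_matrix, float)
        self.baseline_level = np.asarray(self.baseline_level, float)
        if self.sensitivity_matrix.shape[0] != N_SENSORS:
            raise ValueError(f"sensitivity_matrix needs {N_SENSORS} rows")
        if not np.all(np.isfinite(self.sensitivity_matrix)):
            raise ValueError("sensitivity_matrix must be finite")
        if self.baseline_level.shape != (N_SENSORS,):
            raise ValueError(f"baseline_level needs {N_SENSORS} entries")
        if np.any(self.baseline_level <= 0):
            raise ValueError("baseline_level must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 1 <= self.reference_sensor_index <= N_SENSORS:
            raise ValueError("reference_sensor_index must be in 1..7")

    @property
    def n_latent(self) -> int:
        return self.sensitivity_matrix.shape[1]


@dataclass
class VOCProfile:
    """Latent VOC intensities of one subject plus ground-truth labels."""

    latent_components: np.ndarray
    class_label: str
    stage: str | None = None

    def __post_init__(self) -> None:
        self.latent_components = np.asarray(self.latent_components, float)
        if np.any(self.latent_components < 0):
            raise ValueError("latent intensities must be >= 0")
        if self.class_label not in _CLASS_LABELS:
            raise ValueError(f"class_label must be one of {_CLASS_LABELS}")
        involves_cancer = self.class_label != "COPD"
        if involves_cancer and self.stage is None:
            raise ValueError("stage required for cancer-involving labels")
        if not involves_cancer and self.stage is not None:
            raise ValueError("stage only meaningful for cancer-involving labels")
        if self.stage is not None and self.stage not in STAGE_FACTORS:
            raise ValueError("stage must be one of I, II, III, IV")


def simulate_recording(profile: VOCProfile,
                       array: SensorArraySpec,
                       trace: ManeuverTrace,
                       ambient_drift_rate: float | None = None,
                       rng: np.random.Generator | None = None,
                       subject_id: str = "S0000",
                       replicate: int = 1) -> SensorRecording:
    """Simulate the 14-channel recording of one maneuver.

    Exhaled channel s:  ``b_s * (1 + (S @ v)_s * g(t)) + drift*t + noise``
    Ambient channel s:  ``b_s + drift*t + noise``

    where ``S`` is the sensitivity matrix, ``v`` the latent VOC vector
    and ``g`` the maneuver-locked response kernel.  The drift term is
    common-mode across the paired arrays so ambient correction can
    remove it.
    """
    v = profile.latent_components
    if v.shape != (array.n_latent,):
        raise ValueError(
            f"latent vector length {v.shape} does not match sensitivity "
            f"matrix with {array.n_latent} components")
    t = trace.time_s
    g = response_kernel(trace)
    amp = array.sensitivity_matrix @ v  # (7,)
    base = array.baseline_level[:, None]
    drift_ex = array.drift_rate
    drift_am = ambient_drift_rate if ambient_drift_rate is not None else drift_ex

    exhaled = base * (1.0 + amp[:, None] * g[None, :]) + drift_ex * t[None, :]
    ambient = np.broadcast_to(base, (N_SENSORS, t.size)).copy()
    ambient += drift_am * t[None, :]
    if array.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        exhaled = exhaled + rng.normal(0.0, array.noise_sd, exhaled.shape)
        ambient = ambient + rng.normal(0.0, array.noise_sd, ambient.shape)

    return SensorRecording(
        subject_id=subject_id, replicate=replicate, time_s=t,
        exhaled=exhaled, ambient=ambient,
        sample_rate_hz=trace.params.sample_rate_hz, phase=trace.phase)


@dataclass
class CohortSpec:
    """Cohort composition and generative settings.

    Default group sizes mirror the study population (682 COPD of whom 37
    develop lung cancer within 2 years, 211 lung cancer).  ``effect_size``
    is the standardized mean shift (in units of the between-subject
    latent SD) of the cancer-associated latent component in cancer and
    incident-cancer subjects; the default of 2.0 reproduces separations
    of the magnitude reported for real breathprints (AUC around 0.9).
    """

    n_copd: int = 682
    n_cancer: int = 211
    n_incident: int = 37
    effect_size: float = 2.0
    replicate_noise_sd: float = 0.05
    seed: int = 0
    comorbid_fraction: float = 0.55
    covariate_leakage: float = 0.0
    maneuver: ManeuverParams = field(default_factory=ManeuverParams)
    array: SensorArraySpec = field(default_factory=SensorArraySpec)

    def __post_init__(self) -> None:
        if self.n_copd < 0 or self.n_cancer < 0 or self.n_incident < 0:
            raise ValueError("group sizes must be >= 0")
        if self.n_incident > self.n_copd:
            raise ValueError("n_incident cannot exceed n_copd")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.replicate_noise_sd < 0:
            raise ValueError("replicate_noise_sd must be >= 0")
        if not 0 <= self.comorbid_fraction <= 1:
            raise ValueError("comorbid_fraction must be in [0, 1]")


# covariate distribution parameters loosely matching the reported baseline
# tables (means/SDs; categorical probabilities)
_COV = {
    "COPD": dict(male=0.42, age=(64.0, 9.2), bmi=(26.5, 5.3),
                 smoking=(0.005, 0.74, 0.255), packyears=(37.0, 0.44),
                 fev1=(65.0, 19.5)),
    "LUNG_CANCER": dict(male=0.51, age=(63.5, 10.2), bmi=(25.4, 4.7),
                        smoking=(0.10, 0.66, 0.24), packyears=(31.0, 0.44),
                        fev1=(71.0, 19.8)),
}
_GOLD_P = {
    "COPD": (0.09, 0.51, 0.31, 0.09),
    "COPD_INCIDENT_CANCER": (0.0, 0.30, 0.43, 0.27),
    "LUNG_CANCER": (0.22, 0.53, 0.24, 0.01),  # comorbid cancer subjects only
}
_STAGE_P = {
    "LUNG_CANCER": (0.10, 0.22, 0.37, 0.31),
    "COPD_INCIDENT_CANCER": (5 / 37, 12 / 37, 13 / 37, 7 / 37),
}
_STAGES = ("I", "II", "III", "IV")
_HISTOLOGY_P = (0.13, 0.54, 0.21, 0.12)  # SCLC, adeno, squamous, large-cell
_HISTOLOGIES = ("SCLC", "adenocarcinoma", "squamous", "large_cell")


def _draw_covariates(rng: np.random.Generator, labels: np.ndarray) -> pd.DataFrame:
    n = labels.size
    cov = pd.DataFrame(index=range(n))
    base = np.where(labels == "LUNG_CANCER", "LUNG_CANCER", "COPD")
    age = np.empty(n)
    bmi = np.empty(n)
    fev1 = np.empty(n)
    male = np.empty(n, dtype=bool)
    smoking = np.empty(n, dtype=object)
    packyears = np.empty(n)
    for grp in ("COPD", "LUNG_CANCER"):
        m = base == grp
        k = int(m.sum())
        if k == 0:
            continue
        p = _COV[grp]
        age[m] = rng.normal(*p["age"], k)
        bmi[m] = np.clip(rng.normal(*p["bmi"], k), 14, 55)
        fev1[m] = np.clip(rng.normal(*p["fev1"], k), 15, 140)
        male[m] = rng.random(k) < p["male"]
        smoking[m] = rng.choice(
            ["never", "former", "current"], size=k, p=p["smoking"])
        mu, sigma = p["packyears"]
        packyears[m] = rng.lognormal(np.log(mu), sigma, k)
    packyears[smoking == "never"] = 0.0
    cov["age"] = np.clip(age, 30, 95)
    cov["sex"] = np.where(male, "male", "female")
    cov["bmi"] = bmi
    cov["smoking_status"] = smoking
    cov["pack_years"] = packyears
    cov["fev1_pct_pred"] = fev1
    return cov


def generate_cohort(spec: CohortSpec) -> tuple[list[SensorRecording], pd.DataFrame]:
    """Generate duplicate recordings and a metadata table for a cohort.

    Returns ``(recordings, metadata)`` with two replicate recordings per
    subject and one metadata row per subject carrying the ground-truth
    class label, the incident-cancer flag, comorbidity, covariates,
    stage, and the latent cancer intensity used (for recovery tests).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_copd + spec.n_cancer
    labels = np.array(["COPD"] * spec.n_copd + ["LUNG_CANCER"] * spec.n_cancer,
                      dtype=object)
    incident = np.zeros(n, dtype=bool)
    if spec.n_incident:
        incident[rng.choice(spec.n_copd, size=spec.n_incident, replace=False)] = True
    labels[incident] = "COPD_INCIDENT_CANCER"

    cancer_mask = labels == "LUNG_CANCER"
    comorbid = np.zeros(n, dtype=bool)
    comorbid[cancer_mask] = rng.random(int(cancer_mask.sum())) < spec.comorbid_fraction

    # stage for every cancer-involving subject
    stage = np.full(n, "", dtype=object)
    for lab in ("LUNG_CANCER", "COPD_INCIDENT_CANCER"):
        m = labels == lab
        if m.any():
            stage[m] = rng.choice(_STAGES, size=int(m.sum()), p=_STAGE_P[lab])
    stage_factor = np.array(
        [STAGE_FACTORS.get(s, 0.0) for s in stage], dtype=float)

    covariates = _draw_covariates(rng, labels)

    # latent VOC components: (copd, cancer, shared)
    lat = np.empty((n, 3))
    lat[:, 0] = rng.normal(_LATENT_BASE["copd"], LATENT_SD, n)
    lat[:, 1] = rng.normal(_LATENT_BASE["cancer"], LATENT_SD, n)
    lat[:, 2] = rng.normal(_LATENT_BASE["shared"], LATENT_SD, n)
    # cancer subjects without comorbid COPD lack the obstructive-airway
    # signature; like the cancer shift this difference scales with
    # effect_size (effect 0 = fully exchangeable null cohort)
    lat[cancer_mask & ~comorbid, 0] += (
        (_CANCER_COPD_LATENT - _LATENT_BASE["copd"]) * spec.effect_size / 2.0)
    # cancer-associated shift, scaled by stage severity; attenuated in
    # double-diagnosis subjects (intermediate breathprints)
    shift = spec.effect_size * LATENT_SD * stage_factor
    shift[cancer_mask & comorbid] *= _COMORBID_ATTENUATION
    lat[:, 1] += shift
    if spec.covariate_leakage:
        z_py = (covariates["pack_years"].to_numpy()
                - covariates["pack_years"].mean())
        z_py /= max(covariates["pack_years"].std(ddof=1), 1e-12)
        lat[:, 2] += spec.covariate_leakage * z_py
    lat = np.clip(lat, 0.0, None)

    # replicate-level latent jitter (within-subject variability)
    rep_lat = lat[:, None, :] + rng.normal(
        0.0, spec.replicate_noise_sd, (n, 2, 3))
    rep_lat = np.clip(rep_lat, 0.0, None).reshape(n * 2, 3)

    trace = simulate_maneuver(spec.maneuver)
    g = response_kernel(trace)
    t = trace.time_s
    arr = spec.array
    amp = rep_lat @ arr.sensitivity_matrix.T  # (2n, 7)
    base = arr.baseline_level[None, :, None]
    drift = arr.drift_rate * t[None, None, :]
    exhaled = base * (1.0 + amp[:, :, None] * g[None, None, :]) + drift
    ambient = np.broadcast_to(base, (n * 2, N_SENSORS, t.size)) + drift
    if arr.noise_sd > 0:
        exhaled = exhaled + rng.normal(0.0, arr.noise_sd, exhaled.shape)
        ambient = ambient + rng.normal(0.0, arr.noise_sd, ambient.shape)
    else:
        ambient = np.array(ambient)

    subject_ids = [f"S{i:04d}" for i in range(n)]
    recordings: list[SensorRecording] = []
    for i in range(n):
        for r in (1, 2):
            j = 2 * i + (r - 1)
            recordings.append(SensorRecording(
                subject_id=subject_ids[i], replicate=r, time_s=t,
                exhaled=exhaled[j], ambient=ambient[j],
                sample_rate_hz=spec.maneuver.sample_rate_hz,
                phase=trace.phase))

    metadata = pd.DataFrame({
        "subject_id": subject_ids,
        "class_label": labels,
        "incident_cancer_within_2y": incident,
        "comorbid_copd": comorbid | (labels != "LUNG_CANCER"),
        "stage": [s if s else None for s in stage],
        "latent_cancer": lat[:, 1],
    })
    # comorbid_copd means "carries a COPD diagnosis"; for COPD-group rows it
    # is trivially true, the interesting flag is on the cancer group
    metadata = pd.concat([metadata, covariates], axis=1)
    gold = np.full(n, "", dtype=object)
    for lab in ("COPD", "COPD_INCIDENT_CANCER", "LUNG_CANCER"):
        m = labels == lab
        if lab == "LUNG_CANCER":
            m = m & comorbid
        if m.any():
            gold[m] = rng.choice(
                ["I", "II", "III", "IV"], size=int(m.sum()), p=_GOLD_P[lab])
    metadata["gold_stage"] = [s if s else None for s in gold]
    hist = np.full(n, "", dtype=object)
    m = labels != "COPD"
    if m.any():
        hist[m] = rng.choice(_HISTOLOGIES, size=int(m.sum()), p=_HISTOLOGY_P)
    metadata["histology"] = [h if h else None for h in hist]
    return recordings, metadata
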