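"""Synthetic seizure-session generator.

Emulates the statistical structure of an acute chemogenetic seizure-
attenuation experiment: per-session 64-contact ECoG progressing from quiet
baseline through epileptic spikes, spike-wave complexes and multi-spike-wave
complexes into status epilepticus; spatial spread of the discharge from a
focal contact out to the whole array; a treatment-triggered suppression of
epileptiform amplitude with ~1-min latency in DCZ sessions; categorized
convulsion event streams whose rates track the ECoG phase; and a cohort of
two subjects with opposite-signed subject effects over 6 DCZ + 4 vehicle
sessions.

Every generator output is a pure function of (config, seed).  The generator
is *not* a biophysical neural-mass model: waveform templates are stylized
electro-clinical shapes (70-ms biphasic spike, ~3-Hz spike-wave complexes)
and background activity is 1/f noise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .session import (
    ConvulsionEvent,
    EcogRecording,
    ElectrodeGrid,
    EVENT_CATEGORIES,
    SessionBundle,
    SessionTimeline,
    TREMOR_MIN_DURATION_S,
)

PHASES = (
    "baseline",
    "spikes",
    "spike_wave",
    "multi_spike_wave",
    "status_epilepticus",
    "post_suppression",
)

#: Epileptiform phases in severity order (used for the spatial-sigma monotonicity check).
_SEVERITY_ORDER = ("spikes", "spike_wave", "multi_spike_wave", "status_epilepticus")


@dataclass(frozen=True)
class PhaseSchedule:
    """Ordered (phase, start_min, end_min) intervals on the session clock.

    Contiguous, non-overlapping, baseline first; spans the whole session.
    """

    intervals: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        iv = tuple((str(p), float(a), float(b)) for p, a, b in self.intervals)
        if not iv:
            raise ValueError("empty schedule")
        for p, a, b in iv:
            if p not in PHASES:
                raise ValueError(f"unknown phase {p!r}")
            if b <= a:
                raise ValueError(f"phase {p}: empty interval [{a}, {b})")
        for (_, _, b1), (p2, a2, _) in zip(iv, iv[1:]):
            if not math.isclose(b1, a2, abs_tol=1e-9):
                raise ValueError(f"schedule not contiguous at {p2} ({b1} != {a2})")
        if iv[0][0] != "baseline":
            raise ValueError("schedule must start with a baseline phase")
        object.__setattr__(self, "intervals", iv)

    @property
    def start_min(self) -> float:
        return self.intervals[0][1]

    @property
    def end_min(self) -> float:
        return self.intervals[-1][2]

    def phase_at(self, t_min: float) -> str:
        for p, a, b in self.intervals:
            if a - 1e-12 <= t_min < b:
                return p
        return self.intervals[-1][0]


@dataclass(frozen=True)
class PhaseParams:
    """Epileptiform template parameters for one phase.

    amplitude_uV: peak template amplitude at the focus contact.
    complex_rate_hz: repetition rate of discharge complexes.
    spatial_sigma_pitch: Gaussian spread width in grid-pitch units
        (``inf`` flattens the profile over the whole array).
    spikes_per_complex: (lo, hi) spikes per complex, drawn uniformly.
    slow_wave: whether each complex ends in a ~330-ms slow wave.
    """

    amplitude_uV: float
    complex_rate_hz: float = 1.0
    spatial_sigma_pitch: float = math.inf
    spikes_per_complex: tuple[int, int] = (1, 1)
    slow_wave: bool = False


@dataclass(frozen=True)
class TreatmentEffect:
    """Chemogenetic suppression of the epileptiform component.

    After ``latency_min`` past treatment, epileptiform amplitude (and
    convulsion rates) decay exponentially with ``onset_tau_min`` toward
    ``(1 - suppression_fraction)`` times their untreated level.
    """

    latency_min: float = 1.0
    suppression_fraction: float = 0.85
    onset_tau_min: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.suppression_fraction <= 1.0:
            raise ValueError("suppression_fraction must lie in [0, 1]")


DEFAULT_SCHEDULE = PhaseSchedule(
    (
        ("baseline", 0.0, 4.0),
        ("spikes", 4.0, 6.0),
        ("spike_wave", 6.0, 8.0),
        ("multi_spike_wave", 8.0, 10.0),
        ("status_epilepticus", 10.0, 40.0),
    )
)

DEFAULT_PHASE_PARAMS: dict[str, PhaseParams] = {
    "baseline": PhaseParams(amplitude_uV=0.0),
    "spikes": PhaseParams(800.0, complex_rate_hz=1.5, spatial_sigma_pitch=1.3),
    "spike_wave": PhaseParams(
        450.0, complex_rate_hz=1.5, spatial_sigma_pitch=1.5, slow_wave=True
    ),
    "multi_spike_wave": PhaseParams(
        650.0, complex_rate_hz=2.0, spatial_sigma_pitch=1.8,
        spikes_per_complex=(2, 4), slow_wave=True,
    ),
    "status_epilepticus": PhaseParams(
        900.0, complex_rate_hz=3.0, spatial_sigma_pitch=math.inf, slow_wave=True
    ),
    "post_suppression": PhaseParams(amplitude_uV=0.0),
}

#: Events per minute for each phase x category (categories omitted are 0).
DEFAULT_EVENT_RATES: dict[str, dict[str, float]] = {
    "baseline": {"VoluntaryMovement": 0.5},
    "spikes": {"Twitch_contra": 3.0, "VoluntaryMovement": 0.3},
    "spike_wave": {"Twitch_contra": 4.0, "Tremor_contra": 1.0, "VoluntaryMovement": 0.3},
    "multi_spike_wave": {
        "Twitch_contra": 5.0, "Tremor_contra": 2.0, "Body": 1.0, "Head": 1.0,
        "VoluntaryMovement": 0.2,
    },
    "status_epilepticus": {
        "Twitch_contra": 5.0, "Tremor_contra": 2.0, "Twitch_ipsi": 1.5,
        "Tremor_ipsi": 0.5, "Body": 4.0, "Head": 3.0, "VoluntaryMovement": 0.2,
    },
    "post_suppression": {"VoluntaryMovement": 0.5},
}

#: Cohort layout: 2 subjects, 6 DCZ + 4 vehicle sessions.
DEFAULT_SESSIONS: tuple[tuple[str, str], ...] = (
    ("monkey1", "DCZ"),
    ("monkey1", "DCZ"),
    ("monkey1", "DCZ"),
    ("monkey1", "vehicle"),
    ("monkey1", "vehicle"),
    ("monkey2", "DCZ"),
    ("monkey2", "DCZ"),
    ("monkey2", "DCZ"),
    ("monkey2", "vehicle"),
    ("monkey2", "vehicle"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of a synthetic cohort.

    Sessions run on a 40-min clock by default: quiet baseline, graded
    epileptiform phases, then sustained status epilepticus; bicuculline is
    infused at 4 min and the treatment of record given at 25 min, leaving a
    full 15-min pre-treatment window and 15 post-treatment 1-min bins.
    ``subject_effect`` tilts the epileptiform amplitude linearly in time with
    opposite signs for the two subjects (zero mean over the pre-treatment
    window), so normalized post-treatment levels carry an additive
    subject-signed offset as in the observation model's u*d_M term.
    """

    n_rows: int = 8
    n_cols: int = 8
    pitch_mm: float = 2.5
    na_channels: tuple[int, ...] = (63,)
    focus_channel: int = 27
    hemisphere: str = "left"
    sample_rate_hz: float = 250.0
    noise_rms_uV: float = 15.0
    schedule: PhaseSchedule = DEFAULT_SCHEDULE
    phase_params: dict[str, PhaseParams] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_PARAMS)
    )
    event_rates_per_min: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: dict(r) for p, r in DEFAULT_EVENT_RATES.items()}
    )
    bicuculline_min: float = 4.0
    treatment_min: float = 25.0
    treatment: TreatmentEffect = TreatmentEffect()
    subject_effect: float = 0.1
    subjects: tuple[str, ...] = ("monkey1", "monkey2")
    sessions: tuple[tuple[str, str], ...] = DEFAULT_SESSIONS
    master_seed: int = 0

    def __post_init__(self) -> None:
        n_ch = self.n_rows * self.n_cols
        if not 0 <= self.focus_channel < n_ch:
            raise ValueError("focus_channel outside grid")
        if any(not 0 <= c < n_ch for c in self.na_channels):
            raise ValueError("NA channel outside grid")
        for phase, rates in self.event_rates_per_min.items():
            if phase not in PHASES:
                raise ValueError(f"unknown phase {phase!r} in event rates")
            for cat, r in rates.items():
                if cat not in EVENT_CATEGORIES:
                    raise ValueError(f"unknown category {cat!r}")
                if r < 0:
                    raise ValueError(f"negative rate for {phase}/{cat}")
        sigmas = [
            self.phase_params[p].spatial_sigma_pitch
            for p in _SEVERITY_ORDER
            if p in self.phase_params
        ]
        if any(b < a for a, b in zip(sigmas, sigmas[1:])):
            raise ValueError("spatial sigma must be non-decreasing with severity")
        if not self.schedule.start_min <= self.bicuculline_min < self.schedule.end_min:
            raise ValueError("bicuculline time outside session")
        if not self.bicuculline_min < self.treatment_min < self.schedule.end_min:
            raise ValueError("treatment time must follow bicuculline within the session")
        for subj, treat in self.sessions:
            if subj not in self.subjects:
                raise ValueError(f"session subject {subj!r} not in subjects")
            if treat not in ("DCZ", "vehicle"):
                raise ValueError(f"unknown treatment {treat!r}")

    def grid(self) -> ElectrodeGrid:
        mask = [c not in self.na_channels for c in range(self.n_rows * self.n_cols)]
        return ElectrodeGrid(
            n_rows=self.n_rows, n_cols=self.n_cols, pitch_mm=self.pitch_mm,
            valid_mask=tuple(mask), hemisphere=self.hemisphere,
        )

    def subject_sign(self, subject: str) -> int:
        """u-coding: first subject -1, second +1."""
        return -1 if self.subjects.index(subject) == 0 else 1

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(_to_jsonable(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    return obj


def session_seed(master_seed: int, subject_index: int, session_index: int) -> np.random.SeedSequence:
    """Stable per-session seed derivation."""
    return np.random.SeedSequence([int(master_seed), int(subject_index), int(session_index)])


# ---------------------------------------------------------------------------
# waveform templates


def spike_template(fs: float, duration_s: float = 0.07) -> np.ndarray:
    """Biphasic sharp transient (~70 ms), unit peak amplitude."""
    n = max(int(round(duration_s * fs)), 3)
    t = np.arange(n) / n
    w = np.sin(2 * np.pi * t) * np.hanning(n)
    return w / np.max(np.abs(w))


def slow_wave_template(fs: float, duration_s: float = 0.33) -> np.ndarray:
    """After-going slow wave: half-sine, 0.6 relative amplitude."""
    n = max(int(round(duration_s * fs)), 3)
    return 0.6 * np.sin(np.pi * np.arange(n) / n)


def complex_template(fs: float, n_spikes: int, slow_wave: bool) -> np.ndarray:
    parts = [spike_template(fs)] * max(n_spikes, 1)
    if slow_wave:
        parts.append(slow_wave_template(fs))
    return np.concatenate(parts)


def pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS 1/f ("pink") noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shaping = np.ones_like(f)
    shaping[1:] = 1.0 / np.sqrt(f[1:])
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    return x / np.sqrt(np.mean(x**2))


# ---------------------------------------------------------------------------
# treatment / subject modulation


def treatment_modulation(
    t_min: np.ndarray, treatment_min: float, effect: TreatmentEffect, is_dcz: bool
) -> np.ndarray:
    """Multiplier on the epileptiform component: 1 until latency elapses, then
    exponential decay toward (1 - suppression_fraction)."""
    t_min = np.asarray(t_min, dtype=float)
    if not is_dcz or effect.suppression_fraction == 0.0:
        return np.ones_like(t_min)
    onset = treatment_min + effect.latency_min
    dt = np.maximum(t_min - onset, 0.0)
    decayed = 1.0 - effect.suppression_fraction * (
        1.0 - np.exp(-dt / max(effect.onset_tau_min, 1e-9))
    )
    return np.where(t_min < onset, 1.0, decayed)


def event_rate_modulation(
    t_min: np.ndarray, treatment_min: float, effect: TreatmentEffect, is_dcz: bool
) -> np.ndarray:
    """Step multiplier on convulsion rates: 1 before the latency elapses,
    (1 - suppression_fraction) after."""
    t_min = np.asarray(t_min, dtype=float)
    if not is_dcz:
        return np.ones_like(t_min)
    onset = treatment_min + effect.latency_min
    return np.where(t_min < onset, 1.0, 1.0 - effect.suppression_fraction)


def _subject_tilt(t_min: np.ndarray, config: SimulationConfig, u: int) -> np.ndarray:
    """Opposite-signed linear amplitude tilt, zero-mean over the pre window."""
    if config.subject_effect == 0.0:
        return np.ones_like(np.asarray(t_min, dtype=float))
    mid_pre = config.treatment_min - 7.5  # centre of the -15..0 min window
    g = (np.asarray(t_min, dtype=float) - mid_pre) / 15.0
    return np.clip(1.0 + u * config.subject_effect * g, 0.1, None)


# ---------------------------------------------------------------------------
# simulators


def _focal_distances(config: SimulationConfig) -> np.ndarray:
    grid = config.grid()
    return np.array(
        [grid.distance_pitch(c, config.focus_channel) for c in range(grid.n_channels)]
    )


def _min_epileptiform_sigma(config: SimulationConfig) -> float:
    finite = [
        pp.spatial_sigma_pitch
        for pp in config.phase_params.values()
        if pp.amplitude_uV > 0 and math.isfinite(pp.spatial_sigma_pitch)
    ]
    return min(finite) if finite else 1.0


def simulate_ecog(
    config: SimulationConfig,
    subject: str,
    treatment: str,
    seed: int | np.random.SeedSequence,
) -> EcogRecording:
    """Simulate one session's multichannel ECoG (microvolts).

    Per channel: 1/f background noise plus a phase-dependent epileptiform
    template train scaled by a Gaussian spatial profile centred on the focus
    contact.  In DCZ sessions the treatment both scales the epileptiform
    amplitude by the suppression envelope and *retracts* the discharge
    toward the focus (the effective spatial width shrinks toward the focal
    width as suppression deepens), emulating the collapse of a spread
    seizure back to focal residual spikes.  The random stream is consumed
    identically for DCZ and vehicle labels, so a zero suppression fraction
    makes them sample-identical.
    """
    rng = np.random.default_rng(seed)
    grid = config.grid()
    fs = config.sample_rate_hz
    n_samples = int(round((config.schedule.end_min - config.schedule.start_min) * 60 * fs))
    start_s = config.schedule.start_min * 60.0
    u = config.subject_sign(subject)

    out = np.empty((grid.n_channels, n_samples))
    for c in range(grid.n_channels):
        out[c] = config.noise_rms_uV * pink_noise(rng, n_samples)

    d2 = _focal_distances(config) ** 2
    sigma_min = _min_epileptiform_sigma(config)
    is_dcz = treatment == "DCZ"
    valid = grid.valid_channels
    profile_cache: dict[tuple[float, float], np.ndarray] = {}

    def profile(inv_var_phase: float, m: float) -> np.ndarray:
        # suppression pulls the effective width toward the focal width
        inv_var = inv_var_phase + (1.0 - m) / sigma_min**2
        key = (round(inv_var, 4), 0.0)
        g = profile_cache.get(key)
        if g is None:
            g = np.exp(-d2 * inv_var / 2.0) if inv_var > 0 else np.ones(d2.size)
            profile_cache[key] = g
        return g

    for phase, a_min, b_min in config.schedule.intervals:
        pp = config.phase_params[phase]
        if pp.amplitude_uV <= 0 or pp.complex_rate_hz <= 0:
            continue
        sigma = pp.spatial_sigma_pitch
        inv_var_phase = 0.0 if math.isinf(sigma) else 1.0 / sigma**2
        interval = 1.0 / pp.complex_rate_hz
        lo_k, hi_k = pp.spikes_per_complex
        t = 0.0
        span_s = (b_min - a_min) * 60.0
        while t < span_s:
            n_spk = int(rng.integers(lo_k, hi_k + 1))
            tpl = complex_template(fs, n_spk, pp.slow_wave)
            t_abs_min = a_min + t / 60.0
            m = float(
                treatment_modulation(
                    np.array([t_abs_min]), config.treatment_min, config.treatment, is_dcz
                )[0]
            )
            amp = pp.amplitude_uV * m * float(_subject_tilt(np.array([t_abs_min]), config, u)[0])
            g = profile(inv_var_phase, m)
            j = int(round((t_abs_min - config.schedule.start_min) * 60.0 * fs))
            j1 = min(j + tpl.size, n_samples)
            if j1 > j:
                out[np.ix_(valid, np.arange(j, j1))] += (
                    amp * g[valid, None] * tpl[None, : j1 - j]
                )
            t += interval * rng.uniform(0.75, 1.25)

    return EcogRecording(grid=grid, sample_rate_hz=fs, samples=out, start_time_s=start_s)


def simulate_convulsions(
    config: SimulationConfig,
    subject: str,
    treatment: str,
    seed: int | np.random.SeedSequence,
) -> list[ConvulsionEvent]:
    """Simulate the scored event stream for one session.

    Independent inhomogeneous Poisson processes per category; the rate is the
    phase rate times the treatment modulation (convulsive categories only).
    Simulated by thinning, so the random stream does not depend on the
    treatment label.  Tremor events carry durations >= 2 s.
    """
    rng = np.random.default_rng(seed)
    span_min = config.schedule.end_min - config.schedule.start_min
    events: list[ConvulsionEvent] = []
    for category in EVENT_CATEGORIES:
        rate_max = max(
            (config.event_rates_per_min.get(p, {}).get(category, 0.0) for p in PHASES),
            default=0.0,
        )
        if rate_max <= 0:
            continue
        n_cand = rng.poisson(rate_max * span_min)
        cand = np.sort(rng.uniform(config.schedule.start_min, config.schedule.end_min, n_cand))
        accept_u = rng.uniform(size=n_cand)
        durations = 2.0 + rng.exponential(2.0, size=n_cand)
        if category == "VoluntaryMovement":
            mod = np.ones(n_cand)
        else:
            mod = event_rate_modulation(
                cand, config.treatment_min, config.treatment, treatment == "DCZ"
            )
        for t_min, uacc, dur, m in zip(cand, accept_u, durations, mod):
            phase = config.schedule.phase_at(t_min)
            rate = config.event_rates_per_min.get(phase, {}).get(category, 0.0) * m
            if uacc < rate / rate_max:
                duration = float(max(dur, TREMOR_MIN_DURATION_S)) if category.startswith("Tremor") else None
                events.append(
                    ConvulsionEvent(time_s=float(t_min * 60.0), category=category,
                                    duration_s=duration)
                )
    events.sort(key=lambda e: (e.time_s, e.category))
    return events


def simulate_session(
    config: SimulationConfig,
    subject: str,
    treatment: str,
    seed: int | np.random.SeedSequence,
    session_id: str = "session",
) -> SessionBundle:
    """One full SessionBundle (recording + timeline + events + provenance)."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(int(seed))
    ss_ecog, ss_events = ss.spawn(2)
    recording = simulate_ecog(config, subject, treatment, ss_ecog)
    events = simulate_convulsions(config, subject, treatment, ss_events)
    t_treat_s = config.treatment_min * 60.0
    timeline = SessionTimeline(
        subject_id=subject,
        bicuculline_times_s=(config.bicuculline_min * 60.0,),
        treatment_of_record=treatment,
        vehicle_time_s=t_treat_s if treatment == "vehicle" else None,
        dcz_times_s=(t_treat_s,) if treatment == "DCZ" else (),
        dreadd_hemisphere=config.hemisphere,
    )
    return SessionBundle(
        session_id=session_id,
        timeline=timeline,
        recordings=[recording],
        events=events,
        provenance={
            "synthetic": True,
            "config_hash": config.config_hash(),
            "seed_entropy": [int(x) for x in np.asarray(ss.entropy).ravel()]
            if not np.isscalar(ss.entropy)
            else [int(ss.entropy)],
        },
    )


def simulate_cohort(config: SimulationConfig | None = None) -> list[SessionBundle]:
    """Simulate the full cohort (default: 2 subjects, 6 DCZ + 4 vehicle).

    Per-session seeds derive reproducibly from ``config.master_seed`` and the
    (subject index, session index) pair.
    """
    config = config or SimulationConfig()
    bundles = []
    for i, (subject, treatment) in enumerate(config.sessions):
        ss = session_seed(config.master_seed, config.subjects.index(subject), i)
        bundles.append(
            simulate_session(
                config, subject, treatment, ss,
                session_id=f"{subject}_{treatment}_{i:02d}",
            )
        )
    return bundles


# ---------------------------------------------------------------------------
# direct generative draws from the state-space observation model


@dataclass
class StateSpaceDraw:
    """One generative draw from the treatment-effect observation model."""

    bin_start_min: np.ndarray
    u: np.ndarray
    v: np.ndarray
    yhat: np.ndarray
    d_M: float
    d_T: np.ndarray
    y: np.ndarray  # (n_sessions, n_bins)
    sigma: float
    sigma_M: float
    sigma_y: float
    sigma_T: float


def simulate_from_state_space(
    bin_start_min: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    sigma: float = 0.05,
    sigma_M: float = 0.2,
    sigma_y: float = 0.05,
    sigma_T: float = 0.1,
    seed: int | np.random.SeedSequence = 0,
    yhat_init: tuple[float, float] = (1.0, 1.0),
    d_T_path: np.ndarray | None = None,
    d_M: float | None = None,
) -> StateSpaceDraw:
    """Draw y = yhat + u*d_M + v*d_T + eps directly from the process models.

    The basic trend follows the second-order random walk (its increment is a
    Normal random walk with scale ``sigma_y``); the treatment effect follows
    a Cauchy-increment walk with scale ``sigma_T`` unless an explicit
    ``d_T_path`` is supplied (e.g. a step function for recovery studies);
    ``d_M`` ~ Normal(0, sigma_M^2) unless given.
    """
    if min(sigma, sigma_M, sigma_y, sigma_T) < 0:
        raise ValueError("scales must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.asarray(bin_start_min, dtype=float)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.size == 0 or u.size == 0:
        raise ValueError("empty design")
    T, S = t.size, u.size

    yhat = np.empty(T)
    yhat[0] = yhat_init[0]
    if T > 1:
        yhat[1] = yhat_init[1]
    for k in range(2, T):
        yhat[k] = 2 * yhat[k - 1] - yhat[k - 2] + sigma_y * rng.standard_normal()

    if d_T_path is not None:
        d_T = np.asarray(d_T_path, dtype=float)
        if d_T.shape != (T,):
            raise ValueError("d_T_path must match the bin grid")
    else:
        d_T = np.empty(T)
        d_T[0] = 0.0
        for k in range(1, T):
            d_T[k] = d_T[k - 1] + sigma_T * rng.standard_cauchy()

    if d_M is None:
        d_M = float(sigma_M * rng.standard_normal())

    y = (
        yhat[None, :]
        + u[:, None] * d_M
        + v[:, None] * d_T[None, :]
        + sigma * rng.standard_normal((S, T))
    )
    return StateSpaceDraw(
        bin_start_min=t, u=u, v=v, yhat=yhat, d_M=float(d_M), d_T=d_T, y=y,
        sigma=sigma, sigma_M=sigma_M, sigma_y=sigma_y, sigma_T=sigma_T,
    )
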