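"""Synthetic resting-state MEG cohorts with plantable group effects.

Generates two-group cohorts (patients vs controls) of band-limited
cortical oscillations at seed locations, with controllable group
differences in regional band power and in band-specific amplitude
envelope coupling, plus the nuisance structure that makes covariate
adjustment meaningful: group-dependent head motion, age distributions,
ocular/cardiac artifacts, head-position excursions and sensor jumps.

Signal model
------------
Each seed's time series is a sum over canonical bands of band-limited
Gaussian carriers multiplied by slow positive envelopes:

    x_s(t) = sum_b  a_sb * e_sb(t) * c_sb(t)

* carriers ``c_sb`` are constant-modulus band-limited phase-noise
  signals (band-passed Gaussian noise normalised by its own Hilbert
  envelope), independent across seeds.  Removing the carrier's
  Rayleigh amplitude fluctuations makes the measured Hilbert envelope
  track the planted envelope directly, so the full dynamic range of
  envelope coupling is reachable even in the narrow delta band;
* envelopes ``e_sb = 1 + depth * xi_sb`` where ``xi`` is the
  standardised modulus of < 0.5 Hz low-passed Gaussian noise --
  realistic slow amplitude dynamics, bounded away from zero;
* a planted *power* effect multiplies ``a_sb`` for the affected group
  (power scales with the square of the amplitude factor);
* a planted *coupling* effect makes the two endpoint seeds of an edge
  share a common envelope component with mixing weight ``w``; the map
  from ``w`` to the measured amplitude-envelope correlation depends on
  the band filter and envelope dynamics, so it is calibrated
  empirically by a one-off simulation (cached per band).

Negative coupling shifts are expressed against a non-zero baseline: the
affected edges receive the baseline coupling in both groups and
``baseline + shift`` in the affected group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import signal, stats

from .bands import BAND_NAMES, get_band
from .connectivity import (
    aec,
    downsample_envelope,
    fir_bandpass,
    hilbert_envelope,
    symmetric_orthogonalize,
)
from .geometry import HeadModel, SourceModel
from .preprocessing import SensorRecording

GROUPS = ("mtbi", "control")

#: default relative carrier amplitudes per band (roughly 1/f-like)
DEFAULT_BAND_AMPLITUDES = {
    "delta": 1.0,
    "theta": 0.7,
    "alpha": 1.1,
    "beta": 0.45,
    "lowgamma1": 0.25,
    "lowgamma2": 0.15,
    "highgamma": 0.1,
}

_CALIBRATION_SEED = 745_210_317  # fixed: the weight->AEC lookup is a constant of the model


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SubjectMetadata:
    subject_id: str
    group: str  # 'mtbi' | 'control'
    age: float  # years
    sex: str  # 'm' | 'f'
    head_motion: float  # mm, scalar nuisance covariate

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigurationError(f"group must be one of {GROUPS}")
        if self.head_motion < 0:
            raise ConfigurationError("head motion must be >= 0")


@dataclass(frozen=True)
class PowerEffect:
    """Multiplicative band-amplitude change for one group on a seed set."""

    seeds: tuple[int, ...]
    band: str
    amplitude_factor: float
    group: str = "mtbi"

    def __post_init__(self) -> None:
        get_band(self.band)
        if self.amplitude_factor <= 0:
            raise ConfigurationError("amplitude factor must be > 0")


@dataclass(frozen=True)
class CouplingEffect:
    """Target AEC shift for one group on a set of edges.

    The edges carry ``baseline`` AEC in the reference group and
    ``baseline + shift`` in the affected group, so negative shifts
    (hypo-connectivity) are representable.
    """

    edges: tuple[tuple[int, int], ...]
    band: str
    shift: float
    group: str = "mtbi"
    baseline: float = 0.3

    def __post_init__(self) -> None:
        get_band(self.band)
        if not -1 < self.shift < 1:
            raise ConfigurationError("AEC shift must be in (-1, 1)")
        if not 0 <= self.baseline + min(self.shift, 0):
            raise ConfigurationError("baseline + shift must stay non-negative")


@dataclass(frozen=True)
class GroupCovariates:
    age_mean: float
    age_sd: float
    motion_mean: float  # mm
    motion_sd: float  # mm
    male_proportion: float = 0.5


@dataclass(frozen=True)
class CovariateModel:
    """Study-cohort covariate distributions.

    Defaults reproduce the demographic structure of a paediatric
    chronic-mTBI MEG cohort: patients mean age 12.46 y (SD 3.24), mean
    head motion 1.83 mm (SD 1.79); controls 13.14 y (SD 2.69) and
    0.64 mm (SD 0.51).  Motion is lognormal (positive, right-skewed)
    and deliberately group-dependent so covariate adjustment is
    genuinely exercised downstream.
    """

    mtbi: GroupCovariates = GroupCovariates(12.46, 3.24, 1.83, 1.79, 11 / 16)
    control: GroupCovariates = GroupCovariates(13.14, 2.69, 0.64, 0.51, 10 / 20)
    age_range: tuple[float, float] = (6.0, 18.0)


@dataclass(frozen=True)
class ArtifactModel:
    """Amplitudes and rates of the injected artifact types."""

    ocular_amplitude: float = 800.0  # fT at the most affected sensor
    blink_rate: float = 0.25  # blinks per second
    cardiac_amplitude: float = 300.0  # fT
    heart_rate: float = 1.2  # Hz
    n_jumps: int = 0  # step artifacts per recording
    jump_amplitude: float = 2500.0  # fT
    excursion_probability: float = 0.0  # per recording
    excursion_mm: float = 12.0  # straddles the 10 mm rejection threshold
    excursion_duration: float = 8.0  # s


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a synthetic cohort.

    The defaults are the emulated study conditions: n = 16 patients vs
    20 controls, 151-channel recordings at 600 Hz, 5 minutes of
    eyes-open rest, 90 seed locations.
    """

    n_per_group: tuple[int, int] = (16, 20)  # (mtbi, control)
    sampling_rate: float = 600.0
    duration: float = 300.0  # seconds
    n_seeds: int = 90
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    power_effects: tuple[PowerEffect, ...] = ()
    coupling_effects: tuple[CouplingEffect, ...] = ()
    covariate_model: CovariateModel = CovariateModel()
    artifact_model: ArtifactModel = ArtifactModel()
    envelope_cutoff: float = 0.45  # Hz, low-pass defining slow amplitude dynamics
    envelope_depth: float = 0.7  # modulation depth of the envelopes
    dipole_moment: float = 2e-8  # A*m (20 nA*m), typical cortical patch
    sensor_noise_sd: float = 10.0  # fT
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_group):
            raise ConfigurationError("each group needs at least one subject")
        unknown = set(self.band_amplitudes) - set(BAND_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown bands in amplitudes: {unknown}")
        for eff in self.power_effects:
            if any(not 0 <= s < self.n_seeds for s in eff.seeds):
                raise ConfigurationError("power effect references a non-existent seed")
        for eff in self.coupling_effects:
            for i, j in eff.edges:
                if i == j or not (0 <= i < self.n_seeds and 0 <= j < self.n_seeds):
                    raise ConfigurationError("coupling effect references an invalid edge")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


# ---------------------------------------------------------------------------
# coupling calibration: mixing weight -> achieved AEC
# ---------------------------------------------------------------------------

_WEIGHT_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


def _slow_drivers(
    rng: np.random.Generator, count: int, n: int, fs: float, cutoff: float
) -> np.ndarray:
    """Standardised moduli of low-passed Gaussian noise (the xi processes).

    Returns (count, n); rows are independent, each with mean 0, SD 1.
    """
    b, a = signal.butter(4, cutoff, btype="low", fs=fs)
    z = signal.filtfilt(b, a, rng.standard_normal((count, n)), axis=-1)
    x = np.abs(z / z.std(axis=-1, keepdims=True))
    x -= x.mean(axis=-1, keepdims=True)
    return x / x.std(axis=-1, keepdims=True)


def _slow_driver(rng: np.random.Generator, n: int, fs: float, cutoff: float) -> np.ndarray:
    return _slow_drivers(rng, 1, n, fs, cutoff)[0]


def _normalized_envelope(xi: np.ndarray, depth: float) -> np.ndarray:
    """Positive envelope with unit RMS per seed.

    The RMS normalisation keeps band power independent of the envelope
    mixing structure: without it, group-dependent coupling weights
    would subtly shift E[e^2] and leak coupling effects into power.
    Correlations (hence AEC and its calibration) are unaffected by the
    per-seed scaling.
    """
    env = np.clip(1 + depth * xi, 0.05, None)
    return env / np.sqrt(np.mean(env**2, axis=-1, keepdims=True))


def _band_carrier(rng: np.random.Generator, shape: tuple, fs: float, band_name: str) -> np.ndarray:
    """Unit-variance constant-modulus carrier confined to one band.

    Band-passed Gaussian noise divided by its own Hilbert envelope: a
    phase-noise oscillation whose instantaneous amplitude is constant,
    so any amplitude dynamics of the product signal come entirely from
    the imposed envelope.
    """
    band = get_band(band_name)
    b, a = signal.butter(4, [band.f_lo, band.f_hi], btype="band", fs=fs)
    c = signal.filtfilt(b, a, rng.standard_normal(shape), axis=-1)
    analytic = signal.hilbert(c, axis=-1)
    return np.sqrt(2.0) * np.real(analytic / np.abs(analytic))


def measure_planted_aec(
    weight: float,
    band_name: str,
    n_seeds: int = 30,
    fs: float = 600.0,
    n_epochs: int = 10,
    n_ensembles: int = 3,
    coupled_fraction: float = 0.5,
    epoch_length: float = 10.0,
    envelope_cutoff: float = 0.45,
    envelope_depth: float = 0.7,
    rng: np.random.Generator | None = None,
    orthogonalize: bool = True,
) -> float:
    """AEC measured through the analysis pipeline for one mixing weight.

    Simulates ensembles of ``n_seeds`` band-limited sources in which a
    fraction of disjoint seed pairs (``coupled_fraction``, mirroring
    the sparse edge sets of typical planted configurations) share an
    envelope component with the given mixing weight, then runs the
    exact measurement chain (band-pass, joint symmetric
    orthogonalization over the whole ensemble, Hilbert envelope, 1 Hz
    down-sampling, per-epoch Pearson, epoch averaging) and averages
    the AEC over the coupled pairs.

    Orthogonalizing jointly over the full ensemble matters: a narrow
    band has few effective degrees of freedom per epoch, so the
    orthogonality constraint distorts each series more as the ensemble
    grows, attenuating the achieved envelope correlation.  Calibrating
    with the ensemble size of the target cohort makes the planted
    effect self-consistent with its measurement by construction.
    """
    rng = rng or np.random.default_rng(_CALIBRATION_SEED)
    n = int(round(n_epochs * epoch_length * fs))
    coupled = max(1, int(round(coupled_fraction * (n_seeds // 2))))
    spe = int(round(epoch_length * fs))
    band = get_band(band_name)
    vals = []
    for _ in range(n_ensembles):
        xi = _slow_drivers(rng, n_seeds, n, fs, envelope_cutoff)
        shared = _slow_drivers(rng, coupled, n, fs, envelope_cutoff)
        for p in range(coupled):
            for s in (2 * p, 2 * p + 1):
                xi[s] = np.sqrt(1 - weight) * xi[s] + np.sqrt(weight) * shared[p]
        env = _normalized_envelope(xi, envelope_depth)
        x = env * _band_carrier(rng, (n_seeds, n), fs, band_name)
        for e in range(n_epochs):
            block = fir_bandpass(x[:, e * spe : (e + 1) * spe], fs, band)
            if orthogonalize:
                block = symmetric_orthogonalize(block)
            env_ds = downsample_envelope(hilbert_envelope(block), fs)
            r = aec(env_ds)
            vals.extend(r[2 * p, 2 * p + 1] for p in range(coupled))
    return float(np.nanmean(vals))


@lru_cache(maxsize=32)
def _calibration_curve(
    band_name: str, fs: float, envelope_cutoff: float, envelope_depth: float, n_seeds: int
):
    """Monotone lookup (weights, achieved AEC) for one band, cached.

    The weight -> AEC map is measured on a coarse grid and smoothed
    with a quadratic fit (the map is close to linear with a mild
    convexity from envelope clipping and orthogonalization), then
    tabulated on a fine grid for interpolation in
    :func:`weight_for_aec`.
    """
    rng = np.random.default_rng(_CALIBRATION_SEED)
    measured = [
        measure_planted_aec(
            w, band_name, n_seeds, fs,
            envelope_cutoff=envelope_cutoff, envelope_depth=envelope_depth, rng=rng,
        )
        for w in _WEIGHT_GRID
    ]
    coeffs = np.polyfit(np.asarray(_WEIGHT_GRID), np.asarray(measured), deg=2)
    w_fine = np.linspace(0.0, 1.0, 101)
    aec_fine = np.maximum.accumulate(np.polyval(coeffs, w_fine))
    return w_fine, aec_fine


def weight_for_aec(
    target_aec: float,
    band_name: str,
    n_seeds: int = 30,
    fs: float = 600.0,
    envelope_cutoff: float = 0.45,
    envelope_depth: float = 0.7,
) -> float:
    """Invert the calibration curve: mixing weight achieving a target AEC."""
    if target_aec <= 0:
        return 0.0
    weights, achieved = _calibration_curve(
        band_name, fs, envelope_cutoff, envelope_depth, n_seeds
    )
    if target_aec > achieved[-1]:
        raise ConfigurationError(
            f"target AEC {target_aec:.2f} exceeds the maximum achievable "
            f"{achieved[-1]:.2f} for band {band_name!r}"
        )
    return float(np.interp(target_aec, achieved, weights))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _sample_metadata(config: SyntheticConfig, rng: np.random.Generator) -> list[SubjectMetadata]:
    cov = config.covariate_model
    lo, hi = cov.age_range
    out = []
    for group, n in zip(GROUPS, config.n_per_group):
        g: GroupCovariates = getattr(cov, group)
        a, b = (lo - g.age_mean) / g.age_sd, (hi - g.age_mean) / g.age_sd
        ages = stats.truncnorm.rvs(a, b, loc=g.age_mean, scale=g.age_sd, size=n, random_state=rng)
        # lognormal parametrised by its arithmetic mean/sd
        sigma2 = np.log(1 + g.motion_sd**2 / g.motion_mean**2)
        mu = np.log(g.motion_mean) - sigma2 / 2
        motions = rng.lognormal(mu, np.sqrt(sigma2), size=n)
        sexes = np.where(rng.random(n) < g.male_proportion, "m", "f")
        for k in range(n):
            out.append(
                SubjectMetadata(
                    subject_id=f"{group}_{k:03d}",
                    group=group,
                    age=float(ages[k]),
                    sex=str(sexes[k]),
                    head_motion=float(motions[k]),
                )
            )
    return out


def _coupling_weights_for_subject(
    config: SyntheticConfig, group: str
) -> dict[str, list[tuple[tuple[int, int], float]]]:
    """Per band: list of (edge, mixing weight) for a subject of ``group``."""
    out: dict[str, list[tuple[tuple[int, int], float]]] = {}
    for eff in config.coupling_effects:
        target = eff.baseline + (eff.shift if group == eff.group else 0.0)
        w = weight_for_aec(
            target, eff.band, config.n_seeds, config.sampling_rate,
            config.envelope_cutoff, config.envelope_depth,
        )
        out.setdefault(eff.band, []).extend((tuple(e), w) for e in eff.edges)
    return out


def generate_source_signals(
    config: SyntheticConfig,
    subject: SubjectMetadata,
    rng: np.random.Generator,
) -> np.ndarray:
    """Continuous (n_seeds, n_samples) source time series for one subject."""
    n_seeds, n = config.n_seeds, config.n_samples
    fs = config.sampling_rate
    x = np.zeros((n_seeds, n))
    power_scale = {
        (eff.band, s): eff.amplitude_factor
        for eff in config.power_effects
        if eff.group == subject.group
        for s in eff.seeds
    }
    coupling = _coupling_weights_for_subject(config, subject.group)

    for band_name, amp in config.band_amplitudes.items():
        if amp == 0:
            continue
        carriers = _band_carrier(rng, (n_seeds, n), fs, band_name)
        xi = _slow_drivers(rng, n_seeds, n, fs, config.envelope_cutoff)
        effects = coupling.get(band_name, [])
        if effects:
            shared = _slow_drivers(rng, len(effects), n, fs, config.envelope_cutoff)
            for k, ((i, j), w) in enumerate(effects):
                if w == 0:
                    continue
                for s in (i, j):
                    xi[s] = np.sqrt(1 - w) * xi[s] + np.sqrt(w) * shared[k]
        env = _normalized_envelope(xi, config.envelope_depth)
        amps = np.array([amp * power_scale.get((band_name, s), 1.0) for s in range(n_seeds)])
        x += amps[:, None] * env * carriers
    return x


def generate_cohort(
    config: SyntheticConfig,
    source_model: SourceModel | None = None,
) -> tuple[list[SubjectMetadata], dict[str, np.ndarray]]:
    """Metadata plus ground-truth continuous source signals per subject.

    Fully reproducible: the master seed is fanned out into independent
    substreams (one for metadata, one per subject), so the cohort is
    bit-identical across runs with the same config.
    """
    if source_model is not None and source_model.n_seeds != config.n_seeds:
        raise ConfigurationError("source model seed count does not match config")
    ss = np.random.SeedSequence(config.seed)
    n_subjects = sum(config.n_per_group)
    streams = ss.spawn(n_subjects + 1)
    meta = _sample_metadata(config, np.random.default_rng(streams[0]))
    signals = {
        m.subject_id: generate_source_signals(config, m, np.random.default_rng(s))
        for m, s in zip(meta, streams[1:])
    }
    return meta, signals


def epoch_source_signal(
    continuous: np.ndarray, fs: float, epoch_length: float = 10.0
) -> np.ndarray:
    """Cut a continuous (seeds, samples) array into (epochs, seeds, samples)."""
    spe = int(round(epoch_length * fs))
    n_epochs = continuous.shape[-1] // spe
    return np.stack([continuous[:, e * spe : (e + 1) * spe] for e in range(n_epochs)])


# ---------------------------------------------------------------------------
# sensor projection and artifacts
# ---------------------------------------------------------------------------


def _head_position_trace(
    n: int, fs: float, head_motion_mm: float, rng: np.random.Generator,
    epoch_length: float = 10.0,
) -> np.ndarray:
    """Smooth head wander whose mean per-epoch max displacement matches the target."""
    b, a = signal.butter(2, 0.05, btype="low", fs=fs)
    wander = signal.filtfilt(b, a, rng.standard_normal((3, n)), axis=-1)
    wander -= np.median(wander, axis=-1, keepdims=True)
    disp = np.linalg.norm(wander, axis=0)
    spe = int(round(epoch_length * fs))
    n_ep = max(n // spe, 1)
    per_epoch_max = [disp[e * spe : (e + 1) * spe].max() for e in range(n_ep)]
    scale = head_motion_mm / max(np.mean(per_epoch_max), 1e-12)
    return (scale * wander).T  # (n, 3) in mm


def project_to_sensors(
    source_signal: np.ndarray,
    source_model: SourceModel,
    head_model: HeadModel,
    subject: SubjectMetadata,
    config: SyntheticConfig,
    rng: np.random.Generator,
    dipole_angles: np.ndarray | None = None,
) -> SensorRecording:
    """Forward-project sources through the spherical model, add sensor noise.

    Each seed radiates with a fixed tangential dipole moment (radial
    moments are silent in the spherical conductor).  The head-position
    trace is synthesised to match the subject's head-motion covariate.
    """
    from .beamformer import compute_leadfield  # local import avoids cycle

    n_seeds, n = source_signal.shape
    if dipole_angles is None:
        dipole_angles = rng.uniform(0, 2 * np.pi, n_seeds)
    gains = np.empty((head_model.n_sensors, n_seeds))
    for s in range(n_seeds):
        L = compute_leadfield(
            head_model, source_model.seed_positions[s], source_model.tangential_frames[s]
        )
        u = np.array([np.cos(dipole_angles[s]), np.sin(dipole_angles[s])])
        gains[:, s] = L @ u
    data = gains @ (config.dipole_moment * source_signal)
    if config.sensor_noise_sd > 0:
        data = data + rng.normal(0, config.sensor_noise_sd, data.shape)
    trace = _head_position_trace(n, config.sampling_rate, subject.head_motion, rng)
    return SensorRecording(
        data=data,
        sampling_rate=config.sampling_rate,
        head_position_trace=trace,
        subject_id=subject.subject_id,
    )


def _blink_course(n: int, fs: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    course = np.zeros(n)
    n_blinks = rng.poisson(rate * n / fs)
    width = int(0.15 * fs)
    t = np.arange(-3 * width, 3 * width + 1)
    bump = np.exp(-0.5 * (t / width) ** 2)
    for c in rng.integers(0, n, n_blinks):
        lo, hi = max(0, c - 3 * width), min(n, c + 3 * width + 1)
        course[lo:hi] += bump[(lo - c + 3 * width) : (hi - c + 3 * width)]
    return course


def _cardiac_course(n: int, fs: float, heart_rate: float, rng: np.random.Generator) -> np.ndarray:
    course = np.zeros(n)
    width = int(0.04 * fs)
    t = np.arange(-4 * width, 4 * width + 1)
    qrs = -(t / width) * np.exp(-0.5 * (t / width) ** 2)  # biphasic spike
    pos = rng.uniform(0, 1 / heart_rate) * fs
    while pos < n:
        c = int(pos)
        lo, hi = max(0, c - 4 * width), min(n, c + 4 * width + 1)
        course[lo:hi] += qrs[(lo - c + 4 * width) : (hi - c + 4 * width)]
        pos += fs / heart_rate * rng.uniform(0.9, 1.1)
    return course


def inject_artifacts(
    recording: SensorRecording,
    model: ArtifactModel,
    rng: np.random.Generator,
) -> tuple[SensorRecording, dict]:
    """Add ocular/cardiac components, head excursions and step jumps.

    Returns the contaminated recording and a ground-truth report
    (artifact time courses, jump locations, excursion windows) for use
    as oracles in preprocessing tests.  With all amplitudes/rates at
    zero the recording is returned unchanged.
    """
    data = recording.data.copy()
    trace = recording.head_position_trace.copy()
    n_ch, n = data.shape
    fs = recording.sampling_rate
    truth: dict = {"ocular": None, "cardiac": None, "jumps": [], "excursions": []}

    positions = np.arange(n_ch)
    if model.ocular_amplitude > 0:
        topo = np.exp(-0.5 * ((positions - 0.1 * n_ch) / (0.08 * n_ch)) ** 2)
        topo /= topo.max()
        course = _blink_course(n, fs, model.blink_rate, rng)
        data += model.ocular_amplitude * np.outer(topo, course)
        truth["ocular"] = course
    if model.cardiac_amplitude > 0:
        topo = np.sin(np.linspace(0, np.pi, n_ch)) * rng.choice([-1, 1], n_ch) * rng.uniform(0.3, 1, n_ch)
        topo /= np.abs(topo).max()
        course = _cardiac_course(n, fs, model.heart_rate, rng)
        data += model.cardiac_amplitude * np.outer(topo, course)
        truth["cardiac"] = course
    for _ in range(model.n_jumps):
        ch = int(rng.integers(0, n_ch))
        at = int(rng.integers(int(0.05 * n), int(0.95 * n)))
        amp = float(model.jump_amplitude * rng.choice([-1, 1]))
        data[ch, at:] += amp
        truth["jumps"].append((ch, at, amp))
    if rng.random() < model.excursion_probability:
        dur = int(model.excursion_duration * fs)
        start = int(rng.integers(0, max(n - dur, 1)))
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        bump = 0.5 * (1 - np.cos(2 * np.pi * np.arange(dur) / dur))
        trace[start : start + dur] += model.excursion_mm * bump[:, None] * direction
        truth["excursions"].append((start, start + dur))

    out = replace(recording, data=data, head_position_trace=trace)
    return out, truth
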