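"""Synthetic EMG + IMU gait-recording generator.

Emulates the statistical structure of wearable lower-limb recordings during
cyclic locomotion: four-channel surface EMG (rectus femoris, tibialis
anterior, biceps femoris, gastrocnemius) sampled at 2000 Hz and a
three-channel IMU (acceleration, angular velocity, angle about the sensor
Y axis) sampled at 200 Hz.  Each of the four motion modes (running, level
walking, stair ascent, ramp ascent) is a periodic gait pattern:

* EMG channels are amplitude-modulated band-limited Gaussian noise.  The
  modulation envelope is a sum of wrapped Gaussian activation bursts in gait
  phase, one set per muscle; the carrier is white noise band-pass filtered to
  the surface-EMG band (20-500 Hz by default).
* IMU channels are two-harmonic Fourier series of the gait phase plus a
  constant offset and additive Gaussian noise.

Cycle-to-cycle variability is controlled by a per-cycle period jitter, so
the cycle-to-cycle Pearson similarity of the defaults sits in the high
(> 0.85) regime typical of steady treadmill locomotion.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

EMG_RATE = 2000.0
IMU_RATE = 200.0
EMG_CHANNELS = ("RF", "TA", "BF", "GA")
IMU_CHANNELS = ("acc_y", "gyro_y", "angle_y")


class MotionMode(enum.IntEnum):
    """The four locomotion classes, with stable integer labels 0-3."""

    running = 0
    level_walk = 1
    stair_ascent = 2
    ramp_ascent = 3

    @classmethod
    def coerce(cls, value) -> "MotionMode":
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            try:
                return cls[value]
            except KeyError:
                raise ValueError(
                    f"unknown motion mode {value!r}; expected one of "
                    f"{[m.name for m in cls]}"
                ) from None
        return cls(value)


@dataclass(frozen=True)
class Burst:
    """One Gaussian activation burst in gait phase."""

    center: float  # phase in [0, 1)
    width: float  # phase units, > 0
    amplitude: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("burst width must be > 0")


@dataclass(frozen=True)
class Harmonics:
    """Constant offset plus the first two cadence harmonics of one IMU channel."""

    offset: float
    amp1: float
    phase1: float
    amp2: float
    phase2: float


@dataclass(frozen=True)
class GaitParams:
    """Mode-specific generator parameters.

    cadence is the gait-cycle frequency in Hz.  muscle_envelopes maps each
    EMG channel name to its burst set; imu_harmonics maps each IMU channel
    name to its harmonic description.  cycle_jitter is the relative SD of the
    per-cycle period perturbation.  emg_noise_floor and imu_noise_sd are
    additive-noise scales (EMG floor relative to envelope peak, IMU in
    channel units).  emg_band is the carrier band in Hz.
    """

    cadence: float
    muscle_envelopes: dict[str, tuple[Burst, ...]]
    imu_harmonics: dict[str, Harmonics]
    cycle_jitter: float = 0.03
    emg_noise_floor: float = 0.03
    imu_noise_sd: float = 0.08
    emg_band: tuple[float, float] = (20.0, 500.0)

    def __post_init__(self):
        if self.cadence <= 0:
            raise ValueError("cadence must be > 0")
        if self.cycle_jitter < 0:
            raise ValueError("cycle_jitter must be >= 0")
        lo, hi = self.emg_band
        if not (0 < lo < hi < EMG_RATE / 2):
            raise ValueError("emg_band must lie inside (0, 1000) Hz")
        if set(self.muscle_envelopes) != set(EMG_CHANNELS):
            raise ValueError(f"muscle_envelopes must cover {EMG_CHANNELS}")
        if set(self.imu_harmonics) != set(IMU_CHANNELS):
            raise ValueError(f"imu_harmonics must cover {IMU_CHANNELS}")

    def replace(self, **kw) -> "GaitParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject multiplicative perturbation of the mode defaults."""

    subject_id: str
    amplitude_scale: float = 1.0
    cadence_scale: float = 1.0
    seed_offset: int = 0

    def __post_init__(self):
        if self.amplitude_scale <= 0 or self.cadence_scale <= 0:
            raise ValueError("profile scales must be > 0")


@dataclass
class RecordingBundle:
    """One paired EMG/IMU recording with its mode label and provenance."""

    emg: np.ndarray  # (4, T) at 2000 Hz
    imu: np.ndarray  # (3, T') at 200 Hz
    mode: MotionMode
    duration: float
    meta: dict = field(default_factory=dict)

    @property
    def emg_rate(self) -> float:
        return EMG_RATE

    @property
    def imu_rate(self) -> float:
        return IMU_RATE


# ---------------------------------------------------------------------------
# Mode defaults.
#
# The four modes are separated along several axes at once: cadence, IMU
# harmonic shape/amplitude, and EMG burst timing/intensity.  Running has the
# largest amplitudes throughout.  The overlaps are deliberate: level walking
# and ramp ascent share similar IMU kinematics (they differ mostly in EMG
# effort), while stair and ramp ascent share similar EMG intensity (they
# differ mostly in IMU range), so no single modality separates all four
# modes trivially and fusing the two genuinely helps.
# ---------------------------------------------------------------------------

_MODE_DEFAULTS: dict[MotionMode, dict] = {
    MotionMode.running: dict(
        cadence=2.6,
        bursts={
            "RF": [(0.05, 0.06, 2.2), (0.55, 0.08, 1.1)],
            "TA": [(0.92, 0.06, 1.8), (0.35, 0.10, 0.9)],
            "BF": [(0.45, 0.08, 2.0), (0.85, 0.06, 1.0)],
            "GA": [(0.25, 0.07, 2.6), (0.70, 0.09, 0.8)],
        },
        harmonics={
            "acc_y": (0.10, 1.60, 0.0, 0.70, 1.2),
            "gyro_y": (0.0, 220.0, -1.1, 80.0, 0.6),
            "angle_y": (5.0, 38.0, 2.0, 9.0, -0.8),
        },
    ),
    MotionMode.level_walk: dict(
        cadence=1.8,
        bursts={
            "RF": [(0.10, 0.08, 0.9), (0.60, 0.10, 0.45)],
            "TA": [(0.95, 0.08, 0.8), (0.40, 0.12, 0.40)],
            "BF": [(0.50, 0.10, 0.7), (0.90, 0.08, 0.35)],
            "GA": [(0.30, 0.08, 1.0), (0.75, 0.10, 0.35)],
        },
        harmonics={
            "acc_y": (0.05, 0.60, 0.3, 0.22, 1.5),
            "gyro_y": (0.0, 90.0, -0.8, 30.0, 0.9),
            "angle_y": (3.0, 20.0, 2.2, 5.0, -0.5),
        },
    ),
    MotionMode.stair_ascent: dict(
        cadence=1.4,
        bursts={
            # knee/ankle extensor-dominant effort, clearly above level walk
            "RF": [(0.18, 0.10, 1.5), (0.68, 0.10, 0.6)],
            "TA": [(0.05, 0.10, 1.2), (0.52, 0.12, 0.55)],
            "BF": [(0.60, 0.10, 1.1), (0.05, 0.08, 0.5)],
            "GA": [(0.40, 0.10, 1.6), (0.88, 0.10, 0.5)],
        },
        harmonics={
            # large angle excursion, strong second harmonic (step-wise lift)
            "acc_y": (0.08, 0.85, 1.0, 0.50, -0.4),
            "gyro_y": (0.0, 130.0, 0.4, 70.0, -1.2),
            "angle_y": (12.0, 30.0, 1.1, 12.0, 0.7),
        },
    ),
    MotionMode.ramp_ascent: dict(
        cadence=1.72,
        bursts={
            # per-muscle intensities match level walking almost exactly;
            # what changes on the incline is the coordination pattern
            # (which muscles fire together in the cycle), so per-channel
            # summary statistics cannot tell ramp from walk but
            # cross-channel waveform structure can
            "RF": [(0.45, 0.08, 0.95), (0.90, 0.10, 0.50)],
            "TA": [(0.25, 0.08, 0.85), (0.70, 0.12, 0.45)],
            "BF": [(0.10, 0.10, 0.75), (0.55, 0.08, 0.40)],
            "GA": [(0.60, 0.08, 1.05), (0.10, 0.10, 0.40)],
        },
        harmonics={
            # kinematics nearly indistinguishable from level walking: on a
            # moderate incline the leg swing changes little, so the IMU
            # stream alone cannot reliably tell ramp from walk
            "acc_y": (0.06, 0.62, 0.32, 0.23, 1.45),
            "gyro_y": (0.0, 92.0, -0.78, 31.0, 0.88),
            "angle_y": (3.5, 20.5, 2.18, 5.2, -0.48),
        },
    ),
}


def default_params(mode: MotionMode | str | int) -> GaitParams:
    """Return the documented default :class:`GaitParams` for one motion mode.

    Pure function: repeated calls return identical values.  The defaults are
    mutually distinguishable (distinct cadences, envelope phasings and IMU
    harmonic amplitudes) and running has the largest amplitudes.
    """
    mode = MotionMode.coerce(mode)
    raw = _MODE_DEFAULTS[mode]
    envelopes = {
        ch: tuple(Burst(*b) for b in raw["bursts"][ch]) for ch in EMG_CHANNELS
    }
    harmonics = {ch: Harmonics(*raw["harmonics"][ch]) for ch in IMU_CHANNELS}
    return GaitParams(
        cadence=raw["cadence"], muscle_envelopes=envelopes, imu_harmonics=harmonics
    )


def _wrapped_envelope(phase: np.ndarray, bursts: tuple[Burst, ...]) -> np.ndarray:
    """Sum of Gaussian bursts in phase, wrapped on the unit circle."""
    env = np.zeros_like(phase)
    frac = np.mod(phase, 1.0)
    for b in bursts:
        # nearest wrapped distance to the burst centre
        d = frac - b.center
        d -= np.round(d)
        env += b.amplitude * np.exp(-0.5 * (d / b.width) ** 2)
    return env


def _phase_track(duration: float, cadence: float, jitter: float,
                 rng: np.random.Generator, rate: float) -> np.ndarray:
    """Gait phase (in cycles, monotone) sampled at `rate`, with per-cycle
    period jitter.  phase k -> k+1 spans one gait cycle."""
    n_cycles = int(np.ceil(duration * cadence)) + 2
    periods = (1.0 / cadence) * (1.0 + jitter * rng.standard_normal(n_cycles))
    periods = np.maximum(periods, 0.2 / cadence)
    boundaries = np.concatenate([[0.0], np.cumsum(periods)])
    t = np.arange(int(round(duration * rate))) / rate
    # piecewise-linear phase: interpolate cycle index over boundary times
    return np.interp(t, boundaries, np.arange(n_cycles + 1, dtype=float))


def _bandlimited_carrier(n: int, band: tuple[float, float], rate: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-pass filtered to `band`."""
    lo, hi = band
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n + 4000))[2000:-2000]
    return x / np.sqrt(np.mean(x**2))


def generate_recording(params: GaitParams, mode: MotionMode | str | int,
                       duration: float, seed: int) -> RecordingBundle:
    """Generate one paired EMG/IMU recording.

    Identical arguments (including seed) give bit-identical output.  Raises
    if the duration is non-positive or shorter than two gait cycles.
    """
    mode = MotionMode.coerce(mode)
    if duration <= 0:
        raise ValueError("duration must be positive")
    if duration < 2.0 / params.cadence:
        raise ValueError(
            f"duration {duration} s is shorter than two gait cycles "
            f"({2.0 / params.cadence:.2f} s at cadence {params.cadence} Hz)"
        )
    rng = np.random.default_rng(seed)

    phase_emg = _phase_track(duration, params.cadence, params.cycle_jitter,
                             rng, EMG_RATE)
    # IMU shares the same gait-phase track, sampled every 10th EMG sample
    phase_imu = phase_emg[:: int(EMG_RATE // IMU_RATE)]

    n_emg = phase_emg.size
    emg = np.empty((len(EMG_CHANNELS), n_emg))
    for c, ch in enumerate(EMG_CHANNELS):
        env = _wrapped_envelope(phase_emg, params.muscle_envelopes[ch])
        carrier = _bandlimited_carrier(n_emg, params.emg_band, EMG_RATE, rng)
        peak = max(b.amplitude for b in params.muscle_envelopes[ch])
        noise = params.emg_noise_floor * peak * _bandlimited_carrier(
            n_emg, params.emg_band, EMG_RATE, rng
        )
        emg[c] = env * carrier + noise

    imu = np.empty((len(IMU_CHANNELS), phase_imu.size))
    for c, ch in enumerate(IMU_CHANNELS):
        h = params.imu_harmonics[ch]
        scale = max(abs(h.amp1), abs(h.amp2), 1e-12)
        imu[c] = (
            h.offset
            + h.amp1 * np.cos(2 * np.pi * phase_imu + h.phase1)
            + h.amp2 * np.cos(4 * np.pi * phase_imu + h.phase2)
            + params.imu_noise_sd * scale * rng.standard_normal(phase_imu.size)
        )

    meta = {
        "mode": mode.name,
        "seed": int(seed),
        "duration": float(duration),
        "cadence": params.cadence,
        "cycle_jitter": params.cycle_jitter,
        "emg_band": list(params.emg_band),
        "emg_rate": EMG_RATE,
        "imu_rate": IMU_RATE,
    }
    return RecordingBundle(emg=emg, imu=imu, mode=mode, duration=duration, meta=meta)


def apply_profile(params: GaitParams, profile: SubjectProfile) -> GaitParams:
    """Scale mode defaults by one subject's amplitude and cadence factors."""
    envelopes = {
        ch: tuple(
            Burst(b.center, b.width, b.amplitude * profile.amplitude_scale)
            for b in bursts
        )
        for ch, bursts in params.muscle_envelopes.items()
    }
    return params.replace(cadence=params.cadence * profile.cadence_scale,
                          muscle_envelopes=envelopes)


def default_profiles(n_subjects: int = 6) -> list[SubjectProfile]:
    """Deterministic pseudo-subject panel: mild amplitude/cadence spread."""
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    amp = np.linspace(0.85, 1.15, n_subjects)
    cad = np.linspace(0.95, 1.05, n_subjects)
    return [
        SubjectProfile(subject_id=f"S{i + 1}", amplitude_scale=float(amp[i]),
                       cadence_scale=float(cad[i]), seed_offset=i)
        for i in range(n_subjects)
    ]


def _child_seed(seed: int, subject_idx: int, mode: MotionMode, rep: int) -> int:
    ss = np.random.SeedSequence([int(seed), subject_idx, int(mode), rep])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(profiles: list[SubjectProfile],
                     modes: list[MotionMode | str | int],
                     reps_per_mode: int, duration: float,
                     seed: int) -> list[RecordingBundle]:
    """One bundle per (profile, mode, rep); per-bundle seeds are derived
    deterministically from (seed, subject, mode, rep) so all bundles are
    mutually independent and the whole dataset reproduces from one seed."""
    if not profiles or not modes:
        raise ValueError("profiles and modes must be non-empty")
    if reps_per_mode < 1:
        raise ValueError("reps_per_mode must be >= 1")
    modes = [MotionMode.coerce(m) for m in modes]
    bundles = []
    for si, prof in enumerate(profiles):
        for mode in modes:
            params = apply_profile(default_params(mode), prof)
            for rep in range(reps_per_mode):
                s = _child_seed(seed + prof.seed_offset, si, mode, rep)
                b = generate_recording(params, mode, duration, s)
                b.meta.update(subject=prof.subject_id, rep=rep)
                bundles.append(b)
    return bundles


# ---------------------------------------------------------------------------
# Delimited-text I/O: one CSV per modality plus a JSON sidecar.
# ---------------------------------------------------------------------------

def write_recording(bundle: RecordingBundle, outdir: str | Path,
                    stem: str) -> dict[str, Path]:
    """Write `<stem>_emg.csv`, `<stem>_imu.csv` and `<stem>_meta.json`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for modality, data, rate, names in (
        ("emg", bundle.emg, EMG_RATE, EMG_CHANNELS),
        ("imu", bundle.imu, IMU_RATE, IMU_CHANNELS),
    ):
        t = np.arange(data.shape[1]) / rate
        df = pd.DataFrame({"time": t, **{n: data[i] for i, n in enumerate(names)}})
        p = outdir / f"{stem}_{modality}.csv"
        df.to_csv(p, index=False, float_format="%.6g")
        paths[modality] = p
    meta_path = outdir / f"{stem}_meta.json"
    meta_path.write_text(json.dumps(bundle.meta, indent=1))
    paths["meta"] = meta_path
    return paths


def read_recording(outdir: str | Path, stem: str) -> RecordingBundle:
    """Read a recording written by :func:`write_recording`."""
    outdir = Path(outdir)
    meta = json.loads((outdir / f"{stem}_meta.json").read_text())
    emg = pd.read_csv(outdir / f"{stem}_emg.csv")
    imu = pd.read_csv(outdir / f"{stem}_imu.csv")
    return RecordingBundle(
        emg=emg[list(EMG_CHANNELS)].to_numpy().T,
        imu=imu[list(IMU_CHANNELS)].to_numpy().T,
        mode=MotionMode[meta["mode"]],
        duration=float(meta["duration"]),
        meta=meta,
    )


def write_dataset(bundles: list[RecordingBundle], outdir: str | Path) -> list[str]:
    """Write a list of bundles; stems encode subject, mode and repetition."""
    stems = []
    for i, b in enumerate(bundles):
        subj = b.meta.get("subject", "S0")
        rep = b.meta.get("rep", i)
        stem = f"{subj}_{b.mode.name}_r{rep}"
        write_recording(b, outdir, stem)
        stems.append(stem)
    return stems


def read_dataset(outdir: str | Path) -> list[RecordingBundle]:
    outdir = Path(outdir)
    stems = sorted(p.name[: -len("_meta.json")]
                   for p in outdir.glob("*_meta.json"))
    return [read_recording(outdir, s) for s in stems]
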