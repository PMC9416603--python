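"""Signal conditioning, windowing, splitting and repeatability QC.

The conditioning chain mirrors standard wearable-sensor practice: EMG is
band-pass filtered to 20-500 Hz and IMU low-pass filtered at 10 Hz with
zero-phase 4th-order Butterworth filters; the IMU stream is then upsampled
from 200 Hz to 2000 Hz by cubic-spline interpolation so both modalities
share one sample clock; finally the recording is cut into paired
fixed-length windows (4x600 EMG, 3x600 IMU) and the window pairs are split
into train/validation/test at a stratified 7:1:2 ratio.

QC statistics quantify cycle-to-cycle repeatability: pairwise Pearson
correlation between randomly sampled gait cycles of each IMU channel, and
mean +/- SD of per-cycle integrated EMG (iEMG) per muscle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .synthio import (EMG_CHANNELS, EMG_RATE, IMU_CHANNELS, IMU_RATE,
                      MotionMode, RecordingBundle)

WINDOW_LEN = 600
SPLIT_NAMES = ("train", "val", "test")


# ---------------------------------------------------------------------------
# Filtering and resampling
# ---------------------------------------------------------------------------

def bandpass_emg(x: np.ndarray, low: float = 20.0, high: float = 500.0,
                 order: int = 4, rate: float = EMG_RATE) -> np.ndarray:
    """Zero-phase Butterworth band-pass for surface EMG.

    Applied forward-backward (``sosfiltfilt``), so the effective attenuation
    is the squared magnitude of the designed filter and no phase lag is
    introduced — window alignment across modalities is preserved.
    """
    x = np.asarray(x, dtype=float)
    if not (0 < low < high < rate / 2):
        raise ValueError(f"need 0 < low < high < Nyquist ({rate / 2} Hz)")
    if x.shape[-1] <= 3 * order:
        raise ValueError("signal too short for the requested filter order")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def lowpass_imu(x: np.ndarray, cutoff: float = 10.0, order: int = 4,
                rate: float = IMU_RATE) -> np.ndarray:
    """Zero-phase Butterworth low-pass for IMU channels at their native rate."""
    x = np.asarray(x, dtype=float)
    if not (0 < cutoff < rate / 2):
        raise ValueError(f"cutoff must lie in (0, Nyquist={rate / 2}) Hz")
    if x.shape[-1] <= 3 * order:
        raise ValueError("signal too short for the requested filter order")
    sos = sps.butter(order, cutoff, btype="lowpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def resample_cubic(x: np.ndarray, rate_in: float = IMU_RATE,
                   rate_out: float = EMG_RATE) -> np.ndarray:
    """Upsample by cubic-spline interpolation (integer ratio only).

    The interpolant passes through every input sample, so values at the
    original knot positions are reproduced exactly; output length is
    ``len(x) * rate_out / rate_in``.
    """
    x = np.asarray(x, dtype=float)
    ratio = rate_out / rate_in
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError("rate_out must be an integer multiple of rate_in")
    ratio = int(round(ratio))
    if x.shape[-1] < 4:
        raise ValueError("need at least 4 samples for cubic interpolation")
    n_in = x.shape[-1]
    t_in = np.arange(n_in) / rate_in
    t_out = np.arange(n_in * ratio) / rate_out
    cs = CubicSpline(t_in, x, axis=-1, extrapolate=True)
    return cs(t_out)


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

@dataclass
class WindowSet:
    """Paired, time-aligned EMG/IMU windows with labels and split assignment.

    emg has shape (N, 4, 600) and imu (N, 3, 600); both modalities are on the
    2000 Hz clock (IMU upsampled), so equal start indices cover the same
    0.3 s span.  split holds one of {train, val, test, unassigned} per pair.
    """

    emg: np.ndarray
    imu: np.ndarray
    labels: np.ndarray  # int mode codes
    source_id: np.ndarray  # str recording ids
    start_index: np.ndarray  # int sample offsets
    subject: np.ndarray = None  # str subject ids
    split: np.ndarray = None

    def __post_init__(self):
        n = len(self.labels)
        if self.emg.shape != (n, len(EMG_CHANNELS), WINDOW_LEN):
            raise ValueError(f"emg must be (N, 4, {WINDOW_LEN})")
        if self.imu.shape != (n, len(IMU_CHANNELS), WINDOW_LEN):
            raise ValueError(f"imu must be (N, 3, {WINDOW_LEN})")
        if self.split is None:
            self.split = np.array(["unassigned"] * n, dtype=object)
        if self.subject is None:
            self.subject = np.array(["S0"] * n, dtype=object)

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, mask) -> "WindowSet":
        return WindowSet(self.emg[mask], self.imu[mask], self.labels[mask],
                         self.source_id[mask], self.start_index[mask],
                         self.subject[mask], self.split[mask])

    def split_subset(self, *names: str) -> "WindowSet":
        mask = np.isin(self.split, names)
        return self.subset(mask)

    def as_matrix(self) -> np.ndarray:
        """Flatten each window pair to one 4200-vector (EMG block then IMU
        block), the layout the CNN estimators accept."""
        n = len(self)
        return np.hstack([self.emg.reshape(n, -1), self.imu.reshape(n, -1)])

    @staticmethod
    def concat(sets: list["WindowSet"]) -> "WindowSet":
        return WindowSet(
            np.concatenate([s.emg for s in sets]),
            np.concatenate([s.imu for s in sets]),
            np.concatenate([s.labels for s in sets]),
            np.concatenate([s.source_id for s in sets]),
            np.concatenate([s.start_index for s in sets]),
            np.concatenate([s.subject for s in sets]),
            np.concatenate([s.split for s in sets]),
        )


def preprocess_bundle(bundle: RecordingBundle, trim: float = 0.25,
                      low: float = 20.0, high: float = 500.0,
                      imu_cutoff: float = 10.0) -> RecordingBundle:
    """Filter both modalities, upsample IMU to 2000 Hz, trim filter edges.

    IMU is low-pass filtered at its native 200 Hz before upsampling, so the
    spline never amplifies out-of-band noise.  `trim` seconds are dropped
    from each end to discard zero-phase filter transients.
    """
    emg = bandpass_emg(bundle.emg, low, high)
    imu = lowpass_imu(bundle.imu, imu_cutoff)
    imu = resample_cubic(imu, IMU_RATE, EMG_RATE)
    n = min(emg.shape[1], imu.shape[1])
    emg, imu = emg[:, :n], imu[:, :n]
    k = int(round(trim * EMG_RATE))
    if 2 * k >= n:
        raise ValueError("recording shorter than twice the trim margin")
    if k:
        emg, imu = emg[:, k:-k], imu[:, k:-k]
    out = RecordingBundle(emg=emg, imu=imu, mode=bundle.mode,
                          duration=emg.shape[1] / EMG_RATE,
                          meta=dict(bundle.meta))
    out.meta["preprocessed"] = True
    out.meta["imu_rate_effective"] = EMG_RATE
    return out


def segment(bundle: RecordingBundle, window: int = WINDOW_LEN,
            stride: int = WINDOW_LEN) -> WindowSet:
    """Cut a preprocessed bundle into paired windows.

    Yields floor((T - window)/stride) + 1 pairs; the trailing remainder is
    dropped.  Requires the bundle to be preprocessed (IMU on the 2000 Hz
    clock) so EMG and IMU windows with equal start index are time-aligned.
    """
    if bundle.emg.shape[1] != bundle.imu.shape[1]:
        raise ValueError("bundle must be preprocessed (IMU upsampled) first")
    T = bundle.emg.shape[1]
    if T < window:
        raise ValueError(f"recording length {T} shorter than window {window}")
    starts = np.arange(0, T - window + 1, stride)
    emg = np.stack([bundle.emg[:, s:s + window] for s in starts])
    imu = np.stack([bundle.imu[:, s:s + window] for s in starts])
    n = len(starts)
    sid = bundle.meta.get("subject", "S0") + "/" + bundle.mode.name + \
        "/r" + str(bundle.meta.get("rep", 0))
    return WindowSet(
        emg=emg, imu=imu,
        labels=np.full(n, int(bundle.mode)),
        source_id=np.array([sid] * n, dtype=object),
        start_index=starts.astype(int),
        subject=np.array([bundle.meta.get("subject", "S0")] * n, dtype=object),
    )


def segment_dataset(bundles: list[RecordingBundle], window: int = WINDOW_LEN,
                    stride: int = WINDOW_LEN, trim: float = 0.25) -> WindowSet:
    """Preprocess and segment a list of raw bundles into one WindowSet."""
    return WindowSet.concat(
        [segment(preprocess_bundle(b, trim=trim), window, stride) for b in bundles]
    )


def split(ws: WindowSet, ratio: tuple[int, int, int] = (7, 1, 2),
          seed: int = 0, group_by_recording: bool = False) -> WindowSet:
    """Assign train/val/test splits, stratified by motion mode.

    Per mode, windows are shuffled (seeded) and allocated to the three
    splits by largest-remainder rounding of the requested ratio, so split
    fractions are within one window of exact per mode.  With
    ``group_by_recording`` whole recordings are assigned together (greedy
    fill towards the target fractions).
    """
    if len(ws) < 10:
        raise ValueError("need at least 10 window pairs to split")
    fr = np.asarray(ratio, dtype=float)
    fr = fr / fr.sum()
    rng = np.random.default_rng(seed)
    assignment = np.array(["unassigned"] * len(ws), dtype=object)
    carry = np.zeros(3)  # rounding residue propagated across modes
    for mode in np.unique(ws.labels):
        idx = np.flatnonzero(ws.labels == mode)
        if group_by_recording:
            recs = list(dict.fromkeys(ws.source_id[idx]))  # stable unique
            rng.shuffle(recs)
            counts = np.zeros(3)
            total = len(idx)
            for rec in recs:
                rec_idx = idx[ws.source_id[idx] == rec]
                # put the whole recording where the deficit is largest
                deficit = fr - counts / total
                k = int(np.argmax(deficit))
                assignment[rec_idx] = SPLIT_NAMES[k]
                counts[k] += len(rec_idx)
        else:
            perm = rng.permutation(idx)
            quota = len(idx) * fr + carry
            base = np.floor(quota).astype(int)
            rem = quota - base
            short = len(idx) - base.sum()
            order = np.argsort(-rem, kind="stable")
            base[order[:short]] += 1
            carry = quota - base  # keeps global totals on the exact ratio
            alloc = base
            edges = np.concatenate([[0], np.cumsum(alloc)])
            for k, name in enumerate(SPLIT_NAMES):
                assignment[perm[edges[k]:edges[k + 1]]] = name
    out = ws.subset(np.ones(len(ws), dtype=bool))
    out.split = assignment
    return out


# ---------------------------------------------------------------------------
# Repeatability / reproducibility QC
# ---------------------------------------------------------------------------

def iemg(x: np.ndarray) -> float:
    """Integrated EMG: sum of rectified sample amplitudes over a period."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("iemg of empty input is undefined")
    return float(np.sum(np.abs(x)))


def cycle_similarity(cycles: list[np.ndarray]) -> np.ndarray:
    """Pairwise Pearson correlation matrix between equal-length cycles."""
    if len(cycles) < 2:
        raise ValueError("need at least two cycles")
    arr = np.asarray(cycles, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 3:
        raise ValueError("cycles must be equal-length 1-D series of length >= 3")
    if np.any(np.std(arr, axis=1) == 0):
        raise ValueError("Pearson correlation undefined for constant cycles")
    return np.corrcoef(arr)


def _dominant_period(x: np.ndarray) -> int:
    """Fundamental period in samples from the first prominent peak of the
    autocorrelation of the mean-removed signal."""
    x = x - np.mean(x)
    ac = np.correlate(x, x, mode="full")[len(x) - 1:]
    # first local maximum after the zero-lag peak decays
    trough = 1
    while trough < len(ac) - 1 and ac[trough] > ac[trough + 1]:
        trough += 1
    if trough >= len(ac) - 2:
        raise ValueError("no periodicity detected")
    peak = trough + int(np.argmax(ac[trough:min(len(ac), trough * 20)]))
    return max(peak, 2)


def detect_cycles(angle: np.ndarray, min_len: int = 8) -> list[tuple[int, int]]:
    """Gait-cycle boundaries from rising zero crossings of the mean-removed
    IMU angle signal.  Returns (start, end) index pairs.

    A waveform with a strong second harmonic can cross zero more than once
    per gait cycle, so crossings are accepted only if they fall at least
    70% of the autocorrelation-estimated fundamental period after the
    previously accepted one.
    """
    x = np.asarray(angle, dtype=float) - np.mean(angle)
    rising = np.flatnonzero((x[:-1] <= 0) & (x[1:] > 0)) + 1
    if len(rising) < 2:
        return []
    period = _dominant_period(x)
    accepted = [rising[0]]
    for r in rising[1:]:
        if r - accepted[-1] >= 0.7 * period:
            accepted.append(r)
    return [(int(a), int(b)) for a, b in zip(accepted[:-1], accepted[1:])
            if b - a >= min_len]


def _normalize_cycle(x: np.ndarray, n: int = 200) -> np.ndarray:
    """Linearly time-normalize one cycle onto a fixed n-point grid so cycles
    of slightly different duration become comparable."""
    t = np.linspace(0, 1, len(x))
    return np.interp(np.linspace(0, 1, n), t, x)


@dataclass
class QCReport:
    """Per-channel cycle-similarity matrices, per-muscle iEMG statistics and
    pass flags against the configured thresholds."""

    cycle_similarities: dict = field(default_factory=dict)
    iemg_stats: dict = field(default_factory=dict)
    pass_flags: dict = field(default_factory=dict)
    similarity_threshold: float = 0.85


def qc_report(bundle: RecordingBundle, n_cycles: int = 5, seed: int = 0,
              similarity_threshold: float = 0.85) -> QCReport:
    """Repeatability QC on one raw recording.

    Cycles are located from the IMU angle channel, `n_cycles` of them are
    sampled at random (seeded), each is time-normalized to a common grid,
    and pairwise Pearson similarity is computed per IMU channel.  iEMG is
    computed per muscle per gait cycle (cycle boundaries mapped to the EMG
    clock) and summarised as mean +/- SD.
    """
    rng = np.random.default_rng(seed)
    angle = bundle.imu[IMU_CHANNELS.index("angle_y")]
    bounds = detect_cycles(angle)
    if len(bounds) < 2:
        raise ValueError("too few gait cycles detected for QC")
    n_pick = min(n_cycles, len(bounds))
    picked = sorted(rng.choice(len(bounds), size=n_pick, replace=False))

    report = QCReport(similarity_threshold=similarity_threshold)
    for c, ch in enumerate(IMU_CHANNELS):
        cycles = [_normalize_cycle(bundle.imu[c, a:b]) for a, b in
                  (bounds[i] for i in picked)]
        sim = cycle_similarity(cycles)
        report.cycle_similarities[ch] = sim
        off = sim[np.triu_indices_from(sim, k=1)]
        report.pass_flags[ch] = bool(np.mean(off) >= similarity_threshold)

    ratio = int(EMG_RATE // IMU_RATE)
    for c, ch in enumerate(EMG_CHANNELS):
        vals = [iemg(bundle.emg[c, a * ratio:b * ratio]) for a, b in bounds]
        report.iemg_stats[ch] = (float(np.mean(vals)), float(np.std(vals)))
    return report


# ---------------------------------------------------------------------------
# HDF5 container I/O
# ---------------------------------------------------------------------------

def save_windows(ws: WindowSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("emg", data=ws.emg)
        f.create_dataset("imu", data=ws.imu)
        f.create_dataset("label", data=ws.labels.astype(np.int64))
        f.create_dataset("split", data=ws.split.astype("S"))
        f.create_dataset("source", data=ws.source_id.astype("S"))
        f.create_dataset("subject", data=ws.subject.astype("S"))
        f.create_dataset("start_index", data=ws.start_index.astype(np.int64))


def load_windows(path) -> WindowSet:
    with h5py.File(path, "r") as f:
        return WindowSet(
            emg=f["emg"][:], imu=f["imu"][:], labels=f["label"][:],
            source_id=f["source"].asstr()[:].astype(object),
            start_index=f["start_index"][:],
            subject=f["subject"].asstr()[:].astype(object),
            split=f["split"].asstr()[:].astype(object),
        )
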