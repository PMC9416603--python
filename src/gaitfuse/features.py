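"""Hand-designed time- and frequency-domain feature bank.

The classical baseline against which the learned CNN features are compared.
Per channel of a 600-sample window the bank provides:

time domain
    MAV   mean absolute value, (1/N) sum |x_i|
    VAR   mean-square form, (1/(N-1)) sum x_i^2  (no mean subtraction; this
          is the conventional EMG "variance" of a zero-mean signal)
    RMS   sqrt((1/N) sum x_i^2)
    ZC    thresholded zero-crossing count
    WAMP  Willison amplitude: count of consecutive-sample jumps >= threshold
    WL    waveform length, sum |x_{i+1} - x_i|
frequency domain (from a mean-removed one-sided periodogram)
    MDF   median frequency: smallest bin at which cumulative power reaches
          half of total power
    MNP   mean per-bin power

EMG windows use all of {MAV, VAR, RMS, WAMP, ZC, WL, MDF, MNP}; IMU windows
use {MAV, VAR, RMS, ZC, MDF, MNP} (no WAMP/WL — those are EMG conventions).
The ZC and WAMP thresholds default to fractions of the window RMS so counts
stay meaningful whatever the signal units are.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import WindowSet
from .synthio import EMG_CHANNELS, EMG_RATE, IMU_CHANNELS

EMG_TIME = ("MAV", "VAR", "RMS", "WAMP", "ZC", "WL")
EMG_FREQ = ("MDF", "MNP")
IMU_TIME = ("MAV", "VAR", "RMS", "ZC")
IMU_FREQ = ("MDF", "MNP")

#: relative thresholds (fractions of window RMS)
ZC_THRESHOLD_REL = 0.01
WAMP_THRESHOLD_REL = 0.05


def mav(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("mav of empty input")
    return float(np.mean(np.abs(x)))


def var(x: np.ndarray) -> float:
    """Mean-square 'variance' with Bessel denominator and no mean removal."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("var needs at least 2 samples")
    return float(np.sum(x**2) / (x.size - 1))


def rms(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("rms of empty input")
    return float(np.sqrt(np.mean(x**2)))


def zc(x: np.ndarray, threshold: float = 0.0) -> int:
    """Zero crossings: sign changes whose amplitude step exceeds `threshold`."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("zc needs at least 2 samples")
    sign_change = x[:-1] * x[1:] < 0
    big_step = np.abs(x[:-1] - x[1:]) > threshold
    return int(np.count_nonzero(sign_change & big_step))


def wamp(x: np.ndarray, threshold: float) -> int:
    """Willison amplitude: consecutive-sample differences >= threshold."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("wamp needs at least 2 samples")
    return int(np.count_nonzero(np.abs(np.diff(x)) >= threshold))


def wl(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("wl needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


@dataclass(frozen=True)
class SpectrumEstimate:
    """One-sided periodogram: frequency bins and per-bin power."""

    frequencies: np.ndarray
    power: np.ndarray

    @property
    def M(self) -> int:
        return len(self.power)


def power_spectrum(x: np.ndarray, rate: float = EMG_RATE) -> SpectrumEstimate:
    """Mean-removed, boxcar, one-sided periodogram.

    Parseval-consistent: the per-bin powers sum to the mean power of the
    mean-removed signal (scipy ``scaling='spectrum'``).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 samples for a spectrum")
    f, p = sps.periodogram(x, fs=rate, window="boxcar", detrend="constant",
                           scaling="spectrum")
    return SpectrumEstimate(frequencies=f, power=p)


def mdf(spec: SpectrumEstimate) -> float:
    """Median frequency: smallest bin whose cumulative power reaches half
    of the total (the printed half-split equality rarely holds exactly on a
    discrete spectrum)."""
    total = float(np.sum(spec.power))
    if total <= 0:
        raise ValueError("mdf undefined for zero total power")
    cum = np.cumsum(spec.power)
    idx = int(np.searchsorted(cum, total / 2.0))
    return float(spec.frequencies[idx])


def mnp(spec: SpectrumEstimate) -> float:
    """Mean per-bin power."""
    if spec.M < 1:
        raise ValueError("empty spectrum")
    return float(np.mean(spec.power))


def _channel_features(x: np.ndarray, names: tuple[str, ...], rate: float,
                      zc_rel: float, wamp_rel: float) -> list[float]:
    w_rms = rms(x)
    spec = None
    out = []
    for name in names:
        if name == "MAV":
            out.append(mav(x))
        elif name == "VAR":
            out.append(var(x))
        elif name == "RMS":
            out.append(w_rms)
        elif name == "ZC":
            out.append(zc(x, zc_rel * w_rms))
        elif name == "WAMP":
            out.append(wamp(x, wamp_rel * w_rms))
        elif name == "WL":
            out.append(wl(x))
        elif name in ("MDF", "MNP"):
            if spec is None:
                spec = power_spectrum(x, rate)
            out.append(mdf(spec) if name == "MDF" else mnp(spec))
        else:
            raise ValueError(f"unknown feature {name!r}")
    return out


@dataclass
class FeatureMatrix:
    """Windows x features with ordered names and per-window mode labels."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.feature_names)):
            raise ValueError("shape mismatch between values, names and labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    def __len__(self) -> int:
        return len(self.labels)

    def hstack(self, other: "FeatureMatrix") -> "FeatureMatrix":
        if not np.array_equal(self.labels, other.labels):
            raise ValueError("cannot fuse feature matrices with different labels")
        return FeatureMatrix(np.hstack([self.values, other.values]),
                             self.feature_names + other.feature_names,
                             self.labels)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        df.to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy()
        return FeatureMatrix(df.to_numpy(), list(df.columns), labels)


# condition code -> (modality, feature names)
MANUAL_CONDITIONS = {
    "ITD": ("imu", IMU_TIME),
    "IFD": ("imu", IMU_FREQ),
    "ITF": ("imu", IMU_TIME + IMU_FREQ),
    "ETD": ("emg", EMG_TIME),
    "EFD": ("emg", EMG_FREQ),
    "ETF": ("emg", EMG_TIME + EMG_FREQ),
}


def extract_manual(ws: WindowSet, condition: str = "ETF+ITF",
                   zc_rel: float = ZC_THRESHOLD_REL,
                   wamp_rel: float = WAMP_THRESHOLD_REL) -> FeatureMatrix:
    """Compute a manual-feature condition for every window pair.

    `condition` is a code like ``ITD``, ``ETF`` or a "+"-fusion such as
    ``ETF+ITF`` (column blocks concatenated in the order written).  Features
    are computed per channel and concatenated; column names carry the
    modality/channel prefix.  Both modalities are on the 2000 Hz clock.
    """
    if len(ws) == 0:
        raise ValueError("empty window set")
    parts = [p.strip() for p in condition.split("+")]
    blocks = []
    for part in parts:
        if part not in MANUAL_CONDITIONS:
            raise ValueError(
                f"unknown condition {part!r}; expected one of "
                f"{sorted(MANUAL_CONDITIONS)} or their '+' fusions"
            )
        modality, names = MANUAL_CONDITIONS[part]
        data = ws.emg if modality == "emg" else ws.imu
        channels = EMG_CHANNELS if modality == "emg" else IMU_CHANNELS
        cols = [f"{modality}:{ch}:{nm}" for ch in channels for nm in names]
        vals = np.empty((len(ws), len(cols)))
        for i in range(len(ws)):
            row = []
            for c in range(len(channels)):
                row.extend(_channel_features(data[i, c], names, EMG_RATE,
                                             zc_rel, wamp_rel))
            vals[i] = row
        blocks.append(FeatureMatrix(vals, cols, ws.labels))
    out = blocks[0]
    for b in blocks[1:]:
        out = out.hstack(b)
    return out
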