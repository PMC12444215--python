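"""Inertial-signal pipeline: low-pass filtering, windowing, featurization.

Strength sessions are 10 s tri-axial accelerometer recordings at 50 Hz of
repeated shoulder abduction (two repetitions per patient).  The pipeline:

1. zero-phase Butterworth low-pass (default 10 Hz cutoff, order 8),
2. 2 s sliding windows with 1 s step — window starts strictly below
   duration - window, giving 8 segments for the 10 s default,
3. per-segment time- and frequency-domain statistics per axis and for the
   Euclidean magnitude channel.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats

DEFAULT_FS = 50.0  # Hz
DEFAULT_DURATION = 10.0  # s
DEFAULT_CUTOFF = 10.0  # Hz
DEFAULT_ORDER = 8
DEFAULT_WINDOW = 2.0  # s
DEFAULT_STEP = 1.0  # s

AXES = ("ax", "ay", "az")
CHANNELS = AXES + ("mag",)

TIME_FEATURES = (
    "mean", "std", "rms", "min", "max", "range",
    "skew", "kurtosis", "zero_crossings", "sma",
)
FREQ_FEATURES = ("dom_freq", "total_power", "power_0_3", "power_3_10", "spec_entropy")


class ConfigurationError(ValueError):
    pass


@dataclass
class ImuSession:
    """One abduction recording: (n, 3) acceleration samples plus metadata."""

    samples: np.ndarray  # shape (n, 3), columns ax, ay, az
    sampling_rate: float = DEFAULT_FS
    repetition_index: int = 1
    unable_flag: bool = False  # patient could not reach 90 degrees abduction
    units: str = "m/s^2"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError(f"samples must be (n, 3), got {self.samples.shape}")
        if not np.isfinite(self.samples).all():
            raise ValueError("non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.sampling_rate


def read_imu_csv(path: str | Path) -> ImuSession:
    """Read a sensor CSV (columns t, ax, ay, az) with a JSON metadata sidecar.

    The sidecar ``<stem>.meta.json`` provides sampling_rate, repetition_index
    and unable_flag; missing sidecar falls back to defaults.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in AXES if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    meta_path = path.with_suffix("").with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ImuSession(
        df[list(AXES)].to_numpy(float),
        sampling_rate=float(meta.get("sampling_rate", DEFAULT_FS)),
        repetition_index=int(meta.get("repetition_index", 1)),
        unable_flag=bool(meta.get("unable_flag", False)),
    )


def write_imu_csv(session: ImuSession, path: str | Path) -> None:
    path = Path(path)
    n = session.samples.shape[0]
    t = np.arange(n) / session.sampling_rate
    pd.DataFrame({"t": t, **{a: session.samples[:, i] for i, a in enumerate(AXES)}}).to_csv(
        path, index=False
    )
    meta = {
        "sampling_rate": session.sampling_rate,
        "repetition_index": session.repetition_index,
        "unable_flag": session.unable_flag,
        "units": session.units,
    }
    path.with_suffix("").with_suffix(".meta.json").write_text(json.dumps(meta))


def lowpass_filter(
    session: ImuSession, cutoff: float = DEFAULT_CUTOFF, order: int = DEFAULT_ORDER
) -> ImuSession:
    """Zero-phase Butterworth low-pass, applied forward-backward per axis.

    Offline scoring permits non-causal filtering; zero phase avoids biasing
    zero-crossing counts.  Output length equals input length.
    """
    nyq = session.sampling_rate / 2.0
    if cutoff >= nyq:
        raise ConfigurationError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    if order < 1:
        raise ConfigurationError("order must be >= 1")
    sos = signal.butter(order, cutoff, btype="low", fs=session.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, session.samples, axis=0)
    return replace(session, samples=filtered)


def segment(
    session: ImuSession, window: float = DEFAULT_WINDOW, step: float = DEFAULT_STEP
) -> list[np.ndarray]:
    """Sliding windows of exactly window*fs samples.

    Window starts run t = 0, step, 2*step, ... keeping only starts strictly
    less than duration - window: a 10 s session at 2 s / 1 s yields the
    8 segments starting at 0..7 s.
    """
    if step <= 0:
        raise ConfigurationError("step must be positive")
    dur = session.duration
    if window > dur:
        warnings.warn(f"window {window} s exceeds session duration {dur} s; no segments")
        return []
    fs = session.sampling_rate
    wlen = int(round(window * fs))
    out = []
    k = 0
    while k * step < dur - window:
        i0 = int(round(k * step * fs))
        out.append(session.samples[i0 : i0 + wlen])
        k += 1
    if not out:
        warnings.warn("no window start satisfies start < duration - window")
    return out


def _channels(seg: np.ndarray) -> dict[str, np.ndarray]:
    ch = {a: seg[:, i] for i, a in enumerate(AXES)}
    ch["mag"] = np.linalg.norm(seg, axis=1)
    return ch


def time_domain_features(seg: np.ndarray) -> dict[str, float]:
    """Time-domain statistics per axis and for the magnitude channel.

    Constant segments get skewness and kurtosis 0 by convention.
    """
    if seg.size == 0:
        raise ValueError("empty segment")
    out: dict[str, float] = {}
    for name, x in _channels(seg).items():
        sd = float(np.std(x, ddof=0))
        centered = x - x.mean()
        if sd == 0.0:
            skew = kurt = 0.0
        else:
            skew = float(stats.skew(x))
            kurt = float(stats.kurtosis(x))
        zc = int(np.sum(np.diff(np.signbit(centered)) != 0))
        vals = {
            "mean": float(x.mean()),
            "std": sd,
            "rms": float(np.sqrt(np.mean(x**2))),
            "min": float(x.min()),
            "max": float(x.max()),
            "range": float(x.max() - x.min()),
            "skew": skew,
            "kurtosis": kurt,
            "zero_crossings": float(zc),
            "sma": float(np.mean(np.abs(x))),
        }
        out.update({f"{name}_{k}": v for k, v in vals.items()})
    return out


def freq_domain_features(seg: np.ndarray, sampling_rate: float = DEFAULT_FS) -> dict[str, float]:
    """Frequency-domain statistics per axis and for the magnitude channel.

    Power is normalized so the total equals the time-domain mean square
    (Parseval).  Dominant frequency excludes the DC bin; all-zero segments
    get dominant frequency 0 and entropy 0 by convention.
    """
    if seg.shape[0] < 8:
        raise ValueError("segment too short for spectral features")
    n = seg.shape[0]
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    out: dict[str, float] = {}
    for name, x in _channels(seg).items():
        spec = np.fft.rfft(x)
        # one-sided power normalized to mean-square (Parseval)
        power = np.abs(spec) ** 2 / n**2
        if n % 2 == 0:
            power[1:-1] *= 2.0
        else:
            power[1:] *= 2.0
        total = float(power.sum())
        if total == 0.0:
            dom = 0.0
            entropy = 0.0
        else:
            dom = float(freqs[1 + int(np.argmax(power[1:]))])
            p = power / total
            nz = p[p > 0]
            entropy = float(-(nz * np.log2(nz)).sum())
        vals = {
            "dom_freq": dom,
            "total_power": total,
            "power_0_3": float(power[(freqs >= 0) & (freqs <= 3)].sum()),
            "power_3_10": float(power[(freqs > 3) & (freqs <= 10)].sum()),
            "spec_entropy": entropy,
        }
        out.update({f"{name}_{k}": v for k, v in vals.items()})
    return out


def segment_features(seg: np.ndarray, sampling_rate: float = DEFAULT_FS) -> dict[str, float]:
    """All configured features for one segment (40 time + 20 frequency)."""
    out = time_domain_features(seg)
    out.update(freq_domain_features(seg, sampling_rate))
    return out


def session_feature_frame(
    session: ImuSession,
    cutoff: float = DEFAULT_CUTOFF,
    order: int = DEFAULT_ORDER,
    window: float = DEFAULT_WINDOW,
    step: float = DEFAULT_STEP,
) -> pd.DataFrame:
    """Filter, segment and featurize one session; one row per segment."""
    filtered = lowpass_filter(session, cutoff, order)
    rows = [segment_features(seg, session.sampling_rate) for seg in segment(filtered, window, step)]
    df = pd.DataFrame(rows)
    df.index.name = "segment_index"
    return df
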