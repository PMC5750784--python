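"""Preprocessing of raw triaxial IMU streams.

Raw accelerometer/gyroscope recordings are converted into orientation-invariant
resultant (vector-magnitude) signals, rest-bias calibrated, and band-limited to
the frequency range of normal walking (0.5--3.5 Hz).

The resultant ``Mag(t) = sqrt(Rx^2 + Ry^2 + Rz^2)`` is invariant under any
session-constant rotation of the sensor, which is what makes casually-worn
devices usable: the mounting orientation cancels out of the magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy import signal as sps

#: Body placement of the five sensor nodes, by sensor id.
SENSOR_LOCATIONS = {1: "ankle", 2: "wrist", 3: "knee", 4: "chest", 5: "lower-back"}

#: The two inertial modalities of each node.
MODALITIES = ("acc", "gyro")


@dataclass
class ImuRecording:
    """One sensor node/modality's triaxial time series.

    Units are g for accelerometers and deg/s for gyroscopes. ``rest_span`` is a
    half-open ``(start, stop)`` index range covering the initial standing-still
    interval used for bias calibration.
    """

    subject_id: int
    sensor_id: int
    modality: str
    fs: float
    rx: np.ndarray
    ry: np.ndarray
    rz: np.ndarray
    rest_span: Tuple[int, int] = (0, 0)
    session_id: int = 0

    def __post_init__(self):
        self.rx = np.asarray(self.rx, dtype=float)
        self.ry = np.asarray(self.ry, dtype=float)
        self.rz = np.asarray(self.rz, dtype=float)
        if not (len(self.rx) == len(self.ry) == len(self.rz)):
            raise ValueError("triaxial streams must have equal lengths")
        if len(self.rx) == 0:
            raise ValueError("empty recording")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    def __len__(self) -> int:
        return len(self.rx)

    @property
    def xyz(self) -> np.ndarray:
        """Samples as a (n, 3) array."""
        return np.stack([self.rx, self.ry, self.rz], axis=1)


@dataclass
class ResultantSignal:
    """Orientation-invariant magnitude signal of one recording."""

    mag: np.ndarray
    fs: float
    provenance: Tuple = ()
    filtered: bool = False
    band: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        self.mag = np.asarray(self.mag, dtype=float)

    def __len__(self) -> int:
        return len(self.mag)


@dataclass
class GyroInitState:
    """Initial gyroscope direction estimate, copied from the accelerometer.

    The gyroscope measures angular rate, not direction, so its initial
    orientation is seeded from the co-located accelerometer's first sample.
    The estimate is retained as metadata only; no orientation tracking is
    performed downstream (the magnitude path does not need it).
    """

    rx0: float
    ry0: float
    rz0: float


def resultant(rx, ry, rz, fs: float = 1.0, provenance: Tuple = ()) -> ResultantSignal:
    """Per-sample Euclidean norm of a triaxial stream."""
    rx, ry, rz = (np.asarray(a, dtype=float) for a in (rx, ry, rz))
    if not (rx.shape == ry.shape == rz.shape):
        raise ValueError("axis streams must share a shape")
    mag = np.sqrt(rx ** 2 + ry ** 2 + rz ** 2)
    return ResultantSignal(mag=mag, fs=fs, provenance=provenance)


def resultant_of(rec: ImuRecording) -> ResultantSignal:
    """Resultant of a recording, carrying its provenance."""
    return resultant(
        rec.rx, rec.ry, rec.rz, fs=rec.fs,
        provenance=(rec.subject_id, rec.sensor_id, rec.modality),
    )


def calibrate_rest_bias(rec: ImuRecording) -> ImuRecording:
    """Subtract the per-axis mean over the rest interval from the whole stream.

    After calibration the rest-interval samples are (approximately) zero, so
    constant offsets -- gravity projected onto the device axes, gyro bias --
    no longer leak into the walking-signal resultant.
    """
    lo, hi = rec.rest_span
    if hi <= lo:
        raise ValueError("cannot calibrate: empty rest span")
    out = replace(rec)
    for name in ("rx", "ry", "rz"):
        axis = getattr(rec, name)
        setattr(out, name, axis - axis[lo:hi].mean())
    return out


def init_gyro_orientation(acc_rec: ImuRecording, gyro_rec: ImuRecording) -> GyroInitState:
    """Initialize the gyro direction estimate from the accelerometer.

    Both recordings must be synchronized streams from the same node.
    """
    if len(acc_rec) == 0 or len(gyro_rec) == 0:
        raise ValueError("empty recording")
    if len(acc_rec) != len(gyro_rec):
        raise ValueError("accelerometer and gyroscope streams are not synchronized")
    return GyroInitState(rx0=float(acc_rec.rx[0]), ry0=float(acc_rec.ry[0]),
                         rz0=float(acc_rec.rz[0]))


def butter_bandpass_sos(low: float, high: float, fs: float, order: int = 10) -> np.ndarray:
    """Butterworth band-pass of the given overall order, as second-order sections.

    ``order`` is the order of the full band-pass filter and must be even; the
    underlying low-pass prototype has order ``order // 2``.  Second-order
    sections keep the order-10 design numerically stable at fs = 50 Hz.
    """
    if order < 2 or order % 2:
        raise ValueError("band-pass order must be a positive even integer")
    if not (0.0 < low < high < fs / 2.0):
        raise ValueError(f"invalid band ({low}, {high}) for fs={fs}")
    return sps.butter(order // 2, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(sig: ResultantSignal, low: float = 0.5, high: float = 3.5,
             order: int = 10) -> ResultantSignal:
    """Zero-phase Butterworth band-pass of a resultant signal.

    The filter runs forward and backward (``sosfiltfilt``) so gait-cycle
    markers found on the filtered signal are not phase-shifted relative to the
    raw stream; the signal is reflection-padded internally to keep transients
    out of short recordings.
    """
    sos = butter_bandpass_sos(low, high, sig.fs, order)
    padlen = min(len(sig) - 1, 3 * (2 * sos.shape[0] + 1) * 3)
    filtered = sps.sosfiltfilt(sos, sig.mag, padlen=padlen)
    return ResultantSignal(mag=filtered, fs=sig.fs, provenance=sig.provenance,
                           filtered=True, band=(low, high))
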