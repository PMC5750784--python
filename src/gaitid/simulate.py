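"""Synthetic multi-subject, multi-sensor IMU gait sessions with known ground truth.

Each subject is a periodic "gait signature": a cycle frequency near 1 Hz and,
for every (sensor location, modality, axis), amplitudes and phases of the
first few harmonics of that frequency.  A session renders the signature into
triaxial accelerometer and gyroscope streams with

* a leading rest interval (constant bias plus noise only; the accelerometer
  sees 1 g on its vertical axis),
* a session-constant 3D nuisance rotation of every triaxial output, emulating
  casual sensor mounting,
* additive white Gaussian noise.

The generator is deliberately simple -- a harmonic model, not biomechanics --
but it reproduces the structural properties the downstream pipeline depends
on: subject-separable periodic magnitudes, rest intervals for calibration,
orientation nuisance that the resultant cancels, and a dominant in-band
spectral line at the cycle frequency (the harmonics of a resultant's squared
cross-terms fall at k*fcycle, and only k = 1 lies inside the 0.5--1.5 Hz
search band for fcycle >= 0.8 Hz).

All randomness flows from one integer seed through named generators, so a
(profile, spec) pair always produces bit-identical streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .preprocess import MODALITIES, SENSOR_LOCATIONS, ImuRecording

#: Harmonics of the cycle frequency in each signature.
N_HARMONICS = 4

#: Overall signature scale per modality (g for acc, deg/s for gyro).
MODALITY_SCALE = {"acc": 0.45, "gyro": 45.0}

#: Default additive noise scale per modality (same units as above).
DEFAULT_NOISE_SD = {"acc": 0.03, "gyro": 3.0}

#: Rest bias per modality, in the sensor frame before the nuisance rotation:
#: 1 g of gravity on the accelerometer's vertical (z) axis, nothing on gyros.
REST_BIAS = {"acc": np.array([0.0, 0.0, 1.0]), "gyro": np.zeros(3)}


@dataclass
class HarmonicSignature:
    """Per-axis amplitudes/phases of harmonics 1..H for one (sensor, modality)."""

    amps: np.ndarray    # shape (3, H), all >= 0
    phases: np.ndarray  # shape (3, H), radians

    def __post_init__(self):
        self.amps = np.asarray(self.amps, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        if self.amps.shape != self.phases.shape or self.amps.ndim != 2:
            raise ValueError("amps and phases must both be (3, H)")
        if np.any(self.amps < 0):
            raise ValueError("harmonic amplitudes must be non-negative")

    def render(self, t: np.ndarray, fcycle: float) -> np.ndarray:
        """Evaluate the signature at times ``t`` (seconds); returns (len(t), 3)."""
        h = np.arange(1, self.amps.shape[1] + 1)
        # (n, 1, H) phase argument against (3, H) amps -> sum over harmonics
        arg = 2.0 * np.pi * fcycle * np.outer(t, h)[:, None, :] + self.phases[None, :, :]
        return np.sum(self.amps[None, :, :] * np.cos(arg), axis=2)


@dataclass
class SubjectProfile:
    """Ground-truth gait signature of one synthetic subject."""

    subject_id: int
    fcycle: float
    signatures: Dict[Tuple[int, str], HarmonicSignature]
    noise_sd: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))

    def __post_init__(self):
        if not (0.5 <= self.fcycle <= 1.5):
            raise ValueError("fcycle must lie within the 0.5-1.5 Hz search band")


@dataclass
class SessionSpec:
    """Recording-session parameters: duration, rate, rest lead-in, nuisance rotation."""

    duration: float
    fs: float = 50.0
    rest_seconds: float = 5.0
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    seed: int = 0

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        if self.rest_seconds < 0:
            raise ValueError("rest_seconds must be >= 0")
        if self.fs <= 2 * N_HARMONICS * 1.5:
            raise ValueError("sampling rate must exceed twice the highest harmonic")
        R = self.rotation
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8) \
                or not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be orthonormal with determinant +1")


def make_population(M: int, seed: int, n_harmonics: int = N_HARMONICS) -> List[SubjectProfile]:
    """Draw ``M`` reproducible, pairwise-distinct subject profiles.

    Cycle frequencies are uniform on [0.8, 1.2] Hz around the 1 Hz average of
    normal walking.  Harmonic amplitudes decay as 1/h^1.5 so the fundamental
    dominates, with a per-(subject, sensor) gain making sensor locations
    unequally informative, as they are on the body.
    """
    if M < 2:
        raise ValueError("a population needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    profiles = []
    for sid in range(1, M + 1):
        fcycle = float(rng.uniform(0.8, 1.2))
        signatures: Dict[Tuple[int, str], HarmonicSignature] = {}
        for sensor_id in SENSOR_LOCATIONS:
            gain = rng.uniform(0.4, 1.6)  # location-dependent signal strength
            for modality in MODALITIES:
                h = np.arange(1, n_harmonics + 1)
                amps = (MODALITY_SCALE[modality] * gain
                        * rng.uniform(0.3, 1.0, size=(3, n_harmonics)) / h ** 1.5)
                phases = rng.uniform(0.0, 2.0 * np.pi, size=(3, n_harmonics))
                signatures[(sensor_id, modality)] = HarmonicSignature(amps, phases)
        profiles.append(SubjectProfile(subject_id=sid, fcycle=fcycle,
                                       signatures=signatures))
    return profiles


def simulate_session(profile: SubjectProfile,
                     spec: SessionSpec) -> Dict[Tuple[int, str], ImuRecording]:
    """Render one session: 5 sensors x 2 modalities of triaxial streams.

    The walking portion starts after ``rest_seconds`` and carries the harmonic
    signature (phase zero at walk onset) on top of the rest bias; the whole
    triaxial stream is rotated by the session's nuisance rotation and noise is
    added afterwards (white sensor noise is isotropic, so its placement
    relative to the rotation is immaterial).
    """
    n = int(round(spec.duration * spec.fs))
    n_rest = int(round(spec.rest_seconds * spec.fs))
    if n - n_rest < spec.fs / profile.fcycle:
        raise ValueError("session too short to contain a single gait cycle")
    t = np.arange(n) / spec.fs
    walk_mask = (t >= spec.rest_seconds).astype(float)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, profile.subject_id)))
    out: Dict[Tuple[int, str], ImuRecording] = {}
    for sensor_id in SENSOR_LOCATIONS:
        for modality in MODALITIES:
            sig = profile.signatures[(sensor_id, modality)]
            xyz = sig.render(t - spec.rest_seconds, profile.fcycle)
            xyz *= walk_mask[:, None]
            xyz += REST_BIAS[modality][None, :]
            xyz = xyz @ spec.rotation.T
            xyz += rng.normal(0.0, profile.noise_sd[modality], size=xyz.shape)
            out[(sensor_id, modality)] = ImuRecording(
                subject_id=profile.subject_id, sensor_id=sensor_id,
                modality=modality, fs=spec.fs,
                rx=xyz[:, 0], ry=xyz[:, 1], rz=xyz[:, 2],
                rest_span=(0, n_rest),
            )
    return out


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
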