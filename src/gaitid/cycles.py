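"""Gait-cycle extraction from the reference sensor and marker mapping.

Cycles are delimited on the band-passed resultant of the reference sensor
(the ankle accelerometer, sensor 1): the dominant spectral component in the
0.5--1.5 Hz band sets the nominal cycle length ``offset = round(fs / fcycle)``,
active (super-threshold) stretches of the signal form local windows, and each
window is walked one nominal cycle at a time, snapping every tentative cycle
end to the nearest rising zero crossing.  Because data collection is
time-synchronized across nodes, the same markers slice all ten streams.

Indices are 0-based and half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .preprocess import ResultantSignal, bandpass

logger = logging.getLogger(__name__)

#: Search band for the cycle frequency (Hz); normal walking averages ~1 Hz.
CYCLE_BAND = (0.5, 1.5)

#: Snap radius and cycle-length rejection bound, as a fraction of the nominal
#: cycle length.
SNAP_FRACTION = 0.25


@dataclass
class SpectrumEstimate:
    """DFT magnitudes of the narrow-band resultant and its dominant frequency."""

    freqs: np.ndarray
    magnitudes: np.ndarray
    fcycle: float


@dataclass
class LocalWindow:
    """A maximal run of super-threshold activity (global sample indices)."""

    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("window must be non-empty")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class CycleIndex:
    """One gait cycle's global marker pair plus bookkeeping."""

    start: int
    end: int
    offset: int                 # nominal cycle length in samples
    zero_cross_adjust: int = 0  # signed snap correction applied to the end

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("cycle must be non-empty")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GaitCycle:
    """One isolated cycle: identically-indexed excerpts of all ten resultants."""

    cycle_id: int
    subject_id: int
    index: CycleIndex
    excerpts: Dict[Tuple[int, str], np.ndarray]
    ref_sensor: int = 1
    ref_modality: str = "acc"


def estimate_cycle_frequency(sig: ResultantSignal,
                             band: Tuple[float, float] = CYCLE_BAND,
                             order: int = 10) -> SpectrumEstimate:
    """Dominant frequency of the resultant within the walking band.

    The signal is passed through an aggressive band-pass restricted to
    ``band`` (used only here, to kill interference from harmonics while
    determining the cycle frequency), Fourier-transformed, and the magnitude
    argmax within the band is returned as ``fcycle``.

    Requires at least 10 s of signal so the DFT bin width is <= 0.1 Hz.
    """
    if len(sig) < 10 * sig.fs:
        raise ValueError("need >= 10 s of signal to resolve the cycle frequency")
    narrow = bandpass(sig, band[0], band[1], order=order)
    mags = np.abs(np.fft.rfft(narrow.mag))
    freqs = np.fft.rfftfreq(len(narrow), d=1.0 / sig.fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(mags[in_band] > 0):
        raise ValueError("no dominant frequency: signal has no in-band energy")
    band_freqs = freqs[in_band]
    fcycle = float(band_freqs[np.argmax(mags[in_band])])
    return SpectrumEstimate(freqs=freqs, magnitudes=mags, fcycle=fcycle)


def find_local_windows(sig: ResultantSignal, amp_thresh: float = 0.05,
                       max_gap_s: float = 1.0) -> List[LocalWindow]:
    """Runs of super-threshold activity in the band-passed resultant.

    Samples whose absolute value falls below ``amp_thresh`` are neglected;
    the remaining samples are collected into maximal windows.  Sub-threshold
    gaps shorter than ``max_gap_s`` (about one nominal cycle) are bridged, so
    the brief near-zero passes within a cycle do not fragment a walking bout.
    """
    active = np.abs(sig.mag) >= amp_thresh
    if not active.any():
        return []
    idx = np.flatnonzero(active)
    max_gap = int(round(max_gap_s * sig.fs))
    windows: List[LocalWindow] = []
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i - prev > max_gap:
            windows.append(LocalWindow(run_start, prev + 1))
            run_start = i
        prev = i
    windows.append(LocalWindow(run_start, prev + 1))
    return windows


def rising_zero_crossings(x: np.ndarray) -> np.ndarray:
    """Indices k where x[k-1] < 0 <= x[k] (first non-negative sample)."""
    x = np.asarray(x)
    return np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0)) + 1


def extract_cycles(sig: ResultantSignal, windows: List[LocalWindow],
                   fcycle: float) -> List[CycleIndex]:
    """Walk each local window one nominal cycle at a time.

    The nominal cycle length is ``offset = round(fs / fcycle)`` samples.
    Starting from the first rising zero crossing in a window, each tentative
    end ``start + offset`` is snapped to the nearest rising crossing within
    +/- 25% of the nominal length; the next cycle starts where the previous
    one ended, so cycles in a window are contiguous.  If no crossing lies in
    the snap radius the walk stops (this also discards trailing partial
    cycles).  Windows shorter than one nominal cycle are skipped.
    """
    if not (CYCLE_BAND[0] <= fcycle <= CYCLE_BAND[1]):
        raise ValueError(f"fcycle {fcycle} outside the {CYCLE_BAND} search band")
    if sig.fs <= 0:
        raise ValueError("sampling rate must be positive")
    offset = int(round(sig.fs / fcycle))
    radius = SNAP_FRACTION * offset
    cycles: List[CycleIndex] = []
    for win in windows:
        if len(win) < offset:
            logger.info("skipping window [%d, %d): shorter than one cycle (%d)",
                        win.start, win.end, offset)
            continue
        crossings = rising_zero_crossings(sig.mag[win.start:win.end]) + win.start
        if crossings.size == 0:
            logger.info("skipping window [%d, %d): no rising zero crossings",
                        win.start, win.end)
            continue
        start = int(crossings[0])
        while True:
            target = start + offset
            near = crossings[np.abs(crossings - target) <= radius]
            near = near[near > start]
            if near.size == 0:
                # irregular stretch: drop this cycle and restart the chain at
                # the next crossing past the target
                beyond = crossings[crossings > target]
                if beyond.size == 0:
                    break
                start = int(beyond[0])
                continue
            end = int(near[np.argmin(np.abs(near - target))])
            cycles.append(CycleIndex(start=start, end=end, offset=offset,
                                     zero_cross_adjust=end - target))
            start = end
    return cycles


def map_cycles_to_sensors(cycles: List[CycleIndex],
                          resultants: Dict[Tuple[int, str], ResultantSignal],
                          subject_id: int = 0,
                          ref_sensor: int = 1,
                          ref_modality: str = "acc") -> List[GaitCycle]:
    """Slice every sensor/modality resultant at the reference markers.

    All streams are assumed time-synchronized; a stream too short for a
    marker raises an error naming the offending source.
    """
    out: List[GaitCycle] = []
    for k, cyc in enumerate(cycles):
        excerpts: Dict[Tuple[int, str], np.ndarray] = {}
        for key, sig in resultants.items():
            if cyc.end > len(sig):
                raise ValueError(
                    f"marker [{cyc.start}, {cyc.end}) out of range for sensor "
                    f"{key[0]} {key[1]} (length {len(sig)})")
            excerpts[key] = sig.mag[cyc.start:cyc.end].copy()
        out.append(GaitCycle(cycle_id=k, subject_id=subject_id, index=cyc,
                             excerpts=excerpts, ref_sensor=ref_sensor,
                             ref_modality=ref_modality))
    return out
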