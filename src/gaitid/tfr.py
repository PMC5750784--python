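"""Smoothed pseudo Wigner-Ville expansion of gait cycles and image rendering.

A gait-cycle excerpt is resampled to a fixed length, expanded to a quadratic
time-frequency distribution, and rendered as a fixed-size RGB image -- the
input of the convolutional identifier.

The smoothed pseudo Wigner-Ville distribution (SPWVD) of the analytic signal
x_a is computed discretely as

    SPWV(t, w) = F_tau { Ww(tau) * sum_u Wt(u) x_a(t-u+tau) x_a*(t-u-tau) }

with independent, symmetric smoothing windows in time (Wt, normalized to unit
sum) and lag/frequency (Ww, unit at tau = 0).  Time smoothing attenuates the
oscillatory cross-terms the plain Wigner-Ville distribution produces between
signal components, while keeping good time-frequency concentration.  With the
half-sample lag discretization used here, frequency bin k maps to
k * fs / (2 * grid), covering 0..fs/2 for the analytic signal.

Values are scaled so that the double integral of the distribution over time
and frequency approximates the time-domain energy of the (real) excerpt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Tuple

import numpy as np
from PIL import Image
from scipy.signal import hilbert

logger = logging.getLogger(__name__)


def _odd(n: int) -> int:
    n = max(int(n), 3)
    return n if n % 2 else n + 1


@dataclass
class TFConfig:
    """Parameters of the time-frequency expansion and image rendering.

    ``time_win_len``/``freq_win_len`` are odd Hamming-taper lengths for the
    time- and lag-smoothing windows; if left ``None`` they default to about
    ``resample_len / 8`` and ``resample_len / 4``.  ``clip_negative`` selects
    clipping at zero instead of the default absolute value when rendering the
    (not everywhere positive) distribution.
    """

    resample_len: int = 128
    grid: int = 128
    time_win_len: Optional[int] = None
    freq_win_len: Optional[int] = None
    taper: str = "hamming"
    image_size: int = 120
    clip_negative: bool = False

    def __post_init__(self):
        if self.resample_len < 32:
            raise ValueError("resample_len must be >= 32")
        if self.time_win_len is None:
            self.time_win_len = _odd(self.resample_len // 8)
        if self.freq_win_len is None:
            self.freq_win_len = _odd(self.resample_len // 4)
        for L in (self.time_win_len, self.freq_win_len):
            if L < 1 or L % 2 == 0:
                # length 1 = no smoothing in that direction, useful together
                # with taper="boxcar" for comparisons against the unsmoothed
                # WVD; defaults are always >= 3
                raise ValueError("smoothing window lengths must be odd and >= 1")
        if self.taper not in ("hamming", "boxcar"):
            raise ValueError("taper must be 'hamming' or 'boxcar'")


@dataclass
class TFMatrix:
    """Real-valued time x frequency distribution with its axes."""

    values: np.ndarray  # (n_time, n_freq)
    t_axis: np.ndarray  # seconds
    f_axis: np.ndarray  # Hz

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time-frequency matrix contains non-finite entries")

    @property
    def dt(self) -> float:
        return float(self.t_axis[1] - self.t_axis[0]) if len(self.t_axis) > 1 else 1.0

    @property
    def df(self) -> float:
        return float(self.f_axis[1] - self.f_axis[0]) if len(self.f_axis) > 1 else 1.0


@dataclass
class SegmentFeatures:
    """Scalar descriptors of one expanded segment.

    ``track_length`` counts time bins whose frequency-ridge magnitude exceeds
    a fixed fraction of the global maximum; it is one concrete reading of a
    "principal track length" and is recorded for inspection only -- the image
    classifier does not consume it.
    """

    energy: float
    marginal_peak_hz: float
    track_length: int


@dataclass
class TFImage:
    """Fixed-size H x W x C intensity tensor in [0, 1], the CNN input."""

    pixels: np.ndarray
    label: Optional[int] = None
    provenance: Tuple = ()

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3:
            raise ValueError("image must be H x W x C")


def resample_cycle(excerpt: np.ndarray, resample_len: int) -> np.ndarray:
    """Linear-interpolation resampling to a fixed length, endpoints preserved."""
    x = np.asarray(excerpt, dtype=float)
    if x.size < 4:
        raise ValueError("excerpt too short to resample")
    pos = np.linspace(0.0, x.size - 1, resample_len)
    return np.interp(pos, np.arange(x.size), x)


def swvd(x: np.ndarray, fs: float, cfg: Optional[TFConfig] = None,
         *, return_complex: bool = False):
    """Discrete smoothed pseudo Wigner-Ville distribution of a real signal.

    With ``return_complex=True`` the raw complex (freq, time) transform is
    returned instead of a :class:`TFMatrix`; its imaginary part is a
    numerical residue (the lag autocorrelation is Hermitian by construction).
    """
    cfg = cfg or TFConfig()
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < max(cfg.time_win_len, cfg.freq_win_len):
        raise ValueError("signal shorter than the smoothing windows")
    K = cfg.grid
    if np.allclose(x, 0.0):
        xa = np.zeros(n, dtype=complex)
    else:
        xa = hilbert(x)

    win = np.hamming if cfg.taper == "hamming" else np.ones
    g = win(cfg.time_win_len)
    g = g / g.sum()
    h = win(cfg.freq_win_len)
    h = h / h[(cfg.freq_win_len - 1) // 2]  # unit at tau = 0
    lh = (cfg.freq_win_len - 1) // 2
    taumax = min(lh, K // 2 - 1)

    # r[tau, t] = Ww(tau) * (Wt-smoothed instantaneous autocorrelation)
    r = np.zeros((K, n), dtype=complex)
    pad = np.concatenate([np.zeros(taumax, dtype=complex), xa,
                          np.zeros(taumax, dtype=complex)])
    for tau in range(taumax + 1):
        prod = pad[taumax + tau: taumax + tau + n] * np.conj(
            pad[taumax - tau: taumax - tau + n])
        smoothed = np.convolve(prod, g, mode="same")
        r[tau] = h[lh + tau] * smoothed
        if tau:
            r[K - tau] = np.conj(r[tau])

    tfr = np.fft.fft(r, axis=0)
    if return_complex:
        return tfr / fs
    if np.max(np.abs(tfr.imag)) > 1e-6 * max(np.max(np.abs(tfr.real)), 1e-30):
        logger.warning("SPWVD imaginary residue unexpectedly large")
    values = tfr.real.T / fs  # (time, freq); 1/fs makes the double integral an energy
    t_axis = np.arange(n) / fs
    f_axis = np.arange(K) * fs / (2.0 * K)
    return TFMatrix(values=values, t_axis=t_axis, f_axis=f_axis)


def segment_energy(tf: TFMatrix) -> float:
    """Double integral of the distribution over time and frequency."""
    if tf.values.size == 0:
        raise ValueError("empty time-frequency matrix")
    return float(tf.values.sum() * tf.dt * tf.df)


def marginal_frequency(tf: TFMatrix) -> Tuple[np.ndarray, float]:
    """Time-marginal of the distribution and the frequency of its maximum."""
    if tf.values.size == 0:
        raise ValueError("empty time-frequency matrix")
    marg = tf.values.sum(axis=0) * tf.dt
    if np.allclose(tf.values, 0.0):
        raise ValueError("marginal argmax undefined for an all-zero distribution")
    return marg, float(tf.f_axis[int(np.argmax(marg))])


def principal_track_length(tf: TFMatrix, rel_thresh: float = 0.1) -> int:
    """Count of time bins whose frequency-ridge point exceeds the threshold."""
    mags = np.abs(tf.values)
    peak = mags.max()
    if peak == 0:
        return 0
    ridge = mags.max(axis=1)
    return int(np.sum(ridge > rel_thresh * peak))


def segment_features(tf: TFMatrix) -> SegmentFeatures:
    _, fpeak = marginal_frequency(tf)
    return SegmentFeatures(energy=abs(segment_energy(tf)),
                           marginal_peak_hz=fpeak,
                           track_length=principal_track_length(tf))


def load_colormap(path: Optional[str] = None) -> np.ndarray:
    """256 x 3 RGB lookup table in [0, 1] (the packaged jet-like table by default)."""
    if path is None:
        ref = resources.files("gaitid").joinpath("assets/jet256.csv")
        with ref.open("rb") as fh:
            lut = np.loadtxt(fh, delimiter=",", skiprows=1)
    else:
        lut = np.loadtxt(path, delimiter=",", skiprows=1)
    if lut.shape != (256, 3):
        raise ValueError("colormap must be a 256 x 3 table")
    return lut


def render_tf_image(tf: TFMatrix, label: Optional[int] = None,
                    colormap: Optional[np.ndarray] = None,
                    size: int = 120, clip_negative: bool = False,
                    provenance: Tuple = ()) -> TFImage:
    """Render a distribution as a fixed-size RGB image.

    The matrix is rectified (absolute value, or clipped at zero), min-max
    normalized per image to [0, 1], bilinearly resized to ``size x size``
    (frequency increasing upward), and mapped through a 256-entry colormap.
    A degenerate constant matrix renders as the colormap's zero entry.
    """
    lut = load_colormap() if colormap is None else np.asarray(colormap)
    A = np.clip(tf.values, 0.0, None) if clip_negative else np.abs(tf.values)
    lo, hi = A.min(), A.max()
    if hi - lo <= 0:
        logger.warning("degenerate constant TF matrix: rendering as all-zero image")
        norm = np.zeros_like(A)
    else:
        norm = (A - lo) / (hi - lo)
    # rows = frequency (low at the bottom), columns = time
    raster = np.flipud(norm.T)
    if raster.shape != (size, size):
        im = Image.fromarray(raster.astype(np.float32), mode="F")
        raster = np.asarray(im.resize((size, size), Image.BILINEAR), dtype=float)
        raster = np.clip(raster, 0.0, 1.0)
    idx = np.round(raster * 255).astype(int)
    pixels = lut[idx]
    return TFImage(pixels=pixels, label=label, provenance=provenance)


def save_image(img: TFImage, path: str) -> None:
    """Write an image as lossless 8-bit RGB PNG."""
    arr = np.round(np.clip(img.pixels, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path, format="PNG")


def cycle_image(excerpt: np.ndarray, fs: float, cfg: Optional[TFConfig] = None,
                label: Optional[int] = None, colormap: Optional[np.ndarray] = None,
                provenance: Tuple = ()) -> TFImage:
    """Excerpt -> resample -> SPWVD -> rendered image, in one call."""
    cfg = cfg or TFConfig()
    resampled = resample_cycle(excerpt, cfg.resample_len)
    # the excerpt keeps its real duration: resampling rescales the rate
    fs_eff = fs * cfg.resample_len / len(excerpt)
    tf = swvd(resampled, fs_eff, cfg)
    return render_tf_image(tf, label=label, colormap=colormap,
                           size=cfg.image_size, clip_negative=cfg.clip_negative,
                           provenance=provenance)
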