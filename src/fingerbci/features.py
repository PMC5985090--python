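"""Band-power features from Hamming-windowed periodograms.

Each filtered 250 ms chunk (32 samples at 128 Hz) is summarized per
channel by a single band-power scalar:

1. split the chunk into 4 contiguous 62.5 ms windows of 8 samples;
2. taper each window with the 8-point symmetric Hamming weights
   w(n) = 0.54 - 0.46*cos(2*pi*n/(N-1));
3. take the N-point DFT and form the two-sided periodogram
   pxx(k) = |X(k)|^2 / (Fs*L*U), where U = (1/L)*sum w(n)^2 corrects for
   the taper and L is the segment length;
4. average the 4 periodograms bin-wise, scale by 1/(2*pi), and average
   the 8 bins.

With 8-point segments at 128 Hz the bin spacing is 16 Hz, so no within-
band bin selection is possible; band limiting comes entirely from the
preceding 8-30 Hz filter. The 1/(2*pi) factor is a pure rescaling kept
for fidelity with the original embedded implementation; it cancels in
classification. Repeating the procedure over the 14 channels yields the
feature vector the classifier consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filtering import bandpass_8_30
from .io_streaming import CHANNELS, CHUNK_SAMPLES, N_CHANNELS, Chunk


def hamming_window(n_points: int) -> np.ndarray:
    """Symmetric Hamming weights w(n) = 0.54 - 0.46*cos(2*pi*n/(N-1))."""
    if n_points < 2:
        raise ValueError("a Hamming window needs at least 2 points")
    n = np.arange(n_points)
    return 0.54 - 0.46 * np.cos(2.0 * np.pi * n / (n_points - 1))


def window_normalization(w: np.ndarray, L: int | None = None) -> float:
    """Taper power correction U = (1/L) * sum w(n)^2."""
    w = np.asarray(w, dtype=float)
    if w.size == 0:
        raise ValueError("empty window")
    if L is None:
        L = w.size
    if L != w.size:
        raise ValueError(f"L ({L}) must equal the window length ({w.size})")
    return float(np.sum(w ** 2) / L)


@dataclass(frozen=True)
class PSDConfig:
    """Periodogram layout: ``n_windows`` segments of ``window_len`` samples.

    Defaults give 4 windows of 62.5 ms (8 samples) covering one 250 ms
    chunk exactly, with no overlap possible. ``U`` is the Hamming taper
    normalization constant for ``window_len`` points.
    """

    n_windows: int = 4
    window_len: int = 8
    fs: float = 128.0

    def __post_init__(self):
        if self.n_windows < 1 or self.window_len < 2:
            raise ValueError("need n_windows >= 1 and window_len >= 2")

    @property
    def chunk_len(self) -> int:
        return self.n_windows * self.window_len

    @property
    def window(self) -> np.ndarray:
        return hamming_window(self.window_len)

    @property
    def U(self) -> float:
        return window_normalization(self.window)


DEFAULT_PSD = PSDConfig()


def periodogram(segment: np.ndarray, cfg: PSDConfig = DEFAULT_PSD) -> np.ndarray:
    """Two-sided Hamming-tapered periodogram of one segment.

    Returns all ``window_len`` bins of |DFT(w * x)|^2 / (Fs * L * U);
    units are power per unit frequency, up to the decoder's conventions.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.shape != (cfg.window_len,):
        raise ValueError(f"segment must have {cfg.window_len} samples; got {segment.shape}")
    spectrum = np.fft.fft(cfg.window * segment)
    return np.abs(spectrum) ** 2 / (cfg.fs * cfg.window_len * cfg.U)


def channel_band_power(x: np.ndarray, cfg: PSDConfig = DEFAULT_PSD) -> float:
    """Band power of one already-filtered channel of a chunk.

    Averages the periodograms of the ``n_windows`` contiguous segments
    bin-wise, scales by 1/(2*pi), and returns the mean over bins — a
    single non-negative scalar.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (cfg.chunk_len,):
        raise ValueError(f"expected {cfg.chunk_len} samples; got {x.shape}")
    segments = x.reshape(cfg.n_windows, cfg.window_len)
    pxx_mean = np.mean([periodogram(seg, cfg) for seg in segments], axis=0)
    return float(np.mean(pxx_mean / (2.0 * np.pi)))


def extract_features(chunk: Chunk, cfg: PSDConfig = DEFAULT_PSD) -> np.ndarray:
    """14-value feature vector of a chunk: per-channel 8-30 Hz band power.

    Each channel is band-pass filtered (zero-phase 8-30 Hz) and reduced
    by :func:`channel_band_power`; ordering follows the canonical channel
    order, so feature ``i`` always belongs to ``CHANNELS[i]``.
    """
    if chunk.data.shape[1] != cfg.chunk_len:
        raise ValueError(f"chunk length {chunk.data.shape[1]} != config {cfg.chunk_len}")
    return np.array([
        channel_band_power(bandpass_8_30(chunk.data[c]), cfg)
        for c in range(N_CHANNELS)
    ])


FEATURE_NAMES: tuple[str, ...] = CHANNELS
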