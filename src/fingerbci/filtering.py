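"""Mu/Beta band isolation: order-2 Butterworth filters applied zero-phase.

The decoder retains the 8-30 Hz sensorimotor band with a cascade of an
8 Hz high-pass and a 30 Hz low-pass, each a second-order digital
Butterworth section run forward and backward over the signal so the net
phase response is zero. The recursion is the direct difference equation

    a1*y[n] = b1*x[n] + b2*x[n-1] + b3*x[n-2] - a2*y[n-1] - a3*y[n-2]

with zero initial state; each pass is preceded by a 9-sample odd
(antisymmetric) reflection pad at both ends, which absorbs the start-up
transient, and the result is truncated back to the original length.

The coefficients the embedded decoder shipped (``HIGHPASS_8HZ``,
``LOWPASS_30HZ``) are the 4-decimal constants of the original design;
:func:`design_butterworth` re-derives them at full precision by bilinear
transform with frequency prewarping.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as _sig

#: Default pad length per end for zero-phase filtering: 3*(order+1) = 9.
DEFAULT_PAD = 9


@dataclass(frozen=True)
class FilterCoefficients:
    """One normalized second-order IIR section.

    ``b`` and ``a`` are the numerator/denominator triples of the transfer
    function; ``a[0]`` is 1 after normalization. ``kind`` is ``"highpass"``
    or ``"lowpass"``; ``cutoff_hz`` and ``fs`` record the design point.
    """

    b: tuple[float, float, float]
    a: tuple[float, float, float]
    kind: str
    cutoff_hz: float
    fs: float
    order: int = 2

    def __post_init__(self):
        if len(self.b) != self.order + 1 or len(self.a) != self.order + 1:
            raise ValueError(f"order-{self.order} section needs {self.order + 1} coefficients")
        if abs(self.a[0] - 1.0) > 1e-12:
            raise ValueError("denominator must be normalized to a[0] = 1")
        if not self.is_stable():
            raise ValueError("unstable filter: denominator roots outside the unit circle")

    def is_stable(self) -> bool:
        """True iff all poles lie strictly inside the unit circle."""
        return bool(np.all(np.abs(np.roots(self.a)) < 1.0))

    def magnitude_response(self, freqs_hz: Sequence[float]) -> np.ndarray:
        """Single-pass gain |H(e^{j2*pi*f/fs})| at the given frequencies."""
        w = 2.0 * np.pi * np.asarray(freqs_hz, dtype=float) / self.fs
        _, h = _sig.freqz(self.b, self.a, worN=w)
        return np.abs(h)

    def to_json(self) -> str:
        return json.dumps({
            "kind": self.kind, "cutoff_hz": self.cutoff_hz, "fs": self.fs,
            "order": self.order, "b": list(self.b), "a": list(self.a),
        })

    @classmethod
    def from_json(cls, doc: str) -> "FilterCoefficients":
        d = json.loads(doc)
        return cls(b=tuple(d["b"]), a=tuple(d["a"]), kind=d["kind"],
                   cutoff_hz=d["cutoff_hz"], fs=d["fs"], order=d.get("order", 2))


#: 8 Hz high-pass section as shipped on the embedded decoder (4-decimal design).
HIGHPASS_8HZ = FilterCoefficients(
    b=(0.7571, -1.5142, 0.7571), a=(1.0, -1.4542, 0.5741),
    kind="highpass", cutoff_hz=8.0, fs=128.0,
)

#: 30 Hz low-pass section as shipped on the embedded decoder (4-decimal design).
LOWPASS_30HZ = FilterCoefficients(
    b=(0.2647, 0.5294, 0.2647), a=(1.0, -0.1151, 0.1739),
    kind="lowpass", cutoff_hz=30.0, fs=128.0,
)


def design_butterworth(order: int, cutoff_hz: float, fs: float, kind: str) -> FilterCoefficients:
    """Design a second-order digital Butterworth section.

    Bilinear transform of the analog prototype with frequency prewarping,
    denominator normalized to ``a[0] = 1``. At ``(2, 8, 128, "highpass")``
    and ``(2, 30, 128, "lowpass")`` this reproduces the embedded decoder's
    shipped constants to four decimal places.
    """
    if order != 2:
        raise ValueError("only second-order sections are supported")
    if kind not in ("highpass", "lowpass"):
        raise ValueError(f"kind must be 'highpass' or 'lowpass', got {kind!r}")
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(f"cutoff must lie in (0, fs/2) = (0, {fs / 2}); got {cutoff_hz}")
    b, a = _sig.butter(order, cutoff_hz / (fs / 2.0), btype=kind)
    return FilterCoefficients(b=tuple(b), a=tuple(a / a[0]), kind=kind,
                              cutoff_hz=cutoff_hz, fs=fs, order=order)


def apply_difference_equation(x: np.ndarray, coef: FilterCoefficients) -> np.ndarray:
    """Run the IIR recursion sample-by-sample with zero initial state.

    Implements a1*y[n] = b1*x[n] + b2*x[n-1] + b3*x[n-2] - a2*y[n-1]
    - a3*y[n-2] with x[k] = y[k] = 0 for k < 0. Output length equals
    input length.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a non-empty 1-D array")
    b1, b2, b3 = coef.b
    _, a2, a3 = coef.a
    y = np.empty_like(x)
    xm1 = xm2 = ym1 = ym2 = 0.0
    xv = x.tolist()
    for n, xn in enumerate(xv):
        yn = b1 * xn + b2 * xm1 + b3 * xm2 - a2 * ym1 - a3 * ym2
        y[n] = yn
        xm2, xm1 = xm1, xn
        ym2, ym1 = ym1, yn
    return y


def odd_pad(x: np.ndarray, pad: int) -> np.ndarray:
    """Extend a signal by odd (antisymmetric) reflection of ``pad`` samples per end."""
    x = np.asarray(x, dtype=float)
    if x.size <= pad:
        raise ValueError(f"signal of {x.size} samples too short to pad by {pad}")
    left = 2.0 * x[0] - x[pad:0:-1]
    right = 2.0 * x[-1] - x[-2:-pad - 2:-1]
    return np.concatenate([left, x, right])


def zero_phase_filter(x: np.ndarray, coef: FilterCoefficients, pad: int = DEFAULT_PAD) -> np.ndarray:
    """Apply one section forward and backward for zero net phase.

    Pads by odd reflection of ``pad`` samples per end, runs the difference
    equation forward, reverses, runs it again, reverses, and truncates to
    the original length. The effective magnitude response is the square of
    the single-pass response.
    """
    x = np.asarray(x, dtype=float)
    ext = odd_pad(x, pad)
    y = apply_difference_equation(ext, coef)
    y = apply_difference_equation(y[::-1], coef)[::-1]
    return y[pad:pad + x.size]


def bandpass_8_30(
    x: np.ndarray,
    coefficients: tuple[FilterCoefficients, FilterCoefficients] = (HIGHPASS_8HZ, LOWPASS_30HZ),
    pad: int = DEFAULT_PAD,
) -> np.ndarray:
    """Isolate the 8-30 Hz Mu/Beta band: zero-phase high-pass then low-pass."""
    hp, lp = coefficients
    return zero_phase_filter(zero_phase_filter(x, hp, pad=pad), lp, pad=pad)


def save_coefficients(coef: FilterCoefficients, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(coef.to_json() + "\n")


def load_coefficients(path: str | os.PathLike) -> FilterCoefficients:
    with open(path, "r", encoding="utf-8") as fh:
        return FilterCoefficients.from_json(fh.read())
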