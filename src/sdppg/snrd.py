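"""Smooth noise-robust differentiation.

Short antisymmetric FIR kernels that are exact on low-degree polynomials,
match the ideal differentiator closely at low frequencies and have a
guaranteed zero response at the Nyquist frequency, so they do not amplify
the broadband noise the way a plain first difference does.  The 5-point
member is the shortest of the family:

    f'(t0) ~ [2 (f(+1) - f(-1)) + (f(+2) - f(-2))] / (8 h)

Higher derivatives are obtained by repeated application of the first-order
kernel (two passes for the second derivative, four for the fourth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import comb

from .errors import FilterDesignError, SegmentationError
from .signal_io import SampledSignal


@dataclass(frozen=True)
class SnrdKernel:
    """First-derivative kernel over offsets ``-h .. +h``.

    ``coefficients[k]`` multiplies the sample at offset ``k - h``; the array
    is antisymmetric with a zero centre tap.
    """

    length: int
    coefficients: np.ndarray
    step: float

    @property
    def half(self) -> int:
        return self.length // 2


def snrd_kernel(length: int = 5, step: float = 1.0) -> SnrdKernel:
    """Build the smooth noise-robust differentiator of a given odd length.

    ``length`` is the number of taps (>= 5, odd); ``step`` is the sample
    interval in seconds.  Coefficients for tap ``+k`` are

        c_k = [C(2m, m - k + 1) - C(2m, m - k - 1)] / 2^(2m + 1),

    with ``m = (length - 3) / 2``, applied antisymmetrically.
    """
    if length < 5 or length % 2 == 0:
        raise FilterDesignError(
            f"kernel length must be an odd integer >= 5, got {length}")
    if not step > 0:
        raise FilterDesignError(f"step must be positive, got {step}")
    h = length // 2
    m = (length - 3) // 2
    coeffs = np.zeros(length)
    for k in range(1, h + 1):
        c_k = (comb(2 * m, m - k + 1, exact=True)
               - comb(2 * m, m - k - 1, exact=True)) / 2 ** (2 * m + 1)
        coeffs[h + k] = c_k / step
        coeffs[h - k] = -c_k / step
    return SnrdKernel(length=length, coefficients=coeffs, step=step)


def kernel_response(kernel: SnrdKernel, freqs_hz: np.ndarray) -> np.ndarray:
    """Complex frequency response H(f) of the kernel (ideal is ``2 pi i f``)."""
    k = np.arange(-kernel.half, kernel.half + 1)
    w = 2 * np.pi * np.asarray(freqs_hz, dtype=float) * kernel.step
    return (kernel.coefficients[None, :]
            * np.exp(1j * np.outer(w, k))).sum(axis=1)


def differentiate(signal: SampledSignal, kernel: SnrdKernel | None = None,
                  times: int = 1) -> SampledSignal:
    """Apply the differentiator ``times`` times.

    The output is trimmed so only fully supported samples remain and is
    centred (no net shift): ``t0`` advances by ``times * h`` samples.
    """
    if times < 1:
        raise FilterDesignError(f"times must be >= 1, got {times}")
    if kernel is None:
        kernel = snrd_kernel(step=1.0 / signal.fs)
    support = times * 2 * kernel.half
    if signal.samples.size <= support:
        raise SegmentationError(
            f"signal of {signal.samples.size} samples is too short for "
            f"{times}-fold differentiation (needs > {support} samples)")
    y = signal.samples
    for _ in range(times):
        # convolution flips the kernel; coefficients are stored in offset
        # order, so flip once more to correlate.
        y = np.convolve(y, kernel.coefficients[::-1], mode="valid")
    return SampledSignal(samples=y, fs=signal.fs,
                         label=signal.label + f" [d{times}]",
                         t0=signal.t0 + times * kernel.half / signal.fs)
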