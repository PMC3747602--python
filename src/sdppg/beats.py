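"""Beat segmentation, time normalization, equiripple filtering, averaging.

Each detected recurrence (one heartbeat, foot to foot) is resampled so its
duration is exactly 1 s, which puts the pulse fundamental at 1 Hz and all
harmonics at integer Hz on the normalized grid.  The normalized beat and
its second/fourth derivatives are then low-pass filtered with an equiripple
(Parks-McClellan) filter whose passband edge selects how many harmonics
survive, aligned at the 50 % level of the PPG rising front, and ensemble
averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks, freqz, remez

from .errors import FilterDesignError, SegmentationError
from .preprocess import apply_fir
from .signal_io import CANONICAL_FS, RunConfig, SampledSignal
from .snrd import differentiate, snrd_kernel


@dataclass(frozen=True)
class BeatSegment:
    """Half-open foot-to-foot span on the canonical grid of the AC signal."""

    start_index: int
    end_index: int
    fs: float = CANONICAL_FS

    @property
    def duration(self) -> float:
        return (self.end_index - self.start_index) / self.fs


@dataclass
class NormalizedBeat:
    """One recurrence resampled to exactly 1 s on the 1 kHz grid.

    ``ppg``, ``sdppg`` and ``d4`` share the grid; derivative amplitudes keep
    the scale of the original-time derivatives (the k-th derivative of the
    resampled beat equals ``original_duration**k`` times these arrays, a
    factor that cancels in all normalized ratios).
    """

    ppg: np.ndarray
    sdppg: np.ndarray
    d4: np.ndarray
    ref_time: float          # 50 %-rising-front crossing, s, sub-sample
    original_duration: float  # s

    def __post_init__(self) -> None:
        n = self.ppg.size
        if not (n == self.sdppg.size == self.d4.size):
            raise SegmentationError("beat component lengths differ")
        if not 0 < self.ref_time < n / CANONICAL_FS:
            raise SegmentationError(
                f"reference time {self.ref_time:.3f} s outside the beat")


@dataclass
class AveragedWaveformSet:
    """Ensemble averages of aligned beats on a common grid.

    ``tau`` is time in seconds relative to the alignment reference point;
    the grid is the intersection of all aligned beats' supports.
    """

    tau: np.ndarray
    ppg: np.ndarray
    sdppg: np.ndarray
    d4: np.ndarray
    n_beats: int


def estimate_pm_order(ripple_pass: float, ripple_stop: float,
                      transition_hz: float, fs: float) -> int:
    """Classical Herrmann-Rabiner estimate of the minimal equiripple order.

    ``D_inf(d1, d2) / dF - f(d1, d2) * dF`` with ``dF = transition_hz / fs``,
    truncated toward zero.  For ripples of 0.001 and a 1 Hz transition at
    1 kHz this gives 3255.
    """
    for name, r in (("ripple_pass", ripple_pass), ("ripple_stop", ripple_stop)):
        if not 0 < r < 1:
            raise FilterDesignError(f"{name} must lie in (0, 1), got {r}")
    if not 0 < transition_hz < fs / 2:
        raise FilterDesignError(
            f"transition width {transition_hz:g} Hz must lie in (0, {fs/2:g})")
    l1, l2 = math.log10(ripple_pass), math.log10(ripple_stop)
    d_inf = ((0.005309 * l1 ** 2 + 0.07114 * l1 - 0.4761) * l2
             - (0.00266 * l1 ** 2 + 0.5941 * l1 + 0.4278))
    f12 = 11.01217 + 0.51244 * (l1 - l2)
    d_f = transition_hz / fs
    return int(d_inf / d_f - f12 * d_f)


@lru_cache(maxsize=32)
def _design_pm_cached(edge_hz: float, transition_hz: float, ripple: float,
                      fs: float) -> tuple[np.ndarray, int]:
    est = estimate_pm_order(ripple, ripple, transition_hz, fs)
    numtaps = est + 1
    if numtaps % 2:
        numtaps += 1
    grid = None
    for _ in range(64):
        taps = remez(numtaps, [0, edge_hz, edge_hz + transition_hz, fs / 2],
                     [1, 0], fs=fs, maxiter=100)
        w, h = freqz(taps, worN=1 << 16, fs=fs)
        mag = np.abs(h)
        dev = max(np.max(np.abs(mag[w <= edge_hz] - 1)),
                  np.max(mag[w >= edge_hz + transition_hz]))
        if dev <= ripple:
            return taps, numtaps
        numtaps += 16
        grid = dev
    raise FilterDesignError(
        f"equiripple design did not reach ripple {ripple:g} "
        f"(last deviation {grid:g} at {numtaps} taps)")


def design_pm_lowpass(edge_hz: float, transition_hz: float = 1.0,
                      ripple: float = 0.001,
                      fs: float = CANONICAL_FS) -> np.ndarray:
    """Equiripple low-pass meeting the ripple spec in both bands.

    The tap count starts at the Herrmann-Rabiner estimate and is increased
    until the measured deviation is within ``ripple`` on a dense frequency
    grid.  An even tap count is used (the optimizer converges reliably
    there); the resulting half-sample delay is removed by :func:`apply_fir`.
    """
    if not 0 < edge_hz < edge_hz + transition_hz < fs / 2:
        raise FilterDesignError(
            f"need 0 < edge ({edge_hz:g}) < edge+transition < Nyquist")
    taps, _ = _design_pm_cached(float(edge_hz), float(transition_hz),
                                float(ripple), float(fs))
    return taps


def segment_beats(ac_ppg: SampledSignal, n_beats: int | None,
                  config: RunConfig | None = None) -> list[BeatSegment]:
    """Detect ``n_beats`` consecutive foot-to-foot recurrences.

    Steepest-rise points are local maxima of the first derivative exceeding
    half the median rise-peak height, with a 0.3 s refractory period; each
    foot is the signal minimum in the 0.35 s window preceding a rise point.
    Both are localized on a 10 Hz low-passed copy of the signal so that the
    nearly flat diastolic tail does not let broadband noise move the foot;
    the smoothed copy is used for localization only.
    With ``n_beats=None`` every detected recurrence is returned.
    """
    config = config or RunConfig()
    if n_beats is not None and n_beats < 1:
        raise SegmentationError(f"n_beats must be >= 1, got {n_beats}")
    fs = ac_ppg.fs
    if np.ptp(ac_ppg.samples) == 0:
        raise SegmentationError("flat signal: no beats found")
    from .preprocess import design_windowed_fir
    sm_taps = design_windowed_fir("lowpass", 10.0, 200, fs)
    sm, sm_off = apply_fir(ac_ppg.samples, sm_taps)
    sm_off = int(sm_off)           # smoothed[j] sits at ac index j + sm_off
    d1 = differentiate(
        SampledSignal(samples=sm, fs=fs, t0=ac_ppg.t0 + sm_off / fs),
        snrd_kernel(config.snrd_length, 1.0 / fs), 1)
    offset = round((d1.t0 - ac_ppg.t0) * fs)   # d1 index -> ac index shift
    x = d1.samples
    if np.ptp(x) == 0:
        raise SegmentationError("flat signal: no beats found")
    cand, props = find_peaks(x, distance=int(0.3 * fs),
                             height=0.05 * np.max(x))
    if cand.size == 0:
        raise SegmentationError("no rising edges found (0 beats)")
    thresh = 0.5 * np.median(props["peak_heights"])
    rises = cand[x[cand] >= thresh] + offset
    feet = []
    win = int(0.35 * fs)
    for r in rises:
        lo = max(sm_off, r - win)
        if r - lo < 2:
            continue
        feet.append(lo + int(np.argmin(sm[lo - sm_off:r - sm_off])))
    feet = sorted(set(feet))
    segments = []
    for s, e in zip(feet[:-1], feet[1:]):
        d = (e - s) / fs
        if config.min_beat_s <= d <= config.max_beat_s:
            segments.append(BeatSegment(start_index=s, end_index=e, fs=fs))
    if n_beats is None:
        if not segments:
            raise SegmentationError("found 0 beats")
        return segments
    if len(segments) < n_beats:
        raise SegmentationError(
            f"found {len(segments)} beats, need {n_beats}")
    return segments[:n_beats]


def _rising_front_ref(ppg: np.ndarray, fs: float) -> float:
    """Sub-sample time of the 50 % rising-front crossing within one beat."""
    i_pk = int(np.argmax(ppg))
    if i_pk < 2:
        raise SegmentationError("no rising front found in beat")
    i_ft = int(np.argmin(ppg[:i_pk]))
    half = ppg[i_ft] + 0.5 * (ppg[i_pk] - ppg[i_ft])
    above = np.flatnonzero(ppg[i_ft:i_pk + 1] >= half)
    if above.size == 0:
        raise SegmentationError("no rising front found in beat")
    j = i_ft + int(above[0])
    if j == 0:
        return 0.5 / fs
    frac = (half - ppg[j - 1]) / (ppg[j] - ppg[j - 1])
    return (j - 1 + frac) / fs


def normalize_recurrence(ppg: SampledSignal, sdppg: SampledSignal,
                         d4: SampledSignal, segment: BeatSegment,
                         config: RunConfig | None = None) -> NormalizedBeat:
    """Resample one recurrence (plus context) to 1 s and PM-filter it.

    A window of each signal around the segment is spline-resampled by the
    factor ``1/duration`` so the segment spans exactly 1000 samples at 1 kHz,
    filtered with the equiripple low-pass (delay compensated), and the 1 s
    segment extracted.  Derivatives are resampled as-is: the time-scaling
    factor ``duration**k`` they would acquire is common to every sample and
    cancels in the normalized ratios.
    """
    config = config or RunConfig()
    taps = design_pm_lowpass(config.pm_edge_hz, config.pm_transition_hz,
                             config.pm_ripple)
    n_norm = round(CANONICAL_FS)                  # samples in the 1 s beat
    ctx = taps.size // 2 + 8                      # normalized-grid context
    duration = segment.duration
    dt_orig = duration / n_norm                   # normalized step, original s
    t_start = segment.start_index / segment.fs    # in the AC signal timeline

    out = []
    for sig in (ppg, sdppg, d4):
        # times of normalized samples, expressed on sig's own sample grid
        k = np.arange(-ctx, n_norm + ctx)
        t_new = (ppg.t0 + t_start) + k * dt_orig
        idx = (t_new - sig.t0) * sig.fs
        if idx[0] < 0 or idx[-1] > sig.samples.size - 1:
            need = ctx * dt_orig
            raise SegmentationError(
                f"insufficient context around beat for resampling and "
                f"filtering (need {need:.2f} s on each side)")
        spline = CubicSpline(np.arange(sig.samples.size), sig.samples)
        resampled = spline(idx)
        filtered, off = apply_fir(resampled, taps)
        start = round(ctx - off)          # index of normalized time 0
        if start < 0 or start + n_norm > filtered.size:
            raise SegmentationError(
                "insufficient context after filter-delay compensation")
        out.append(filtered[start:start + n_norm])

    ppg_n, sd_n, d4_n = out
    ref = _rising_front_ref(ppg_n, CANONICAL_FS)
    return NormalizedBeat(ppg=ppg_n, sdppg=sd_n, d4=d4_n, ref_time=ref,
                          original_duration=duration)


def align_and_average(beats: list[NormalizedBeat]) -> AveragedWaveformSet:
    """Shift beats so their 50 %-front references coincide, then average.

    The common grid runs over the intersection of the aligned supports at
    the 1 kHz step, with the reference point at ``tau = 0``.
    """
    if len(beats) < 2:
        raise SegmentationError(
            f"need at least 2 beats to average, got {len(beats)}")
    dt = 1.0 / CANONICAL_FS
    lo = max(-b.ref_time for b in beats)
    hi = min((b.ppg.size - 1) * dt - b.ref_time for b in beats)
    k0 = int(math.ceil(lo / dt)) + 1
    k1 = int(math.floor(hi / dt)) - 1
    if k1 <= k0:
        raise SegmentationError("aligned beats share no common support")
    tau = np.arange(k0, k1 + 1) * dt
    acc = {name: np.zeros(tau.size) for name in ("ppg", "sdppg", "d4")}
    for b in beats:
        t = np.arange(b.ppg.size) * dt
        for name in acc:
            spline = CubicSpline(t, getattr(b, name))
            acc[name] += spline(tau + b.ref_time)
    n = len(beats)
    return AveragedWaveformSet(tau=tau, ppg=acc["ppg"] / n,
                               sdppg=acc["sdppg"] / n, d4=acc["d4"] / n,
                               n_beats=n)


def beat_frame(beat: NormalizedBeat) -> AveragedWaveformSet:
    """View a single normalized beat on the reference-relative grid."""
    dt = 1.0 / CANONICAL_FS
    tau = np.arange(beat.ppg.size) * dt - beat.ref_time
    return AveragedWaveformSet(tau=tau, ppg=beat.ppg, sdppg=beat.sdppg,
                               d4=beat.d4, n_beats=1)
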