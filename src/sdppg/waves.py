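"""Detection of the SDPPG waves a-e and the ageing index.

The five systolic waves are alternating extrema of the second-derivative
waveform: a (maximum), b (minimum), c (maximum), d (minimum), e (maximum).
Zero crossings of the fourth derivative bracket them: between two
consecutive crossings the SDPPG has at most one extremum.  The a wave is
the dominant SDPPG maximum inside the systolic search window; b-e are then
sought in the successive inter-crossing intervals.  Where the expected c or
d extremum does not exist (a monotone limb with only an inflection), the
wave is placed at the fourth-derivative extremum of its interval.

The ageing index is AGI = (b - c - d - e) / a, dimensionless, increasing
with arterial stiffness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .beats import AveragedWaveformSet, BeatSegment, beat_frame, segment_beats
from .errors import DetectionError
from .signal_io import RunConfig, SampledSignal
from .snrd import differentiate, snrd_kernel

WAVE_NAMES = ("a", "b", "c", "d", "e")


@dataclass
class WaveFeatures:
    """Amplitudes and times of waves a-e plus the derived ratios.

    Times are in seconds relative to the alignment reference (the 50 %
    rising-front point); amplitudes are in the (arbitrary) units of the
    SDPPG they were read from.  ``fallback`` lists the waves placed at a
    fourth-derivative extremum because no SDPPG extremum existed.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    t_a: float
    t_b: float
    t_c: float
    t_d: float
    t_e: float
    fallback: tuple[str, ...] = ()
    beat_index: int | None = None

    def __post_init__(self) -> None:
        if not self.t_a < self.t_b < self.t_c < self.t_d < self.t_e:
            raise DetectionError("wave times are not strictly ordered")
        if not self.a > 0:
            raise DetectionError(f"wave a must be positive, got {self.a:g}")
        if not self.b < 0:
            raise DetectionError(f"wave b must be negative, got {self.b:g}")

    @property
    def b_over_a(self) -> float:
        return self.b / self.a

    @property
    def c_over_a(self) -> float:
        return self.c / self.a

    @property
    def d_over_a(self) -> float:
        return self.d / self.a

    @property
    def e_over_a(self) -> float:
        return self.e / self.a

    @property
    def agi(self) -> float:
        return agi(self.a, self.b, self.c, self.d, self.e)

    def ratio(self, name: str) -> float:
        return getattr(self, name)


def agi(a: float, b: float, c: float, d: float, e: float) -> float:
    """Ageing index (b - c - d - e) / a."""
    if a == 0:
        raise DetectionError("AGI undefined: wave a amplitude is zero")
    return (b - c - d - e) / a


def zero_crossings(y: np.ndarray) -> np.ndarray:
    """Sub-sample (linearly interpolated) sign-change locations.

    Exact zeros are reported once; an empty result is allowed.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise DetectionError("need at least 2 samples for zero crossings")
    out: list[float] = []
    i = 0
    n = y.size
    while i < n:
        if y[i] == 0.0:
            j = i
            while j + 1 < n and y[j + 1] == 0.0:
                j += 1
            out.append(0.5 * (i + j))
            i = j + 1
        else:
            if i + 1 < n and y[i + 1] != 0.0 and y[i] * y[i + 1] < 0:
                out.append(i + y[i] / (y[i] - y[i + 1]))
            i += 1
    return np.array(out)


def _parabolic_refine(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample extremum via a 3-point parabola around index ``i``."""
    if i <= 0 or i >= y.size - 1:
        return float(i), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(i), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    val = y1 - 0.25 * (y0 - y2) * delta
    return i + delta, float(val)


def detect_waves(avg: AveragedWaveformSet,
                 config: RunConfig | None = None) -> WaveFeatures:
    """Locate waves a-e on an averaged (or single-beat) waveform set.

    The search window is ``[search_start_s, search_end_s]`` relative to the
    alignment reference, intersected with the available support.  Raises
    :class:`DetectionError`, reporting how many waves were resolved, when
    the zero-crossing structure cannot accommodate all five waves.
    """
    config = config or RunConfig()
    tau, sd, d4 = avg.tau, avg.sdppg, avg.d4
    dt = tau[1] - tau[0]
    sel = (tau >= config.search_start_s) & (tau <= config.search_end_s)
    if np.count_nonzero(sel) < 8:
        raise DetectionError("search window not covered by the waveform "
                             "(0 of 5 waves resolved)")
    w0 = int(np.argmax(sel))
    sdw = sd[sel]
    d4w = d4[sel]
    zc = zero_crossings(d4w)

    spline_sd = CubicSpline(np.arange(sdw.size), sdw)

    # wave a: dominant SDPPG maximum of the window
    ia = int(np.argmax(sdw))
    k = int(np.searchsorted(zc, ia))
    if k >= zc.size:
        raise DetectionError("no fourth-derivative zero crossing follows "
                             "wave a (1 of 5 waves resolved)")
    pos_a, amp_a = _parabolic_refine(sdw, ia)
    times = [pos_a]
    amps = [amp_a]
    fallback: list[str] = []

    want_min = True
    for w, name in enumerate(WAVE_NAMES[1:], start=1):
        if k + w >= zc.size + 1:
            raise DetectionError(
                f"ran out of fourth-derivative zero crossings "
                f"({w} of 5 waves resolved)")
        lo = zc[k + w - 1]
        hi = zc[k + w] if k + w < zc.size else sdw.size - 1.0
        ilo = int(np.ceil(lo))
        ihi = int(np.floor(hi))
        if ihi <= ilo:
            raise DetectionError(
                f"degenerate inter-crossing interval ({w} of 5 waves "
                "resolved)")
        seg = sdw[ilo:ihi + 1]
        j = int(np.argmin(seg)) if want_min else int(np.argmax(seg))
        interior = 0 < j < seg.size - 1
        if interior:
            pos, amp = _parabolic_refine(sdw, ilo + j)
        else:
            # monotone limb: place the wave at the fourth-derivative
            # extremum of the interval (largest |d4|, ties -> earliest)
            segd = np.abs(d4w[ilo:ihi + 1])
            jd = int(np.argmax(segd))
            pos, _ = _parabolic_refine(np.abs(d4w), ilo + jd)
            amp = float(spline_sd(pos))
            fallback.append(name)
        times.append(pos)
        amps.append(amp)
        want_min = not want_min

    t = [tau[w0] + p * dt for p in times]
    try:
        return WaveFeatures(a=amps[0], b=amps[1], c=amps[2], d=amps[3],
                            e=amps[4], t_a=t[0], t_b=t[1], t_c=t[2],
                            t_d=t[3], t_e=t[4], fallback=tuple(fallback))
    except DetectionError as exc:
        raise DetectionError(f"wave pattern violated: {exc} "
                             "(5 of 5 waves located)") from exc


def per_beat_features(beats, config: RunConfig | None = None
                      ) -> list[WaveFeatures | None]:
    """Run detection on each normalized beat with its own fourth derivative.

    Failures yield ``None`` entries rather than aborting the batch.
    """
    out: list[WaveFeatures | None] = []
    for i, beat in enumerate(beats):
        try:
            f = detect_waves(beat_frame(beat), config)
            f.beat_index = i
            out.append(f)
        except DetectionError:
            out.append(None)
    return out


def baseline_per_beat(ac_ppg: SampledSignal, n_beats: int,
                      config: RunConfig | None = None
                      ) -> list[WaveFeatures | None]:
    """Simplified per-beat detection without normalization or averaging.

    Reconstructs the conventional per-beat approach for dispersion
    comparisons: the SDPPG and fourth derivative are computed on the
    band-passed signal at the original rate, each beat gets its own 50 %
    rising-front reference, and the a-e search runs per beat with the
    search window scaled by the beat duration.  No time normalization,
    equiripple filtering or ensemble averaging is applied.
    """
    config = config or RunConfig()
    fs = ac_ppg.fs
    kern = snrd_kernel(config.snrd_length, 1.0 / fs)
    d2 = differentiate(ac_ppg, kern, times=2)
    d4 = differentiate(ac_ppg, kern, times=4)
    segs = segment_beats(ac_ppg, n_beats, config)
    from .beats import _rising_front_ref  # shared sub-sample front finder

    out: list[WaveFeatures | None] = []
    for i, seg in enumerate(segs):
        try:
            s0, s1 = seg.start_index, seg.end_index
            ref = _rising_front_ref(ac_ppg.samples[s0:s1], fs)
            scale = seg.duration  # window is defined on the normalized base
            tau_lo = config.search_start_s * scale
            tau_hi = config.search_end_s * scale

            off2 = round((d2.t0 - ac_ppg.t0) * fs)
            off4 = round((d4.t0 - ac_ppg.t0) * fs)
            st = max(s0, off2, off4)
            en = min(s1, off2 + d2.samples.size, off4 + d4.samples.size)
            if en - st < 8:
                raise DetectionError("beat outside derivative support")
            tau = (np.arange(st, en) - s0) / fs - ref
            frame = AveragedWaveformSet(tau=tau,
                                        ppg=ac_ppg.samples[st:en],
                                        sdppg=d2.samples[st - off2:en - off2],
                                        d4=d4.samples[st - off4:en - off4],
                                        n_beats=1)
            cfg = config.replace(search_start_s=tau_lo, search_end_s=tau_hi)
            f = detect_waves(frame, cfg)
            f.beat_index = i
            out.append(f)
        except DetectionError:
            out.append(None)
    return out
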