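"""Synthetic finger-PPG generator with analytic ground truth.

One heartbeat is modelled as a sum of five Gaussian components (systolic
onset, main systolic peak, late-systolic shoulder, dicrotic wave, diastolic
tail) on the unit period.  A single ``stiffness`` parameter in [0, 1]
morphs the shape from a compliant, wavy waveform (pronounced c-e waves,
strongly negative ageing index) to a stiff, near-triangular one (shallow b,
negative c and d, ageing index above zero); the clean template's ageing
index is strictly monotone in the stiffness, which lets the generator
invert it to hit a target index.

Because the waveform is a Gaussian sum with an analytic Fourier series, the
ground truth (wave times/amplitudes and ageing index of the
harmonic-limited template, beat boundaries, the 50 %-front reference) is
computed exactly in the frequency domain at high resolution, independently
of the sample-domain pipeline.

Recordings are assembled from period-jittered beats plus low-frequency
baseline drift, broadband white noise and an optional powerline component;
a seed fixes the output bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import GenerationError
from .signal_io import CANONICAL_FS, CohortRecord, SampledSignal

# (amplitude, centre, width) per Gaussian, as fractions of the period.
# Compliant endpoint: distinct shoulder and dicrotic waves.
_COMPLIANT = ((0.80, 0.10, 0.055),
              (0.80, 0.22, 0.085),
              (0.65, 0.40, 0.068),
              (0.30, 0.56, 0.068),
              (0.08, 0.72, 0.100))
# Stiff endpoint: broadened, merged components -> near-triangular pulse.
_STIFF = ((0.18, 0.12, 0.060),
          (0.95, 0.27, 0.110),
          (0.48, 0.45, 0.100),
          (0.17, 0.61, 0.100),
          (0.05, 0.75, 0.105))

_NMAX = 64  # harmonics kept when evaluating the exact (unfiltered) template


@dataclass(frozen=True)
class BeatTemplate:
    """A Gaussian-sum beat shape.

    ``components`` are (amplitude, centre, width) triples in period
    fractions; ``stiffness`` records the morph parameter when the template
    came from :meth:`from_stiffness`.
    """

    components: tuple[tuple[float, float, float], ...]
    stiffness: Optional[float] = None

    @classmethod
    def from_stiffness(cls, s: float) -> "BeatTemplate":
        if not 0.0 <= s <= 1.0:
            raise GenerationError(f"stiffness must lie in [0, 1], got {s}")
        comps = tuple(
            tuple((1 - s) * y + s * o for y, o in zip(cy, co))
            for cy, co in zip(_COMPLIANT, _STIFF))
        return cls(components=comps, stiffness=s)

    def fourier_coefficients(self, nmax: int = _NMAX) -> np.ndarray:
        """One-sided coefficients c_0..c_nmax of the 1-periodic waveform."""
        n = np.arange(nmax + 1)
        c = np.zeros(nmax + 1, dtype=complex)
        for amp, mu, sig in self.components:
            c += (amp * sig * math.sqrt(2 * math.pi)
                  * np.exp(-2 * np.pi ** 2 * sig ** 2 * n ** 2)
                  * np.exp(-2j * np.pi * n * mu))
        return c

    def evaluate(self, phase: np.ndarray, deriv: int = 0,
                 nmax: int = _NMAX) -> np.ndarray:
        """Evaluate the periodic waveform (or a phase-derivative) exactly."""
        c = self.fourier_coefficients(nmax)
        n = np.arange(nmax + 1)
        w = (2j * np.pi * n) ** deriv
        ph = np.exp(2j * np.pi * np.outer(np.asarray(phase, float), n))
        vals = 2.0 * (ph @ (w * c)).real - (w[0] * c[0]).real
        return vals


@dataclass(frozen=True)
class TemplateAnnotation:
    """Ground-truth features of the harmonic-limited clean template.

    Times are on the normalized 1 s base, relative to the 50 %-front
    reference; amplitudes are second-derivative values of the unit-period
    template.
    """

    agi: float
    amplitudes: dict
    times: dict
    fallback: tuple[str, ...]
    foot_phase: float
    ref_phase: float
    edge_hz: float


def _series(c: np.ndarray, t: np.ndarray, deriv: int) -> np.ndarray:
    n = np.arange(c.size)
    w = (2j * np.pi * n) ** deriv
    ph = np.exp(2j * np.pi * np.outer(t, n))
    return 2.0 * (ph @ (w * c)).real - (w[0] * c[0]).real


def annotate_template(template: BeatTemplate, edge_hz: float = 6.0,
                      n_grid: int = 8192,
                      search_start_s: float = -0.15,
                      search_end_s: float = 0.45) -> TemplateAnnotation:
    """Brute-force a-e detection on the harmonic-limited clean template.

    The template's Fourier series is truncated at the last harmonic inside
    the passband (ideal filtering of the 1 Hz-normalized beat), evaluated on
    a dense grid, and the waves are located by direct search between the
    zero crossings of the fourth derivative, mirroring the pipeline's
    conventions (dominant-maximum anchor for a, alternating polarities,
    fourth-derivative fallback for missing waves).

    Raises :class:`GenerationError` when the template does not produce the
    alternating five-wave pattern.
    """
    nmax = int(math.floor(edge_hz + 1e-9))
    c = template.fourier_coefficients(nmax)
    t = np.arange(n_grid) / n_grid
    ppg = _series(c, t, 0)
    # roll so the pulse foot (global minimum) is at index 0
    i_min = int(np.argmin(ppg))
    foot_phase = i_min / n_grid
    ppg = np.roll(ppg, -i_min)
    sd = np.roll(_series(c, t, 2), -i_min)
    d4 = np.roll(_series(c, t, 4), -i_min)

    i_pk = int(np.argmax(ppg))
    half = ppg[0] + 0.5 * (ppg[i_pk] - ppg[0])
    i_ref = int(np.argmax(ppg[:i_pk + 1] >= half))
    ref_phase = (foot_phase + i_ref / n_grid) % 1.0

    lo = i_ref + int(round(search_start_s * n_grid))
    hi = i_ref + int(round(search_end_s * n_grid))
    idx = np.arange(lo, hi)
    sdw = sd[idx % n_grid]
    d4w = d4[idx % n_grid]
    sign = np.sign(d4w)
    zc = np.flatnonzero(np.diff(sign) != 0)

    ia = int(np.argmax(sdw))
    k = int(np.searchsorted(zc, ia))
    if k >= zc.size:
        raise GenerationError("template: no fourth-derivative zero "
                              "crossing follows wave a")
    amps = {"a": float(sdw[ia])}
    times = {"a": (lo + ia) / n_grid - i_ref / n_grid}
    fallback: list[str] = []
    want_min = True
    for w, name in enumerate("bcde", start=1):
        if k + w > zc.size:
            raise GenerationError(
                f"template: no interval for wave {name!r}")
        a0 = zc[k + w - 1]
        a1 = zc[k + w] if k + w < zc.size else sdw.size - 1
        seg = sdw[a0:a1 + 1]
        if seg.size < 3:
            raise GenerationError(
                f"template: degenerate interval for wave {name!r}")
        j = int(np.argmin(seg)) if want_min else int(np.argmax(seg))
        if 0 < j < seg.size - 1:
            amps[name] = float(seg[j])
        else:
            jd = int(np.argmax(np.abs(d4w[a0:a1 + 1])))
            j = jd
            amps[name] = float(sdw[a0 + j])
            fallback.append(name)
        times[name] = (lo + a0 + j) / n_grid - i_ref / n_grid
        want_min = not want_min
    if not (amps["a"] > 0 and amps["b"] < 0):
        raise GenerationError("template: a/b wave polarities violated")
    if not (times["a"] < times["b"] < times["c"] < times["d"] < times["e"]):
        raise GenerationError("template: wave times not ordered")
    agi_val = (amps["b"] - amps["c"] - amps["d"] - amps["e"]) / amps["a"]
    return TemplateAnnotation(agi=float(agi_val), amplitudes=amps,
                              times=times, fallback=tuple(fallback),
                              foot_phase=foot_phase, ref_phase=ref_phase,
                              edge_hz=edge_hz)


@lru_cache(maxsize=4096)
def _agi_of_stiffness(s: float, edge_hz: float) -> float:
    return annotate_template(BeatTemplate.from_stiffness(s), edge_hz).agi


def template_agi(stiffness: float, edge_hz: float = 6.0) -> float:
    """Ageing index of the clean harmonic-limited template at ``stiffness``."""
    return _agi_of_stiffness(round(float(stiffness), 12), float(edge_hz))


def attainable_agi_range(edge_hz: float = 6.0) -> tuple[float, float]:
    return (template_agi(0.0, edge_hz), template_agi(1.0, edge_hz))


def stiffness_for_agi(target: float, edge_hz: float = 6.0,
                      tol: float = 1e-4) -> float:
    """Invert the (strictly monotone) stiffness -> ageing index map."""
    lo, hi = attainable_agi_range(edge_hz)
    if not lo <= target <= hi:
        raise GenerationError(
            f"target ageing index {target:.3f} outside the attainable "
            f"range [{lo:.3f}, {hi:.3f}] at a {edge_hz:g} Hz edge")
    s = brentq(lambda x: template_agi(x, edge_hz) - target, 0.0, 1.0,
               xtol=tol)
    return float(s)


@dataclass(frozen=True)
class RecordingSpec:
    """Conditions of one synthetic recording.

    Defaults emulate a one-minute resting finger recording: 75 beats of
    0.8 s mean period with 2 % period jitter, respiratory-band baseline
    drift at 0.2 Hz with amplitude 0.3 of the pulse amplitude, and white
    noise whose SD is ``noise_rel`` times the clean pulse peak-to-peak
    amplitude.  The seed fixes the output bit for bit.
    """

    n_beats: int = 75
    mean_period_s: float = 0.8
    period_jitter: float = 0.02    # fractional SD of the beat period
    drift_rel: float = 0.3         # drift amplitude / pulse peak-to-peak
    drift_hz: float = 0.2
    noise_rel: float = 0.0         # white-noise SD / pulse peak-to-peak
    powerline_hz: float = 0.0      # 0 disables the powerline component
    powerline_rel: float = 0.0
    fs: float = CANONICAL_FS
    seed: int = 0


@dataclass
class RecordingAnnotations:
    """Ground truth shipped with a synthetic recording."""

    beats: pd.DataFrame            # beat_index, t_start, period_s, t_foot
    template: TemplateAnnotation   # per-beat truth on the normalized base
    spec: RecordingSpec

    def foot_times(self) -> np.ndarray:
        return self.beats["t_foot"].to_numpy()

    def to_csv(self, path) -> None:
        df = self.beats.copy()
        for name in "abcde":
            df[f"true_{name}"] = self.template.amplitudes[name]
            df[f"true_t_{name}"] = self.template.times[name]
        df["true_agi"] = self.template.agi
        df.to_csv(path, index=False, float_format="%.12g",
                  lineterminator="\n")


def peak_to_peak(template: BeatTemplate) -> float:
    t = np.arange(4096) / 4096
    v = template.evaluate(t)
    return float(np.ptp(v))


def noise_rel_for_snr_db(template: BeatTemplate, snr_db: float) -> float:
    """Relative noise SD giving the requested AC signal-to-noise ratio."""
    t = np.arange(4096) / 4096
    v = template.evaluate(t)
    rms = float(np.sqrt(np.mean((v - v.mean()) ** 2)))
    return rms / peak_to_peak(template) / 10 ** (snr_db / 20)


def generate_recording(template: BeatTemplate, spec: RecordingSpec,
                       edge_hz: float = 6.0
                       ) -> tuple[SampledSignal, RecordingAnnotations]:
    """Assemble a recording of jittered beats with drift and noise.

    The template is validated (it must produce the alternating a-e wave
    pattern at the given passband edge) and annotated before synthesis.
    """
    ann = annotate_template(template, edge_hz)   # validates the pattern
    rng = np.random.default_rng(spec.seed)
    if spec.n_beats < 1:
        raise GenerationError("n_beats must be >= 1")
    periods = spec.mean_period_s * (
        1.0 + spec.period_jitter * rng.standard_normal(spec.n_beats))
    periods = np.clip(periods, 0.3, 2.0)
    starts = np.concatenate([[0.0], np.cumsum(periods)])
    total = starts[-1]
    n = int(math.floor(total * spec.fs))
    t = np.arange(n) / spec.fs
    beat_idx = np.clip(np.searchsorted(starts, t, side="right") - 1,
                       0, spec.n_beats - 1)
    phase = (t - starts[beat_idx]) / periods[beat_idx]
    x = template.evaluate(phase)

    pp = peak_to_peak(template)
    if spec.drift_rel:
        x = x + spec.drift_rel * pp * np.sin(
            2 * np.pi * spec.drift_hz * t + rng.uniform(0, 2 * np.pi))
    if spec.powerline_hz and spec.powerline_rel:
        x = x + spec.powerline_rel * pp * np.sin(
            2 * np.pi * spec.powerline_hz * t + rng.uniform(0, 2 * np.pi))
    if spec.noise_rel:
        x = x + spec.noise_rel * pp * rng.standard_normal(n)

    beats = pd.DataFrame({
        "beat_index": np.arange(spec.n_beats),
        "t_start": starts[:-1],
        "period_s": periods,
        "t_foot": starts[:-1] + ann.foot_phase * periods,
    })
    sig = SampledSignal(samples=x, fs=spec.fs,
                        label=f"synthetic(seed={spec.seed})")
    return sig, RecordingAnnotations(beats=beats, template=ann, spec=spec)


@dataclass(frozen=True)
class SubjectSpec:
    """One simulated subject: cohort record plus synthesis inputs."""

    record: CohortRecord
    spec: RecordingSpec
    template: Optional[BeatTemplate] = None


def generate_cohort(n_healthy: int = 21, n_patient: int = 20,
                    age_range: tuple[float, float] = (21.0, 66.0),
                    patient_age_range: tuple[float, float] = (27.0, 66.0),
                    model: tuple[float, float, float] = (0.019, -1.556, 0.126),
                    patient_offset: float = 0.359,
                    seed: int = 0,
                    build_templates: bool = True,
                    recording: RecordingSpec | None = None,
                    edge_hz: float = 6.0) -> list[SubjectSpec]:
    """Draw a cohort whose ageing indices follow a linear age model.

    Healthy target indices are ``slope * age + intercept`` plus Gaussian
    residual noise; patient targets are additionally offset upward.  With
    ``build_templates`` the stiffness of each subject's template is
    inverted numerically so the clean template attains its target index
    (within the inversion tolerance); targets outside the template family's
    attainable range raise :class:`GenerationError` naming the range.
    """
    if n_healthy < 1 or n_patient < 0:
        raise GenerationError("need n_healthy >= 1 and n_patient >= 0")
    slope, intercept, residual_sd = model
    rng = np.random.default_rng(seed)
    base = recording or RecordingSpec()
    out: list[SubjectSpec] = []
    groups = [("healthy", n_healthy, age_range, 0.0),
              ("patient", n_patient, patient_age_range, patient_offset)]
    for group, count, arange_, offset in groups:
        for i in range(count):
            age = float(rng.uniform(*arange_))
            target = (slope * age + intercept + offset
                      + residual_sd * rng.standard_normal())
            sub_seed = int(rng.integers(0, 2 ** 31 - 1))
            template = None
            agi_val = target
            if build_templates:
                s = stiffness_for_agi(target, edge_hz)
                template = BeatTemplate.from_stiffness(s)
                agi_val = template_agi(s, edge_hz)
            rec = CohortRecord(subject_id=f"{group[:3]}{i:03d}", age=age,
                               group=group, agi=agi_val)
            out.append(SubjectSpec(
                record=rec,
                spec=replace(base, seed=sub_seed),
                template=template))
    return out
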