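"""End-to-end orchestration: raw PPG in, wave features and dispersions out."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beats import (AveragedWaveformSet, NormalizedBeat, align_and_average,
                    normalize_recurrence, segment_beats)
from .errors import SegmentationError
from .preprocess import bandpass_ppg
from .signal_io import RunConfig, SampledSignal
from .snrd import differentiate, snrd_kernel
from .variability import sd_about_reference
from .waves import WaveFeatures, detect_waves, per_beat_features

#: statistics reported per analysis: dimensionless ratios and the index,
#: then wave-peak times (converted to ms in the dispersion tables)
RATIO_STATS = ("agi", "b_over_a", "c_over_a", "d_over_a", "e_over_a")
TIME_STATS = ("t_a", "t_b", "t_c", "t_d", "t_e")


@dataclass
class AnalysisResult:
    """Everything the pipeline computes for one recording."""

    averaged: AveragedWaveformSet
    averaged_features: WaveFeatures
    beat_features: list[WaveFeatures | None]
    beats: list[NormalizedBeat]
    sds: dict[str, float]           # dispersion about the averaged value
    n_rejected: int

    @property
    def agi(self) -> float:
        return self.averaged_features.agi


def _derivative_chain(ac: SampledSignal, config: RunConfig
                      ) -> tuple[SampledSignal, SampledSignal]:
    kern = snrd_kernel(config.snrd_length, 1.0 / ac.fs)
    d2 = differentiate(ac, kern, times=2)
    d4 = differentiate(d2, kern, times=2)
    return d2, d4


def dispersion_table(beat_features: list[WaveFeatures | None],
                     averaged_features: WaveFeatures) -> dict[str, float]:
    """Per-statistic dispersion of the per-beat values about the
    averaged-waveform value (times in ms).

    Beats with missing features are excluded (with n reduced); a statistic
    with fewer than 2 surviving beats is reported as NaN.
    """
    good = [f for f in beat_features if f is not None]
    sds: dict[str, float] = {}
    for stat in RATIO_STATS + TIME_STATS:
        ref = getattr(averaged_features, stat)
        vals = np.array([getattr(f, stat) for f in good])
        if stat in TIME_STATS:
            vals = vals * 1000.0
            ref = ref * 1000.0
        sds[stat] = (sd_about_reference(vals, ref)
                     if vals.size >= 2 else float("nan"))
    return sds


def analyze_signal(signal: SampledSignal,
                   config: RunConfig | None = None) -> AnalysisResult:
    """Run the full analysis on one raw PPG recording.

    Band separation, noise-robust differentiation (x2 and x4), foot-to-foot
    segmentation, per-recurrence time normalization and equiripple
    filtering, 50 %-front alignment and averaging, wave detection on the
    averaged waveform, per-beat wave detection, and the dispersion of every
    per-beat statistic about its averaged-waveform value.

    The first ``config.n_beats`` recurrences with enough surrounding signal
    for the per-recurrence filtering are used.
    """
    config = config or RunConfig()
    ac = bandpass_ppg(signal, config)
    d2, d4 = _derivative_chain(ac, config)

    # segment every recurrence, then keep beats with enough context
    all_segs = segment_beats(ac, None, config)
    if len(all_segs) < config.n_beats:
        raise SegmentationError(
            f"found {len(all_segs)} beats, need {config.n_beats}")

    beats: list[NormalizedBeat] = []
    rejected = 0
    for seg in all_segs:
        if len(beats) == config.n_beats:
            break
        try:
            beats.append(normalize_recurrence(ac, d2, d4, seg, config))
        except SegmentationError:
            rejected += 1
    if len(beats) < config.n_beats:
        raise SegmentationError(
            f"only {len(beats)} of the requested {config.n_beats} beats "
            f"could be normalized ({rejected} rejected for context)")

    averaged = align_and_average(beats)
    avg_features = detect_waves(averaged, config)
    beat_feats = per_beat_features(beats, config)
    sds = dispersion_table(beat_feats, avg_features)
    return AnalysisResult(averaged=averaged, averaged_features=avg_features,
                          beat_features=beat_feats, beats=beats, sds=sds,
                          n_rejected=rejected)
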