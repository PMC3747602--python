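import numpy as np
import pytest
from hypothesis import given, strategies as st

import sdppg
from sdppg import DetectionError, WaveFeatures, agi, detect_waves, zero_crossings
from sdppg.beats import AveragedWaveformSet
from sdppg.waves import per_beat_features


def test_agi_hand_examples():
    assert agi(1, -0.5, -0.2, -0.3, 0.1) == pytest.approx(-0.1)
    assert agi(2, -1.0, -0.4, -0.6, 0.2) == pytest.approx(-0.1)
    assert agi(1, 0, 0, 0, 0) == 0.0
    with pytest.raises(DetectionError):
        agi(0, 1, 1, 1, 1)


@given(st.floats(min_value=0.1, max_value=50),
       st.floats(min_value=-5, max_value=5),
       st.floats(min_value=-5, max_value=5),
       st.floats(min_value=-5, max_value=5),
       st.floats(min_value=-5, max_value=5),
       st.floats(min_value=0.1, max_value=20))
def test_agi_scale_invariance(a, b, c, d, e, gamma):
    assert agi(gamma * a, gamma * b, gamma * c, gamma * d, gamma * e) == \
        pytest.approx(agi(a, b, c, d, e), rel=1e-9, abs=1e-12)


def test_zero_crossings_examples():
    assert zero_crossings([1.0, -1.0]) == pytest.approx([0.5])
    assert zero_crossings([1.0, 2.0, 0.5]).size == 0
    t = np.arange(2000) / 1000.0
    zc = zero_crossings(np.sin(2 * np.pi * t))     # two periods at 1 Hz
    interior = zc[(zc > 0) & (zc < 1999)]
    assert np.allclose(interior, [500, 1000, 1500], atol=1.0)
    assert zero_crossings([1.0, 0.0, -1.0]) == pytest.approx([1.0])
    with pytest.raises(DetectionError):
        zero_crossings([1.0])


def test_wavefeatures_invariants():
    with pytest.raises(DetectionError):
        WaveFeatures(a=1, b=-1, c=0, d=0, e=0,
                     t_a=0.2, t_b=0.1, t_c=0.3, t_d=0.4, t_e=0.5)
    with pytest.raises(DetectionError):
        WaveFeatures(a=-1, b=-1, c=0, d=0, e=0,
                     t_a=0.1, t_b=0.2, t_c=0.3, t_d=0.4, t_e=0.5)
    f = WaveFeatures(a=2.0, b=-1.0, c=0.4, d=-0.6, e=0.2,
                     t_a=0.1, t_b=0.2, t_c=0.3, t_d=0.4, t_e=0.5)
    assert f.agi == pytest.approx((-1.0 - 0.4 + 0.6 - 0.2) / 2.0)
    assert f.ratio("b_over_a") == pytest.approx(-0.5)


def test_detect_on_clean_average_matches_annotation(clean_analysis):
    res, ann = clean_analysis
    f = res.averaged_features
    truth = ann.template
    for name in "abcde":
        assert getattr(f, "t_" + name) == pytest.approx(
            truth.times[name], abs=0.002)
    for name in "abcde":
        # derivative amplitudes carry the duration^2 normalization factor,
        # which cancels in ratios; compare ratios at 1 %
        assert getattr(f, name) / f.a == pytest.approx(
            truth.amplitudes[name] / truth.amplitudes["a"], abs=0.01)
    assert not f.fallback


def test_detect_scaling_homogeneity(clean_analysis):
    res, _ = clean_analysis
    avg = res.averaged
    scaled = AveragedWaveformSet(tau=avg.tau, ppg=10 * avg.ppg,
                                 sdppg=10 * avg.sdppg, d4=10 * avg.d4,
                                 n_beats=avg.n_beats)
    f0, f1 = detect_waves(avg), detect_waves(scaled)
    assert f1.a == pytest.approx(10 * f0.a, rel=1e-9)
    assert f1.agi == pytest.approx(f0.agi, rel=1e-9)
    assert f1.t_b == pytest.approx(f0.t_b, abs=1e-9)


def test_detect_error_reports_progress():
    # a waveform with no d4 sign change after its maximum
    tau = np.arange(-100, 400) / 1000.0
    sd = np.exp(-((tau - 0.05) ** 2) / 0.01)
    d4 = np.ones_like(tau)
    frame = AveragedWaveformSet(tau=tau, ppg=sd, sdppg=sd, d4=d4, n_beats=1)
    with pytest.raises(DetectionError, match="1 of 5"):
        detect_waves(frame)
    # window not covered at all
    frame2 = AveragedWaveformSet(tau=tau + 5.0, ppg=sd, sdppg=sd, d4=d4,
                                 n_beats=1)
    with pytest.raises(DetectionError, match="0 of 5"):
        detect_waves(frame2)


def test_per_beat_features_clean(clean_analysis):
    res, _ = clean_analysis
    feats = per_beat_features(res.beats)
    assert len(feats) == 15
    assert all(f is not None for f in feats)
    agis = [f.agi for f in feats]
    # identical jitter-free beats -> per-beat AGI equals averaged AGI
    assert np.allclose(agis, res.agi, atol=1e-4)
    assert [f.beat_index for f in feats] == list(range(15))


def test_per_beat_flags_corrupt_beat(clean_analysis):
    res, _ = clean_analysis
    import copy
    beats = [copy.deepcopy(b) for b in res.beats]
    beats[3].sdppg[:] = 0.0
    beats[3].d4[:] = 0.0
    feats = per_beat_features(beats)
    assert feats[3] is None
    assert sum(f is not None for f in feats) == 14
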