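import numpy as np
import pytest

import sdppg
from sdppg import (BeatTemplate, GenerationError, RecordingSpec,
                   annotate_template, attainable_agi_range, generate_cohort,
                   generate_recording, noise_rel_for_snr_db,
                   stiffness_for_agi, template_agi)
from sdppg.simulate import peak_to_peak


def test_same_seed_identical():
    tpl = BeatTemplate.from_stiffness(0.5)
    spec = RecordingSpec(n_beats=10, noise_rel=0.05, seed=42)
    s1, a1 = generate_recording(tpl, spec)
    s2, a2 = generate_recording(tpl, spec)
    assert np.array_equal(s1.samples, s2.samples)
    assert a1.beats.equals(a2.beats)
    s3, _ = generate_recording(tpl, RecordingSpec(n_beats=10, noise_rel=0.05,
                                                  seed=43))
    assert not np.array_equal(s1.samples, s3.samples)


def test_stiffness_bounds():
    with pytest.raises(GenerationError):
        BeatTemplate.from_stiffness(1.2)
    with pytest.raises(GenerationError):
        BeatTemplate.from_stiffness(-0.1)


def test_template_agi_strictly_monotone():
    s = np.linspace(0.0, 1.0, 41)
    vals = [template_agi(float(x)) for x in s]
    assert all(a < b for a, b in zip(vals, vals[1:]))
    for x in s:
        ann = annotate_template(BeatTemplate.from_stiffness(float(x)))
        assert ann.fallback == ()
        assert ann.amplitudes["a"] > 0 > ann.amplitudes["b"]


def test_inversion_roundtrip():
    lo, hi = attainable_agi_range()
    for target in np.linspace(lo + 0.05, hi - 0.05, 7):
        s = stiffness_for_agi(float(target))
        assert template_agi(s) == pytest.approx(float(target), abs=0.01)


def test_inversion_out_of_range_names_range():
    lo, hi = attainable_agi_range()
    with pytest.raises(GenerationError, match=f"{lo:.3f}"):
        stiffness_for_agi(lo - 1.0)
    with pytest.raises(GenerationError, match=f"{hi:.3f}"):
        stiffness_for_agi(hi + 1.0)


def test_annotation_pattern_and_times():
    ann = annotate_template(BeatTemplate.from_stiffness(0.3))
    t = ann.times
    assert t["a"] < t["b"] < t["c"] < t["d"] < t["e"]
    assert 0.0 <= ann.foot_phase < 1.0
    assert ann.agi == pytest.approx(
        (ann.amplitudes["b"] - ann.amplitudes["c"] - ann.amplitudes["d"]
         - ann.amplitudes["e"]) / ann.amplitudes["a"])


def test_noise_rel_for_snr():
    tpl = BeatTemplate.from_stiffness(0.4)
    r20 = noise_rel_for_snr_db(tpl, 20.0)
    r40 = noise_rel_for_snr_db(tpl, 40.0)
    assert r20 == pytest.approx(10.0 * r40)
    # realized noise SD over peak-to-peak matches the request
    spec0 = RecordingSpec(n_beats=8, period_jitter=0.0, drift_rel=0.0, seed=3)
    specn = RecordingSpec(n_beats=8, period_jitter=0.0, drift_rel=0.0, seed=3,
                          noise_rel=r20)
    clean, _ = generate_recording(tpl, spec0)
    noisy, _ = generate_recording(tpl, specn)
    realized = np.std(noisy.samples - clean.samples)
    assert realized == pytest.approx(r20 * peak_to_peak(tpl), rel=0.05)


def test_harmonic_concentration_without_jitter():
    # integer number of exact periods -> >= 95 % of AC power on harmonics
    tpl = BeatTemplate.from_stiffness(0.4)
    spec = RecordingSpec(n_beats=16, mean_period_s=1.0, period_jitter=0.0,
                         drift_rel=0.0, seed=0)
    sig, _ = generate_recording(tpl, spec)
    x = sig.samples - np.mean(sig.samples)
    spec_pow = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, 1.0 / sig.fs)
    near = np.abs(freqs - np.round(freqs)) <= 0.1
    frac = spec_pow[near & (freqs > 0.5)].sum() / spec_pow[freqs > 0.5].sum()
    assert frac >= 0.95


def test_noise_doubling_does_not_reduce_dispersion(mid_template):
    nr = noise_rel_for_snr_db(mid_template, 25.0)
    sds = {}
    for rel in (nr, 2 * nr):
        vals = []
        for seed in range(20):
            spec = RecordingSpec(n_beats=28, noise_rel=rel, seed=seed)
            sig, _ = generate_recording(mid_template, spec)
            vals.append(sdppg.analyze_signal(sig).sds["agi"])
        sds[rel] = float(np.mean(vals))
    assert sds[2 * nr] >= sds[nr]


def test_generate_cohort_structure():
    subs = generate_cohort(n_healthy=5, n_patient=3, seed=2,
                           build_templates=False)
    assert len(subs) == 8
    groups = [s.record.group for s in subs]
    assert groups.count("healthy") == 5 and groups.count("patient") == 3
    ids = [s.record.subject_id for s in subs]
    assert len(set(ids)) == 8
    seeds = [s.spec.seed for s in subs]
    assert len(set(seeds)) == 8
    only_h = generate_cohort(n_healthy=4, n_patient=0, seed=2,
                             build_templates=False)
    assert all(s.record.group == "healthy" for s in only_h)
    with pytest.raises(GenerationError):
        generate_cohort(n_healthy=0, n_patient=2)


def test_cohort_exact_model_targets():
    subs = generate_cohort(n_healthy=6, n_patient=4,
                           model=(0.019, -1.556, 0.0), patient_offset=0.359,
                           seed=9, build_templates=False)
    for s in subs:
        expect = 0.019 * s.record.age - 1.556
        if s.record.group == "patient":
            expect += 0.359
        assert s.record.agi == pytest.approx(expect, abs=1e-12)


def test_cohort_template_targets_within_tolerance():
    subs = generate_cohort(n_healthy=4, n_patient=2, seed=4,
                           build_templates=True)
    for s in subs:
        assert s.template is not None
        assert template_agi(s.template.stiffness) == pytest.approx(
            s.record.agi, abs=0.01)


def test_cohort_out_of_range_target():
    with pytest.raises(GenerationError, match="attainable"):
        generate_cohort(n_healthy=3, n_patient=0, model=(0.0, -25.0, 0.0),
                        seed=0, build_templates=True)


def test_annotation_csv(tmp_path, clean_recording):
    _, ann = clean_recording
    path = tmp_path / "truth.csv"
    ann.to_csv(path)
    import pandas as pd
    df = pd.read_csv(path)
    assert {"beat_index", "t_foot", "true_agi", "true_t_a"} <= set(df.columns)
    assert len(df) == 28
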