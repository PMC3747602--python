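import numpy as np
import pytest
from hypothesis import given, strategies as st

from sdppg import (CANONICAL_FS, CohortRecord, ConfigError, RunConfig,
                   SampledSignal, load_config, read_cohort, read_signal,
                   write_cohort, write_signal)
from sdppg.errors import SignalParseError
from sdppg.signal_io import read_features, write_features
from sdppg.waves import WaveFeatures


def test_signal_roundtrip(tmp_path):
    sig = SampledSignal(np.sin(np.arange(100) / 7.0), CANONICAL_FS, "x")
    path = tmp_path / "sig.csv"
    write_signal(sig, path)
    back = read_signal(path)
    assert back.fs == CANONICAL_FS
    assert np.allclose(back.samples, sig.samples, atol=1e-11)


def test_fs_precedence(tmp_path):
    path = tmp_path / "sig.csv"
    path.write_text("fs=500\n" + "\n".join(str(v) for v in range(50)) + "\n")
    assert read_signal(path, resample=False).fs == 500.0
    assert read_signal(path, fs_override=250.0, resample=False).fs == 250.0
    no_header = tmp_path / "plain.csv"
    no_header.write_text("\n".join(str(v) for v in range(50)) + "\n")
    assert read_signal(no_header, default_fs=100.0, resample=False).fs == 100.0
    with pytest.raises(ConfigError):
        read_signal(no_header)


def test_resampled_to_canonical(tmp_path):
    t = np.arange(200) / 100.0
    path = tmp_path / "slow.csv"
    write_signal(SampledSignal(np.sin(2 * np.pi * 2 * t), 100.0), path)
    back = read_signal(path)
    assert back.fs == CANONICAL_FS
    expected = np.sin(2 * np.pi * 2 * back.times)
    assert np.allclose(back.samples, expected, atol=1e-3)


def test_malformed_rows_report_position(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("1.0\n2.0\noops\n")
    with pytest.raises(SignalParseError, match="row 3"):
        read_signal(path, default_fs=100.0)
    path.write_text("fs=abc\n1.0\n")
    with pytest.raises(SignalParseError, match="fs header"):
        read_signal(path)
    path.write_text("1.0\nnan\n2.0\n")
    with pytest.raises(SignalParseError, match="row 2"):
        read_signal(path, default_fs=100.0)


def test_signal_validation():
    with pytest.raises(ConfigError):
        SampledSignal(np.zeros(10), -1.0)
    with pytest.raises(ConfigError):
        SampledSignal(np.zeros((2, 5)), 100.0)
    with pytest.raises(SignalParseError):
        SampledSignal(np.array([1.0, np.inf]), 100.0)


def test_runconfig_validation_and_replace():
    cfg = RunConfig()
    assert cfg.pm_edge_hz == 6.0 and cfg.n_beats == 15
    assert cfg.sweep_grid_hz == tuple(float(f) for f in range(4, 15))
    cfg2 = cfg.replace(pm_edge_hz=8.0)
    assert cfg2.pm_edge_hz == 8.0 and cfg.pm_edge_hz == 6.0
    with pytest.raises(ConfigError):
        RunConfig(pm_ripple=1.5)
    with pytest.raises(ConfigError):
        RunConfig(pm_edge_hz=0.0)
    with pytest.raises(ConfigError):
        RunConfig(pm_edge_hz=499.5)


def test_load_config(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("pm_edge_hz: 8\nn_beats: 9\n")
    cfg = load_config(path)
    assert cfg.pm_edge_hz == 8.0 and cfg.n_beats == 9
    path.write_text("bogus_key: 1\n")
    with pytest.raises(ConfigError, match="bogus_key"):
        load_config(path)


def _features(i=0):
    return WaveFeatures(a=1.0, b=-0.8, c=0.1, d=-0.2, e=0.05,
                        t_a=-0.05, t_b=0.06, t_c=0.16, t_d=0.23, t_e=0.3,
                        beat_index=i)


def test_features_roundtrip(tmp_path):
    path = tmp_path / "feat.csv"
    write_features([_features(0), _features(1)], path)
    df = read_features(path)
    assert len(df) == 2
    assert df.loc[0, "agi"] == pytest.approx((-0.8 - 0.1 + 0.2 - 0.05) / 1.0)
    with pytest.raises(ConfigError):
        write_features([], tmp_path / "empty.csv")
    (tmp_path / "short.csv").write_text("a,b\n1,2\n")
    with pytest.raises(SignalParseError):
        read_features(tmp_path / "short.csv")


def test_cohort_roundtrip(tmp_path):
    recs = [CohortRecord("h000", 30.0, "healthy", -1.0),
            CohortRecord("pat0", 55.0, "patient", -0.2, agi_sd=0.05)]
    path = tmp_path / "cohort.csv"
    write_cohort(recs, path)
    back = read_cohort(path)
    assert [r.subject_id for r in back] == ["h000", "pat0"]
    assert back[1].agi_sd == pytest.approx(0.05)
    path.write_text("subject_id,age,group,agi\nx,-3,healthy,0.1\n")
    with pytest.raises(SignalParseError, match="row 2"):
        read_cohort(path)


@given(st.lists(st.floats(min_value=-100, max_value=100, allow_nan=False),
                min_size=2, max_size=40))
def test_signal_write_read_any_values(tmp_path_factory, values):
    path = tmp_path_factory.mktemp("sig") / "s.csv"
    sig = SampledSignal(np.asarray(values), CANONICAL_FS)
    write_signal(sig, path)
    back = read_signal(path)
    assert np.allclose(back.samples, sig.samples, rtol=1e-10, atol=1e-10)
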