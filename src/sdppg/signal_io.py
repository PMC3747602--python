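"""Data containers, file readers/writers and run configuration.

The canonical processing rate is 1 kHz: the fixed FIR orders used by the
pipeline (500 for the 30 Hz low-pass, 4000 for the 0.5 Hz high-pass) only
have their designed responses at that rate, so signals read at other rates
are resampled to 1 kHz on ingestion.

File dialect is fixed: comma-separated, ``.`` decimal, UTF-8, LF.  Signal
files carry one sample per row with an optional single header row
``fs=<value>``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import CubicSpline

from .errors import ConfigError, SignalParseError

#: Canonical processing rate in Hz.  All filter orders below assume it.
CANONICAL_FS = 1000.0

GROUPS = ("healthy", "patient")


@dataclass
class SampledSignal:
    """A uniformly sampled real-valued series.

    Parameters
    ----------
    samples
        The sample values (arbitrary units for a PPG; derivative units scale
        accordingly).
    fs
        Sampling frequency in Hz.
    label
        Free-text description.
    t0
        Time of the first sample in seconds.  Filtering and differentiation
        trim their outputs to the fully supported region and advance ``t0``
        so that different stages stay aligned on the same timeline.
    """

    samples: np.ndarray
    fs: float
    label: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.fs > 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ConfigError("signal must be a 1-D series of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise SignalParseError("signal contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class CohortRecord:
    """One subject's entry in the cohort table."""

    subject_id: str
    age: float
    group: str
    agi: float
    agi_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not self.age > 0:
            raise ConfigError(f"age must be positive, got {self.age}")
        if self.agi_sd < 0:
            raise ConfigError(f"agi_sd must be non-negative, got {self.agi_sd}")


@dataclass
class RunConfig:
    """All tunable parameters of the analysis pipeline.

    Defaults reproduce the published operating point: band separation with a
    30 Hz low-pass (order 500) and 0.5 Hz high-pass (order 4000), a 5-point
    noise-robust differentiator, an equiripple low-pass with 6 Hz passband
    edge, 1 Hz transition band and 0.001 ripples applied after time
    normalization, and 15 beats per analysis.
    """

    lp_cutoff_hz: float = 30.0
    hp_cutoff_hz: float = 0.5
    lp_order: int = 500
    hp_order: int = 4000
    snrd_length: int = 5
    pm_edge_hz: float = 6.0
    pm_transition_hz: float = 1.0
    pm_ripple: float = 0.001
    n_beats: int = 15
    sweep_grid_hz: Sequence[float] = tuple(range(4, 15))
    #: a-e search window relative to the 50 %-rising-front reference, in
    #: seconds on the normalized 1 s base.
    search_start_s: float = -0.15
    search_end_s: float = 0.45
    #: physiological beat-duration bounds, seconds
    min_beat_s: float = 0.3
    max_beat_s: float = 2.0

    def __post_init__(self) -> None:
        for name in ("lp_cutoff_hz", "hp_cutoff_hz", "pm_edge_hz",
                     "pm_transition_hz"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")
        if not self.pm_edge_hz + self.pm_transition_hz < CANONICAL_FS / 2:
            raise ConfigError("PM stopband edge must lie below the Nyquist "
                              f"frequency ({CANONICAL_FS / 2:g} Hz)")
        if not 0 < self.pm_ripple < 1:
            raise ConfigError("pm_ripple must lie in (0, 1)")
        self.sweep_grid_hz = tuple(float(f) for f in self.sweep_grid_hz)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path) -> RunConfig:
    """Read a YAML file whose keys mirror :class:`RunConfig` fields."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _resample_to_canonical(samples: np.ndarray, fs: float) -> np.ndarray:
    """Cubic-spline resample to the canonical 1 kHz grid."""
    t_old = np.arange(samples.size) / fs
    spline = CubicSpline(t_old, samples)
    n_new = int(math.floor(t_old[-1] * CANONICAL_FS)) + 1
    return spline(np.arange(n_new) / CANONICAL_FS)


def read_signal(path, fs_override: Optional[float] = None,
                default_fs: Optional[float] = None,
                resample: bool = True) -> SampledSignal:
    """Read a one-sample-per-row signal file.

    The sampling rate is taken from ``fs_override`` if given, else from an
    ``fs=<value>`` header row, else from ``default_fs``.  Signals at rates
    other than 1 kHz are resampled to 1 kHz unless ``resample=False``.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh]
    lines = [ln for ln in lines if ln]
    fs_header = None
    if lines and lines[0].lower().startswith("fs="):
        try:
            fs_header = float(lines[0][3:])
        except ValueError as exc:
            raise SignalParseError(f"{path}: malformed fs header "
                                   f"{lines[0]!r}") from exc
        lines = lines[1:]
    fs = fs_override if fs_override is not None else (
        fs_header if fs_header is not None else default_fs)
    if fs is None:
        raise ConfigError(f"{path}: no sampling rate (no fs= header, no "
                          "override, no default)")
    samples = np.empty(len(lines))
    for i, ln in enumerate(lines):
        try:
            samples[i] = float(ln)
        except ValueError as exc:
            raise SignalParseError(
                f"{path}: non-numeric sample in data row {i + 1}: {ln!r}"
            ) from exc
    if not np.all(np.isfinite(samples)):
        bad = int(np.flatnonzero(~np.isfinite(samples))[0]) + 1
        raise SignalParseError(f"{path}: non-finite sample in data row {bad}")
    if resample and fs != CANONICAL_FS:
        samples = _resample_to_canonical(samples, fs)
        fs = CANONICAL_FS
    return SampledSignal(samples=samples, fs=fs, label=path.stem)


def write_signal(signal: SampledSignal, path) -> None:
    """Write a signal in the same dialect :func:`read_signal` accepts."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"fs={signal.fs:g}\n")
        for v in signal.samples:
            fh.write(f"{v:.12g}\n")


FEATURE_COLUMNS = ["beat_index", "a", "b", "c", "d", "e",
                   "t_a", "t_b", "t_c", "t_d", "t_e",
                   "b_over_a", "c_over_a", "d_over_a", "e_over_a", "agi"]


def write_features(features: Iterable, path) -> None:
    """Write a sequence of :class:`~sdppg.waves.WaveFeatures` rows to CSV.

    Values round-trip losslessly at >= 12 significant digits.
    """
    rows = []
    for i, f in enumerate(features):
        idx = getattr(f, "beat_index", None)
        rows.append([i if idx is None else idx,
                     f.a, f.b, f.c, f.d, f.e,
                     f.t_a, f.t_b, f.t_c, f.t_d, f.t_e,
                     f.b_over_a, f.c_over_a, f.d_over_a, f.e_over_a, f.agi])
    if not rows:
        raise ConfigError("refusing to write an empty feature table")
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise SignalParseError(f"{path}: missing feature columns {sorted(missing)}")
    return df


def write_cohort(records: Sequence[CohortRecord], path) -> None:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def read_cohort(path) -> list[CohortRecord]:
    df = pd.read_csv(path)
    required = {"subject_id", "age", "group", "agi"}
    missing = required - set(df.columns)
    if missing:
        raise SignalParseError(f"{path}: missing cohort columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(CohortRecord(
                subject_id=str(row["subject_id"]), age=float(row["age"]),
                group=str(row["group"]), agi=float(row["agi"]),
                agi_sd=float(row.get("agi_sd", 0.0) or 0.0)))
        except (ValueError, ConfigError) as exc:
            raise SignalParseError(f"{path}: bad cohort row {i + 2}: {exc}") from exc
    return records
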