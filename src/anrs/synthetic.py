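"""Synthetic hybrid tables and a tremor-signal feature pipeline.

Two generators make every other module testable without external data:

* :func:`generate_hybrid_dataset` draws decision tables with a controlled
  number of numeric and categorical attributes, class separation (distance
  between class centers in units of the unit within-class spread),
  categorical fidelity (probability of emitting the class's canonical token
  rather than a decoy), and label noise.
* :func:`simulate_tremor_signal` emulates a wrist-worn tri-axial
  accelerometer: each axis is a sinusoid at the tremor frequency with an
  axis-specific phase plus white Gaussian noise, sampled at 62.5 Hz by
  default.  :func:`extract_fft_features` turns a signal into one numeric
  record (per-axis dominant frequency, total power and band-power
  fractions), and :func:`tremor_feature_table` assembles a labeled
  high-amplitude vs low-amplitude feature table — the desk-scale analogue
  of a resting-tremor monitoring experiment.

Canonical categorical tokens are random letter strings, so decoys sit at
graded edit distances from the canonical token rather than plain
match/mismatch — deliberately exercising the graded string metric.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    CATEGORICAL,
    NUMERIC,
    HybridRecord,
    HybridSchema,
    HybridTable,
)
from .errors import ConfigurationError

#: physiological convention for resting tremor, not a measured value
DEFAULT_TREMOR_FREQ = 5.0
DEFAULT_FS = 62.5
DEFAULT_BANDS = ((0.0, 3.0), (3.0, 7.0), (7.0, 12.0), (12.0, 31.25))


@dataclass(frozen=True)
class SyntheticSpec:
    """Stated world for one synthetic decision table."""

    n: int = 200
    n_numeric: int = 4
    n_categorical: int = 2
    n_classes: int = 2
    separation: float = 3.0
    cat_fidelity: float = 0.9
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if self.n < self.n_classes:
            raise ConfigurationError("need at least one record per class")
        if self.n_numeric < 0 or self.n_categorical < 0:
            raise ConfigurationError("attribute counts must be nonnegative")
        if self.n_numeric + self.n_categorical == 0:
            raise ConfigurationError("need at least one condition attribute")
        if not (0.0 <= self.cat_fidelity <= 1.0):
            raise ConfigurationError("cat_fidelity must be in [0, 1]")
        if not (0.0 <= self.label_noise <= 1.0):
            raise ConfigurationError("label_noise must be in [0, 1]")
        if self.separation < 0:
            raise ConfigurationError("separation must be nonnegative")


def _random_token(rng: np.random.Generator, length: int = 5) -> str:
    letters = np.array(list(string.ascii_lowercase))
    return "".join(rng.choice(letters, size=length))


def generate_hybrid_dataset(spec: SyntheticSpec) -> HybridTable:
    """Draw a labeled hybrid decision table from the spec's stated world.

    Numeric attribute j has class-conditional mean ``class_index *
    separation / sqrt(n_numeric)`` and unit standard deviation, so the
    Euclidean distance between adjacent class centers equals ``separation``.
    Categorical attribute j emits its class's canonical token with
    probability ``cat_fidelity``, else a uniformly random decoy from the
    attribute's pool.  Labels are then flipped to a different class with
    probability ``label_noise``.  Fully deterministic given ``seed``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.arange(spec.n) % spec.n_classes
    rng.shuffle(labels)

    cols: dict[str, object] = {}
    if spec.n_numeric:
        offset = spec.separation / np.sqrt(spec.n_numeric)
        for j in range(spec.n_numeric):
            cols[f"num{j}"] = labels * offset + rng.normal(0.0, 1.0, size=spec.n)
    canon: dict[tuple[int, int], str] = {}
    for j in range(spec.n_categorical):
        pool = [_random_token(rng) for _ in range(spec.n_classes + 3)]
        for c in range(spec.n_classes):
            canon[(j, c)] = pool[c]
        use_canon = rng.random(spec.n) < spec.cat_fidelity
        decoys = rng.integers(0, len(pool), size=spec.n)
        cols[f"cat{j}"] = [
            pool[labels[i]] if use_canon[i] else pool[decoys[i]] for i in range(spec.n)
        ]

    flip = rng.random(spec.n) < spec.label_noise
    shift = rng.integers(1, spec.n_classes, size=spec.n)
    noisy = np.where(flip, (labels + shift) % spec.n_classes, labels)
    cols["class"] = [f"c{int(v)}" for v in noisy]

    attrs = tuple([(f"num{j}", NUMERIC) for j in range(spec.n_numeric)]) + tuple(
        [(f"cat{j}", CATEGORICAL) for j in range(spec.n_categorical)]
    )
    schema = HybridSchema(attributes=attrs, decision="class")
    return HybridTable(schema, pd.DataFrame(cols))


@dataclass(frozen=True)
class TriaxialSignal:
    """Equal-length x/y/z acceleration series sampled at ``fs`` Hz."""

    fs: float
    axes: tuple[np.ndarray, np.ndarray, np.ndarray]
    duration: float

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")
        n = round(self.fs * self.duration)
        for ax in self.axes:
            if len(ax) != n:
                raise ConfigurationError(
                    f"axis length {len(ax)} != round(fs * duration) = {n}"
                )


def simulate_tremor_signal(
    duration: float,
    fs: float = DEFAULT_FS,
    tremor_freq: float = DEFAULT_TREMOR_FREQ,
    amplitude: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> TriaxialSignal:
    """Tri-axial tremor-like oscillation with additive Gaussian noise.

    Each axis is ``amplitude * sin(2π f t + φ_axis)`` with axis phases
    0, 2π/3, 4π/3 plus ``N(0, noise_sd²)`` noise; deterministic given seed.
    """
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    if fs <= 0:
        raise ConfigurationError("sampling rate must be positive")
    if tremor_freq >= fs / 2:
        raise ConfigurationError(
            f"tremor frequency {tremor_freq} Hz is at or above Nyquist ({fs / 2} Hz)"
        )
    rng = np.random.default_rng(seed)
    n = round(fs * duration)
    t = np.arange(n) / fs
    axes = []
    for phase in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):
        clean = amplitude * np.sin(2 * np.pi * tremor_freq * t + phase)
        noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
        axes.append(clean + noise)
    return TriaxialSignal(fs=fs, axes=tuple(axes), duration=duration)


def _axis_features(
    x: np.ndarray, fs: float, bands: Sequence[tuple[float, float]]
) -> dict[str, float]:
    n = len(x)
    spec = np.fft.rfft(x)
    # one-sided power spectrum scaled so the sum equals the time-domain
    # mean square (Parseval)
    power = np.abs(spec) ** 2 / n**2
    if n % 2 == 0:
        power[1:-1] *= 2
    else:
        power[1:] *= 2
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    total = float(power.sum())
    dominant = float(freqs[int(np.argmax(power))]) if total > 0 else 0.0
    feats = {"dom_freq": dominant, "total_power": total}
    for lo, hi in bands:
        mask = (freqs >= lo) & (freqs < hi)
        feats[f"band_{lo:g}_{hi:g}"] = float(power[mask].sum() / total) if total > 0 else 0.0
    return feats


def extract_fft_features(
    signal: TriaxialSignal,
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
) -> HybridRecord:
    """One numeric record of spectral features for a tri-axial signal.

    Per axis: dominant frequency (Hz), total power (mean-square units), and
    the fraction of power inside each band.  Rectangular window, one-sided
    spectrum; band edges are ``[lo, hi)`` and must sit inside [0, Nyquist].
    """
    nyquist = signal.fs / 2
    prev_hi = None
    for lo, hi in bands:
        if lo < 0 or hi > nyquist or lo >= hi:
            raise ConfigurationError(f"band ({lo}, {hi}) outside [0, {nyquist}] Hz")
        if prev_hi is not None and lo < prev_hi:
            raise ConfigurationError("bands must be non-overlapping and ordered")
        prev_hi = hi
    values: dict[str, object] = {}
    for axis_name, x in zip(("x", "y", "z"), signal.axes):
        for key, val in _axis_features(np.asarray(x, dtype=float), signal.fs, bands).items():
            values[f"{axis_name}_{key}"] = val
    return HybridRecord(values=values, label=None)


def fft_feature_schema(
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
    decision: str = "class",
) -> HybridSchema:
    """Schema matching :func:`extract_fft_features` output (all numeric)."""
    names = ["dom_freq", "total_power"] + [f"band_{lo:g}_{hi:g}" for lo, hi in bands]
    attrs = tuple(
        (f"{axis}_{name}", NUMERIC) for axis in ("x", "y", "z") for name in names
    )
    return HybridSchema(attributes=attrs, decision=decision)


def tremor_feature_table(
    n_per_class: int = 30,
    amp_high: float = 1.0,
    amp_low: float = 0.0,
    noise_sd: float = 0.2,
    duration: float = 4.0,
    fs: float = DEFAULT_FS,
    tremor_freq: float = DEFAULT_TREMOR_FREQ,
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
    seed: int = 0,
) -> HybridTable:
    """Labeled feature table: high-amplitude ("tremor") vs low ("rest") signals.

    Simulates ``n_per_class`` signals per condition with fresh sub-seeds,
    featurizes each, and stacks them into one numeric decision table.
    """
    if n_per_class < 1:
        raise ConfigurationError("need at least one signal per class")
    rng = np.random.default_rng(seed)
    schema = fft_feature_schema(bands)
    rows = []
    labels = []
    for label, amp in (("tremor", amp_high), ("rest", amp_low)):
        for _ in range(n_per_class):
            sub = int(rng.integers(0, 2**31 - 1))
            sig = simulate_tremor_signal(
                duration=duration,
                fs=fs,
                tremor_freq=tremor_freq,
                amplitude=amp,
                noise_sd=noise_sd,
                seed=sub,
            )
            rows.append(extract_fft_features(sig, bands).values)
            labels.append(label)
    df = pd.DataFrame(rows)
    df[schema.decision] = labels
    return HybridTable(schema, df)


def signal_to_frame(signal: TriaxialSignal) -> pd.DataFrame:
    """Plain (t, x, y, z) frame for CSV export of a simulated signal."""
    n = len(signal.axes[0])
    return pd.DataFrame(
        {
            "t": np.arange(n) / signal.fs,
            "x": signal.axes[0],
            "y": signal.axes[1],
            "z": signal.axes[2],
        }
    )
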