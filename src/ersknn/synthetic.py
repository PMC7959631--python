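"""Synthetic multichannel trial generation with known ground truth.

Motor-imagery classes differ by event-related desynchronisation and
synchronisation: the spatial distribution of 8-30 Hz band power shifts with
the imagined movement.  The generator reproduces exactly that structure —
and nothing else.  Each trial is

    x(t) = M s(t) + noise,

where the columns of the mixing matrix M are fixed source topographies,
s(t) are independent band-limited Gaussian sources (white noise through
the same 8-30 Hz third-order Butterworth filter the pipeline uses,
normalised to unit variance), and the per-class, per-source variance
multipliers ``class_power`` carry all class information.  Channels listed
as noise channels have their mixing rows zeroed and carry background noise
only.  The per-class channel covariance therefore converges to

    M diag(class_power[c]) M^T + noise_sd^2 I,

the exact model CSP assumes, and the ideal unmixing directions (rows of
the pseudo-inverse of M) are recorded as ground truth.

A second generator emits plain feature tables (class-shifted informative
columns among pure-noise columns) to exercise the feature selector and
classifier without the signal stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .csp import FeatureMatrix
from .trials_io import TrialSet

_DEF_RATIO = 4.0


def _default_mixing(n_channels: int, n_sources: int, n_noise: int, seed: int) -> np.ndarray:
    """Random orthonormal source topographies over the informative channels."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    n_inf = n_channels - n_noise
    gauss = rng.standard_normal((n_inf, n_sources))
    q, _ = np.linalg.qr(gauss)
    mixing = np.zeros((n_channels, n_sources))
    mixing[:n_inf] = q[:, :n_sources]
    return mixing


def _default_class_power(n_classes: int, ratio: float = _DEF_RATIO) -> np.ndarray:
    """One elevated source per class: class c has power ``ratio`` on source c."""
    power = np.ones((n_classes, n_classes))
    np.fill_diagonal(power, ratio)
    return power


@dataclass
class SyntheticSpec:
    """Parameters of the trial generator.

    Defaults echo a desk-scale motor-imagery recording: 8 channels (2 of
    them pure noise), 50 trials per class, 250 Hz, 2-second epochs, sources
    band-limited to 8-30 Hz, and a 4:1 per-class band-power ratio along one
    planted source direction per class.
    """

    n_classes: int = 2
    n_channels: int = 8
    n_trials_per_class: int = 50
    fs: float = 250.0
    duration_s: float = 2.0
    source_band: tuple[float, float] = (8.0, 30.0)
    class_power: np.ndarray | None = None
    mixing: np.ndarray | None = None
    noise_sd: float = 1.0
    n_noise_channels: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError(f"n_classes must be >= 1; got {self.n_classes}")
        if self.n_trials_per_class < 1:
            raise ValueError(
                f"n_trials_per_class must be >= 1; got {self.n_trials_per_class}"
            )
        if self.fs <= 0:
            raise ValueError(f"fs must be positive; got {self.fs}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive; got {self.duration_s}")
        if not (0 < self.source_band[0] < self.source_band[1] < self.fs / 2):
            raise ValueError(f"source_band {self.source_band} invalid for fs={self.fs}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0; got {self.noise_sd}")
        if self.class_power is None:
            self.class_power = _default_class_power(self.n_classes)
        self.class_power = np.atleast_2d(np.asarray(self.class_power, dtype=np.float64))
        if self.class_power.shape[0] != self.n_classes:
            raise ValueError(
                f"class_power has {self.class_power.shape[0]} rows for "
                f"{self.n_classes} classes"
            )
        n_sources = self.class_power.shape[1]
        if not (0 <= self.n_noise_channels <= self.n_channels - n_sources):
            raise ValueError(
                f"n_noise_channels={self.n_noise_channels} leaves fewer than "
                f"{n_sources} informative channels of {self.n_channels}"
            )
        if self.mixing is None:
            self.mixing = _default_mixing(
                self.n_channels, n_sources, self.n_noise_channels, self.seed
            )
        self.mixing = np.asarray(self.mixing, dtype=np.float64)
        if self.mixing.shape != (self.n_channels, n_sources):
            raise ValueError(
                f"mixing shape {self.mixing.shape} != "
                f"({self.n_channels}, {n_sources})"
            )
        if np.linalg.matrix_rank(self.mixing) < n_sources:
            raise ValueError("mixing matrix is not full column rank")
        if self.n_classes > 1 and np.unique(self.class_power, axis=0).shape[0] < self.n_classes:
            raise ValueError(
                "class_power rows must be distinct between classes, "
                "else classes are indistinguishable by construction"
            )

    @property
    def n_sources(self) -> int:
        return self.class_power.shape[1]


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    mixing: np.ndarray
    unmixing: np.ndarray           # rows recover the sources (pinv of mixing)
    informative_channels: np.ndarray
    class_power: np.ndarray
    expected_covariances: np.ndarray = field(default=None)  # per class


def generate(spec: SyntheticSpec) -> tuple[TrialSet, GroundTruth]:
    """Draw a TrialSet from the spec; same seed, same data, bit for bit."""
    n_samp = int(round(spec.duration_s * spec.fs))
    sos = signal.butter(
        3, list(spec.source_band), btype="bandpass", fs=spec.fs, output="sos"
    )
    n_total = spec.n_classes * spec.n_trials_per_class
    labels = np.repeat(np.arange(spec.n_classes), spec.n_trials_per_class)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1,)))
    data = np.empty((n_total, spec.n_channels, n_samp))
    # generous pad so the filter reaches steady state before the epoch
    pad = max(n_samp // 2, 200)
    for i, c in enumerate(labels):
        white = rng.standard_normal((spec.n_sources, n_samp + 2 * pad))
        src = signal.sosfiltfilt(sos, white, axis=-1)[:, pad:-pad]
        src = src / src.std(axis=-1, keepdims=True)
        src *= np.sqrt(spec.class_power[c])[:, None]
        noise = spec.noise_sd * rng.standard_normal((spec.n_channels, n_samp))
        data[i] = spec.mixing @ src + noise
    inf_channels = np.flatnonzero(np.abs(spec.mixing).sum(axis=1) > 0)
    expected = np.stack(
        [
            spec.mixing @ np.diag(spec.class_power[c]) @ spec.mixing.T
            + spec.noise_sd**2 * np.eye(spec.n_channels)
            for c in range(spec.n_classes)
        ]
    )
    tset = TrialSet(
        data=data,
        labels=labels,
        fs=spec.fs,
        class_names=[f"task{c + 1}" for c in range(spec.n_classes)],
    )
    truth = GroundTruth(
        mixing=spec.mixing.copy(),
        unmixing=np.linalg.pinv(spec.mixing),
        informative_channels=inf_channels,
        class_power=spec.class_power.copy(),
        expected_covariances=expected,
    )
    return tset, truth


def generate_feature_table(
    n_informative: int,
    n_noise: int,
    n_samples: int,
    effect: float,
    seed: int = 0,
    n_classes: int = 2,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Feature table with class-shifted informative columns among pure noise.

    Informative columns are unit-variance Gaussian with a between-class
    mean separation of ``effect`` standard deviations; noise columns are
    label-independent N(0, 1).  Labels are balanced.  Returns the matrix
    and the informative column indices (the first ``n_informative``).
    """
    if n_informative < 1 or n_noise < 0 or n_samples < n_classes:
        raise ValueError(
            f"invalid sizes: n_informative={n_informative}, n_noise={n_noise}, "
            f"n_samples={n_samples}"
        )
    rng = np.random.default_rng(seed)
    labels = np.tile(np.arange(n_classes), n_samples // n_classes + 1)[:n_samples]
    p = n_informative + n_noise
    values = rng.standard_normal((n_samples, p))
    shift = effect * (labels / max(n_classes - 1, 1))  # 0..effect across classes
    values[:, :n_informative] += shift[:, None]
    names = [f"inf{j}" for j in range(n_informative)] + [
        f"noise{j}" for j in range(n_noise)
    ]
    fm = FeatureMatrix(values=values, feature_names=names, labels=labels)
    return fm, np.arange(n_informative)
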