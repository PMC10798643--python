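"""Synthetic epoched EEG and odd-one-out triplet generators.

The EEG generator emits pre-epoched data (events x channels x time) on the
standard grid of -100..600 ms at 250 Hz.  Feature-selective signals are
injected as level-specific spatial patterns modulated by an asymmetric
temporal bump with a controllable onset and peak; conjunction-selective
signals use double-centred cell patterns so they add no single-feature
information.  Noise is Gaussian, spatially correlated across channels with
distance decay and AR(1)-correlated in time.

The triplet generator draws odd-one-out choices from a softmax over summed
pairwise dissimilarities, where the ground-truth dissimilarity is a
weighted sum of the four feature-model RDMs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimuli import (
    FEATURES,
    N_LEVELS,
    N_STIMULI,
    SequenceDesign,
    StimulusSet,
    build_stimulus_set,
    _check_feature,
)

DEFAULT_TIMES_MS = np.arange(-100, 601, 4)  # 250 Hz epochs, 176 samples


@dataclass(frozen=True)
class SignalComponent:
    """One injected signal: a spatial pattern set with a temporal envelope.

    onset_ms/peak_ms place the envelope; amplitude scales the (unit-norm)
    spatial patterns.  pattern_seed fixes the patterns independently of the
    subject (e.g. to share topographies across a group); left None, each
    subject draws its own patterns from its subject seed, mimicking
    idiosyncratic sensor topographies.  ``graded`` interpolates the four
    level patterns between two anchors so that nearby levels have similar
    patterns (needed for the neural RDM to mirror a rank model).
    """

    onset_ms: float
    peak_ms: float
    amplitude: float
    pattern_seed: int | None = None
    graded: bool = False

    def __post_init__(self):
        if not self.onset_ms < self.peak_ms:
            raise ValueError("onset_ms must be < peak_ms")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class SignalSpec:
    """Which features/conjunctions carry signal, and the envelope decay."""

    features: dict = field(default_factory=dict)       # feature -> SignalComponent
    conjunctions: dict = field(default_factory=dict)   # (feat_a, feat_b) -> SignalComponent
    width_ms: float = 60.0

    def __post_init__(self):
        for f in self.features:
            _check_feature(f)
        for a, b in self.conjunctions:
            _check_feature(a)
            _check_feature(b)
            if a == b:
                raise ValueError("conjunction features must differ")
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    channel_noise_sd: float = 1.0
    spatial_correlation: float = 0.3
    temporal_autocorrelation: float = 0.3

    def __post_init__(self):
        if self.channel_noise_sd <= 0:
            raise ValueError("channel_noise_sd must be positive")
        for name in ("spatial_correlation", "temporal_autocorrelation"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")


@dataclass
class EpochedDataset:
    """Per-subject epoched data with event metadata.

    data: (n_events, n_channels, n_times) array, arbitrary units.
    events: DataFrame with sequence, position, stimulus_id and the four
    ``<feature>_level`` columns.  channel_positions: (n_channels, 3) unit
    sphere coordinates.
    """

    subject_id: str
    data: np.ndarray
    times: np.ndarray
    events: pd.DataFrame
    channel_positions: np.ndarray

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("data must be events x channels x times")
        if len(self.events) != self.data.shape[0]:
            raise ValueError("event metadata rows must match data's first axis")
        if len(self.times) != self.data.shape[2]:
            raise ValueError("times length must match data's last axis")
        steps = np.diff(self.times)
        if len(steps) and not (np.all(steps > 0) and np.allclose(steps, steps[0])):
            raise ValueError("times must be strictly increasing on a uniform grid")
        if self.channel_positions.shape != (self.data.shape[1], 3):
            raise ValueError("channel_positions must be n_channels x 3")

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class TripletSet:
    """Odd-one-out judgements: columns participant_id, stim1..3, chosen."""

    trials: pd.DataFrame

    def __post_init__(self):
        trio = self.trials[["stim1", "stim2", "stim3"]].to_numpy()
        chosen = self.trials["chosen"].to_numpy()
        if not (trio == chosen[:, None]).any(axis=1).all():
            raise ValueError("every chosen id must be a member of its triple")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False)


def default_signal_spec(
    amplitude_scale: float = 1.0, graded: bool = False
) -> SignalSpec:
    """Signal spec echoing the observed feature-coding dynamics.

    Onsets/peaks follow the estimated latencies for the four features:
    contrast earliest-peaking (96 ms), SF and colour at 112 ms, orientation
    latest (120 ms) with a later onset and a weaker amplitude (orientation
    coding is reliably the weakest feature).  Amplitudes are in units of
    per-channel noise SD.
    """
    return SignalSpec(
        features={
            "contrast": SignalComponent(72, 96, 1.4 * amplitude_scale, None, graded),
            "sf": SignalComponent(72, 112, 1.2 * amplitude_scale, None, graded),
            "colour": SignalComponent(72, 112, 1.2 * amplitude_scale, None, graded),
            "orientation": SignalComponent(92, 120, 0.8 * amplitude_scale, None, graded),
        },
    )


def channel_layout(n_channels: int) -> np.ndarray:
    """Deterministic quasi-uniform sensor positions on the upper unit sphere.

    A Fibonacci lattice restricted to z >= 0, standing in for a scalp
    montage; only relative distances matter (searchlight neighbourhoods).
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    i = np.arange(n_channels)
    golden = (1 + 5**0.5) / 2
    z = i / max(n_channels - 1, 1)  # upper hemisphere
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    theta = 2 * np.pi * i / golden
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def _envelope(times_ms: np.ndarray, onset: float, peak: float, width: float) -> np.ndarray:
    """Gamma-like bump: 0 before onset, 1 at peak, exponential decay ~width."""
    u = np.asarray(times_ms, dtype=float) - onset
    r = peak - onset
    k = r / width
    with np.errstate(divide="ignore", invalid="ignore"):
        env = np.where(u > 0, (u / r) ** k * np.exp(k * (1 - u / r)), 0.0)
    return env


def _level_patterns(rng: np.random.Generator, n_channels: int, graded: bool) -> np.ndarray:
    """(4, n_channels) unit-norm, channel-mean-centred patterns per level."""
    if graded:
        anchors = rng.standard_normal((2, n_channels))
        w = np.linspace(0, 1, N_LEVELS)[:, None]
        pats = (1 - w) * anchors[0] + w * anchors[1]
    else:
        pats = rng.standard_normal((N_LEVELS, n_channels))
    pats = pats - pats.mean(axis=1, keepdims=True)
    return pats / np.linalg.norm(pats, axis=1, keepdims=True)


def _cell_patterns(rng: np.random.Generator, n_channels: int) -> np.ndarray:
    """(4, 4, n_channels) conjunction-cell patterns, double-centred.

    Removing the per-level marginal means over both features guarantees the
    injected signal carries no additive single-feature component: the mean
    pattern at any level of either feature is exactly zero.
    """
    pats = rng.standard_normal((N_LEVELS, N_LEVELS, n_channels))
    pats = pats - pats.mean(axis=0, keepdims=True)
    pats = pats - pats.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(pats.reshape(-1, n_channels), axis=1).mean()
    return pats / norm


def _spatial_chol(positions: np.ndarray, rho: float, sd: float) -> np.ndarray:
    n = len(positions)
    if rho == 0:
        return sd * np.eye(n)
    d = np.linalg.norm(positions[:, None] - positions[None, :], axis=2)
    scale = np.median(d[np.triu_indices(n, 1)])
    cov = sd**2 * rho ** (d / scale)  # exponential kernel, positive definite
    return np.linalg.cholesky(cov + 1e-10 * sd**2 * np.eye(n))


def generate_epochs(
    design: SequenceDesign,
    n_channels: int,
    signal: SignalSpec,
    noise: NoiseSpec,
    subject_seed: int,
    subject_id: str | None = None,
    stimuli: StimulusSet | None = None,
    times_ms: np.ndarray = DEFAULT_TIMES_MS,
    dtype=np.float32,
) -> EpochedDataset:
    """Simulate one subject's epoched responses to a sequence design.

    Each event's response is the sum over injected components of
    pattern(level or cell) * envelope(t) * amplitude, plus correlated noise.
    Bit-identical for identical seeds.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    times_ms = np.asarray(times_ms, dtype=float)
    for comp in list(signal.features.values()) + list(signal.conjunctions.values()):
        if not (times_ms[0] <= comp.onset_ms and comp.peak_ms <= times_ms[-1]):
            raise ValueError(
                f"envelope (onset {comp.onset_ms}, peak {comp.peak_ms}) outside "
                f"time grid [{times_ms[0]}, {times_ms[-1]}]"
            )

    stimuli = stimuli if stimuli is not None else build_stimulus_set()
    events = design.events.merge(
        stimuli.table[["stimulus_id"] + [f + "_level" for f in FEATURES]],
        on="stimulus_id",
        how="left",
        sort=False,
    )
    n_events, n_times = len(events), len(times_ms)

    root = np.random.SeedSequence(subject_seed)
    noise_ss, pattern_ss = root.spawn(2)
    rng = np.random.default_rng(noise_ss)
    # per-component pattern streams: explicit pattern_seed overrides the
    # subject-derived stream (shared topographies across subjects)
    pattern_children = iter(
        pattern_ss.spawn(len(signal.features) + len(signal.conjunctions))
    )

    def pattern_rng(comp):
        child = next(pattern_children)
        if comp.pattern_seed is not None:
            return np.random.default_rng(comp.pattern_seed)
        return np.random.default_rng(child)

    positions = channel_layout(n_channels)

    data = np.zeros((n_events, n_channels, n_times), dtype=dtype)
    for feat, comp in signal.features.items():
        pats = _level_patterns(pattern_rng(comp), n_channels, comp.graded)
        env = _envelope(times_ms, comp.onset_ms, comp.peak_ms, signal.width_ms)
        lv = events[feat + "_level"].to_numpy()
        data += (comp.amplitude * pats[lv][:, :, None] * env[None, None, :]).astype(dtype)
    for (fa, fb), comp in signal.conjunctions.items():
        pats = _cell_patterns(pattern_rng(comp), n_channels)
        env = _envelope(times_ms, comp.onset_ms, comp.peak_ms, signal.width_ms)
        la = events[fa + "_level"].to_numpy()
        lb = events[fb + "_level"].to_numpy()
        data += (comp.amplitude * pats[la, lb][:, :, None] * env[None, None, :]).astype(dtype)

    # noise: innovations spatially correlated via Cholesky, AR(1) over time
    chol = _spatial_chol(positions, noise.spatial_correlation, noise.channel_noise_sd)
    a = noise.temporal_autocorrelation
    innov_scale = np.sqrt(1 - a**2)
    white = rng.standard_normal((n_events, n_times, n_channels)).astype(dtype)
    eps = white @ chol.T.astype(dtype)  # (events, times, channels)
    noise_arr = np.empty_like(eps)
    noise_arr[:, 0, :] = eps[:, 0, :]
    for t in range(1, n_times):
        noise_arr[:, t, :] = a * noise_arr[:, t - 1, :] + innov_scale * eps[:, t, :]
    data += noise_arr.transpose(0, 2, 1)

    return EpochedDataset(
        subject_id=subject_id if subject_id is not None else f"sim-{subject_seed}",
        data=data,
        times=times_ms,
        events=events,
        channel_positions=positions,
    )


def ground_truth_rdm(weights: dict) -> np.ndarray:
    """Weighted sum of the four feature-model RDMs (256 x 256)."""
    from .rsa import build_feature_model_rdm

    stimuli = build_stimulus_set()
    total = np.zeros((N_STIMULI, N_STIMULI))
    for feat, w in weights.items():
        _check_feature(feat)
        if w < 0:
            raise ValueError("weights must be non-negative")
        total += w * build_feature_model_rdm(feat, stimuli).values
    return total


def generate_triplets(
    weights: dict,
    n_participants: int,
    n_trials_per_participant: int,
    decision_noise_beta: float = 2.0,
    seed: int = 0,
    n_stimuli: int = N_STIMULI,
) -> TripletSet:
    """Simulate odd-one-out choices from weighted feature dissimilarities.

    Each trial samples 3 distinct stimuli uniformly; the odd one out x among
    {x, y, z} is chosen with probability proportional to
    exp(beta * (d(x,y) + d(x,z))), d being the weighted model distance.
    """
    if not any(w > 0 for w in weights.values()):
        raise ValueError("at least one weight must be positive")
    if decision_noise_beta <= 0:
        raise ValueError("decision_noise_beta must be positive")
    if n_stimuli < 3:
        raise ValueError("need at least 3 stimuli")
    D = ground_truth_rdm(weights)[:n_stimuli, :n_stimuli]

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_trials = n_participants * n_trials_per_participant
    trios = rng.integers(0, n_stimuli, size=(n_trials, 3))
    bad = (
        (trios[:, 0] == trios[:, 1])
        | (trios[:, 0] == trios[:, 2])
        | (trios[:, 1] == trios[:, 2])
    )
    while bad.any():
        trios[bad] = rng.integers(0, n_stimuli, size=(int(bad.sum()), 3))
        bad = (
            (trios[:, 0] == trios[:, 1])
            | (trios[:, 0] == trios[:, 2])
            | (trios[:, 1] == trios[:, 2])
        )

    # oddness score of each item = summed distance to the two others
    d01 = D[trios[:, 0], trios[:, 1]]
    d02 = D[trios[:, 0], trios[:, 2]]
    d12 = D[trios[:, 1], trios[:, 2]]
    scores = np.stack([d01 + d02, d01 + d12, d02 + d12], axis=1)
    logits = decision_noise_beta * scores
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(n_trials)
    choice_idx = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
    chosen = trios[np.arange(n_trials), choice_idx]

    trials = pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(n_participants), n_trials_per_participant),
            "stim1": trios[:, 0],
            "stim2": trios[:, 1],
            "stim3": trios[:, 2],
            "chosen": chosen,
        }
    )
    return TripletSet(trials=trials)
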