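"""Factorial stimulus space and experimental design combinatorics.

The stimulus set is a 4x4x4x4 factorial grid over orientation, spatial
frequency (SF), colour and contrast (256 gratings).  All analyses operate on
integer feature levels 0..3; the physical values (degrees, cycles/degree,
Michelson contrast, colour index) are carried as metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable

import numpy as np
import pandas as pd

#: Canonical feature order used throughout the package.
FEATURES = ("orientation", "sf", "colour", "contrast")

#: Physical values per level, ordered to match levels 0..3.
PHYSICAL_VALUES = {
    "orientation": (22.5, 67.5, 112.5, 157.5),  # degrees, circularly spaced
    "sf": (2.17, 1.58, 0.98, 0.39),             # cycles / degree
    "colour": (0, 1, 2, 3),                     # index into the colour list
    "contrast": (0.9, 0.7, 0.5, 0.3),
}

N_LEVELS = 4
N_STIMULI = N_LEVELS ** len(FEATURES)

#: Presentation rates (Hz) used in the rapid-presentation design.
RATES = (6.67, 20.0)


def _level_columns() -> list[str]:
    return [f + "_level" for f in FEATURES]


@dataclass(frozen=True)
class StimulusSet:
    """The full factorial stimulus set.

    ``table`` has one row per stimulus with columns ``stimulus_id``,
    ``<feature>_level`` for each feature, and ``<feature>_value`` with the
    physical value.  ``stimulus_id`` encodes the levels in mixed radix
    (orientation most significant), so the map levels -> id is a bijection.
    """

    table: pd.DataFrame

    @property
    def n_stimuli(self) -> int:
        return len(self.table)

    def levels(self, feature: str) -> np.ndarray:
        """Per-stimulus integer level of ``feature``, indexed by stimulus_id."""
        _check_feature(feature)
        return self.table[feature + "_level"].to_numpy()

    def stimulus_id(self, orientation: int, sf: int, colour: int, contrast: int) -> int:
        for lv in (orientation, sf, colour, contrast):
            _check_level(lv)
        return ((orientation * N_LEVELS + sf) * N_LEVELS + colour) * N_LEVELS + contrast

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def build_stimulus_set() -> StimulusSet:
    """Enumerate all 256 feature combinations.

    Deterministic; stimulus_id runs 0..255 in lexicographic level order.
    """
    rows = []
    for sid, levels in enumerate(product(range(N_LEVELS), repeat=len(FEATURES))):
        row = {"stimulus_id": sid}
        for feat, lv in zip(FEATURES, levels):
            row[feat + "_level"] = lv
            row[feat + "_value"] = PHYSICAL_VALUES[feat][lv]
        rows.append(row)
    return StimulusSet(table=pd.DataFrame(rows))


@dataclass(frozen=True)
class SequenceDesign:
    """Ordered presentation events for one rate condition.

    Each sequence is a permutation of all 256 stimulus ids, so every
    stimulus appears exactly once per sequence.  ``events`` columns:
    ``sequence``, ``position`` (0..255 within sequence), ``stimulus_id``.
    """

    rate: float
    events: pd.DataFrame

    @property
    def n_sequences(self) -> int:
        return int(self.events["sequence"].nunique())

    @property
    def n_events(self) -> int:
        return len(self.events)

    def to_tsv(self, path) -> None:
        self.events.to_csv(path, sep="\t", index=False)


def build_sequences(n_sequences: int, rate: float = 6.67, seed: int = 0) -> SequenceDesign:
    """Draw ``n_sequences`` independent random orderings of the stimulus set.

    One master seed spawns per-sequence child seeds so partial designs are
    reproducible prefixes of longer ones.
    """
    if n_sequences < 1:
        raise ValueError(f"n_sequences must be >= 1, got {n_sequences}")
    if rate not in RATES:
        raise ValueError(f"rate must be one of {RATES}, got {rate}")
    children = np.random.SeedSequence(seed).spawn(n_sequences)
    frames = []
    for s, child in enumerate(children):
        order = np.random.default_rng(child).permutation(N_STIMULI)
        frames.append(
            pd.DataFrame(
                {"sequence": s, "position": np.arange(N_STIMULI), "stimulus_id": order}
            )
        )
    return SequenceDesign(rate=rate, events=pd.concat(frames, ignore_index=True))


@dataclass(frozen=True)
class ConjunctionContrast:
    """A two-class split of a 2x2 cell grid that no single feature separates.

    Two levels are chosen for each of two features; the four (level_a,
    level_b) cells are split into "diagonal" classes, e.g. {(1,1),(2,2)}
    versus {(1,2),(2,1)}.  Both classes then contain the same levels of
    feature_a and the same levels of feature_b, so only a response to the
    *combination* of the two features can separate them.
    """

    feature_a: str
    feature_b: str
    levels_a: tuple[int, int]
    levels_b: tuple[int, int]
    class1_cells: frozenset = field(default_factory=frozenset)
    class2_cells: frozenset = field(default_factory=frozenset)

    def class_stimuli(self, stimuli: StimulusSet) -> tuple[np.ndarray, np.ndarray]:
        """Stimulus ids in each class, expanded over the untouched features."""
        la = stimuli.levels(self.feature_a)
        lb = stimuli.levels(self.feature_b)
        ids = stimuli.table["stimulus_id"].to_numpy()
        cells = np.stack([la, lb], axis=1)
        in1 = np.array([tuple(c) in self.class1_cells for c in cells])
        in2 = np.array([tuple(c) in self.class2_cells for c in cells])
        return ids[in1], ids[in2]


def enumerate_conjunction_contrasts(feature_a: str, feature_b: str) -> list[ConjunctionContrast]:
    """All 36 conjunction contrasts for a feature pair.

    For each unordered pair of levels of each feature (6 x 6 choices) the
    2x2 grid admits exactly one two-cell/two-cell split that is balanced on
    both features: the diagonal split.  Swapping class labels is not a new
    contrast; the class containing (min level_a, min level_b) is class 1.
    """
    _check_feature(feature_a)
    _check_feature(feature_b)
    if feature_a == feature_b:
        raise ValueError("feature_a and feature_b must differ")
    contrasts = []
    for la1, la2 in combinations(range(N_LEVELS), 2):
        for lb1, lb2 in combinations(range(N_LEVELS), 2):
            class1 = frozenset({(la1, lb1), (la2, lb2)})
            class2 = frozenset({(la1, lb2), (la2, lb1)})
            contrasts.append(
                ConjunctionContrast(
                    feature_a=feature_a,
                    feature_b=feature_b,
                    levels_a=(la1, la2),
                    levels_b=(lb1, lb2),
                    class1_cells=class1,
                    class2_cells=class2,
                )
            )
    return contrasts


def select_interaction_subset(
    stimuli: StimulusSet, conditioning_feature: str, level: int
) -> np.ndarray:
    """Stimulus ids with ``conditioning_feature`` fixed at ``level`` (64 ids)."""
    _check_feature(conditioning_feature)
    _check_level(level)
    mask = stimuli.levels(conditioning_feature) == level
    return stimuli.table.loc[mask, "stimulus_id"].to_numpy()


def _check_feature(feature: str) -> None:
    if feature not in FEATURES:
        raise ValueError(f"unknown feature {feature!r}; expected one of {FEATURES}")


def _check_level(level: int) -> None:
    if not (isinstance(level, (int, np.integer)) and 0 <= level < N_LEVELS):
        raise ValueError(f"level must be an integer in 0..{N_LEVELS - 1}, got {level!r}")
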