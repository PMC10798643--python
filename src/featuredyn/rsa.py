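"""Representational dissimilarity matrices and their comparison.

Feature-model RDMs use rank distance between levels (circular for
orientation); behavioural RDMs come from odd-one-out triplet judgements;
neural RDMs come from pairwise decoding (module ``decoding``).  RDMs are
compared by Spearman correlation over lower-triangle entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .simulate import TripletSet
from .stimuli import N_STIMULI, StimulusSet, build_stimulus_set, _check_feature


@dataclass
class RDM:
    """Symmetric stimulus x stimulus dissimilarity matrix.

    Missing entries (behavioural pairs never co-presented) are NaN and are
    pairwise-deleted in correlations.  For behavioural RDMs the raw pair
    co-presentation and "survival" (third item chosen) counts are kept.
    """

    stimulus_ids: np.ndarray
    values: np.ndarray
    kind: str  # model | behavioural | neural
    pair_counts: np.ndarray | None = field(default=None, repr=False)
    survival_counts: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.stimulus_ids = np.asarray(self.stimulus_ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.stimulus_ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be square on stimulus_ids")
        finite = ~np.isnan(self.values)
        if not np.allclose(
            self.values[finite & finite.T], self.values.T[finite & finite.T]
        ):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(self.values), 0, equal_nan=False):
            raise ValueError("RDM diagonal must be 0")

    @property
    def n(self) -> int:
        return len(self.stimulus_ids)

    def lower_triangle(self) -> np.ndarray:
        """The n(n-1)/2 unique values, row-major lower triangle."""
        return self.values[np.tril_indices(self.n, -1)]

    def subset(self, stimulus_ids) -> "RDM":
        """Restrict to a subset of stimuli, preserving their given order."""
        lookup = {int(s): k for k, s in enumerate(self.stimulus_ids)}
        try:
            idx = [lookup[int(s)] for s in stimulus_ids]
        except KeyError as err:
            raise ValueError(f"stimulus id {err} not in RDM") from None
        sel = np.ix_(idx, idx)
        return RDM(
            stimulus_ids=np.asarray(stimulus_ids),
            values=self.values[sel],
            kind=self.kind,
            pair_counts=None if self.pair_counts is None else self.pair_counts[sel],
            survival_counts=(
                None if self.survival_counts is None else self.survival_counts[sel]
            ),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.values, index=self.stimulus_ids, columns=self.stimulus_ids
        ).to_csv(path)


def build_feature_model_rdm(feature: str, stimuli: StimulusSet | None = None) -> RDM:
    """Rank-distance model RDM for one feature (values 0..3).

    For SF, colour and contrast the dissimilarity between stimuli i and j
    is |level_i - level_j|.  Orientation is circular over the four levels
    (22.5..157.5 deg, 45 deg apart): min(|d|, 4 - |d|), so 22.5 vs 157.5
    deg is as dissimilar (1) as 22.5 vs 67.5 deg.
    """
    _check_feature(feature)
    stimuli = stimuli if stimuli is not None else build_stimulus_set()
    lv = stimuli.levels(feature)
    d = np.abs(lv[:, None] - lv[None, :]).astype(float)
    if feature == "orientation":
        d = np.minimum(d, 4 - d)
    return RDM(
        stimulus_ids=stimuli.table["stimulus_id"].to_numpy(), values=d, kind="model"
    )


def build_behavioural_rdm(
    triplets: TripletSet, stimuli: StimulusSet | None = None
) -> RDM:
    """Behavioural RDM from odd-one-out judgements.

    similarity(i, j) = (# triplets containing i and j where the third item
    was chosen) / (# triplets containing i and j); dissimilarity = 1 -
    similarity.  Pairs never co-presented are NaN.
    """
    stimuli = stimuli if stimuli is not None else build_stimulus_set()
    ids = stimuli.table["stimulus_id"].to_numpy()
    n = len(ids)
    pos = {int(s): k for k, s in enumerate(ids)}
    trio = triplets.trials[["stim1", "stim2", "stim3"]].to_numpy()
    if not np.isin(trio, ids).all():
        raise ValueError("triplet stimulus ids outside the stimulus set")
    chosen = triplets.trials["chosen"].to_numpy()
    trio_pos = np.vectorize(pos.__getitem__)(trio)

    counts = np.zeros((n, n), dtype=np.int64)
    survive = np.zeros((n, n), dtype=np.int64)
    # each trial contributes to its three pairs; the pair not containing
    # the chosen item "survives"
    for a, b in ((0, 1), (0, 2), (1, 2)):
        i, j = trio_pos[:, a], trio_pos[:, b]
        np.add.at(counts, (i, j), 1)
        won = chosen == trio[:, 3 - a - b]
        np.add.at(survive, (i[won], j[won]), 1)
    counts = counts + counts.T
    survive = survive + survive.T

    with np.errstate(invalid="ignore"):
        dissim = 1.0 - survive / counts
    np.fill_diagonal(dissim, 0.0)
    return RDM(
        stimulus_ids=ids,
        values=dissim,
        kind="behavioural",
        pair_counts=counts,
        survival_counts=survive,
    )


def correlate_rdms(rdm_x: RDM, rdm_y: RDM) -> tuple[float, float]:
    """Spearman rho (and p) over shared non-missing lower-triangle entries.

    Ties receive average ranks; missing entries in either RDM are
    pairwise-deleted.  The p-value is the large-n t approximation and is
    reported for reference only.
    """
    if rdm_x.n != rdm_y.n or not np.array_equal(rdm_x.stimulus_ids, rdm_y.stimulus_ids):
        raise ValueError("RDMs must share the same stimulus ordering")
    x = rdm_x.lower_triangle()
    y = rdm_y.lower_triangle()
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ValueError("need at least 3 shared non-missing pairs")
    rho, p = spearmanr(x[ok], y[ok])
    return float(rho), float(p)


def rsa_timecourse(neural_rdms, stimulus_ids, target: RDM) -> np.ndarray:
    """Correlate a per-timepoint neural RDM stack against a target RDM.

    neural_rdms: (T, n, n) array as returned by ``pairwise_rdm_decoding``.
    Returns rho per timepoint.
    """
    neural_rdms = np.asarray(neural_rdms)
    rhos = np.empty(neural_rdms.shape[0])
    for t in range(neural_rdms.shape[0]):
        rdm_t = RDM(stimulus_ids=stimulus_ids, values=neural_rdms[t], kind="neural")
        rhos[t], _ = correlate_rdms(rdm_t, target)
    return rhos
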