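"""Pairwise probabilities of correct discrimination (PCD).

For two equiprobable stimuli x_i, x_j the Bayes rule assigns a response y to
the input with the larger posterior, so the probability of assigning y
correctly is max{P(x_i|Y=y), P(x_j|Y=y)} — between 0.5 (fully overlapping
output distributions) and 1 (disjoint).  Averaging over the responses of both
levels with equal weight gives the overall PCD of the pair.

The posterior is estimated by the two-class logistic model recalibrated to the
equal prior (1/2, 1/2).  Because a classifier evaluated on its own training
responses overstates discriminability, each PCD is the mean over repeated
stratified train/test splits: fit on a training fraction, evaluate the PCD
average on the held-out cells.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channel_data import ChannelSample, InputDistribution
from .posterior_model import DEFAULT_REGULARIZATION, PosteriorModel, fit_posterior

__all__ = [
    "PCDMatrix",
    "pcd_pointwise",
    "estimate_pcd_pair",
    "estimate_pcd_matrix",
    "pcd_difference",
]

DEFAULT_TRAIN_FRACTION = 0.8
DEFAULT_REPEATS = 50


@dataclass(frozen=True)
class PCDMatrix:
    """Symmetric m x m matrix of pairwise PCD estimates with bootstrap spread.

    The diagonal is NaN (self-discrimination is undefined).
    """

    levels: tuple
    values: np.ndarray
    spread: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        s = np.asarray(self.spread, dtype=float)
        m = len(self.levels)
        if v.shape != (m, m) or s.shape != (m, m):
            raise ValueError("matrix shapes must be (m, m)")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spread", s)
        object.__setattr__(self, "levels", tuple(self.levels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.levels), columns=list(self.levels))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, float_format="%.6g")

    def to_dict(self) -> dict:
        return {
            "levels": list(self.levels),
            "values": self.values.tolist(),
            "spread": self.spread.tolist(),
        }


def pcd_pointwise(model: PosteriorModel, y: np.ndarray) -> float:
    """PCD of a single response under a fitted two-class equal-prior model:
    max of the two posteriors, in [0.5, 1]."""
    if model.m != 2:
        raise ValueError("pointwise PCD requires a model over exactly 2 levels")
    if not np.allclose(model.prior.probs, 0.5, atol=1e-9):
        raise ValueError("pointwise PCD requires the equal prior (1/2, 1/2)")
    y = np.atleast_1d(np.asarray(y, dtype=float))
    post = model.posteriors(y[None, :])[0]
    return float(post.max())


def _pcd_on(model: PosteriorModel, Y_a: np.ndarray, Y_b: np.ndarray) -> float:
    """Overall PCD: equal-weight average of max-posteriors over both levels."""
    best_a = model.posteriors(Y_a).max(axis=1)
    best_b = model.posteriors(Y_b).max(axis=1)
    return 0.5 * float(best_a.mean()) + 0.5 * float(best_b.mean())


def estimate_pcd_pair(
    sample: ChannelSample,
    level_a,
    level_b,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
    regularization: float = DEFAULT_REGULARIZATION,
) -> dict:
    """Estimate the overall PCD between two input levels.

    Per repeat: stratified split into train/test, fit the two-class posterior
    on the training cells, recalibrate to the (1/2, 1/2) prior, average the
    max-posterior over the *test* responses of both levels with equal weight.
    Returns ``{"mean", "sd", "replicates"}``; the mean over repeats is the
    final estimate.
    """
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    pair = sample.subset_levels([level_a, level_b])
    counts = pair.counts
    if counts.min() < 10:
        raise ValueError(
            f"need n >= 10 per level for train/test PCD; counts are {dict(zip(pair.input_levels, counts))}"
        )
    half = InputDistribution(np.array([0.5, 0.5]))
    rng = np.random.default_rng(seed)
    idx_by_level = [np.nonzero(pair.level_index == i)[0] for i in range(2)]
    n_train = [max(2, int(np.floor(train_fraction * c))) for c in counts]
    if any(c - t < 1 for c, t in zip(counts, n_train)):
        raise ValueError("train_fraction leaves no test cells for some level")

    reps = np.empty(repeats)
    for r in range(repeats):
        train_rows, test_sets = [], []
        for ix, t in zip(idx_by_level, n_train):
            perm = rng.permutation(ix)
            train_rows.append(perm[:t])
            test_sets.append(pair.outputs[perm[t:]])
        train = pair.subset_rows(np.sort(np.concatenate(train_rows)))
        model = fit_posterior(train, prior=half, regularization=regularization)
        reps[r] = _pcd_on(model, test_sets[0], test_sets[1])
    sd = float(reps.std(ddof=1)) if repeats > 1 else 0.0
    return {"mean": float(reps.mean()), "sd": sd, "replicates": reps}


def _pair_seed(seed: int, level_a, level_b) -> int:
    """Stable per-pair seed so the matrix is reproducible and parallelizable."""
    a, b = sorted([str(level_a), str(level_b)])
    digest = hashlib.blake2s(f"{seed}|{a}|{b}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)


def estimate_pcd_matrix(
    sample: ChannelSample,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
    regularization: float = DEFAULT_REGULARIZATION,
) -> PCDMatrix:
    """PCD for every unordered pair of input levels, as a symmetric matrix."""
    levels = sample.input_levels
    m = len(levels)
    values = np.full((m, m), np.nan)
    spread = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i + 1, m):
            try:
                res = estimate_pcd_pair(
                    sample,
                    levels[i],
                    levels[j],
                    train_fraction=train_fraction,
                    repeats=repeats,
                    seed=_pair_seed(seed, levels[i], levels[j]),
                    regularization=regularization,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"PCD estimation failed for pair ({levels[i]!r}, {levels[j]!r}): {exc}"
                ) from exc
            values[i, j] = values[j, i] = res["mean"]
            spread[i, j] = spread[j, i] = res["sd"]
    return PCDMatrix(tuple(levels), values, spread)


def pcd_difference(matrix_a: PCDMatrix, matrix_b: PCDMatrix) -> PCDMatrix:
    """Elementwise ``matrix_b - matrix_a`` (e.g. time-series minus time-point);
    spreads combine in quadrature."""
    if matrix_a.levels != matrix_b.levels:
        raise ValueError("PCD matrices cover different level sets")
    return PCDMatrix(
        matrix_a.levels,
        matrix_b.values - matrix_a.values,
        np.sqrt(matrix_a.spread**2 + matrix_b.spread**2),
    )
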