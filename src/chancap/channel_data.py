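"""Empirical-channel data model and tabular I/O.

A *channel sample* is the standard single-cell layout for information-theoretic
analysis of signaling data: one row per cell, a first column holding the
stimulus (input) level and the remaining numeric columns holding the response
(output) dimensions — typically successive time points of a trajectory.

The module houses the :class:`ChannelSample` container, validation, delimited
text I/O, probability vectors over input levels, and the trajectory views
(single time point vs cumulative time window) used when asking how much
information dynamics adds over snapshots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChannelSample",
    "InputDistribution",
    "read_channel_table",
    "write_channel_table",
    "time_point_view",
    "time_window_view",
]

DEFAULT_INPUT_COLUMN = "input"

_PROB_TOL = 1e-12


class ValidationError(ValueError):
    """Raised when input data violates the channel-sample contract."""


def _level_sort_key(labels: Sequence[str]):
    """Sort numerically when every label parses as a number, else lexicographic.

    The last level in the resulting order serves as the logistic-regression
    baseline class.
    """
    try:
        numeric = [float(lab) for lab in labels]
    except (TypeError, ValueError):
        return sorted(labels, key=str)
    order = np.argsort(numeric, kind="stable")
    return [labels[i] for i in order]


@dataclass(frozen=True)
class InputDistribution:
    """Probability vector over the m input levels of a channel.

    Represents the input distribution P(X) = (P(x_1), ..., P(x_m)); also used
    for the iterates P^(k) and the capacity-achieving P* of the alternate
    maximization.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.ndim != 1 or p.size < 1:
            raise ValidationError("probability vector must be 1-dimensional and non-empty")
        if not np.all(np.isfinite(p)) or np.any(p < 0):
            raise ValidationError("probabilities must be finite and non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError(f"probabilities must sum to 1 (got {p.sum()!r})")
        # renormalize residual float error so downstream sums hold to 1e-12
        object.__setattr__(self, "probs", p / p.sum())

    @classmethod
    def uniform(cls, m: int) -> "InputDistribution":
        return cls(np.full(m, 1.0 / m))

    @property
    def m(self) -> int:
        return self.probs.size

    def __len__(self) -> int:
        return self.probs.size

    def __getitem__(self, i: int) -> float:
        return float(self.probs[i])


@dataclass
class ChannelSample:
    """Labeled collection of (input level, output vector) single-cell records.

    Parameters
    ----------
    labels
        Raw per-row input labels, length N.
    outputs
        Response matrix of shape (N, d).
    column_names
        The d output-dimension identifiers (e.g. time stamps).
    """

    labels: list
    outputs: np.ndarray
    column_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        y = np.asarray(self.outputs, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        self.outputs = y
        n, d = y.shape
        if len(self.labels) != n:
            raise ValidationError("labels and outputs disagree in length")
        if n == 0 or d == 0:
            raise ValidationError("sample must contain at least one record and one output column")
        bad = ~np.isfinite(y)
        if bad.any():
            rows = sorted(set(np.nonzero(bad)[0].tolist()))
            raise ValidationError(f"non-finite output values in rows {rows[:20]}")
        if not self.column_names:
            self.column_names = [f"output{i + 1}" for i in range(d)]
        if len(self.column_names) != d:
            raise ValidationError("column_names length must equal output dimension")
        self.labels = [str(lab) for lab in self.labels]
        self._levels = _level_sort_key(sorted(set(self.labels)))
        if len(self._levels) < 2:
            raise ValidationError("m >= 2 required: need at least two distinct input levels")
        lookup = {lab: i for i, lab in enumerate(self._levels)}
        self._level_idx = np.fromiter((lookup[lab] for lab in self.labels), dtype=np.intp, count=n)

    # -- structure ---------------------------------------------------------

    @property
    def input_levels(self) -> list:
        """Ordered distinct input labels x_1 ... x_m (x_m is the baseline)."""
        return list(self._levels)

    @property
    def m(self) -> int:
        return len(self._levels)

    @property
    def d(self) -> int:
        return self.outputs.shape[1]

    @property
    def n_total(self) -> int:
        return self.outputs.shape[0]

    @property
    def level_index(self) -> np.ndarray:
        """Per-row index into :attr:`input_levels`."""
        return self._level_idx

    @property
    def counts(self) -> np.ndarray:
        """Per-level record counts n_1 ... n_m."""
        return np.bincount(self._level_idx, minlength=self.m)

    def records(self, level) -> np.ndarray:
        """Output vectors y_l^i for one input level (n_i, d)."""
        level = str(level)
        if level not in self._levels:
            raise KeyError(f"unknown input level {level!r}")
        return self.outputs[self._level_idx == self._levels.index(level)]

    def empirical_prior(self) -> InputDistribution:
        return InputDistribution(self.counts / self.n_total)

    # -- derived samples ---------------------------------------------------

    def subset_levels(self, keep: Sequence) -> "ChannelSample":
        """Restrict to a subset of input levels (order re-derived)."""
        keep = {str(k) for k in keep}
        unknown = keep - set(self._levels)
        if unknown:
            raise KeyError(f"unknown input levels {sorted(unknown)}")
        mask = np.fromiter((lab in keep for lab in self.labels), dtype=bool, count=self.n_total)
        return ChannelSample(
            [lab for lab, m_ in zip(self.labels, mask) if m_],
            self.outputs[mask],
            list(self.column_names),
        )

    def subset_rows(self, rows: np.ndarray) -> "ChannelSample":
        rows = np.asarray(rows)
        return ChannelSample(
            [self.labels[i] for i in rows], self.outputs[rows], list(self.column_names)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChannelSample):
            return NotImplemented
        return (
            self.labels == other.labels
            and self.column_names == other.column_names
            and self.outputs.shape == other.outputs.shape
            and np.allclose(self.outputs, other.outputs, rtol=0, atol=1e-9)
        )


# -- tabular I/O -----------------------------------------------------------


def read_channel_table(
    path,
    delimiter: str = ",",
    input_column: str = DEFAULT_INPUT_COLUMN,
) -> ChannelSample:
    """Read a delimited single-cell response table into a :class:`ChannelSample`.

    The file must have a header row; ``input_column`` holds the stimulus label
    and every other column must be numeric output.
    """
    frame = pd.read_csv(path, sep=delimiter, header=0, dtype=str)
    if input_column not in frame.columns:
        raise ValidationError(f"input column {input_column!r} not found in {list(frame.columns)}")
    out_cols = [c for c in frame.columns if c != input_column]
    if not out_cols:
        raise ValidationError("table has no output columns")
    labels = frame[input_column].astype(str).tolist()
    numeric = frame[out_cols].apply(pd.to_numeric, errors="coerce")
    bad_rows = numeric.index[numeric.isna().any(axis=1)].tolist()
    if bad_rows:
        raise ValidationError(
            f"missing or non-numeric output cells in rows {bad_rows[:20]} (0-based, after header)"
        )
    return ChannelSample(labels, numeric.to_numpy(dtype=float), out_cols)


def write_channel_table(
    sample: ChannelSample,
    path,
    delimiter: str = ",",
    input_column: str = DEFAULT_INPUT_COLUMN,
) -> None:
    """Write a sample in the one-row-per-cell layout; round-trips with
    :func:`read_channel_table` up to float text precision."""
    frame = pd.DataFrame(sample.outputs, columns=sample.column_names)
    frame.insert(0, input_column, sample.labels)
    frame.to_csv(path, sep=delimiter, index=False, float_format="%.12g")


# -- trajectory views ------------------------------------------------------


def _resolve_stamp(sample: ChannelSample, t) -> int:
    names = [str(c) for c in sample.column_names]
    if str(t) in names:
        return names.index(str(t))
    raise KeyError(f"unknown column stamp {t!r}; available: {names}")


def time_point_view(sample: ChannelSample, t) -> ChannelSample:
    """Single-time-point representation: the response is the one column at
    stamp ``t`` (d = 1); input structure unchanged."""
    j = _resolve_stamp(sample, t)
    return ChannelSample(list(sample.labels), sample.outputs[:, [j]], [sample.column_names[j]])


def time_window_view(sample: ChannelSample, t) -> ChannelSample:
    """Cumulative time-series representation: all columns from the start up to
    and including stamp ``t``, order preserved."""
    j = _resolve_stamp(sample, t)
    return ChannelSample(
        list(sample.labels), sample.outputs[:, : j + 1], list(sample.column_names[: j + 1])
    )
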