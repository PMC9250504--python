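"""Localization and waveform accuracy metrics.

* localization error: Euclidean distance (mm) between the true source
  position and the vertex whose estimated power, averaged over a
  time-of-interest (TOI), is highest;
* relative error and Pearson correlation between source time courses
  reconstructed with different electrode sets;
* accuracy index: percentage of trials in which a channel subset's
  localization error is equal to or lower than the all-channel baseline's,
  paired per trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TOI",
    "LocalizationResult",
    "toi_to_samples",
    "estimate_location",
    "loc_error",
    "rel_error",
    "pearson_r",
    "accuracy_index",
]


@dataclass(frozen=True)
class TOI:
    """Time-of-interest window in seconds, [start, end)."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.start < self.end:
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")


@dataclass(frozen=True)
class LocalizationResult:
    estimated_vertex: int
    estimated_position: np.ndarray  # (3,), mm
    loc_error: float | None = None  # mm


def toi_to_samples(toi: TOI, fs: float, n_samples: int) -> slice:
    """Half-open sample window [round(start*fs), round(end*fs)).

    A boundary shared by two consecutive TOIs therefore belongs to the later
    window only, so no sample is counted twice.
    """
    i0 = int(round(toi.start * fs))
    i1 = int(round(toi.end * fs))
    if i0 >= i1:
        raise ValueError(f"TOI [{toi.start}, {toi.end}) maps to an empty sample window at fs={fs}")
    if i1 > n_samples:
        raise ValueError(f"TOI end sample {i1} exceeds the epoch length {n_samples}")
    return slice(i0, i1)


def estimate_location(
    x_hat: np.ndarray,
    source_positions: np.ndarray,
    toi: TOI,
    fs: float,
) -> LocalizationResult:
    """Locate a source as the vertex of highest TOI-mean estimated power.

    The element-wise power ``x_hat**2`` is averaged over the TOI samples and
    the argmax over vertices taken; exact power ties resolve to the lowest
    vertex index.
    """
    x_hat = np.asarray(x_hat, dtype=float)
    window = toi_to_samples(toi, fs, x_hat.shape[1])
    mean_power = np.mean(x_hat[:, window] ** 2, axis=1)
    vertex = int(np.argmax(mean_power))  # argmax returns the first (lowest) index on ties
    return LocalizationResult(vertex, np.asarray(source_positions[vertex], dtype=float))


def loc_error(p_true: np.ndarray, p_est: np.ndarray) -> float:
    """Euclidean distance (mm) between true and estimated source positions."""
    p_true = np.asarray(p_true, dtype=float)
    p_est = np.asarray(p_est, dtype=float)
    if not (np.all(np.isfinite(p_true)) and np.all(np.isfinite(p_est))):
        raise ValueError("positions must be finite")
    return float(np.linalg.norm(p_true - p_est))


def rel_error(x1: np.ndarray, x2: np.ndarray) -> float:
    """Relative reconstruction error ||x1 - x2|| / ||x1||.

    ``x1`` is the reference time course (by convention the reconstruction
    computed with the highest number of electrodes).
    """
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if x1.size != x2.size:
        raise ValueError("time courses must have equal length")
    denom = np.linalg.norm(x1)
    if denom == 0:
        raise ValueError("reference time course has zero norm")
    return float(np.linalg.norm(x1 - x2) / denom)


def pearson_r(x1: np.ndarray, x2: np.ndarray) -> float:
    """Pearson correlation coefficient between two time courses."""
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if x1.size != x2.size or x1.size < 2:
        raise ValueError("time courses must have equal length >= 2")
    d1 = x1 - x1.mean()
    d2 = x2 - x2.mean()
    s1 = np.sum(d1**2)
    s2 = np.sum(d2**2)
    if s1 == 0 or s2 == 0:
        raise ValueError("correlation is undefined for a constant time course")
    return float(np.sum(d1 * d2) / np.sqrt(s1 * s2))


def accuracy_index(errors_subset: np.ndarray, errors_allchannels: np.ndarray) -> float:
    """Percentage of trials where the subset error is <= the baseline error.

    Inputs are paired per trial; exact <= on floating mm values, so ties
    count as successes.
    """
    sub = np.asarray(errors_subset, dtype=float).ravel()
    ref = np.asarray(errors_allchannels, dtype=float).ravel()
    if sub.size != ref.size:
        raise ValueError(f"paired vectors required, got lengths {sub.size} and {ref.size}")
    if sub.size == 0:
        raise ValueError("at least one trial required")
    return 100.0 * float(np.count_nonzero(sub <= ref)) / sub.size
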