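"""Outer optimization loop: channel weighting, candidate evaluation,
full-run orchestration, pseudo-Pareto extraction and dataset summaries.

A candidate chromosome weights the EEG (excluded channels become all-zero
rows), the weighted epoch is inverted with the full-dimension lead field,
and each target source is localized within its own time-of-interest; the
objective vector is [number of selected channels, per-source localization
errors].  From the log of all evaluated candidates the best combination per
channel count is extracted (the pseudo-Pareto front, ranked by the mean of
the per-source errors), and compared against the all-channels baseline via
the accuracy index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import inverse, metrics, nsga2
from .headmodel import LeadField, MontageMask
from .simulator import Trial

__all__ = [
    "RunConfig",
    "OptimizationResult",
    "CandidateEvaluator",
    "weight_eeg",
    "evaluate_candidate",
    "run_optimization",
    "extract_pseudo_pareto",
    "summarize_dataset",
    "search_space_size",
    "plot_front",
    "PENALTY_LOC_ERROR",
]

#: Objective value (mm) assigned to each localization error of the degenerate
#: all-zero chromosome, so "no channels" never survives selection.
PENALTY_LOC_ERROR = 1e6


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one optimization run on one trial."""

    solver: inverse.SolverConfig
    ga: nsga2.GAConfig
    tois: tuple[metrics.TOI, ...]
    montage: str | MontageMask = "full"

    def __post_init__(self) -> None:
        if len(self.tois) < 1:
            raise ValueError("at least one TOI (one per target source) is required")

    @property
    def n_sources(self) -> int:
        return len(self.tois)

    @property
    def n_objectives(self) -> int:
        return len(self.tois) + 1


@dataclass
class OptimizationResult:
    log: nsga2.CandidateLog
    front: pd.DataFrame
    baseline: dict


def search_space_size(n_channels: int, n_sources: int = 1) -> float:
    """Number of inverse solutions needed to evaluate every electrode subset.

    ``2^C - 1`` for a single source, ``s * 2^C - 1`` for s sources (one
    localization per source and candidate).  Returned as a float because the
    count overflows 64-bit integers already at C = 63.
    """
    if n_channels < 1 or n_sources < 1:
        raise ValueError("n_channels and n_sources must be >= 1")
    if n_sources == 1:
        return float(2**n_channels - 1)
    return float(n_sources * 2**n_channels - 1)


def weight_eeg(y: np.ndarray, chromosome: np.ndarray) -> np.ndarray:
    """Zero the rows of ``y`` whose gene is off; selected rows pass through."""
    y = np.asarray(y, dtype=float)
    genes = np.asarray(chromosome, dtype=bool)
    if genes.ndim != 1 or genes.size != y.shape[0]:
        raise ValueError(f"chromosome length {genes.size} does not match {y.shape[0]} channels")
    return y * genes[:, None]


class CandidateEvaluator:
    """Objective function over chromosomes for one trial.

    Precomputes the inverse kernel once (the operator never changes — only
    the data rows are zeroed), so evaluating a candidate is a single matrix
    product plus TOI power averaging.
    """

    def __init__(
        self,
        trial: Trial,
        leadfield_inverse: LeadField,
        solver: inverse.SolverConfig,
        tois: Sequence[metrics.TOI],
    ) -> None:
        if trial.y.shape[0] != leadfield_inverse.n_channels:
            raise ValueError("trial channel count does not match the inversion lead field")
        if len(tois) > len(trial.sources):
            raise ValueError("more TOIs than ground-truth sources in the trial")
        self.trial = trial
        self.leadfield = leadfield_inverse
        self.tois = tuple(tois)
        self.kernel, self.lambda_used, _ = inverse.make_kernel(leadfield_inverse, solver)
        windows = [metrics.toi_to_samples(t, trial.fs, trial.n_samples) for t in self.tois]
        # only TOI samples ever reach the power average, so crop the epoch to
        # their span once instead of inverting the full trial per candidate
        lo = min(w.start for w in windows)
        hi = max(w.stop for w in windows)
        self._y = trial.y[:, lo:hi]
        self._windows = [slice(w.start - lo, w.stop - lo) for w in windows]
        self._true_positions = [np.asarray(s.position, dtype=float) for s in trial.sources[: len(self.tois)]]

    def __call__(self, chromosome: np.ndarray) -> np.ndarray:
        genes = np.asarray(chromosome, dtype=bool)
        n_selected = int(genes.sum())
        if n_selected == 0:
            return np.array([0.0] + [PENALTY_LOC_ERROR] * len(self.tois))
        x_hat = self.kernel @ weight_eeg(self._y, genes)
        objs = [float(n_selected)]
        for window, p_true in zip(self._windows, self._true_positions):
            mean_power = np.mean(x_hat[:, window] ** 2, axis=1)
            vertex = int(np.argmax(mean_power))
            objs.append(metrics.loc_error(p_true, self.leadfield.source_positions[vertex]))
        return np.asarray(objs)


def evaluate_candidate(
    chromosome: np.ndarray,
    trial: Trial,
    leadfield_inverse: LeadField,
    solver: inverse.SolverConfig,
    tois: Sequence[metrics.TOI],
) -> np.ndarray:
    """Objectives [n_selected_channels, locE per source] of one chromosome."""
    return CandidateEvaluator(trial, leadfield_inverse, solver, tois)(chromosome)


def _resolve_mask(montage: str | MontageMask, leadfield: LeadField) -> np.ndarray:
    if isinstance(montage, MontageMask):
        if montage.included.size != leadfield.n_channels:
            raise ValueError("montage mask length does not match the lead field")
        return montage.included
    from .headmodel import make_montage_mask

    return make_montage_mask(leadfield, montage).included


def run_optimization(
    trial: Trial,
    leadfield_inverse: LeadField,
    config: RunConfig,
) -> OptimizationResult:
    """Evolve channel subsets for one trial and extract the pseudo-Pareto front.

    Also evaluates the all-channels baseline (every channel of the montage
    switched on) and records its objectives alongside the front.
    """
    mask = _resolve_mask(config.montage, leadfield_inverse)
    evaluator = CandidateEvaluator(trial, leadfield_inverse, config.solver, config.tois)
    log = nsga2.evolve(evaluator, leadfield_inverse.n_channels, config.ga, mask=mask)
    log.meta.update(
        {
            "solver": config.solver.method,
            "lambda_used": evaluator.lambda_used,
            "montage": config.montage if isinstance(config.montage, str) else config.montage.name,
            "trial_seed": trial.seed,
        }
    )
    front = extract_pseudo_pareto(log, config.n_sources)
    baseline_obj = evaluator(mask)
    baseline = {
        "n_channels": int(baseline_obj[0]),
        "loc_errors": baseline_obj[1:].tolist(),
        "mean_loc_error": float(np.mean(baseline_obj[1:])),
    }
    return OptimizationResult(log, front, baseline)


def extract_pseudo_pareto(log: nsga2.CandidateLog, s: int) -> pd.DataFrame:
    """Best logged candidate per channel count.

    Candidates are ranked by the mean of the ``s`` per-source localization
    errors (for s=1, the error itself); exact ties resolve to the earliest
    generation, then the lexicographically smallest bitstring.  The all-zero
    chromosome (channel count 0) is excluded.
    """
    frame = log.frame
    if len(frame) == 0:
        raise ValueError("candidate log is empty")
    err_cols = [f"obj_{k}" for k in range(1, s + 1)]
    work = frame[frame["n_channels"] > 0].copy()
    work["mean_loc_error"] = work[err_cols].mean(axis=1)
    work = work.sort_values(
        ["n_channels", "mean_loc_error", "generation", "chromosome"],
        kind="stable",
    )
    best = work.groupby("n_channels", as_index=False).first()
    cols = ["n_channels", "chromosome", "generation"] + err_cols + ["mean_loc_error"]
    return best[cols].reset_index(drop=True)


def summarize_dataset(
    fronts: Sequence[pd.DataFrame],
    baselines: Sequence[dict],
) -> pd.DataFrame:
    """Cross-trial summary per channel count.

    For each channel count, the mean and sample standard deviation (ddof=1;
    0 for a single trial) of the per-trial front errors across the trials
    whose fronts contain that count, plus the accuracy index against the
    paired all-channel baselines.  Full precision is kept — round only for
    presentation.
    """
    if len(fronts) == 0 or len(fronts) != len(baselines):
        raise ValueError("need one baseline per trial front")
    base_err = np.array([b["mean_loc_error"] for b in baselines], dtype=float)
    per_trial = []
    for i, front in enumerate(fronts):
        sub = front[["n_channels", "mean_loc_error"]].copy()
        sub["trial"] = i
        per_trial.append(sub)
    stacked = pd.concat(per_trial, ignore_index=True)
    rows = []
    for count, grp in stacked.groupby("n_channels"):
        errs = grp["mean_loc_error"].to_numpy()
        trial_ids = grp["trial"].to_numpy()
        rows.append(
            {
                "n_channels": int(count),
                "n_trials": len(grp),
                "mean_loc_error": float(errs.mean()),
                "sd_loc_error": float(errs.std(ddof=1)) if len(errs) > 1 else 0.0,
                "accuracy_index": metrics.accuracy_index(errs, base_err[trial_ids]),
            }
        )
    return pd.DataFrame(rows).sort_values("n_channels").reset_index(drop=True)


def plot_front(summary: pd.DataFrame, baselines: Sequence[dict], ax=None):
    """Diagnostic plot: mean +/- sd localization error vs channel count, with
    the all-channels baseline as a horizontal reference."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = summary["n_channels"]
    mean = summary["mean_loc_error"]
    sd = summary["sd_loc_error"]
    ax.plot(x, mean, "-o", label="optimized subsets")
    ax.fill_between(x, mean - sd, mean + sd, alpha=0.3)
    base = float(np.mean([b["mean_loc_error"] for b in baselines]))
    ax.axhline(base, color="k", ls="--", label="all channels")
    ax.set_xlabel("number of channels")
    ax.set_ylabel("localization error (mm)")
    ax.legend()
    return ax
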