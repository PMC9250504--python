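"""Elitist non-dominated sorting genetic algorithm (NSGA-II) over binary
channel chromosomes.

Each gene switches one EEG channel on or off.  Following the classic NSGA-II
operator suite, simulated binary crossover (SBX) and polynomial mutation act
on real-valued gene proxies in [0, 1] which are thresholded at 0.5 when a
chromosome is evaluated; a pure-binary mode (uniform crossover + bit flips)
is available as an alternative representation.  Selection is binary
tournament on (non-domination rank, crowding distance), survivors are the
best P of the merged parent+offspring population, and every evaluated
candidate of every generation is logged so the best subset per channel count
can be extracted afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GAConfig",
    "CandidateLog",
    "dominates",
    "nondominated_sort",
    "crowding_distance",
    "make_offspring",
    "evolve",
    "threshold",
]

_SBX_EPS = 1e-14


@dataclass(frozen=True)
class GAConfig:
    """NSGA-II run parameters.

    Defaults follow common practice for this operator suite: population 100,
    400 generations, crossover probability 0.9, per-gene mutation probability
    1/C (set when ``pm`` is None), distribution indices 20.
    """

    population: int = 100
    generations: int = 400
    pc: float = 0.9
    pm: float | None = None
    sbx_eta: float = 20.0
    mut_eta: float = 20.0
    seed: int = 0
    representation: str = "real"  # "real" (SBX + polynomial) or "binary"
    include_full_chromosome: bool = True  # anchor the initial population at the full montage

    def __post_init__(self) -> None:
        if self.population < 2 or self.population % 2 != 0:
            raise ValueError("population must be an even number >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 0.0 <= self.pc <= 1.0:
            raise ValueError("pc must be in [0, 1]")
        if self.pm is not None and not 0.0 <= self.pm <= 1.0:
            raise ValueError("pm must be in [0, 1]")
        if self.representation not in ("real", "binary"):
            raise ValueError(f"unknown representation {self.representation!r}")


@dataclass
class CandidateLog:
    """Every evaluated (chromosome, objectives) pair of a run.

    ``frame`` columns: generation (0 = initial population), chromosome
    (bitstring), n_channels, obj_0 .. obj_{O-1}.  ``history`` holds the
    per-generation survivor-population minima of each objective (rows
    0..generations), a direct record of elitist convergence.
    """

    frame: pd.DataFrame
    meta: dict
    history: np.ndarray

    @property
    def n_offspring_evaluations(self) -> int:
        return int((self.frame["generation"] >= 1).sum())

    @property
    def n_evaluations(self) -> int:
        return int(len(self.frame))

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            for key, val in self.meta.items():
                fh.write(f"# {key}: {val}\n")
            self.frame.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CandidateLog":
        path = Path(path)
        meta: dict = {}
        skip = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                skip += 1
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
        frame = pd.read_csv(path, sep="\t", skiprows=skip, dtype={"chromosome": str})
        return cls(frame, meta, np.empty((0, 0)))


def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff objective vector ``a`` Pareto-dominates ``b`` (minimization)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"objective vectors differ in length: {a.shape} vs {b.shape}")
    return bool(np.all(a <= b) and np.any(a < b))


def _domination_matrix(objs: np.ndarray) -> np.ndarray:
    le = np.all(objs[:, None, :] <= objs[None, :, :], axis=2)
    lt = np.any(objs[:, None, :] < objs[None, :, :], axis=2)
    return le & lt  # dom[i, j]: i dominates j


def nondominated_sort(objectives: np.ndarray) -> list[np.ndarray]:
    """Partition a population into Pareto fronts (front 1 first).

    Returns a list of index arrays; every individual appears in exactly one
    front.
    """
    objs = np.asarray(objectives, dtype=float)
    if objs.ndim != 2 or objs.shape[0] == 0:
        raise ValueError("objectives must be a non-empty (N, O) array")
    dom = _domination_matrix(objs)
    n_dominators = dom.sum(axis=0).astype(int)
    remaining = np.ones(objs.shape[0], dtype=bool)
    fronts: list[np.ndarray] = []
    while remaining.any():
        current = remaining & (n_dominators == 0)
        if not current.any():  # cannot happen for a finite strict partial order
            raise RuntimeError("non-dominated sorting failed to make progress")
        idx = np.flatnonzero(current)
        fronts.append(idx)
        remaining[idx] = False
        n_dominators -= dom[idx].sum(axis=0)
    return fronts


def crowding_distance(front_objectives: np.ndarray) -> np.ndarray:
    """Crowding distance of each member of one front.

    Boundary individuals on any objective get +inf; interior individuals sum
    the normalized gaps between their neighbours over all objectives; an
    objective with zero range across the front contributes nothing.
    """
    objs = np.asarray(front_objectives, dtype=float)
    if objs.ndim != 2 or objs.shape[0] == 0:
        raise ValueError("front must be a non-empty (F, O) array")
    f = objs.shape[0]
    if f <= 2:
        return np.full(f, np.inf)
    dist = np.zeros(f)
    for k in range(objs.shape[1]):
        vals = objs[:, k]
        order = np.argsort(vals, kind="stable")
        span = vals[order[-1]] - vals[order[0]]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        if span > 0:
            gaps = (vals[order[2:]] - vals[order[:-2]]) / span
            interior = order[1:-1]
            finite = np.isfinite(dist[interior])
            dist[interior[finite]] += gaps[finite]
    return dist


def _rank_and_crowding(objs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    fronts = nondominated_sort(objs)
    ranks = np.empty(objs.shape[0], dtype=int)
    crowd = np.empty(objs.shape[0])
    for r, idx in enumerate(fronts, start=1):
        ranks[idx] = r
        crowd[idx] = crowding_distance(objs[idx])
    return ranks, crowd


def _tournament(ranks: np.ndarray, crowd: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    p = ranks.size
    i = rng.integers(0, p, size=p)
    j = rng.integers(0, p, size=p)
    j_wins = (ranks[j] < ranks[i]) | ((ranks[j] == ranks[i]) & (crowd[j] > crowd[i]))
    return np.where(j_wins, j, i)


def _sbx(p1: np.ndarray, p2: np.ndarray, pc: float, eta: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    c1, c2 = p1.copy(), p2.copy()
    do_pair = rng.random(p1.shape[0]) <= pc
    do_gene = (rng.random(p1.shape) <= 0.5) & do_pair[:, None] & (np.abs(p1 - p2) > _SBX_EPS)
    u = rng.random(p1.shape)
    beta = np.where(u <= 0.5, (2.0 * u) ** (1.0 / (eta + 1.0)), (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0)))
    a = 0.5 * ((1.0 + beta) * p1 + (1.0 - beta) * p2)
    b = 0.5 * ((1.0 - beta) * p1 + (1.0 + beta) * p2)
    c1[do_gene] = a[do_gene]
    c2[do_gene] = b[do_gene]
    return np.clip(c1, 0.0, 1.0), np.clip(c2, 0.0, 1.0)


def _polynomial_mutation(x: np.ndarray, pm: float, eta: float, rng: np.random.Generator) -> np.ndarray:
    y = x.copy()
    do = rng.random(x.shape) <= pm
    u = rng.random(x.shape)
    d1 = y  # (x - lower) / span with bounds [0, 1]
    d2 = 1.0 - y
    left = (2.0 * u + (1.0 - 2.0 * u) * (1.0 - d1) ** (eta + 1.0)) ** (1.0 / (eta + 1.0)) - 1.0
    right = 1.0 - (2.0 * (1.0 - u) + 2.0 * (u - 0.5) * (1.0 - d2) ** (eta + 1.0)) ** (1.0 / (eta + 1.0))
    delta = np.where(u < 0.5, left, right)
    y[do] = y[do] + delta[do]
    return np.clip(y, 0.0, 1.0)


def _uniform_crossover(p1: np.ndarray, p2: np.ndarray, pc: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    c1, c2 = p1.copy(), p2.copy()
    do_pair = rng.random(p1.shape[0]) <= pc
    swap = (rng.random(p1.shape) <= 0.5) & do_pair[:, None]
    c1[swap], c2[swap] = p2[swap], p1[swap]
    return c1, c2


def _bitflip_mutation(x: np.ndarray, pm: float, rng: np.random.Generator) -> np.ndarray:
    flip = rng.random(x.shape) <= pm
    y = x.copy()
    y[flip] = 1.0 - y[flip]
    return y


def make_offspring(
    proxies: np.ndarray,
    ranks: np.ndarray,
    crowd: np.ndarray,
    config: GAConfig,
    rng: np.random.Generator,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Produce P children from a ranked population of P gene-proxy vectors."""
    pm = config.pm if config.pm is not None else 1.0 / proxies.shape[1]
    winners = proxies[_tournament(ranks, crowd, rng)]
    p1, p2 = winners[0::2], winners[1::2]
    if config.representation == "real":
        c1, c2 = _sbx(p1, p2, config.pc, config.sbx_eta, rng)
        children = np.concatenate([c1, c2], axis=0)
        children = _polynomial_mutation(children, pm, config.mut_eta, rng)
    else:
        c1, c2 = _uniform_crossover(p1, p2, config.pc, rng)
        children = np.concatenate([c1, c2], axis=0)
        children = _bitflip_mutation(children, pm, rng)
    if mask is not None:
        children[:, ~mask] = 0.0
    return children


def threshold(proxies: np.ndarray) -> np.ndarray:
    """Binary chromosome(s) from real gene proxies: gene on iff proxy > 0.5."""
    return np.asarray(proxies) > 0.5


def _bitstring(genes: np.ndarray) -> str:
    return "".join("1" if g else "0" for g in genes)


def evolve(
    evaluate: Callable[[np.ndarray], np.ndarray],
    n_genes: int,
    config: GAConfig,
    mask: np.ndarray | None = None,
) -> CandidateLog:
    """Run NSGA-II and log every evaluated candidate.

    ``evaluate(genes)`` maps a boolean chromosome to an objective vector
    (minimization; must be deterministic within a run — results are cached
    on the thresholded chromosome, so duplicates cost nothing).  ``mask``
    clamps excluded genes to 0 in the initial population and in every child.
    The initial population is logged as generation 0; each of the
    ``config.generations`` generations contributes exactly P offspring rows.
    """
    rng = np.random.default_rng(config.seed)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (n_genes,):
            raise ValueError("mask length must equal n_genes")
    cache: dict[bytes, np.ndarray] = {}

    def eval_cached(genes: np.ndarray) -> np.ndarray:
        key = genes.tobytes()
        if key not in cache:
            cache[key] = np.asarray(evaluate(genes), dtype=float)
        return cache[key]

    rows: list[dict] = []

    def log_population(genes_pop: np.ndarray, generation: int) -> np.ndarray:
        objs = []
        for genes in genes_pop:
            obj = eval_cached(genes)
            objs.append(obj)
            row = {"generation": generation, "chromosome": _bitstring(genes), "n_channels": int(genes.sum())}
            row.update({f"obj_{k}": float(v) for k, v in enumerate(obj)})
            rows.append(row)
        return np.asarray(objs, dtype=float)

    p = config.population
    proxies = rng.random((p, n_genes))
    if mask is not None:
        proxies[:, ~mask] = 0.0
    if config.include_full_chromosome:
        # seed the reference montage (all channels of the search space on) so
        # the candidate log always contains the HD baseline and the front
        # spans the full channel range
        proxies[0] = 1.0 if mask is None else mask.astype(float)
    objs = log_population(threshold(proxies), 0)
    history = [objs.min(axis=0)]
    ranks, crowd = _rank_and_crowding(objs)
    for gen in range(1, config.generations + 1):
        children = make_offspring(proxies, ranks, crowd, config, rng, mask)
        child_objs = log_population(threshold(children), gen)
        merged = np.concatenate([proxies, children], axis=0)
        merged_objs = np.concatenate([objs, child_objs], axis=0)
        fronts = nondominated_sort(merged_objs)
        keep: list[int] = []
        for idx in fronts:
            if len(keep) + idx.size <= p:
                keep.extend(idx.tolist())
            else:
                dist = crowding_distance(merged_objs[idx])
                order = np.argsort(-dist, kind="stable")
                keep.extend(idx[order[: p - len(keep)]].tolist())
                break
        proxies = merged[keep]
        objs = merged_objs[keep]
        history.append(objs.min(axis=0))
        ranks, crowd = _rank_and_crowding(objs)
    frame = pd.DataFrame(rows)
    meta = {
        "seed": config.seed,
        "population": p,
        "generations": config.generations,
        "pc": config.pc,
        "pm": config.pm if config.pm is not None else 1.0 / n_genes,
        "sbx_eta": config.sbx_eta,
        "mut_eta": config.mut_eta,
        "representation": config.representation,
        "n_genes": n_genes,
        "n_unique_candidates": len(cache),
    }
    return CandidateLog(frame, meta, np.asarray(history))
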