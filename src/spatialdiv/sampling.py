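"""Geographically even selection of sampling locations by simulated annealing.

Given candidate coordinates (known collection/observation records of a
taxon), the sampler picks ``k`` locations spread as evenly as possible,
the idea being that under isolation by distance an even spatial spread
covers the taxon's genetic variation.  Evenness is scored by default as
the maximin (p-dispersion) objective — maximise the smallest pairwise
geodesic distance among the chosen points, ties broken by the total
pairwise distance — with a sum-of-distances alternative.  The optimiser
is simulated annealing over k-subsets: each step proposes either a
global swap (replace one chosen location by a uniformly random unchosen
one) or a local slide (replace a chosen location by one of its nearest
unchosen neighbours — the move that lets the annealer redistribute
spacing across plateaus of equal minimum distance), with geometric
cooling over a fixed proposal budget (100,000 proposals by default,
matching the spatial-sampling protocol this package studies).

Runs are deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from spatialdiv.geodesy import GeoPoint, distance_matrix

__all__ = ["SpatialSelection", "spatial_sample", "subset_objective"]

Objective = Literal["maximin", "sumdist"]


@dataclass(frozen=True)
class SpatialSelection:
    """Result of one annealing run."""

    chosen: tuple[int, ...]
    #: (min pairwise distance, total pairwise distance) for maximin,
    #: (total pairwise distance,) for sumdist — larger is better,
    #: compared lexicographically
    objective_value: tuple[float, ...]
    iterations: int
    seed: int
    objective: str


def subset_objective(D: np.ndarray, idx: Sequence[int], objective: Objective) -> tuple:
    """Score of a candidate subset (larger is better, lexicographic)."""
    sub = D[np.ix_(idx, idx)]
    total = float(sub.sum() / 2.0)
    if objective == "sumdist":
        return (total,)
    k = len(idx)
    if k < 2:
        return (math.inf, 0.0)
    mn = float(sub[np.triu_indices(k, 1)].min())
    return (mn, total)


def _energy(score: tuple) -> float:
    """Scalar energy for the annealer (lower is better).

    The tie-breaking total distance enters with a weight small enough
    not to override genuine differences in the primary objective.
    """
    if len(score) == 1:
        return -score[0]
    mn, total = score
    return -(mn + 1e-9 * total)


def spatial_sample(
    candidates: Sequence[GeoPoint],
    k: int,
    *,
    iterations: int = 100_000,
    seed: int = 0,
    objective: Objective = "maximin",
    distances: np.ndarray | None = None,
) -> SpatialSelection:
    """Select ``k`` evenly spread locations from the candidates.

    Parameters
    ----------
    candidates:
        Candidate :class:`~spatialdiv.geodesy.GeoPoint` locations
        (duplicate coordinates are allowed; they simply never both end
        up in a maximin-optimal subset unless forced).
    k:
        Number of locations to choose; must not exceed the number of
        candidates.
    iterations:
        Number of annealing proposals.
    seed:
        Seed for the proposal stream; same seed, same selection.
    objective:
        ``"maximin"`` (default) or ``"sumdist"``.
    distances:
        Optional precomputed pairwise distance matrix (metres); computed
        from the coordinates when omitted.

    Returns the best subset seen during the whole run.
    """
    N = len(candidates)
    if k > N:
        raise ValueError(f"cannot choose k={k} from {N} candidates")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if k == N:
        idx = tuple(range(N))
        D = distances if distances is not None else distance_matrix(candidates)
        return SpatialSelection(
            chosen=idx,
            objective_value=subset_objective(D, idx, objective),
            iterations=0,
            seed=seed,
            objective=objective,
        )
    D = distances if distances is not None else distance_matrix(candidates)
    rng = np.random.default_rng(seed)
    # each point's candidates ranked by proximity, for the slide move
    neighbour_rank = np.argsort(D, axis=1)

    chosen = list(rng.choice(N, size=k, replace=False))
    in_subset = np.zeros(N, dtype=bool)
    in_subset[chosen] = True
    others = [i for i in range(N) if not in_subset[i]]
    other_pos = {p: i for i, p in enumerate(others)}
    score = subset_objective(D, chosen, objective)
    energy = _energy(score)
    best_idx = tuple(sorted(chosen))
    best_score = score

    def propose():
        ci = int(rng.integers(k))
        if rng.random() < 0.5:
            # global swap
            return ci, others[int(rng.integers(N - k))]
        # local slide: one of the nearest unchosen neighbours
        for cand in neighbour_rank[chosen[ci]][1:]:
            if not in_subset[cand] and rng.random() < 0.5:
                return ci, int(cand)
        return ci, others[int(rng.integers(N - k))]

    # initial temperature: spread of energy deltas over 100 random proposals
    deltas = []
    for _ in range(100):
        ci, cand = propose()
        trial = chosen.copy()
        trial[ci] = cand
        deltas.append(_energy(subset_objective(D, trial, objective)) - energy)
    t0 = float(np.std(deltas))
    if t0 == 0.0:
        t0 = 1.0
    t_final = t0 * 1e-4
    cool = (t_final / t0) ** (1.0 / max(iterations - 1, 1))

    temp = t0
    for _ in range(iterations):
        ci, cand = propose()
        trial = chosen.copy()
        trial[ci] = cand
        trial_score = subset_objective(D, trial, objective)
        trial_energy = _energy(trial_score)
        delta = trial_energy - energy
        if delta <= 0.0 or rng.random() < math.exp(-delta / temp):
            swapped_out = chosen[ci]
            chosen = trial
            in_subset[swapped_out] = False
            in_subset[cand] = True
            oi = other_pos.pop(cand)
            others[oi] = swapped_out
            other_pos[swapped_out] = oi
            score, energy = trial_score, trial_energy
            if score > best_score:
                best_score = score
                best_idx = tuple(sorted(chosen))
        temp *= cool

    return SpatialSelection(
        chosen=best_idx,
        objective_value=best_score,
        iterations=iterations,
        seed=seed,
        objective=objective,
    )
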