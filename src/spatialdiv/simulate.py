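"""Structured-coalescent population simulator with GTR sequence evolution.

The simulator generates whole statistical populations: a deme layout
(grid stepping-stone, distance-decay island, or a single panmictic
deme), integer deme sizes summing to the total population size, a
backward-in-time structured-coalescent genealogy over every haploid
individual, and aligned nucleotide sequences evolved along the
genealogy under a GTR substitution model.

Model conventions
-----------------
* Time is measured in generations; demes are haploid with size ``N_d``.
* Within a deme holding ``k`` lineages, each pair coalesces at rate
  ``1/N_d`` per generation (total ``k(k-1)/(2 N_d)``).
* The migration matrix entries ``m[i, j]`` are backward (lineage-tracing)
  rates: each lineage currently in deme ``i`` jumps to deme ``j`` at
  rate ``m[i, j]`` per generation.  Stepping-stone rates are applied
  per adjacent pair without renormalising by the number of neighbours.
* Sequence evolution is site-independent GTR with the rate matrix
  scaled so the expected number of substitutions per site per
  generation equals ``mu``.  The default model uses equal
  exchangeabilities and base frequencies (a Jukes-Cantor-equivalent
  parameterisation of GTR).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from spatialdiv.alignment import Alignment
from spatialdiv.geodesy import GeoPoint, distance_matrix

__all__ = [
    "DemeLayout",
    "Genealogy",
    "SubstitutionModel",
    "build_grid_layout",
    "build_island_layout",
    "build_single_deme",
    "assign_sizes",
    "largest_remainder_round",
    "simulate_genealogy",
    "mutate_sequences",
]

logger = logging.getLogger(__name__)

GridStructure = Literal["A", "B", "C", "D"]

# metres per degree used to place artificial grid layouts (meridian arc
# at the equator and at the pole, equatorial parallel); only the induced
# pairwise distances matter downstream
_M_PER_DEG_LON_EQ = 111319.49079327358
_M_PER_DEG_LAT_EQ = 110574.30485906031
_M_PER_DEG_LAT_POLE = 111694.0


@dataclass(frozen=True)
class DemeLayout:
    """Deme coordinates, sizes and the pairwise migration-rate matrix."""

    demes: tuple[GeoPoint, ...]
    sizes: np.ndarray
    migration: np.ndarray
    model: str  # "stepping_stone" | "island" | "single"
    structure: str = ""
    #: integer grid position of each deme (column, row); empty for
    #: non-grid layouts
    grid_pos: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))
    grid_shape: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        L = len(self.demes)
        if self.migration.shape != (L, L):
            raise ValueError("migration matrix shape mismatch")
        if (self.migration < 0).any():
            raise ValueError("migration rates must be non-negative")
        if np.diagonal(self.migration).any():
            raise ValueError("migration diagonal must be zero")
        if len(self.sizes) != L or (np.asarray(self.sizes) < 1).any():
            raise ValueError("each deme needs a positive size")

    @property
    def n_demes(self) -> int:
        return len(self.demes)

    @property
    def total_size(self) -> int:
        return int(np.sum(self.sizes))

    def distances(self) -> np.ndarray:
        """Pairwise geodesic distance matrix of the deme coordinates."""
        return distance_matrix(self.demes)

    def with_sizes(self, sizes: np.ndarray) -> "DemeLayout":
        return DemeLayout(
            demes=self.demes,
            sizes=np.asarray(sizes, dtype=int),
            migration=self.migration,
            model=self.model,
            structure=self.structure,
            grid_pos=self.grid_pos,
            grid_shape=self.grid_shape,
        )


def _grid_geometry(
    structure: GridStructure, n_demes: int, spacing_m: float
):
    """Coordinates, grid positions and adjacency for the four grids.

    A: linear (n x 1); B: circular (n x 1 ring); C: square plane;
    D: cylinder (n/2 x 2, wrapped longitudinally).  Grids are embedded
    on the ellipsoid so adjacent demes sit approximately ``spacing_m``
    apart: linear/plane layouts along the equator, ring layouts as
    circles of latitude around the pole (where rotational symmetry makes
    all adjacent distances exactly equal).
    """
    if structure == "A":
        nx, ny, wrap_x = n_demes, 1, False
    elif structure == "B":
        nx, ny, wrap_x = n_demes, 1, True
    elif structure == "C":
        g = round(math.sqrt(n_demes))
        if g * g != n_demes:
            raise ValueError(
                f"plane structure C needs a square deme count, got {n_demes}"
            )
        nx, ny, wrap_x = g, g, False
    elif structure == "D":
        if n_demes % 2:
            n_demes -= 1
        nx, ny, wrap_x = n_demes // 2, 2, True
    else:
        raise ValueError(f"unknown grid structure {structure!r}")

    pos = np.array([(ix, iy) for iy in range(ny) for ix in range(nx)], dtype=int)
    points = []
    if wrap_x:
        # rings of latitude around the north pole, one per row
        mean_colat_m = nx * spacing_m / (2 * math.pi)
        for ix, iy in pos:
            colat_m = mean_colat_m + (iy - (ny - 1) / 2) * spacing_m
            lat = 90.0 - colat_m / _M_PER_DEG_LAT_POLE
            lon = ix * 360.0 / nx - 180.0
            points.append(GeoPoint(id=f"deme{len(points)}", lat=lat, lon=lon))
    else:
        dlon = spacing_m / _M_PER_DEG_LON_EQ
        dlat = spacing_m / _M_PER_DEG_LAT_EQ
        for ix, iy in pos:
            lat = (iy - (ny - 1) / 2) * dlat
            lon = (ix - (nx - 1) / 2) * dlon
            points.append(GeoPoint(id=f"deme{len(points)}", lat=lat, lon=lon))

    L = len(points)
    adj = np.zeros((L, L), dtype=bool)
    index = {tuple(p): i for i, p in enumerate(pos)}
    for i, (ix, iy) in enumerate(pos):
        steps = [(ix + 1, iy), (ix - 1, iy), (ix, iy + 1), (ix, iy - 1)]
        for jx, jy in steps:
            if wrap_x:
                jx %= nx
            if (jx, jy) in index:
                adj[i, index[(jx, jy)]] = True
    np.fill_diagonal(adj, False)
    return tuple(points), pos, (nx, ny), adj


def build_grid_layout(
    structure: GridStructure,
    migration_rate: float,
    *,
    n_demes: int = 100,
    spacing_m: float = 10_000.0,
    deme_size: int = 100,
) -> DemeLayout:
    """Stepping-stone layout: linear (A), ring (B), plane (C), cylinder (D).

    Every grid-adjacent pair of demes exchanges migrants at the same
    per-generation rate ``migration_rate``; at most four neighbours per
    deme.  Sizes default to ``deme_size`` each (reassign with
    :func:`assign_sizes`).
    """
    if not 0.0 <= migration_rate < 1.0:
        raise ValueError("migration_rate must lie in [0, 1)")
    points, pos, shape, adj = _grid_geometry(structure, n_demes, spacing_m)
    migration = np.where(adj, migration_rate, 0.0)
    sizes = np.full(len(points), deme_size, dtype=int)
    return DemeLayout(
        demes=points,
        sizes=sizes,
        migration=migration,
        model="stepping_stone",
        structure=structure,
        grid_pos=pos,
        grid_shape=shape,
    )


def build_island_layout(
    n_demes: int = 100,
    r: float = 0.01,
    *,
    seed: int = 0,
    deme_size: int = 100,
    min_distance_m: float = 1_000.0,
    literal_normalisation: bool = False,
) -> DemeLayout:
    """Island layout: random coordinates, migration decaying with distance.

    Coordinates are uniform in latitude [-90, 90] and longitude
    [-180, 180).  Migration between every pair is inversely proportional
    to the geodesic distance and scaled so the mean rate over ordered
    pairs equals ``r``:

        m_ij = r * (1/d_ij) / mean_over_pairs(1/d_kl)

    ``literal_normalisation=True`` instead applies the scaling
    ``(r/d_mean) * (sum d_kl) / d_ij``, kept for archaeology: it
    preserves the inverse-distance shape but not the mean-rate
    calibration.  Coincident or very close demes have their distance
    floored at ``min_distance_m``.
    """
    if not 0.0 < r < 1.0:
        raise ValueError("average migration rate r must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    lats = rng.uniform(-90.0, 90.0, n_demes)
    lons = rng.uniform(-180.0, 180.0, n_demes)
    points = tuple(
        GeoPoint(id=f"deme{i}", lat=float(lats[i]), lon=float(lons[i]))
        for i in range(n_demes)
    )
    D = distance_matrix(points)
    off = ~np.eye(n_demes, dtype=bool)
    if (D[off] < min_distance_m).any():
        logger.info("flooring %d close deme distances at %.0f m",
                    int((D[off] < min_distance_m).sum()) // 2, min_distance_m)
    Df = np.maximum(D, min_distance_m)
    inv = np.where(off, 1.0 / Df, 0.0)
    if literal_normalisation:
        d_mean = D[off].mean()
        migration = (r / d_mean) * D[off].sum() * inv
    else:
        migration = r * inv / inv[off].mean()
    sizes = np.full(n_demes, deme_size, dtype=int)
    return DemeLayout(
        demes=points, sizes=sizes, migration=migration, model="island"
    )


def build_single_deme(total_size: int) -> DemeLayout:
    """A single panmictic deme (no migration, no geography)."""
    return DemeLayout(
        demes=(GeoPoint(id="deme0", lat=0.0, lon=0.0),),
        sizes=np.array([total_size], dtype=int),
        migration=np.zeros((1, 1)),
        model="single",
    )


def largest_remainder_round(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to ``weights``.

    Every weight's share is rounded down, then the leftover units are
    handed out one by one in order of decreasing fractional remainder
    (ties broken by index), so the result sums exactly to ``total``.
    """
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    exact = total * w / w.sum()
    sizes = np.floor(exact).astype(int)
    residuals = exact - sizes
    short = total - int(sizes.sum())
    if short > 0:
        order = np.argsort(-residuals, kind="stable")
        sizes[order[:short]] += 1
    return sizes


def assign_sizes(
    layout: DemeLayout,
    scheme: Literal["even", "truncated_normal", "latitude_normal"],
    total: int,
    *,
    latitude_coefficient: float = 0.027,
    truncation: float = 3.0,
) -> np.ndarray:
    """Integer deme sizes summing exactly to ``total``.

    ``even``
        Equal shares (largest-remainder rounded when not divisible).
    ``truncated_normal``
        Standard-normal density over the grid axes, each axis mapped
        linearly onto ``[-truncation, truncation]`` — a centre-periphery
        profile (abundant in the middle, sparse at the edges).  Requires
        a grid layout with at least one open axis.
    ``latitude_normal``
        ``total * dnorm(c * lat_i) / sum dnorm(c * lat_i)`` with the
        standard-normal density ``dnorm`` and ``c = 0.027`` by default,
        then largest-remainder rounding — most individuals near the
        equator, few near the poles.

    Zero sizes after rounding are promoted to 1, compensated by
    decrementing the largest deme.
    """
    L = layout.n_demes
    if total < L:
        raise ValueError("total size must be at least the number of demes")
    if scheme == "even":
        sizes = largest_remainder_round(np.ones(L), total)
    elif scheme == "truncated_normal":
        if len(layout.grid_pos) != L:
            raise ValueError("truncated_normal sizing requires a grid layout")
        nx, ny = layout.grid_shape
        weights = np.ones(L)
        for axis, extent in ((0, nx), (1, ny)):
            if extent < 2:
                continue
            x = layout.grid_pos[:, axis] / (extent - 1) * 2 * truncation - truncation
            weights *= np.exp(-0.5 * x**2)
        sizes = largest_remainder_round(weights, total)
    elif scheme == "latitude_normal":
        lats = np.array([p.lat for p in layout.demes])
        x = latitude_coefficient * lats
        weights = np.exp(-0.5 * x**2) / math.sqrt(2 * math.pi)
        sizes = largest_remainder_round(weights, total)
    else:
        raise ValueError(f"unknown size scheme {scheme!r}")

    zero = sizes == 0
    if zero.any():
        n_zero = int(zero.sum())
        logger.info("promoting %d zero-size demes to 1", n_zero)
        sizes[zero] = 1
        for _ in range(n_zero):
            sizes[int(np.argmax(sizes))] -= 1
    return sizes


@dataclass(frozen=True)
class Genealogy:
    """A rooted binary coalescent tree over the sampled lineages.

    Nodes ``0 .. n_leaves-1`` are leaves at time 0; internal nodes are
    numbered in coalescence order; the root's parent is -1.  Times are
    in generations.
    """

    parent: np.ndarray
    time: np.ndarray
    n_leaves: int
    leaf_deme: np.ndarray
    #: (time, kind, detail) event log; kind is "coal" or "mig"
    events: tuple = ()

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    @property
    def total_branch_length(self) -> float:
        keep = self.parent >= 0
        return float(
            (self.time[self.parent[keep]] - self.time[keep]).sum()
        )

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for node, par in enumerate(self.parent):
            if par >= 0:
                ch[par].append(node)
        return ch

    def to_newick(self, leaf_names: Sequence[str] | None = None) -> str:
        """Newick string with branch lengths in generations."""
        if leaf_names is None:
            leaf_names = [f"n{i}" for i in range(self.n_leaves)]
        ch = self.children()
        parts: dict[int, str] = {}
        # children-first iteration: internal nodes are numbered after
        # their descendants, so ascending order is a valid postorder
        for node in range(self.n_nodes):
            if node < self.n_leaves:
                parts[node] = leaf_names[node]
            else:
                inner = ",".join(
                    f"{parts[c]}:{self.time[node] - self.time[c]:.8g}"
                    for c in ch[node]
                )
                parts[node] = f"({inner})"
        return parts[self.root] + ";"


def simulate_genealogy(
    layout: DemeLayout,
    seed: int | np.random.Generator = 0,
    *,
    sample_sizes: Sequence[int] | None = None,
    max_events: int = 50_000_000,
    record_events: bool = False,
) -> Genealogy:
    """Backward-in-time structured coalescent over the layout's lineages.

    One lineage per individual by default (whole-population mode); pass
    ``sample_sizes`` (per deme) to trace a subsample instead.  Within
    deme ``d`` with ``k`` lineages and haploid size ``N_d``, some pair
    coalesces at rate ``k(k-1)/(2 N_d)``; each lineage migrates from
    ``i`` to ``j`` at rate ``m[i, j]``.  Events compete as independent
    exponentials until the grand MRCA.

    Raises ``RuntimeError`` if lineages are split across demes that no
    migration path can join, or if ``max_events`` is exceeded.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = layout.n_demes
    sizes = np.asarray(layout.sizes, dtype=float)
    counts = (
        np.asarray(layout.sizes, dtype=int)
        if sample_sizes is None
        else np.asarray(sample_sizes, dtype=int)
    )
    if len(counts) != L or (counts < 0).any():
        raise ValueError("sample_sizes must give a count per deme")
    n_leaves = int(counts.sum())
    if n_leaves < 2:
        raise ValueError("need at least two lineages")

    mig_total = layout.migration.sum(axis=1)
    # per-deme cumulative destination distribution
    mig_cum = [
        np.cumsum(layout.migration[d]) if mig_total[d] > 0 else None for d in range(L)
    ]

    leaf_deme = np.repeat(np.arange(L), counts)
    lineages: list[list[int]] = []
    node = 0
    for d in range(L):
        lineages.append(list(range(node, node + counts[d])))
        node += counts[d]

    n_nodes = 2 * n_leaves - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    events: list[tuple] = []

    k = counts.astype(float)
    inv2N = 0.5 / sizes
    t = 0.0
    next_node = n_leaves
    total_lineages = n_leaves
    n_events = 0

    while total_lineages > 1:
        coal_rates = k * (k - 1.0) * inv2N
        mig_rates = k * mig_total
        cum = np.cumsum(np.concatenate([coal_rates, mig_rates]))
        total_rate = cum[-1]
        if total_rate <= 0.0:
            raise RuntimeError(
                "no coalescence or migration possible with lineages in "
                "multiple demes (zero migration): no MRCA exists"
            )
        n_events += 1
        if n_events > max_events:
            raise RuntimeError(f"event cap {max_events} exceeded")
        t += rng.exponential(1.0 / total_rate)
        pick = int(np.searchsorted(cum, rng.random() * total_rate, side="right"))
        if pick < L:
            d = pick
            pool = lineages[d]
            i1 = int(rng.integers(len(pool)))
            c1 = pool[i1]
            pool[i1] = pool[-1]
            pool.pop()
            i2 = int(rng.integers(len(pool)))
            c2 = pool[i2]
            parent[c1] = next_node
            parent[c2] = next_node
            time[next_node] = t
            pool[i2] = next_node
            if record_events:
                events.append((t, "coal", d))
            next_node += 1
            k[d] -= 1.0
            total_lineages -= 1
        else:
            d = pick - L
            pool = lineages[d]
            i1 = int(rng.integers(len(pool)))
            lin = pool[i1]
            pool[i1] = pool[-1]
            pool.pop()
            dest = int(
                np.searchsorted(mig_cum[d], rng.random() * mig_total[d], side="right")
            )
            dest = min(dest, L - 1)
            lineages[dest].append(lin)
            if record_events:
                events.append((t, "mig", (d, dest)))
            k[d] -= 1.0
            k[dest] += 1.0

    return Genealogy(
        parent=parent,
        time=time,
        n_leaves=n_leaves,
        leaf_deme=leaf_deme,
        events=tuple(events),
    )


@dataclass(frozen=True)
class SubstitutionModel:
    """GTR substitution model scaled to ``mu`` substitutions/site/generation.

    ``exchangeabilities`` are the six upper-triangle rates in the order
    (AC, AG, AT, CG, CT, GT); ``base_freqs`` in the order A, C, G, T.
    """

    exchangeabilities: tuple[float, ...] = (1.0,) * 6
    base_freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    mu: float = 2e-8

    def __post_init__(self) -> None:
        if len(self.exchangeabilities) != 6 or len(self.base_freqs) != 4:
            raise ValueError("need 6 exchangeabilities and 4 base frequencies")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if any(x < 0 for x in self.exchangeabilities) or self.mu < 0:
            raise ValueError("rates must be non-negative")

    def rate_matrix(self) -> np.ndarray:
        """The scaled 4x4 generator Q (rows sum to zero)."""
        s = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        s[iu] = self.exchangeabilities
        s += s.T
        pi = np.asarray(self.base_freqs)
        Q = s * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -float(pi @ np.diagonal(Q))
        if rate > 0:
            Q *= self.mu / rate
        return Q

    def spectral(self):
        """Eigendecomposition of Q via the reversible symmetrisation."""
        pi = np.asarray(self.base_freqs)
        d = np.sqrt(pi)
        Q = self.rate_matrix()
        S = (d[:, None] * Q) / d[None, :]
        vals, vecs = np.linalg.eigh((S + S.T) / 2.0)
        left = vecs.T * d[None, :]  # rows: v^T D^{1/2}
        right = vecs / d[:, None]  # D^{-1/2} v
        return vals, right, left

    def transition_matrix(self, t: float, spectral=None) -> np.ndarray:
        """P(t) = exp(Q t), clipped to a valid stochastic matrix."""
        vals, right, left = spectral if spectral is not None else self.spectral()
        P = (right * np.exp(vals * t)[None, :]) @ left
        P = np.clip(P, 0.0, 1.0)
        return P / P.sum(axis=1, keepdims=True)


def mutate_sequences(
    genealogy: Genealogy,
    model: SubstitutionModel,
    length: int,
    seed: int | np.random.Generator = 0,
    *,
    ids: Sequence[str] | None = None,
) -> Alignment:
    """Evolve sequences down the genealogy; one leaf sequence per lineage.

    The root sequence is drawn from the model's base frequencies; each
    branch applies the site-independent transition matrix ``exp(Q t)``.
    Leaves are emitted in leaf order.
    """
    if length < 1:
        raise ValueError("sequence length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spectral = model.spectral()
    ch = genealogy.children()
    root = genealogy.root
    pi = np.asarray(model.base_freqs)

    seqs: dict[int, np.ndarray] = {}
    seqs[root] = rng.choice(4, size=length, p=pi).astype(np.uint8)
    pending = [root]
    leaf_codes: dict[int, np.ndarray] = {}
    while pending:
        node = pending.pop()
        seq = seqs[node]
        if node < genealogy.n_leaves:
            leaf_codes[node] = seq
        for child in ch[node]:
            dt = float(genealogy.time[node] - genealogy.time[child])
            if dt <= 0.0 or model.mu == 0.0:
                child_seq = seq.copy() if len(ch[node]) > 1 else seq
            else:
                P = model.transition_matrix(dt, spectral)
                # a site changes with prob 1 - P[b, b]; conditional on a
                # change, the new base follows the renormalised
                # off-diagonal row — together an exact draw from P[b, :]
                stay = np.diagonal(P)[seq]
                u = rng.random(length)
                child_seq = seq.copy()
                hit = np.flatnonzero(u >= stay)
                for b in range(4):
                    sites = hit[seq[hit] == b]
                    if sites.size == 0:
                        continue
                    probs = P[b].copy()
                    probs[b] = 0.0
                    cum = np.cumsum(probs / probs.sum())
                    draws = np.searchsorted(
                        cum, rng.random(sites.size), side="right"
                    ).clip(max=3)
                    child_seq[sites] = draws.astype(np.uint8)
            seqs[child] = child_seq
            pending.append(child)
        del seqs[node]

    mat = np.stack([leaf_codes[i] for i in range(genealogy.n_leaves)])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    strings = tuple(bases[row].tobytes().decode("ascii") for row in mat)
    if ids is None:
        ids = tuple(
            f"d{genealogy.leaf_deme[i]}_i{i}" for i in range(genealogy.n_leaves)
        )
    return Alignment(ids=tuple(ids), seqs=strings)
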