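"""Bias/accuracy simulation study of diversity estimators under spatial sampling.

Five experiment designs are supported, mirroring the simulation study
this package implements:

======  ==================  ==========================  ==============
  #     migration           subpopulation structure     deme sizes
======  ==================  ==========================  ==============
  1     stepping stone      grids A (linear), B (ring), even
                            C (plane), D (cylinder)
  2     stepping stone      grids A and C               centre-periphery
                                                        (truncated normal)
  3     island (1/d decay)  random coordinates          even
  4     island (1/d decay)  random coordinates          latitude-normal
  5     none                single panmictic deme       n/a
======  ==================  ==========================  ==============

For every (structure, migration rate, replicate): a whole statistical
population of N sequences is simulated; the population parameters
(nucleotide diversity pi, expected heterozygosity He, the average
substitution rate among allele types sigma) are computed on all N
sequences; a sample of each requested size is drawn — spatially
(annealing-chosen demes, one random individual per chosen deme) for
experiments 1-4, uniformly at random for experiment 5 — and the
estimators are compared to the parameters.

Per cell (experiment, structure, migration, sample size, measure) the
study reports the scaled mean error SME = mean((est - param) / param)
over replicates and the scaled root mean square error
SRMSE = mean(|est - param| / param), with their standard deviations.
Replicates whose whole population carries no segregating site have an
undefined relative error and are excluded outright.

Watterson's theta has no population parameter of its own; its per-site
value is benchmarked against the per-site Watterson value computed on
all N sequences (the headline: a geographically even sample keeps most
of the population's segregating sites while the harmonic-number
denominator shrinks, which is the overestimation mechanism under
study), and secondarily against the population nucleotide diversity
(measure ``theta_w_site_vs_pi``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from spatialdiv.alignment import Alignment, collapse_alleles
from spatialdiv.differentiation import SubdividedSample, gst, nst
from spatialdiv.diversity import (
    calc_diversity,
    expected_heterozygosity,
    nucleotide_diversity,
    pairwise_rate_matrix,
    segregating_sites,
    sigma_tilde,
)
from spatialdiv.sampling import spatial_sample
from spatialdiv.simulate import (
    DemeLayout,
    SubstitutionModel,
    assign_sizes,
    build_grid_layout,
    build_island_layout,
    build_single_deme,
    mutate_sequences,
    simulate_genealogy,
)

__all__ = [
    "ExperimentConfig",
    "PopulationParameters",
    "ReplicateResult",
    "ExperimentResult",
    "compute_parameters",
    "draw_sample",
    "run_experiment",
    "summarize",
    "MEASURES",
]

logger = logging.getLogger(__name__)

#: measure name -> (estimator key in DiversitySummary, parameter key)
MEASURES: dict[str, tuple[str, str]] = {
    "pi_tilde": ("pi_tilde", "pi"),
    "He_hat": ("He_hat", "He"),
    "sigma_hat": ("sigma_hat", "sigma"),
    "theta_w_site": ("theta_w_site", "theta_w_site"),
    "theta_w_site_vs_pi": ("theta_w_site", "pi"),
}

_DEFAULT_STRUCTURES = {
    1: ("A", "B", "C", "D"),
    2: ("A", "C"),
    3: ("island",),
    4: ("island",),
    5: ("single",),
}

_SIZE_SCHEMES = {
    1: "even",
    2: "truncated_normal",
    3: "even",
    4: "latitude_normal",
    5: "even",
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Full factorial description of one experiment run."""

    experiment: int
    migration_rates: tuple[float, ...] = (0.001, 0.01, 0.1, 0.5, 0.9)
    sample_sizes: tuple[int, ...] = (10, 20, 30, 40, 50)
    replicates: int = 20
    n_demes: int = 100
    total_size: int = 10_000
    sequence_length: int = 1_000
    mu: float = 2e-8
    annealing_iterations: int = 100_000
    spacing_m: float = 10_000.0
    seed: int = 0
    structures: tuple[str, ...] = ()
    substitution_model: SubstitutionModel | None = None

    def __post_init__(self) -> None:
        if self.experiment not in range(1, 6):
            raise ValueError("experiment must be 1..5")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.structures:
            object.__setattr__(
                self, "structures", _DEFAULT_STRUCTURES[self.experiment]
            )
        if self.experiment == 5:
            # single panmictic population: no migration dimension
            object.__setattr__(self, "migration_rates", (0.0,))
        if max(self.sample_sizes) > self.total_size:
            raise ValueError("sample sizes cannot exceed the population size")

    @classmethod
    def scaled(cls, experiment: int, *, seed: int = 0) -> "ExperimentConfig":
        """Desk-scale configuration: 25 demes, N = 1,000, mu = 2e-7.

        A proportionally shrunk version of the full design (which uses
        100 demes of 10,000 individuals at mu = 2e-8): the mutation rate
        is raised tenfold so the per-site diversity keeps its order of
        magnitude, migration rate 0.9 is dropped (at this scale it
        yields mostly mutation-free populations), and sample sizes are
        capped by the deme count.
        """
        return cls(
            experiment=experiment,
            migration_rates=(0.001, 0.01, 0.1, 0.5),
            sample_sizes=(10, 20, 30),
            replicates=10,
            n_demes=25,
            total_size=1_000,
            mu=2e-7,
            seed=seed,
        )

    def model(self) -> SubstitutionModel:
        base = self.substitution_model or SubstitutionModel()
        return replace(base, mu=self.mu)


@dataclass(frozen=True)
class PopulationParameters:
    """Statistical parameters computed on all N sequences."""

    pi: float
    He: float
    sigma: float
    theta_w_site: float
    N: int
    M: int
    K: int

    @property
    def excluded(self) -> bool:
        """True when the population carries no mutations (K = 0)."""
        return self.K == 0

    def get(self, key: str) -> float:
        return getattr(self, key)


@dataclass(frozen=True)
class ReplicateResult:
    """One replicate: parameters, per-sample-size estimates, diagnostics."""

    experiment: int
    structure: str
    migration: float
    replicate: int
    parameters: PopulationParameters
    #: sample size -> measure estimates (DiversitySummary.as_dict())
    estimates: dict[int, dict[str, float]]
    gst: float | None = None
    nst: float | None = None

    @property
    def excluded(self) -> bool:
        return self.parameters.excluded


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    replicates: list[ReplicateResult]
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def differentiation_table(self) -> pd.DataFrame:
        rows = [
            {
                "experiment": r.experiment,
                "structure": r.structure,
                "migration": r.migration,
                "replicate": r.replicate,
                "gst": r.gst,
                "nst": r.nst,
                "excluded": r.excluded,
            }
            for r in self.replicates
            if r.gst is not None
        ]
        return pd.DataFrame(rows)


def compute_parameters(population: Alignment) -> PopulationParameters:
    """Population parameters from all N sequences.

    pi via the frequency-weighted double sum over allele types, He from
    the haplotype frequencies, sigma as the unweighted mean substitution
    rate over allele-type pairs.  A population without segregating
    sites is flagged for exclusion (relative errors are undefined).
    """
    alleles = collapse_alleles(population)
    rates = pairwise_rate_matrix(alleles.haplotypes)
    freqs = alleles.freqs
    pi = nucleotide_diversity(freqs, rates)
    He = expected_heterozygosity(freqs)
    sigma = sigma_tilde(alleles, rates)
    K = segregating_sites(population)
    harmonic = sum(1.0 / i for i in range(1, population.n))
    theta_site = K / harmonic / population.length if population.length else 0.0
    return PopulationParameters(
        pi=pi,
        He=He,
        sigma=sigma,
        theta_w_site=theta_site,
        N=population.n,
        M=alleles.m,
        K=K,
    )


def draw_sample(
    population: Alignment,
    rng: np.random.Generator,
    *,
    mode: Literal["spatial", "random"],
    k: int,
    leaf_deme: np.ndarray | None = None,
    chosen_demes: Sequence[int] | None = None,
) -> Alignment:
    """Draw a size-k sample from the whole population.

    ``spatial``: one uniformly random individual from each chosen deme
    (the demes themselves having been selected for geographic evenness).
    ``random``: k individuals uniformly without replacement.
    """
    if mode == "random":
        if k > population.n:
            raise ValueError("sample size exceeds the population size")
        idx = rng.choice(population.n, size=k, replace=False)
        return population.subset(sorted(int(i) for i in idx))
    if leaf_deme is None or chosen_demes is None:
        raise ValueError("spatial sampling needs deme labels and chosen demes")
    if len(chosen_demes) != k:
        raise ValueError("number of chosen demes must equal k")
    idx = []
    for d in chosen_demes:
        members = np.flatnonzero(leaf_deme == d)
        if members.size == 0:
            raise ValueError(f"deme {d} holds no individuals")
        idx.append(int(members[rng.integers(members.size)]))
    return population.subset(idx)


def _build_layout(cfg: ExperimentConfig, structure: str, migration: float) -> DemeLayout:
    if structure in ("A", "B", "C", "D"):
        layout = build_grid_layout(
            structure,
            migration,
            n_demes=cfg.n_demes,
            spacing_m=cfg.spacing_m,
        )
    elif structure == "island":
        layout = build_island_layout(
            cfg.n_demes,
            migration,
            seed=_subseed(cfg.seed, cfg.experiment, "layout"),
        )
    elif structure == "single":
        return build_single_deme(cfg.total_size)
    else:
        raise ValueError(f"unknown structure {structure!r}")
    sizes = assign_sizes(layout, _SIZE_SCHEMES[cfg.experiment], cfg.total_size)
    return layout.with_sizes(sizes)


def _subseed(*parts) -> np.random.SeedSequence:
    entropy = []
    for p in parts:
        if isinstance(p, str):
            entropy.extend(p.encode())
        elif isinstance(p, float):
            entropy.append(int(p * 10**9))
        else:
            entropy.append(int(p))
    return np.random.SeedSequence(entropy)


def _spatial_selection_cache(cfg: ExperimentConfig):
    cache: dict[tuple, tuple[int, ...]] = {}

    def get(structure: str, layout: DemeLayout, k: int, distances) -> tuple[int, ...]:
        key = (structure, k)
        if key not in cache:
            sel = spatial_sample(
                layout.demes,
                k,
                iterations=cfg.annealing_iterations,
                seed=int(
                    _subseed(cfg.seed, cfg.experiment, structure, k, "anneal")
                    .generate_state(1)[0] % (2**31)
                ),
                distances=distances,
            )
            cache[key] = sel.chosen
        return cache[key]

    return get


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run the full factorial and summarise bias and accuracy per cell.

    Geometry-dependent work is shared where the design allows: the
    annealing-based deme selection depends only on (structure, k), not
    on the simulated sequences, so it is performed once per combination;
    each replicate then gets its own random streams for the genealogy,
    the mutation process and the one-individual-per-deme draws.
    """
    model = cfg.model()
    select = _spatial_selection_cache(cfg)
    spatial = cfg.experiment in (1, 2, 3, 4)
    replicates: list[ReplicateResult] = []

    for structure in cfg.structures:
        for migration in cfg.migration_rates:
            layout = _build_layout(cfg, structure, migration)
            distances = layout.distances() if spatial else None
            feasible = [
                k for k in cfg.sample_sizes if not spatial or k <= layout.n_demes
            ]
            skipped = set(cfg.sample_sizes) - set(feasible)
            if skipped:
                logger.info(
                    "experiment %d %s: sample sizes %s exceed the %d demes; skipped",
                    cfg.experiment, structure, sorted(skipped), layout.n_demes,
                )
            selections = {
                k: select(structure, layout, k, distances) if spatial else None
                for k in feasible
            }
            for rep in range(cfg.replicates):
                ss = _subseed(cfg.seed, cfg.experiment, structure, migration, rep)
                rng_gene, rng_mut, rng_draw = (
                    np.random.default_rng(s) for s in ss.spawn(3)
                )
                genealogy = simulate_genealogy(layout, rng_gene)
                population = mutate_sequences(
                    genealogy, model, cfg.sequence_length, rng_mut
                )
                params = compute_parameters(population)
                g = n = None
                if spatial and not params.excluded:
                    groups = [
                        population.subset(np.flatnonzero(genealogy.leaf_deme == d))
                        for d in range(layout.n_demes)
                    ]
                    sub = SubdividedSample.from_alignments(groups)
                    g, n = gst(sub), nst(sub)
                estimates: dict[int, dict[str, float]] = {}
                if not params.excluded:
                    for k in feasible:
                        sample = draw_sample(
                            population,
                            rng_draw,
                            mode="spatial" if spatial else "random",
                            k=k,
                            leaf_deme=genealogy.leaf_deme,
                            chosen_demes=selections[k],
                        )
                        estimates[k] = calc_diversity(sample).as_dict()
                replicates.append(
                    ReplicateResult(
                        experiment=cfg.experiment,
                        structure=structure,
                        migration=migration,
                        replicate=rep,
                        parameters=params,
                        estimates=estimates,
                        gst=g,
                        nst=n,
                    )
                )
    table = summarize(replicates)
    return ExperimentResult(config=cfg, replicates=replicates, table=table)


def summarize(results: Sequence[ReplicateResult]) -> pd.DataFrame:
    """Per-cell SME/SRMSE table from replicate results.

    Excluded replicates (mutation-free populations) are dropped from
    every cell's denominator; cells with no included replicate are
    omitted.
    """
    rows = []
    keyfunc = lambda r: (r.experiment, r.structure, r.migration)
    groups: dict[tuple, list[ReplicateResult]] = {}
    for r in results:
        groups.setdefault(keyfunc(r), []).append(r)
    for (exp, structure, migration), reps in groups.items():
        included = [r for r in reps if not r.excluded]
        n_excluded = len(reps) - len(included)
        if not included:
            continue
        sizes = sorted({k for r in included for k in r.estimates})
        for k in sizes:
            for measure, (est_key, par_key) in MEASURES.items():
                errs = []
                for r in included:
                    if k not in r.estimates:
                        continue
                    param = r.parameters.get(par_key)
                    if param == 0:
                        continue
                    errs.append((r.estimates[k][est_key] - param) / param)
                if not errs:
                    continue
                errs = np.asarray(errs)
                rows.append(
                    {
                        "experiment": exp,
                        "structure": structure,
                        "migration": migration,
                        "sample_size": k,
                        "measure": measure,
                        "sme": errs.mean(),
                        "srmse": np.abs(errs).mean(),
                        "sme_sd": errs.std(ddof=1) if len(errs) > 1 else 0.0,
                        "srmse_sd": np.abs(errs).std(ddof=1)
                        if len(errs) > 1
                        else 0.0,
                        "n_replicates": len(errs),
                        "n_excluded": n_excluded,
                    }
                )
    return pd.DataFrame(rows)
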