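# Methods

## The measures

All statistics operate on an alignment of `n` equal-length nucleotide
sequences, one per individual, after removal of every column containing a
character outside {A, C, G, T}.  The alignment collapses into `m` distinct
haplotypes ("allele types") with frequencies `p_i = counts / n`, and the
per-site substitution rate between types `i` and `j` is the raw p-distance
`pi_ij` (mismatching sites / length; no multiple-hit correction — deliberate,
since every quantity downstream is defined on observed differences).

| measure | definition | notes |
|---|---|---|
| `He` | `1 − Σ p_i²` | expected heterozygosity |
| `He_hat` | `2n/(2n−1) · He` | finite-sample correction, implemented with the printed `2n/(2n−1)` factor |
| `pi_hat` | `Σ_i Σ_j p_i p_j pi_ij` | plug-in nucleotide diversity |
| `pi_tilde` | `n/(n−1) · pi_hat` | bias-corrected nucleotide diversity |
| `theta_w` | `K / Σ_{i<n} 1/i` | `K` = segregating sites; per-site value divides by the alignment length |
| `sigma_hat` | `(Σ_{i≠j} pi_ij) / (m(m−1))`, `0` if `m = 1` | frequency-independent average substitution rate among allele types |

On a whole statistical population of `N` sequences with `M` allele types the
same formulas give the parameters `He`, `pi` and `sigma`.  The `sigma`
piecewise definition is applied for every `m ≥ 2`: at `m = 2` the general
formula evaluates to the single pairwise rate, which is what the worked
examples and the expectation argument require; only the monomorphic case is
pinned to zero.

`sigma` weighs every allele type equally, so rare, phylogenetically distant
alleles contribute as much as common ones.  Its natural estimation context is
one-individual-per-location spatial sampling: under isolation by distance the
distant rare types live in distant demes, which an evenly spread sample
visits.  The auxiliary quantity `sigma_n` — the maximum of `sigma_hat` over
all size-`n` subsets of the population — is computed by exhaustive enumeration
(`sigma_n_oracle`) and is only feasible on toy populations; the guard refuses
when `C(N, n)` exceeds a configurable cap.

## Geodesics

No geodesic library is available in the target environment, so the GRS80
inverse problem is solved in-package: reduced latitudes map the geodesic onto
a great circle of an auxiliary sphere; the ellipsoidal longitude difference
and arc length are the standard integrals in the spherical arc `sigma` with
modulus `k² = e'² cos² alpha0`, evaluated by 64-node Gauss-Legendre
quadrature (the integrands vary by at most `e'² ≈ 0.0067`, so quadrature
error is far below a micrometre); the departure azimuth is found by bracketed
Brent root finding on the longitude equation, which — unlike Vincenty-style
fixed-point iteration — cannot fail to converge, including near-antipodal
geometry.  Pure-meridian, equatorial and antipodal-in-longitude cases are
handled by their closed-form special cases.  Agreement with an independent
high-accuracy implementation (R `geosphere::distGeo`) is better than 4e-8 m
on 300 random pairs and ~1 mm in the worst near-antipodal case.

## Spatial sampling

Location selection maximises geographic evenness over k-subsets of the
candidate coordinates by simulated annealing: each proposal either swaps a
chosen point for a uniformly random unchosen one or slides it to one of its
nearest unchosen neighbours (the local move that redistributes spacing across
plateaus of equal minimum distance); geometric cooling; best-seen subset
returned.  The default
objective is maximin (p-dispersion: maximise the smallest pairwise geodesic
distance), tie-broken by total pairwise distance; a sum-of-distances
objective is available.  The published protocol this mirrors does not print
its objective or schedule; maximin is the one consistent with its description
("geographically even") and its ring-structure behaviour (every 10th deme of
a 100-deme ring), and the iteration budget of 100,000 proposals matches the
printed repetition count.  Initial temperature is the standard deviation of
objective deltas over 100 random swaps; final temperature is 1e-4 of that.
Runs are deterministic given the seed.

## Population simulator

Backward-in-time structured coalescent in continuous time over haploid demes:
within a deme holding `k` lineages of size `N_d`, pairwise coalescence at
total rate `k(k−1)/(2 N_d)` per generation; each lineage in deme `i` migrates
to `j` at the backward rate `m_ij`.  Stepping-stone grids (linear A, ring B,
plane C, cylinder D) give every adjacent pair the same rate without
renormalising by neighbour count; the island model draws uniform random
coordinates and sets `m_ij = r (1/d_ij) / mean(1/d_kl)`, so rates decay
inversely with geodesic distance and average exactly `r` over ordered pairs.
The simulator was validated against the two-deme closed form
(`E[T|same deme] = 2N`, `E[T|different] = 2N + 1/(2m)`) and against msprime
whole-population tree lengths on a 25-deme chain.

Deme sizes are apportioned by largest-remainder rounding (floor everything,
then hand out the shortfall in order of decreasing fractional remainder),
guaranteeing the exact total.  Size schemes: even; centre-periphery
(standard-normal density over each open grid axis mapped to [−3, 3]); and
latitude-normal (`total · dnorm(0.027 · lat_i) / Σ dnorm(0.027 · lat_i)`),
which concentrates individuals near the equator.

Sequences evolve site-independently along the genealogy under a GTR model
scaled to `mu` expected substitutions/site/generation (default `2e-8`, the
rate used throughout the full-scale study design; equal exchangeabilities and
base frequencies by default, i.e. a Jukes-Cantor-equivalent GTR, since no
GTR parameters are printed for the original study and the neutral choice
moves no diversity expectation).  Transition matrices come from the symmetric
eigendecomposition of the reversible generator; per branch, each site mutates
with probability `1 − P[b,b]` and conditional draws over the off-diagonal
row, which is an exact per-site draw from `exp(Qt)` at a cost proportional to
the (small) number of actual changes.

## The bias/accuracy study

For each (structure, migration rate, replicate) a whole population is
simulated and its parameters computed from all `N` sequences; samples are
drawn spatially (annealing-chosen demes, one uniformly random individual per
chosen deme) in experiments #1–4 and uniformly at random in #5; every
estimator is compared with its own population parameter.  Per cell
(experiment, structure, migration, sample size, measure):

    SME   = mean over replicates of (estimate − parameter) / parameter
    SRMSE = mean over replicates of |estimate − parameter| / parameter

with standard deviations of both.  A replicate whose population carries no
segregating site is excluded outright (its relative errors are undefined);
exclusion never alters the included replicates.  Grand means average cells
with equal weight; "grand bias" figures keep the sign of each cell's SME
before averaging — positive and negative cells may cancel, which is exactly
what "nearly unbiased on average" means — and are reported as absolute
values of that signed mean.

Watterson's theta estimates the population mutation rate and has no
population counterpart among the three diversity parameters.  Its headline
benchmark is the per-site Watterson value computed on all `N` sequences: a
geographically even sample keeps most of the population's segregating sites
while the harmonic-number denominator shrinks from `H_{N−1}` to `H_{n−1}`,
which is the overestimation mechanism the study quantifies.  Cross-referencing
the sample theta against the population's nucleotide diversity is also
emitted (`theta_w_site_vs_pi`) but shows no systematic signal — confirmed
both with this package's simulator and with an independent msprime
resimulation at the full design scale.

The annealing selection depends only on the layout and `k`, not on the
simulated sequences, so it runs once per (experiment, structure, k); the
genealogy, mutation process and per-deme individual draws get independent
per-replicate streams spawned from the master seed.

### Problem sizes

The full printed design (100 demes, `N = 10,000`, `mu = 2e-8`, 20
replicates, sample sizes 10–50, migration rates 0.001–0.9) is supported
throughout.  The package's standard study configuration
(`ExperimentConfig.scaled`) runs 25 demes (A/B 25×1, C 5×5, D 12×2),
`N = 1,000`, `mu = 2e-7` — ten times the full-scale rate so `theta = 2 N mu`
keeps its order of magnitude — 10 replicates, migration rates
{0.001, 0.01, 0.1, 0.5} and sample sizes {10, 20, 30}.  Rate 0.9 is dropped
because at this population size it yields mostly mutation-free populations;
spatial sample size 30 exceeds the 25-deme count and is skipped for
experiments #1–4 (one individual per location is a hard constraint) while
experiment #5 keeps it.  Experiment #5 additionally runs at the full printed
scale, where a single panmictic deme is cheap.

### What the scaled runs do and do not show

The scaled conditions reproduce the study's qualitative contrasts: corrected
nucleotide diversity is nearly unbiased under spatial sampling (grand bias
~1%) but clearly positively biased under random sampling from a panmictic
population; Watterson's theta is strongly overestimated overall and by far
more than 50% in every low-migration even-grid cell; the allele-type average
substitution rate always exceeds corrected nucleotide diversity on sample
averages.  Two full-scale quantitative features do not carry down:

1. **Low-diversity cells dominate some grand averages.**  With
   `theta_locus ≈ 0.4`, weakly structured populations hold only a handful of
   segregating sites and allele types, so relative errors per cell are large
   and heavy-tailed, inflating grand SRMSE, and the average-substitution-rate
   estimator is systematically low there (a sample of 10–30 individuals
   misses rare allele types; the estimator equals the parameter only when
   most types are seen).  This is the same mechanism the original study
   reports for its own low-parameter conditions (its panmictic experiment
   showed biases of tens of percent); at the reduced deme count a larger
   fraction of cells sits in that regime.
2. **The island model is nearly panmictic under the mean-calibrated
   migration reading.**  Solving the expected pairwise coalescence times
   exactly shows mean depth ≈ the total population size at both 25 and 100
   demes when `m_ij` averages to `r`, so the island experiments contribute
   little isolation-by-distance signal.  The deep island diversities the
   original study reports are only reachable if its printed (dimensionally
   inconsistent, unit-dependent) normalisation — or a composite-rate
   convention of its simulator — produced much smaller absolute rates; that
   cannot be recovered from the text, and the mean-rate reading is the one
   its own description states.  The literal normalisation is available via
   `build_island_layout(..., literal_normalisation=True)`.

## Numerical policy

Double precision throughout; test equality at 1e-9 absolute unless
integer-exact.  Degenerate inputs: monomorphic samples return zero for every
measure; cleaning may return a zero-length alignment (with a warning);
differentiation indices return 0 when total diversity is 0; the coalescent
raises when lineages are split across demes that migration cannot join, and
guards non-termination with an event cap.  Ties in largest-remainder
apportionment and annealing tie-breaks resolve by index order, making every
run reproducible bit for bit given its seed.
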