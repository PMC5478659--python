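# Methods

This note documents the models and procedures implemented in `sadscale`,
the parameter choices that matter, the numerical details, and what the
synthetic data generator does and does not emulate.

## Octave binning and moments

Abundance class *i* holds the species with between 2^i and 2^(i+1) − 1
individuals (1; 2–3; 4–7; …), so a species with n individuals falls in
class ⌊log₂ n⌋. The number of classes of a sample is
NB = ⌊log₂ N_max⌋ + 1 and interior empty classes are kept as explicit
zeros, so a histogram's support is always the contiguous integer lattice
{0..NB−1} — the domain the Tchebichef basis needs.

All moments use the base-2 logarithms of abundance and the population
convention (division by the species count S, no Bessel correction):
M_n = (1/S)Σx_jⁿ, C_n = (1/S)Σ(x_j−x̄)ⁿ, T_n = (1/S)Σ((x_j−x̄)/σ_x)ⁿ.
Skewness is T₃. When σ_x = 0 (every species equally abundant) the
standardized moments are undefined; the package raises
`DegenerateDistributionError` rather than silently returning 0, and
trajectory averages exclude (and count) such steps. This matters at very
small accumulations, where a pooled sample can consist entirely of
singletons.

There are two abscissa conventions. The vector form uses the continuous
values x_j = log₂ n_j; the histogram form (`binned_raw_moment`) uses the
integer class index i ∈ {0..NB−1} weighted by the class proportions p_i.
Moments on class indices determine the histogram exactly (see below);
moments on log₂ values are the quantities that scale cleanly with sample
size. The forecast follows the established practice of feeding the
log₂-value moments into the class-index reconstruction — a deliberate
approximation (each x_j sits inside, not at the left edge of, its class,
an offset of up to one bin) accepted because the class-index moments do
not show the clean power-law growth that makes extrapolation possible.

## Transect accumulation

Transects are pooled in order of spatial proximity, treating transect
count as a surrogate for area and effort. Two orderings: *concentric*
(nearest, second nearest, … to a fixed start) and *sequential* (greedy
nearest-neighbour chain). Each of the T transects starts one ordering, so
T orderings exist per method; trajectory statistics are the mean and
sample standard deviation (ddof = 1) over those T orderings, plotted as
±2 SD bands. The two methods give virtually identical results on both
real-world designs and our simulations; concentric is the default.
Distance ties break by ascending transect id, making orderings
deterministic. Coordinates are planar metres; latitude/longitude input is
projected with a small-region equirectangular projection on ingest, which
is accurate to well under a percent at km-scale island extents.

`perturb_dispersal_labels` flips the high/low class of a seeded random
fraction of species, emulating misclassification of dispersal ability by
the assessing taxonomist; the sensitivity analysis checks that the
high-vs-low skewness contrast survives a 5 % misidentification rate.

## Power-law scaling of the moments

Raw moments M_n(t), richness S(t) and maximum abundance N_max(t) are
fitted as power laws by OLS of log(value) on log(size) (statsmodels;
natural logs internally — exponents are base-invariant). The default
scaling region is all sizes ≥ 2 transects, because power laws are known
to fail at the very smallest samples; the lower cutoff is configurable
and no automatic changepoint detection is attempted. Accumulated moments
at successive sizes reuse the same data, so residuals are autocorrelated;
`residual_diagnostics` reports the lag-1 autocorrelation of the log-space
residuals. The oscillation amplitude is typically very small and
generalized least squares with AR(1) errors is reported in the literature
to leave such fits unchanged, so OLS is the single estimator here.
`extrapolate` warns beyond a factor of 4 of the largest fitted size —
the method has only been validated to ×2 and (optimistically) ×4.

## Tchebichef reconstruction

The scaled discrete Tchebichef polynomials are orthonormal with unit
weight on {0..N−1}: t₀(x) = 1/√N, t₁(x) = (2x+1−N)√(3/(N(N²−1))), and
for n ≥ 2 the three-term recurrence

    t_n(x) = (α₁x + α₂) t_{n−1}(x) − α₃ t_{n−2}(x)

with α₁ = (2/n)√((4n²−1)/(N²−n²)), α₂ = ((1−N)/n)√((4n²−1)/(N²−n²)),
α₃ = ((n−1)/n)·√((2n+1)/(2n−3))·√((N²−(n−1)²)/(N²−n²)). The recurrence
is run both on values and on monomial coefficients c_{n,k}
(t_n(x) = Σ c_{n,k}x^k), the latter giving the linear map from power
moments to Tchebichef moments, T_n = Σ_k c_{n,k} μ_k. Reconstruction is
p̂(x) = Σ_{n≤k} T_n t_n(x); with all N moments it is exact (the basis is
complete), and with fewer it is the least-squares projection, so the
truncation error decreases monotonically in k.

Numerics. Converting *power* moments to Tchebichef moments is severely
ill-conditioned: the c_{n,k} are large with alternating signs, and at
order ~31 on a 32-class support double precision loses everything
(errors ~10²⁰). The conversion and, for full-order work, the basis
evaluation therefore accept a `dps` argument that reruns them in
extended precision (mpmath); with 60 digits the round trip
histogram → class-index moments → Tchebichef moments → histogram is
exact to ~10⁻¹⁵ for N ≤ 32. The forecast pipeline never needs this: it
uses orders ≤ 6, where float64 is accurate to ~10⁻¹², and the projection
route T_n = Σ p(x)t_n(x) is stable at any order.

Truncated reconstructions can dip negative; negative entries are clipped
to zero and the density renormalized. The clipped mass is logged as an
instability indicator. The paper trail for clipping conventions in
moment-based density reconstruction is thin, and this choice slightly
redistributes mass to the retained classes; at the low orders selected in
practice the clipped mass is at most a few percent.

## Order selection and the forecast

The reconstruction order k\* is the k ∈ {1..k_max} whose k-moment
reconstruction, scaled by S, minimizes the sum of squared differences to
the empirical histogram at the largest observed size; ties break toward
smaller k. The default k_max is min(6, NB−1): ten moment orders are
fitted (they help judge the scaling region), but extrapolated high-order
moments amplify fitting error and published applications used orders
3–5. Two guards run at forecast time: extrapolated moments are screened
against the power-mean inequality (M_n^{1/n} nondecreasing in n — any
genuine moment sequence satisfies it, extrapolated ones need not), and
the reconstruction falls back to a lower order with a logged warning if
any converted |T_n| exceeds 2 (a true density has |T_n| ≤ 1) or more
than half the mass is clipped.

The forecast support NB\* = ⌊log₂ N_max\*⌋ + 1 comes from the
extrapolated maximum abundance; a target support smaller than the
observed one is rejected as inconsistent. Each ordering yields its own
scaling fits, order and forecast; the ensemble across start transects is
aggregated per class (mean, sample SD), and k\* is selected per ordering
before averaging. The choice to select per ordering (rather than once on
pooled fits) keeps each ensemble member a complete, internally
consistent run of the procedure.

The half-data validation refits everything on the first T/2 accumulation
steps of each ordering and forecasts to the full T; coverage is the
fraction of octave classes whose full-data empirical count lies within
the ensemble's ±2 SD band. On simulated two-community tables coverage is
typically 0.8–1.0 per group. The weak spot is the rightmost class: a
single mega-abundant species dominates N_max, whose power-law
extrapolation is the noisiest ingredient.

## The neutral simulator

A point-mutation, zero-sum Moran process on an L × L torus, one
individual per cell: each event kills a uniformly chosen individual and
replaces it, with probability ν, by a brand-new species (point
speciation), otherwise by the offspring of a parent drawn from the
dispersal kernel centred on the vacated cell. One generation is L²
events. Kernels: `global` (parent uniform over the landscape — the
high-dispersal community), `gaussian` (offsets are rounded normal
deviates of scale σ cells, torus-wrapped, the vacated cell excluded —
the low-dispersal community at σ = 1) and `nearest_neighbour`. This is
the minimal model consistent with the neutral tenets (identical death,
birth, speciation and dispersal probabilities for all individuals); no
habitat heterogeneity, species interactions, or continuous dispersal
traits.

Defaults are desk scale: **L = 256, ν = 10⁻³, 200 generations, single
ancestral species**. ν = 10⁻³ yields 300–450 coexisting species, the
order of magnitude of a well-sampled island arthropod community, and
200 generations suffice for the diffusive clusters of the σ = 1
community to reach tens of cells across — the regime in which the
dispersal contrast expresses itself. Richness is recorded per generation
and `is_stationary` (relative change < 1 % over 10 generations) monitors
burn-in adequacy; at these defaults richness is still creeping upward
slowly, which mirrors the empirical situation (real samples are nowhere
near the asymptotic community either) and does not affect the
qualitative contrast. A 1024² landscape is supported but takes
correspondingly longer.

Nested-square sampling (`sample_squares`) averages the octave histograms
of all disjoint 2^k-sided tiles; `landscape_to_transects` instead places
disjoint elongated windows (default ~16:1, emulating long thin field
transects) at seeded random positions, and `paired_transect_tables`
samples identical windows from the high- and low-dispersal landscapes to
build a merged two-group table.

What the generator does *not* emulate: observation error, taxonomic
lumping, the soil/canopy sub-sampling structure of real transects,
habitat mosaics, and dispersal as a continuum. Passing the dispersal
contrast tests therefore shows that the analysis pipeline detects the
aggregation signal the neutral model produces — not that real arthropod
communities are neutral.

## Problem sizes used in the tests

The test and acceptance runs use 24 transects of 256 cells from paired
L = 256 communities, a 10-replicate simulation panel for the dispersal
contrast, 200 random histograms (N ≤ 32) for the reconstruction round
trip, and supports up to N = 64 at orders ≤ 12 for orthonormality —
sizes at which every property is sharply resolved while the whole suite
runs in a couple of minutes on one CPU.

## Known limitations

- The forecast inherits every assumption of the power-law fits; moments
  of SADs very likely show scaling transitions over wider ranges of
  sample size, and no multi-regime detection is attempted.
- The log₂-value / class-index approximation (up to one bin of offset)
  biases reconstructed shapes slightly leftward; it is accepted for the
  reasons above and shared by the method this package implements.
- N_max extrapolation controls the forecast support and is driven by a
  single species; forecasts of the rightmost one or two classes are the
  least reliable.
- Skewness is undefined for degenerate pooled samples; at t = 1–2 the
  trajectory can rest on few orderings (the counts are reported).
- At the simulator's desk-scale defaults the single ancestral species is
  still a transient mega-dominant, so a label-misidentification draw
  that happens to flip *that* species moves the skewness contrast far
  more than flipping 5 % of ordinary species; the robustness summary is
  therefore reported as a fraction over independent flip draws rather
  than a single binary outcome.
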