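# sadscale

Multi-scale analysis and forecasting of **species abundance distributions
(SADs)** — for community ecologists and macroecologists who want to know
not just what a SAD looks like at one sampling effort, but how its shape
changes as samples accumulate, and what it will probably look like at two
or four times the current effort.

## The problem and the method

A SAD is the histogram of species counts over doubling (octave) abundance
classes: 1 individual; 2–3; 4–7; *et seq.* (class *i* holds species with
abundance in [2^i, 2^(i+1)−1]). Small samples are dominated by singletons
and lean hard to the left; as sampling grows, a hump develops at
intermediate classes — and how fast it develops depends on how spatially
aggregated the species are, hence on their dispersal ability.

Instead of fitting a parametric distribution at each scale, `sadscale`
describes the SAD by its moments of the base-2 log abundances
x_j = log₂ n_j:

- raw moments **M_n = (1/S) Σ_j x_jⁿ**, with S the number of species;
- central moments C_n = (1/S) Σ_j (x_j − x̄)ⁿ;
- standardized moments T_n = (1/S) Σ_j ((x_j − x̄)/σ_x)ⁿ, with
  **skewness = T₃** as the key shape descriptor.

Transects (standardized sampling units with known coordinates) are pooled
in order of spatial proximity — concentrically from a start transect, or
by greedy nearest-neighbour chaining — and every transect serves once as
the start, giving T orderings for T transects. Along each accumulation the
raw moments, species richness S(t) and the maximum abundance N_max(t) all
grow approximately as **power laws of the number of transects t** (straight
lines in log–log, like the species–area relationship). The forecast at a
larger sample size then:

1. fits log M_n vs log t by OLS for orders n = 1..10, plus S(t) and
   N_max(t);
2. picks the reconstruction order k\* that best reproduces (least squares)
   the observed histogram at the largest available size;
3. extrapolates M_1..M_k\*, S and N_max to the target size (×2 or,
   optimistically, ×4 — further extrapolation triggers a warning);
4. sets the forecast support to NB\* = ⌊log₂ N_max\*⌋ + 1 octave classes
   and inverts the moments into a density with **scaled discrete Tchebichef
   polynomials** — polynomials orthonormal on the integer lattice
   {0..NB\*−1}, borrowed from image analysis, which reconstruct a discrete
   density exactly when all class-index moments are supplied;
5. scales the density by S\* and aggregates mean ± 2 SD across the T
   orderings.

A spatially explicit zero-sum neutral simulator (point-mutation Moran
process on a torus with a configurable dispersal kernel) generates
communities of contrasting dispersal ability, reproducing the predicted
pattern: well-mixed ("high dispersal") communities keep a high singleton
count and high skewness as samples grow, while aggregated ("low
dispersal") communities develop an interior mode much earlier.

## Worked example

Simulate a high- and a low-dispersal community on a 256 × 256 torus,
sample 24 paired transect windows, and look at the skewness trajectory:

```python
import sadscale as ss

high = ss.run_simulation(ss.SimConfig(kernel="global", seed=1))
low  = ss.run_simulation(ss.SimConfig(kernel="gaussian", sigma=1.0, seed=2))
table = ss.paired_transect_tables(high, low, n_transects=24,
                                  transect_cells=256, seed=5)

traj = ss.skewness_trajectory(table)
print(traj[traj.n_transects.isin([4, 12, 24])])
```

```
group  n_transects  mean_skewness  sd_skewness  n_orderings  n_excluded
 high            4       3.943195     0.355714           24           0
 high           12       2.437431     0.041898           24           0
 high           24       1.750061     0.000000           24           0
  low            4       1.373700     0.412546           24           0
  low           12       1.448760     0.282910           24           0
  low           24       1.184831     0.000000           24           0
```

The mean is taken over the 24 concentric orderings (one per start
transect) and the ±2 SD band is the plotted confidence interval; at the
final step all orderings pool the same data, so the SD is 0. The
high-dispersal SAD is consistently the more skewed, as predicted.

Forecast the low-dispersal SAD at twice the sampling effort:

```python
res = ss.forecast_across_orderings(table, "low", factor=2.0)
print(f"S* = {res.predicted_richness:.1f} species in "
      f"{res.predicted_num_classes} classes, order k* = {res.moment_order_used}")
print("mean:", res.class_counts.round(1))
print("sd:  ", res.class_sd.round(1))
```

```
S* = 238.9 species in 14 classes, order k* = 4
mean: [25.2 45.7 51.7 46.3 34.1 19.8  7.6  0.9  0.   0.8  1.2  1.7  2.8  1. ]
sd:   [8.  5.1 5.5 5.4 3.4 2.7 3.7 1.2 0.  1.5 2.5 1.4 1.8 1.8]
```

Class 0 is the singleton class; the forecast says that at 48 transects the
distribution's maximum sits at the 4–7 individuals class (class 2) with
about 52 ± 11 species — an interior hump, not a singleton-dominated curve.

The same stages are available from the shell:

```bash
sadscale simulate --kernel gaussian --seed 2 --out low.csv
sadscale skewness --input table.csv --out skew.csv
sadscale forecast --input table.csv --group low --factor 2 --out fc.csv
sadscale pipeline --config run.json
```

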