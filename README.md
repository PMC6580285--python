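# hybridcline

Characterization of geographic hybrid zones from binary haplotype
surveys. The package grew out of the avian secondary-contact zones of
the southeastern United States (the Northern Florida Suture Zone region,
where the red-shouldered hawk *Buteo lineatus*, barred owl, red-bellied
woodpecker, and Carolina chickadee all show a southeast/northwest
mitochondrial break), but every stage is generic: any organism scored
for a binary haplotype class at georeferenced localities can be analyzed
the same way.

## What it computes

**Transect projection.** A study transect is a piecewise great-circle
path through configurable waypoints (default: Key Largo FL
north-northwest to Lakeland GA, then west along ~31°N into east Texas).
Each specimen is projected perpendicularly onto the transect, giving an
along-transect coordinate X in km (exact spherical cross-track
geometry, Earth radius 6,371.0 km).

**Cumulative-normal cline fitting.** The frequency of one haplotype
class along the transect is modeled as

    F(X) = Φ(mX + b)

with Φ the standard normal CDF; (m, b) are estimated by maximizing the
Bernoulli log-likelihood (Newton–Raphson with step-halving; complete
separation is detected and flagged). Derived statistics follow from the
normal distribution: center −b/m (the 50% point), maximum slope
m/√(2π), and 20–80% width 1.68/m. Case-resampling bootstrap intervals
for center and width are provided.

**Population-genetic summaries.** From per-locus FASTA alignments with
population/region labels: nucleotide diversity π, Tajima's D,
hierarchical AMOVA Φ-statistics (Φ_ST, Φ_CT, Φ_SC from pairwise
difference counts, with permutation tests), pairwise p-distance,
four-gamete trimming to the largest recombination-free fragment, and
phasing of heterozygous Sanger sequences by allele subtraction.

**Gene flow and comparative analysis.** Dispersal-based gene-flow
distances (root-mean-square distance, or √N·SE from a reported mean and
standard error), and a cross-species comparison of zone width against
dispersal σ and against mitochondrial divergence (Pearson correlations,
width max/min ratio). A literature-transcribed table for the four Gulf
Coast avian zones is packaged.

**Neutral-diffusion simulation.** A 1-D stepping-stone simulator
relaxes a step initial condition under Gaussian dispersal (optionally
with drift); the 20–80% width grows as 1.683·σ√t, the expectation the
comparative analysis leans on.

## Worked example

```python
from hybridcline import derive_cline_stats, zone_comparison

stats = derive_cline_stats((0.00145, -0.6512))  # hawk-zone ML estimates
print(f"center {stats.center_km:.1f} km, "
      f"max slope {stats.max_slope_per_km:.3g}/km, "
      f"width {stats.width_20_80_km:.1f} km")

comp = zone_comparison()  # packaged four-species table
print(f"width ratio {comp['width_ratio']:.1f}, "
      f"r(width, sigma) {comp['r_width_sigma']:.2f}, "
      f"r(width, divergence) {comp['r_width_divergence']:.2f}")
```

prints

```
center 449.1 km, max slope 0.000578/km, width 1158.6 km
width ratio 6.6, r(width, sigma) 0.97, r(width, divergence) -0.70
```

i.e. the hawk cline crosses 50% eastern-haplotype frequency 449 km up
the transect (near Ocala, FL) and takes ~1,159 km to rise from 20% to
80%; across the four species, zone width tracks dispersal distance
almost perfectly (r = 0.97) and correlates only weakly (negatively)
with sequence divergence.

The `examples/` directory has one short script per capability
(projection + fitting, popgen summaries, zone comparison, diffusion,
full pipeline); each prints its numbers with a line on what they mean.
A thin CLI mirrors the stages:

```bash
hybridcline simulate cline --seed 1 -o specimens.csv
hybridcline fit specimens.csv --x-col x_km
hybridcline compare
hybridcline run study.yaml
```

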