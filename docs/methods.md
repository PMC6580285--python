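# Methods

## The model

A hybrid zone is summarized as a one-dimensional frequency cline along a
geographic transect. Each specimen contributes a binary observation
y ∈ {0, 1} (which of two haplotype clades it carries) at an
along-transect coordinate X (km). The frequency of the y = 1 class is
modeled as the cumulative-normal curve

    F(X) = Φ(mX + b)

where Φ is the standard normal CDF. This is binary probit regression;
(m, b) maximize the Bernoulli log-likelihood
Σ[y·ln Φ(mX+b) + (1−y)·ln(1−Φ(mX+b))]. The derived statistics follow
from the definition of the normal distribution:

- **center** = −b/m — the X at which the probit argument is zero and
  F = 0.5. (The ratio is sometimes printed as b/m in the literature;
  with the convention F(X) = Φ(mX + b) the 50% point is −b/m, and that
  is what is implemented — for m > 0, b < 0 the two agree in magnitude.)
- **maximum slope** = |m|/√(2π) — the density Φ′ at the center times m.
- **20–80% width** = 1.68/|m|. The exact constant is
  2·Φ⁻¹(0.8) = 1.6832…; the conventional rounded value 1.68 is used
  deliberately, matching how widths are reported in the hybrid-zone
  literature. The algebraic identity width × max-slope = 1.68/√(2π)
  ≈ 0.6703 holds for every fit and is asserted in the tests.

The response coding (y = 1 for the "common"/eastern clade) only flips
the signs of (m, b); center and width are invariant.

### Optimizer

Newton–Raphson on (m, b) with analytic gradient and observed
information, step-halving line search, starting from
(0, Φ⁻¹(ȳ)). Convergence requires |Δlog-likelihood| < 1e-10 and
gradient norm < 1e-8. Standard errors come from the inverse observed
information. If the information matrix is singular the optimizer falls
back to a golden-section search on the profile likelihood in m (with b
maximized by 1-D Newton at each m).

Complete separation — no overlap between the classes along X, so the
likelihood supremum is at |m| → ∞ — is detected two ways: diverging
probit arguments during iteration (min |mX+b| > 30 over observations),
and at "convergence" a perfect fit (min |mX+b| > 6 or log-likelihood
> −1e-6, i.e. every point classified with probability ≈ 1). Separated
fits return `converged=False` with a diagnostic, never silent
estimates.

### Bootstrap

Case-resampling (specimens resampled with replacement), percentile
2.5/97.5 intervals for center and width. Non-convergent or degenerate
replicates are dropped and counted; more than 50% failures raises. At
the study scale (n = 78) the width interval is wide — a fact the tests
quantify (coverage of the generating width ≥ 85% across seeded
replicates) rather than hide.

## Transect geometry

The transect is a piecewise great-circle path through ordered waypoints
on a sphere of radius 6,371.0 km. The packaged default approximates the
Gulf Coast survey axis: Key Largo FL (25.0865, −80.4473) → Lakeland GA
(31.0405, −83.0752) → (31.0, −95.4) near Houston's longitude, ~1,884 km
total. The waypoints are configuration, not constants: the exact axis
any given study used is rarely published, so fitted X values depend on
the configured waypoints and should not be expected to reproduce
third-party coordinates exactly.

Projection uses exact spherical cross-track geometry: for each segment
the specimen's angular coordinates in the segment's great-circle plane
give the foot of the perpendicular directly; feet beyond a segment end
clamp to the nearer endpoint, and the segment with the smallest
perpendicular offset wins. A planar (equirectangular) approximation was
considered and rejected: over a 700 km segment spanning six degrees of
latitude its error reaches ~0.7 km, while the spherical solution is
exact and no harder to implement. Points beyond either terminus clamp
to X = 0 or X = total length rather than being rejected, so peripheral
specimens stay in the analysis. Projection is idempotent to < 1e-6 km.

## Population-genetic statistics

Computed from equal-length nucleotide alignments with per-sequence
population and region labels (every population belongs to exactly one
region).

- **π** — mean pairwise proportion of differing sites over all
  n(n−1)/2 pairs. Gapped/ambiguous positions are excluded pairwise
  (each pair compared over its own valid sites); same for p-distance.
- **Tajima's D** — D = (k̂ − S/a₁)/√(e₁S + e₂S(S−1)) with the standard
  constants a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ computed from n, k̂ the mean
  pairwise difference count, S the number of segregating sites. Sites
  with any gap/ambiguity are excluded globally (also for the
  four-gamete test). S = 0 raises rather than returning 0/0.
- **AMOVA** — variance decomposition of pairwise difference counts
  (used directly as squared distances; no multiple-hit correction,
  appropriate for the small intraspecific divergences targeted).
  Three-level designs partition among regions (σ²ₐ), among populations
  within regions (σ²_b), and within populations (σ²_c);
  Φ_ST = (σ²ₐ+σ²_b)/total, Φ_CT = σ²ₐ/total, Φ_SC = σ²_b/(σ²_b+σ²_c).
  Designs with one region, or exactly one population per region,
  collapse to a single-level F_ST. Negative components are reported as
  estimated, never truncated. Permutation p-values
  ((#exceeding + 1)/(n_perm + 1), default 1,000 permutations) permute
  individuals among populations for Φ_ST, whole populations among
  regions for Φ_CT, and individuals within regions for Φ_SC.
- **Four-gamete trimming** — biallelic site pairs exhibiting all four
  gametes imply recombination (or recurrent mutation); the reported
  window is the longest contiguous interval containing no complete
  violating pair, found by a linear sweep over right endpoints. Ties
  break to the leftmost window (an arbitrary, documented convention).
- **Allele subtraction** — phasing of heterozygous Sanger sequences: at
  each two-fold IUPAC position the alternate allele's base is the
  member of the ambiguity set that is not the known allele's base.
  Codes not containing the known base, and three/four-fold codes, raise
  (they cannot be phased from one known allele).

## Gene flow and the comparative analysis

Gene-flow distance σ is the root-mean-square natal dispersal distance
when individual distances are available. When a study reports only a
mean with its standard error, σ is estimated as √N·SE — algebraically
the sample standard deviation of dispersal distances, which is a proxy
for (not identical to) the RMS distance; the discrepancy vanishes only
when the mean dispersal is small relative to its spread. Implemented as
the convention is printed in the comparative literature, with this
caveat.

The packaged four-zone table (hawk, owl, woodpecker, chickadee:
centers 449/877/503/1,248 km, widths 1,158/844/435/176 km, ND2
divergences 0.0029/0.0048/0.0010/0.0423, σ 112.4/69/2/4 km) is
transcribed from the published literature on the Gulf Coast zones; the
hawk and chickadee σ values are medians of the available estimates
({22.9, 112.4, 185.6} and {1, 4, 8} km). The comparison reports the
width max/min ratio and Pearson correlations of width with σ and with
divergence. With four points these correlations are descriptive, not
inferential; no p-values are attached.

## Neutral-diffusion simulator

A deterministic 1-D stepping-stone model on the transect axis: demes at
fixed spacing (default 5 km) over a 4,000 km domain, frequencies
convolved each generation with a discretized Gaussian kernel
(sd = σ, truncated at ±6σ, renormalized) under reflecting (mirror)
boundaries, which conserves total allele mass to < 1e-9 per step. From
a step initial condition the field after t generations is
Φ((x − x_c)/(σ√t)) up to discretization error (verified ≤ 1e-3
sup-norm), so the 20–80% width grows as 1.683·σ√t. An optional drift
mode resamples each deme Binomial(2N, p)/2N with an explicit generator.

The domain default keeps the boundaries > 10σ√t away from the zone for
all tested t (≤ 256 generations at σ = 10 km), so boundary effects
never reach the front. Width is measured as the distance between the
linearly interpolated 0.2 and 0.8 frequency crossings; resolution is
therefore about one deme spacing, and the t = 0 step reads as ~0.6
spacings rather than exactly zero. This simulator tests the scaling law
only; it does not calibrate calendar time since contact.

## Synthetic data and what passing tests show

The generators emulate the study conditions: 78 binary specimens
uniform over a ~1,800 km transect with Bernoulli(Φ(mX+b)) classes at
the fitted hawk-zone parameters; two-clade alignments with a controlled
budget of fixed differences and within-clade polymorphisms; half-normal
dispersal samples. They do not emulate spatially clumped sampling,
sequencing error, within-clade phylogenetic structure, or selection
against hybrids — so green tests demonstrate estimator correctness and
internal consistency under the stated model, not robustness to those
real-data features. All generators take explicit integer seeds and
never touch global RNG state.

## Numerical conventions

- Probit tail terms use `logcdf`/`logsf` throughout; the per-point
  score is computed as exp(logpdf − logcdf) to avoid 0/0 in the tails.
- Perpendicular offsets use atan2(|u×v|, u·v), stable for the
  near-zero angles of points on the transect (acos is not).
- Distances are reported in km (printed to 1 decimal); Φ-statistics
  printed to 2 decimals; machine-readable outputs keep full precision.
- The pipeline's JSON report has sorted keys and no timestamps, so a
  rerun with the same config and seed is byte-identical.

## Known limitations

- The cline model has no tails, stepped segments, or concordance
  machinery; it is the two-parameter cumulative normal only.
- AMOVA assumes the difference-count distance; no gamma/Kimura
  correction hooks.
- The four-gamete trim ignores sites with > 2 states and treats
  recurrent mutation as recombination, as the test itself does.
- Transect waypoints are approximations whenever a source study gives
  only a verbal description; fitted centers shift with the chosen axis.
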