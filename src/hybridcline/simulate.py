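"""Synthetic inputs and neutral-diffusion secondary-contact simulation.

Provides every input the analysis pipeline consumes — cline-distributed
binary specimens, two-clade haplotype alignments with a controlled site
budget, dispersal samples — plus a deterministic (optionally drifting)
1-D stepping-stone diffusion of a step initial condition.  After t
generations of Gaussian dispersal with per-generation scale sigma the
step relaxes to Phi(x/(sigma*sqrt(t))), so the 20-80% width grows as
1.683*sigma*sqrt(t); the simulator exists to exercise that scaling law.

All generators take explicit integer seeds; none touch global RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

from .cline import ClineObservation
from .popgen import HaplotypeAlignment

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_cline_specimens(m: float, b: float, n: int,
                             x_range: tuple[float, float] = (0.0, 1800.0),
                             seed: int = 0) -> list[ClineObservation]:
    """Draw n specimens with x ~ Uniform(x_range), y ~ Bernoulli(Phi(m*x+b))."""
    lo, hi = x_range
    if not (math.isfinite(lo) and math.isfinite(hi)) or hi <= lo or lo < 0:
        raise ValueError("invalid x_range")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.uniform(lo, hi, size=n)
    p = norm.cdf(m * x + b)
    y = (rng.random(n) < p).astype(int)
    return [ClineObservation(float(xi), int(yi)) for xi, yi in zip(x, y)]


def simulate_two_clade_alignment(n1: int, n2: int, L: int,
                                 divergence_sites: int, polymorphic_sites: int,
                                 seed: int = 0) -> HaplotypeAlignment:
    """Two-clade alignment with fixed differences and within-clade SNPs.

    The clades are fixed for alternative bases at ``divergence_sites``
    positions; ``polymorphic_sites`` further positions each carry a
    within-clade polymorphism (segregating in one clade only, minor
    count between 1 and clade size - 1).  Clade 1 is labeled population
    A1 / region A, clade 2 population B1 / region B.
    """
    if n1 < 1 or n2 < 1 or L < 1:
        raise ValueError("n1, n2, L must be positive")
    if divergence_sites + polymorphic_sites > L:
        raise ValueError("site budget exceeds alignment length")
    if polymorphic_sites > 0 and max(n1, n2) < 2:
        raise ValueError("within-clade polymorphism needs a clade of >= 2")
    rng = np.random.default_rng(seed)
    base = rng.choice(_BASES, size=L)
    mat = np.tile(base, (n1 + n2, 1)).copy()
    sites = rng.choice(L, size=divergence_sites + polymorphic_sites, replace=False)
    div_sites = sites[:divergence_sites]
    poly_sites = sites[divergence_sites:]
    for j in div_sites:
        alts = _BASES[_BASES != base[j]]
        mat[n1:, j] = rng.choice(alts)
    eligible_clades = [c for c, nc in ((0, n1), (1, n2)) if nc >= 2]
    for j in poly_sites:
        clade = eligible_clades[rng.integers(len(eligible_clades))]
        rows = np.arange(0, n1) if clade == 0 else np.arange(n1, n1 + n2)
        alts = _BASES[_BASES != mat[rows[0], j]]
        alt = rng.choice(alts)
        k = int(rng.integers(1, len(rows)))  # minor count in [1, nc-1]
        carriers = rng.choice(rows, size=k, replace=False)
        mat[carriers, j] = alt
    seqs = [bytes(row).decode("ascii") for row in mat]
    ids = [f"c1_{i}" for i in range(n1)] + [f"c2_{i}" for i in range(n2)]
    pops = ["A1"] * n1 + ["B1"] * n2
    regs = ["A"] * n1 + ["B"] * n2
    return HaplotypeAlignment(ids=ids, sequences=seqs, populations=pops, regions=regs)


def simulate_dispersal_sample(sigma: float, n: int, seed: int = 0) -> np.ndarray:
    """Dispersal distances |N(0, sigma^2)| — half-normal with RMS sigma."""
    if sigma <= 0 or n < 1:
        raise ValueError("sigma must be positive, n >= 1")
    rng = np.random.default_rng(seed)
    return np.abs(rng.normal(0.0, sigma, size=n))


@dataclass(frozen=True)
class DiffusionState:
    """1-D stepping-stone allele-frequency field.

    ``positions`` are evenly spaced deme coordinates (km); ``freqs`` the
    per-deme frequency of allele 1; ``t`` the generation count;
    ``sigma_km`` the per-generation Gaussian dispersal scale; ``deme_size``
    (2N chromosomes per deme when drifting) enables drift when not None.
    """

    positions: np.ndarray
    freqs: np.ndarray
    t: int
    sigma_km: float
    deme_size: int | None = None

    def __post_init__(self) -> None:
        if self.freqs.min() < 0 or self.freqs.max() > 1:
            raise ValueError("frequencies must lie in [0, 1]")
        if len(self.positions) != len(self.freqs):
            raise ValueError("positions and freqs differ in length")

    @property
    def spacing_km(self) -> float:
        return float(self.positions[1] - self.positions[0])

    @property
    def contact_km(self) -> float:
        """Contact front: the 0.5-frequency crossing of the field.

        For the step initial condition this is the midpoint between the
        last empty and first fixed deme.
        """
        x = _crossing(self.positions, self.freqs, 0.5)
        if x is None:
            raise ValueError("no 0.5 crossing in the frequency field")
        return x


def make_step_state(sigma_km: float = 10.0, spacing_km: float = 5.0,
                    domain_km: float = 4000.0,
                    deme_size: int | None = None) -> DiffusionState:
    """Step initial condition: allele absent left of the domain midpoint,
    fixed right of it — secondary contact at t = 0."""
    if sigma_km <= 0 or spacing_km <= 0 or domain_km <= 2 * spacing_km:
        raise ValueError("invalid geometry")
    n = int(round(domain_km / spacing_km)) + 1
    positions = np.arange(n) * spacing_km
    freqs = np.where(positions < positions.mean(), 0.0, 1.0)
    return DiffusionState(positions=positions, freqs=freqs, t=0,
                          sigma_km=sigma_km, deme_size=deme_size)


def _gaussian_kernel(sigma: float, spacing: float) -> np.ndarray:
    half = int(math.ceil(6.0 * sigma / spacing))
    offs = np.arange(-half, half + 1) * spacing
    k = norm.pdf(offs, scale=sigma)
    return k / k.sum()


def diffuse_step(state: DiffusionState, rng: np.random.Generator | None = None
                 ) -> DiffusionState:
    """Advance one generation of Gaussian dispersal (plus optional drift).

    Deterministic mode convolves the frequency field with a discretized
    Gaussian kernel (sd = sigma_km) under reflecting boundaries, which
    conserves total allele mass.  With ``deme_size`` set, each deme is
    then resampled Binomial(deme_size, p)/deme_size using ``rng``
    (required in that case).
    """
    kernel = _gaussian_kernel(state.sigma_km, state.spacing_km)
    half = len(kernel) // 2
    if half >= len(state.freqs):
        raise ValueError("domain too small for the dispersal kernel")
    padded = np.pad(state.freqs, half, mode="symmetric")
    new = np.convolve(padded, kernel, mode="valid")
    new = np.clip(new, 0.0, 1.0)
    if state.deme_size is not None:
        if rng is None:
            raise ValueError("drift mode requires an explicit rng")
        new = rng.binomial(state.deme_size, new) / state.deme_size
    return replace(state, freqs=new, t=state.t + 1)


def _crossing(positions: np.ndarray, freqs: np.ndarray, level: float) -> float | None:
    """Leftmost linear-interpolated crossing of ``level``; None if absent."""
    f = freqs - level
    sign_change = np.flatnonzero((f[:-1] <= 0) & (f[1:] > 0) | (f[:-1] >= 0) & (f[1:] < 0))
    if len(sign_change) == 0:
        if np.any(f == 0):
            return float(positions[np.flatnonzero(f == 0)[0]])
        return None
    j = sign_change[0]
    frac = -f[j] / (f[j + 1] - f[j])
    return float(positions[j] + frac * (positions[j + 1] - positions[j]))


def cline_width_20_80(state: DiffusionState) -> float | None:
    """Distance between the 0.2 and 0.8 frequency crossings (linear
    interpolation between demes); None when a crossing is not bracketed.
    Resolution is limited to roughly one deme spacing."""
    x20 = _crossing(state.positions, state.freqs, 0.2)
    x80 = _crossing(state.positions, state.freqs, 0.8)
    if x20 is None or x80 is None:
        return None
    return abs(x80 - x20)


def width_trajectory(state0: DiffusionState, t_max: int,
                     record_at: list[int] | None = None,
                     rng: np.random.Generator | None = None
                     ) -> list[tuple[int, float]]:
    """20-80% width at each recorded generation of a diffusion run.

    Generations whose width is undefined (crossing not bracketed) are
    skipped with a warning.
    """
    import warnings

    if t_max < 0:
        raise ValueError("t_max must be >= 0")
    record = set(record_at) if record_at is not None else set(range(t_max + 1))
    out: list[tuple[int, float]] = []
    state = state0
    if state.t in record:
        w = cline_width_20_80(state)
        if w is None:
            warnings.warn(f"width undefined at t={state.t}; skipped")
        else:
            out.append((state.t, w))
    while state.t < t_max:
        state = diffuse_step(state, rng=rng)
        if state.t in record:
            w = cline_width_20_80(state)
            if w is None:
                warnings.warn(f"width undefined at t={state.t}; skipped")
            else:
                out.append((state.t, w))
    return out


def write_demo_inputs(outdir, seed: int = 0, n_specimens: int = 78,
                      m: float = 0.00145, b: float = -0.6512) -> dict:
    """Write a complete synthetic study-input bundle; return a config dict.

    Emulates the study conditions: 78 binary haplotype observations whose
    clade frequencies follow Phi(m*x + b) along the packaged transect
    (specimens placed on the transect itself), one two-clade alignment
    with fixed differences plus within-clade polymorphism, and the
    packaged four-species comparative table.  Suitable for
    ``StudyConfig(**returned_dict)``.
    """
    from pathlib import Path

    import pandas as pd

    from .geo import default_transect, point_at
    from .dispersal import gulf_coast_zones

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    transect = default_transect()
    obs = simulate_cline_specimens(m, b, n_specimens,
                                   (0.0, transect.total_length_km), seed=seed)
    rows = []
    for i, o in enumerate(obs):
        p = point_at(transect, o.x)
        region = ("peninsula" if o.x < 600 else
                  "panhandle" if o.x < 1200 else "west")
        pop = f"P{int(o.x // 300)}"
        rows.append(dict(id=f"S{i:03d}", lat=round(p.latitude, 5),
                         lon=round(p.longitude, 5), pop=pop, region=region,
                         hap_class=o.y))
    spec_path = out / "specimens.csv"
    pd.DataFrame(rows).to_csv(spec_path, index=False)

    aln = simulate_two_clade_alignment(8, 8, 600, 12, 8, seed=seed + 1)
    fasta_path = out / "nd2.fasta"
    with open(fasta_path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.sequences):
            fh.write(f">{sid}\n{seq}\n")
    labels_path = out / "nd2_labels.csv"
    pd.DataFrame({"seq_id": aln.ids, "pop": aln.populations,
                  "region": aln.regions}).to_csv(labels_path, index=False)

    comp_path = out / "zones.csv"
    pd.DataFrame([
        dict(species=z.species, center_km=z.center_km,
             width_km=z.width_20_80_km, nd2_div=z.nd2_divergence,
             sigma_km=z.sigma_km)
        for z in gulf_coast_zones()
    ]).to_csv(comp_path, index=False)

    return {
        "output_dir": str(out / "results"),
        "specimen_table": str(spec_path),
        "loci": {"nd2": {"fasta": str(fasta_path), "labels": str(labels_path)}},
        "comparative_table": str(comp_path),
        "seed": seed,
    }


def analytic_profile(state0: DiffusionState, t: int) -> np.ndarray:
    """Closed-form heat-equation solution Phi((x - x_c)/(sigma*sqrt(t)))
    for the step initial condition, evaluated at the deme positions."""
    if t < 1:
        raise ValueError("t must be >= 1")
    xc = state0.contact_km
    return norm.cdf((state0.positions - xc) / (state0.sigma_km * math.sqrt(t)))
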