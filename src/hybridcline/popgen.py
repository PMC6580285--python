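"""Sequence-based population-genetic summary statistics.

Operates on equal-length nucleotide alignments with per-sequence
population and region labels: nucleotide diversity (pi), Tajima's D,
hierarchical AMOVA Phi-statistics with permutation tests, pairwise
p-distance, four-gamete recombination trimming, and phasing of
heterozygous Sanger sequences by allele subtraction.

Site handling conventions: positions containing gaps or IUPAC ambiguity
codes are excluded pairwise for pi and p-distance, and globally for
Tajima's D and the four-gamete test.  AMOVA distances are raw pairwise
difference counts (no multiple-hit correction), appropriate at the small
intraspecific divergences this package targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_VALID = frozenset(b"ACGT")

# two-fold IUPAC ambiguity codes
IUPAC2 = {
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
}
_BASE_PAIR_TO_CODE = {frozenset(v): k for k, v in IUPAC2.items()}
IUPAC_MULTI = frozenset("BDHVN")


@dataclass
class HaplotypeAlignment:
    """Equal-length nucleotide matrix with population/region labels.

    ``populations[i]`` and ``regions[i]`` label sequence i; every
    population must map to exactly one region.
    """

    ids: list[str]
    sequences: list[str]
    populations: list[str]
    regions: list[str]
    _matrix: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.sequences)
        if n < 1:
            raise ValueError("alignment needs at least one sequence")
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise ValueError("sequences differ in length")
        if not (len(self.ids) == len(self.populations) == len(self.regions) == n):
            raise ValueError("ids/populations/regions must match sequence count")
        pop_region = {}
        for p, r in zip(self.populations, self.regions):
            if pop_region.setdefault(p, r) != r:
                raise ValueError(f"population {p!r} assigned to multiple regions")
        self.sequences = [s.upper() for s in self.sequences]
        self._matrix = np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype="S1"
        ).reshape(n, L)

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def matrix(self) -> np.ndarray:
        """(n, L) byte matrix view of the alignment."""
        return self._matrix

    def valid_mask(self) -> np.ndarray:
        """(n, L) bool mask of unambiguous A/C/G/T positions."""
        m = self._matrix
        return (m == b"A") | (m == b"C") | (m == b"G") | (m == b"T")

    @classmethod
    def from_fasta(cls, fasta_path: str | Path, labels: pd.DataFrame | str | Path) -> "HaplotypeAlignment":
        """Load from a FASTA file plus a label table.

        ``labels`` is a DataFrame (or path to delimited text) with
        columns seq_id, pop, region.  Sequences without a label row are
        an error.
        """
        from Bio import SeqIO

        if not isinstance(labels, pd.DataFrame):
            labels = pd.read_csv(labels, sep=None, engine="python")
        lab = labels.set_index("seq_id")
        ids, seqs, pops, regs = [], [], [], []
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            if rec.id not in lab.index:
                raise ValueError(f"sequence {rec.id!r} has no population label")
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper())
            pops.append(str(lab.loc[rec.id, "pop"]))
            regs.append(str(lab.loc[rec.id, "region"]))
        return cls(ids=ids, sequences=seqs, populations=pops, regions=regs)

    def subset(self, indices: Sequence[int]) -> "HaplotypeAlignment":
        idx = list(indices)
        return HaplotypeAlignment(
            ids=[self.ids[i] for i in idx],
            sequences=[self.sequences[i] for i in idx],
            populations=[self.populations[i] for i in idx],
            regions=[self.regions[i] for i in idx],
        )


@dataclass(frozen=True)
class AmovaResult:
    """Hierarchical molecular variance decomposition.

    sigma2_a: among regions; sigma2_b: among populations within regions;
    sigma2_c: within populations.  Phi_ST = (a+b)/(a+b+c),
    Phi_CT = a/(a+b+c), Phi_SC = b/(b+c).  For two-level designs
    (single region level) sigma2_a is 0 and Phi_ST is the single-level
    fixation index.  Negative components are reported as estimated.
    """

    sigma2_a: float
    sigma2_b: float
    sigma2_c: float
    phi_st: float
    phi_ct: float | None
    phi_sc: float | None
    p_phi_st: float | None
    p_phi_ct: float | None
    p_phi_sc: float | None
    n_permutations: int
    levels: int


def _pair_diff_matrix(aln: HaplotypeAlignment) -> np.ndarray:
    """Pairwise nucleotide difference counts (valid-site intersection)."""
    m = aln.matrix
    valid = aln.valid_mask()
    n = aln.n
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid
        diff = (m[i] != m) & both
        d[i] = diff.sum(axis=1)
    np.fill_diagonal(d, 0.0)
    return d


def nucleotide_diversity(aln: HaplotypeAlignment) -> float:
    """Nucleotide diversity pi: mean pairwise proportion of differing sites.

    Averaged over all n(n-1)/2 sequence pairs; gapped/ambiguous
    positions are excluded pairwise (each pair compared over its own
    valid sites).
    """
    if aln.n < 2:
        raise ValueError("nucleotide diversity needs n >= 2")
    m = aln.matrix
    valid = aln.valid_mask()
    total = 0.0
    npairs = 0
    for i in range(aln.n):
        for j in range(i + 1, aln.n):
            both = valid[i] & valid[j]
            nsites = int(both.sum())
            if nsites == 0:
                raise ValueError(f"no comparable sites between {aln.ids[i]} and {aln.ids[j]}")
            total += float(((m[i] != m[j]) & both).sum()) / nsites
            npairs += 1
    return total / npairs


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites between two aligned sequences.

    Positions where either sequence is gapped/ambiguous are excluded.
    """
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    aa = np.frombuffer(a.upper().encode("ascii"), dtype="S1")
    bb = np.frombuffer(b.upper().encode("ascii"), dtype="S1")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    va = np.isin(aa, bases) & np.isin(bb, bases)
    ncmp = int(va.sum())
    if ncmp == 0:
        raise ValueError("no comparable sites")
    return float(((aa != bb) & va).sum()) / ncmp


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(aln: HaplotypeAlignment) -> float:
    """Tajima's D from the alignment's unambiguous sites.

    D = (pi_hat - S/a1) / sqrt(e1*S + e2*S*(S-1)) where pi_hat is the
    mean pairwise difference *count* and S the number of segregating
    sites.  Sites with any gap/ambiguity are excluded globally.
    Raises when S = 0 (statistic undefined) or n < 4.
    """
    n = aln.n
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    m = aln.matrix
    keep = aln.valid_mask().all(axis=0)
    sub = m[:, keep]
    seg = (sub != sub[0]).any(axis=0)
    S = int(seg.sum())
    if S == 0:
        raise ValueError("Tajima's D undefined: no segregating sites")
    segm = sub[:, seg]
    pi_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            pi_total += float((segm[i] != segm[j]).sum())
    pi_total /= n * (n - 1) / 2.0
    c = _tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (pi_total - S / c["a1"]) / math.sqrt(var)


def _amova_ssd(d2: np.ndarray, groups: list[np.ndarray]) -> float:
    """SSD within listed groups: sum over groups of (1/n_g) sum_{i<j} d2."""
    total = 0.0
    for idx in groups:
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            total += sub.sum() / (2.0 * len(idx))
    return total


def _amova_components(d2: np.ndarray, pops: np.ndarray, regs: np.ndarray):
    """Excoffier-Smouse-Quattro variance components from squared distances.

    Returns (sigma2_a, sigma2_b, sigma2_c, phi_st, phi_ct, phi_sc,
    levels).  Two-level designs (one region) return sigma2_a = 0 and
    phi_ct/phi_sc as None.
    """
    N = len(pops)
    pop_ids = pd.unique(pops)
    reg_ids = pd.unique(regs)
    P, G = len(pop_ids), len(reg_ids)
    all_idx = [np.arange(N)]
    pop_groups = [np.flatnonzero(pops == p) for p in pop_ids]
    reg_groups = [np.flatnonzero(regs == g) for g in reg_ids]
    ssd_total = _amova_ssd(d2, all_idx)
    ssd_wp = _amova_ssd(d2, pop_groups)
    if G < 2 or P == G:
        # collapses to a single-level F_ST: either one region, or one
        # population per region (no among-pops-within-regions stratum)
        df_ap, df_wp = P - 1, N - P
        ms_ap = (ssd_total - ssd_wp) / df_ap
        sigma_c = ssd_wp / df_wp if df_wp > 0 else 0.0
        n0 = (N - sum(len(g)**2 for g in pop_groups) / N) / (P - 1)
        sigma_b = (ms_ap - sigma_c) / n0
        tot = sigma_b + sigma_c
        phi_st = sigma_b / tot if tot != 0 else 0.0
        return 0.0, sigma_b, sigma_c, phi_st, None, None, 2
    ssd_wg = _amova_ssd(d2, reg_groups)
    ssd_ag = ssd_total - ssd_wg
    ssd_ap_wg = ssd_wg - ssd_wp
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    ms_ag = ssd_ag / df_ag
    ms_ap = ssd_ap_wg / df_ap
    sigma_c = ssd_wp / df_wp if df_wp > 0 else 0.0
    pop_sizes = {p: np.sum(pops == p) for p in pop_ids}
    reg_sizes = {g: np.sum(regs == g) for g in reg_ids}
    pop_region = {}
    for p, g in zip(pops, regs):
        pop_region[p] = g
    sum_npg = sum(
        pop_sizes[p]**2 / reg_sizes[pop_region[p]] for p in pop_ids
    )
    n1 = (N - sum_npg) / df_ap
    n2 = (sum_npg - sum(pop_sizes[p]**2 for p in pop_ids) / N) / df_ag
    n3 = (N - sum(reg_sizes[g]**2 for g in reg_ids) / N) / df_ag
    sigma_b = (ms_ap - sigma_c) / n1
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    tot = sigma_a + sigma_b + sigma_c
    phi_st = (sigma_a + sigma_b) / tot if tot != 0 else 0.0
    phi_ct = sigma_a / tot if tot != 0 else 0.0
    bc = sigma_b + sigma_c
    phi_sc = sigma_b / bc if bc != 0 else 0.0
    return sigma_a, sigma_b, sigma_c, phi_st, phi_ct, phi_sc, 3


def hierarchical_amova(aln: HaplotypeAlignment, n_perm: int = 1000,
                       seed: int | None = None) -> AmovaResult:
    """AMOVA on pairwise nucleotide differences with permutation tests.

    Three-level when >= 2 regions are present (among regions, among
    populations within regions, within populations), else the design
    collapses to a single F_ST.  Permutation schemes: whole populations
    among regions for Phi_CT; individuals among populations within their
    region for Phi_SC; individuals among populations (ignoring regions)
    for Phi_ST.  p = (#exceeding + 1)/(n_perm + 1).  ``n_perm < 1``
    omits p-values with a warning.
    """
    import warnings

    pops = np.asarray(aln.populations)
    regs = np.asarray(aln.regions)
    pop_ids = pd.unique(pops)
    if len(pop_ids) < 2:
        raise ValueError("AMOVA needs at least two populations")
    for p in pop_ids:
        if np.sum(pops == p) < 1:
            raise ValueError(f"population {p!r} has no sequences")
    d2 = _pair_diff_matrix(aln)  # difference counts serve as squared distances
    sa, sb, sc, phi_st, phi_ct, phi_sc, levels = _amova_components(d2, pops, regs)

    if n_perm < 1:
        warnings.warn("n_perm < 1: permutation p-values omitted")
        return AmovaResult(sa, sb, sc, phi_st, phi_ct, phi_sc,
                           None, None, None, 0, levels)

    rng = np.random.default_rng(seed)
    exceed_st = exceed_ct = exceed_sc = 0
    pop_region = dict(zip(pops, regs))
    reg_of_pop = np.asarray([pop_region[p] for p in pop_ids])
    for _ in range(n_perm):
        # Phi_ST: permute individuals among populations (keep pop->region map)
        perm = rng.permutation(len(pops))
        p_st = _amova_components(d2, pops[perm], regs[perm])
        # note: permuting (pop, region) jointly shuffles individuals among
        # populations while preserving the design structure
        if p_st[3] >= phi_st:
            exceed_st += 1
        if levels == 3:
            # Phi_CT: permute whole populations among regions
            new_regs_of_pop = reg_of_pop[rng.permutation(len(pop_ids))]
            reg_map = dict(zip(pop_ids, new_regs_of_pop))
            regs_p = np.asarray([reg_map[p] for p in pops])
            p_ct = _amova_components(d2, pops, regs_p)
            if p_ct[4] is not None and phi_ct is not None and p_ct[4] >= phi_ct:
                exceed_ct += 1
            # Phi_SC: permute individuals among populations within regions
            pops_p = pops.copy()
            for g in pd.unique(regs):
                idx = np.flatnonzero(regs == g)
                pops_p[idx] = pops_p[idx[rng.permutation(len(idx))]]
            p_sc = _amova_components(d2, pops_p, regs)
            if p_sc[5] is not None and phi_sc is not None and p_sc[5] >= phi_sc:
                exceed_sc += 1
    p_st_val = (exceed_st + 1) / (n_perm + 1)
    if levels == 3:
        p_ct_val = (exceed_ct + 1) / (n_perm + 1)
        p_sc_val = (exceed_sc + 1) / (n_perm + 1)
    else:
        p_ct_val = p_sc_val = None
    return AmovaResult(sa, sb, sc, phi_st, phi_ct, phi_sc,
                       p_st_val, p_ct_val, p_sc_val, n_perm, levels)


def four_gamete_trim(aln: HaplotypeAlignment) -> tuple[int, int]:
    """Longest contiguous window with no four-gamete violation.

    Biallelic sites are detected among globally unambiguous columns; a
    pair of sites violates the four-gamete condition when all four
    haplotype combinations occur.  Returns the (1-based, inclusive)
    bounds of the longest window containing no complete violating pair;
    ties break to the leftmost window.  The full length is returned when
    nothing violates.
    """
    if aln.n < 2:
        raise ValueError("four-gamete test needs n >= 2")
    m = aln.matrix
    L = aln.length
    keep = aln.valid_mask().all(axis=0)
    cols = []
    positions = []
    for j in range(L):
        if not keep[j]:
            continue
        states = np.unique(m[:, j])
        if len(states) == 2:
            cols.append(m[:, j] == states[0])
            positions.append(j)  # 0-based
    violations = []  # (i, j) 0-based positions, i < j
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            x, y = cols[a], cols[b]
            gametes = {(bool(xi), bool(yi)) for xi, yi in zip(x, y)}
            if len(gametes) == 4:
                violations.append((positions[a], positions[b]))
    if not violations:
        return (1, L)
    # sweep right end; a window ending at e must start after i for every
    # violation (i, j) with j <= e
    by_j: dict[int, list[int]] = {}
    for i, j in violations:
        by_j.setdefault(j, []).append(i)
    best_start, best_end = 0, -1
    min_start = 0
    for e in range(L):
        for i in by_j.get(e, ()):
            min_start = max(min_start, i + 1)
        if e - min_start > best_end - best_start:
            best_start, best_end = min_start, e
    return (best_start + 1, best_end + 1)


def subtract_allele(het: str, known: str) -> str:
    """Reconstruct the alternate allele of a heterozygous sequence.

    At each two-fold IUPAC ambiguity position the returned base is the
    member of the ambiguity set that is not the known allele's base; at
    unambiguous positions the known base is returned (and must match).
    Triple/quadruple ambiguity codes cannot be phased and raise.
    """
    if len(het) != len(known):
        raise ValueError("sequences differ in length")
    het = het.upper()
    known = known.upper()
    out = []
    for i, (h, k) in enumerate(zip(het, known)):
        if h in IUPAC_MULTI:
            raise ValueError(f"cannot phase: >2-fold ambiguity {h!r} at position {i + 1}")
        if h in IUPAC2:
            members = IUPAC2[h]
            if k not in members:
                raise ValueError(
                    f"inconsistent phase at position {i + 1}: {h!r} does not contain {k!r}")
            (alt,) = members - {k}
            out.append(alt)
        else:
            if h != k:
                raise ValueError(
                    f"unambiguous mismatch at position {i + 1}: {h!r} vs {k!r}")
            out.append(k)
    return "".join(out)


def combine_alleles(a: str, b: str) -> str:
    """Inverse of :func:`subtract_allele`: merge two phased alleles back
    into an IUPAC consensus."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    out = []
    for x, y in zip(a.upper(), b.upper()):
        if x == y:
            out.append(x)
        else:
            out.append(_BASE_PAIR_TO_CODE[frozenset((x, y))])
    return "".join(out)


def population_summary(aln: HaplotypeAlignment) -> pd.DataFrame:
    """Per-population n, segregating sites, pi, and Tajima's D.

    D is reported as NaN where undefined (S = 0 or n < 4).
    """
    rows = []
    for pop in pd.unique(np.asarray(aln.populations)):
        idx = [i for i, p in enumerate(aln.populations) if p == pop]
        sub = aln.subset(idx)
        keep = sub.valid_mask().all(axis=0)
        segm = sub.matrix[:, keep]
        S = int(((segm != segm[0]).any(axis=0)).sum()) if sub.n > 1 else 0
        pi = nucleotide_diversity(sub) if sub.n >= 2 else float("nan")
        try:
            D = tajimas_d(sub)
        except ValueError:
            D = float("nan")
        rows.append(dict(population=pop, region=sub.regions[0],
                         n=sub.n, S=S, pi=pi, tajimas_d=D))
    return pd.DataFrame(rows)
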