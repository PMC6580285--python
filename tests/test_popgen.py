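"""Population-genetic summaries against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hybridcline.popgen import (
    HaplotypeAlignment,
    combine_alleles,
    four_gamete_trim,
    hierarchical_amova,
    nucleotide_diversity,
    p_distance,
    population_summary,
    subtract_allele,
    tajimas_d,
)
from hybridcline.simulate import simulate_two_clade_alignment


def make_aln(seqs, pops=None, regs=None):
    n = len(seqs)
    pops = pops or ["p"] * n
    regs = regs or ["r"] * n
    return HaplotypeAlignment(ids=[f"s{i}" for i in range(n)], sequences=seqs,
                              populations=pops, regions=regs)


def random_seqs(rng, n, L):
    return ["".join(rng.choice(list("ACGT"), size=L)) for _ in range(n)]


class TestNucleotideDiversity:
    def test_two_sequences(self):
        a = "A" * 100
        b = "A" * 97 + "CGT"
        assert nucleotide_diversity(make_aln([a, b])) == pytest.approx(0.03)

    def test_identical_sequences(self):
        assert nucleotide_diversity(make_aln(["ACGT" * 10] * 5)) == 0.0

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            nucleotide_diversity(make_aln(["ACGT"]))

    def test_matches_all_pairs_oracle(self, rng):
        seqs = random_seqs(rng, 8, 50)
        aln = make_aln(seqs)
        vals = [sum(c1 != c2 for c1, c2 in zip(s1, s2)) / 50
                for s1, s2 in itertools.combinations(seqs, 2)]
        assert nucleotide_diversity(aln) == pytest.approx(np.mean(vals), abs=1e-12)

    def test_per_site_times_length_equals_count_form(self, rng):
        seqs = random_seqs(rng, 6, 80)
        aln = make_aln(seqs)
        counts = [sum(c1 != c2 for c1, c2 in zip(s1, s2))
                  for s1, s2 in itertools.combinations(seqs, 2)]
        assert nucleotide_diversity(aln) * 80 == pytest.approx(np.mean(counts), abs=1e-9)


class TestPDistance:
    def test_identical(self):
        s = "ACGT" * 260 + "A"  # 1,041 bp
        assert p_distance(s, s) == 0.0

    def test_three_differences_over_1041(self):
        a = "A" * 1041
        b = "C" * 3 + "A" * 1038
        assert p_distance(a, b) == pytest.approx(3 / 1041)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            p_distance("ACGT", "ACG")

    def test_matches_position_count_oracle(self, rng):
        a, b = random_seqs(rng, 2, 200)
        expected = sum(x != y for x, y in zip(a, b)) / 200
        assert p_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_ambiguous_sites_excluded(self):
        assert p_distance("ARGT", "AAGT") == 0.0  # R site dropped, 3 compared


def tajima_oracle(aln: HaplotypeAlignment) -> float:
    """Independent Tajima's D from the published constants."""
    n, L = aln.n, aln.length
    seqs = aln.sequences
    S = sum(1 for j in range(L) if len({s[j] for s in seqs}) > 1)
    k = np.mean([sum(c1 != c2 for c1, c2 in zip(s1, s2))
                 for s1, s2 in itertools.combinations(seqs, 2)])
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_no_segregating_sites_rejected(self):
        with pytest.raises(ValueError):
            tajimas_d(make_aln(["ACGT" * 5] * 6))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            tajimas_d(make_aln(["ACGT", "ACGA", "ACGT"]))

    def test_singleton_gives_negative_d(self):
        seqs = ["AAAA", "AAAA", "AAAA", "AAAT"]
        assert tajimas_d(make_aln(seqs)) < 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_constants_oracle(self, seed):
        """Independent per-site polymorphism simulation, compared to a
        scripted reimplementation of the published constants."""
        rng = np.random.default_rng(seed)
        n, L = 10, 60
        base = rng.choice(list("ACGT"), size=L)
        mat = np.tile(base, (n, 1))
        for j in rng.choice(L, size=12, replace=False):
            alt = rng.choice([b for b in "ACGT" if b != base[j]])
            carriers = rng.choice(n, size=rng.integers(1, n), replace=False)
            mat[carriers, j] = alt
        aln = make_aln(["".join(row) for row in mat])
        assert tajimas_d(aln) == pytest.approx(tajima_oracle(aln), abs=1e-10)

    def test_zero_when_pi_equals_watterson(self):
        """A configuration with mean pairwise differences exactly S/a1
        gives D = 0: n=4 (a1 = 11/6), 11 sites each at frequency 2/4
        with identical split => k = 11 * (4/6) per pair... constructed
        so k = S/a1 exactly."""
        # n=4, a1=1+1/2+1/3=11/6.  One site split 2/2 contributes
        # 4 differing pairs of 6 => 2/3 per site to k.  With S sites all
        # split 2/2: k = 2S/3.  Require k = S/a1 = 6S/11 -> not equal, so
        # mix site splits: x sites 2/2 (2/3 each) and y singleton sites
        # (3/6 = 1/2 each): k = 2x/3 + y/2, S = x + y, need
        # 2x/3 + y/2 = 6(x+y)/11 -> 22x/33 + 16.5y/33 = 18x/33 + 18y/33
        # -> 4x = 1.5y -> y = 8, x = 3 works.
        n = 4
        x_sites, y_sites = 3, 8
        L = x_sites + y_sites
        rows = [["A"] * L for _ in range(n)]
        for j in range(x_sites):           # 2/2 splits: 2/3 per pair each
            rows[0][j] = rows[1][j] = "G"
        for idx, j in enumerate(range(x_sites, L)):   # singletons: 1/2 each
            rows[idx % n][j] = "G"
        aln = make_aln(["".join(r) for r in rows])
        assert tajimas_d(aln) == pytest.approx(0.0, abs=1e-10)


def amova_oracle_3level(diff, pops, regs):
    """Hand-coded sums-of-squares decomposition (Excoffier et al.)."""
    N = len(pops)
    pop_ids = sorted(set(pops))
    reg_ids = sorted(set(regs))
    P, G = len(pop_ids), len(reg_ids)

    def ssd(indices):
        tot = 0.0
        for i in indices:
            for j in indices:
                tot += diff[i][j]
        return tot / (2 * len(indices))

    ssd_t = ssd(range(N))
    ssd_wp = sum(ssd([i for i in range(N) if pops[i] == p]) for p in pop_ids)
    ssd_wg = sum(ssd([i for i in range(N) if regs[i] == g]) for g in reg_ids)
    ms_ag = (ssd_t - ssd_wg) / (G - 1)
    ms_ap = (ssd_wg - ssd_wp) / (P - G)
    sc = ssd_wp / (N - P)
    sizes_p = {p: sum(1 for q in pops if q == p) for p in pop_ids}
    sizes_g = {g: sum(1 for h in regs if h == g) for g in reg_ids}
    pop_reg = {p: regs[pops.index(p)] for p in pop_ids}
    s_npg = sum(sizes_p[p]**2 / sizes_g[pop_reg[p]] for p in pop_ids)
    n1 = (N - s_npg) / (P - G)
    n2 = (s_npg - sum(v**2 for v in sizes_p.values()) / N) / (G - 1)
    n3 = (N - sum(v**2 for v in sizes_g.values()) / N) / (G - 1)
    sb = (ms_ap - sc) / n1
    sa = (ms_ag - sc - n2 * sb) / n3
    return sa, sb, sc


class TestAmova:
    def test_fixed_difference_populations(self):
        aln = simulate_two_clade_alignment(5, 5, 100, 10, 0, seed=1)
        r = hierarchical_amova(aln, n_perm=99, seed=0)
        assert r.phi_st == pytest.approx(1.0)
        assert r.p_phi_st <= 0.05

    def test_identical_composition_phi_near_zero(self, rng):
        seqs = random_seqs(rng, 4, 60)
        # both populations carry the same four haplotypes
        aln = make_aln(seqs + seqs, pops=["a"] * 4 + ["b"] * 4,
                       regs=["r1"] * 4 + ["r2"] * 4)
        r = hierarchical_amova(aln, n_perm=99, seed=0)
        assert r.phi_st <= 0.05  # negative estimates allowed

    def test_three_level_components_match_ssd_oracle(self, rng):
        # 3 regions x 2 populations x 4 sequences
        pops, regs, seqs = [], [], []
        for g in range(3):
            for p in range(2):
                for _ in range(4):
                    pops.append(f"g{g}p{p}")
                    regs.append(f"g{g}")
        seqs = random_seqs(rng, 24, 40)
        aln = make_aln(seqs, pops=pops, regs=regs)
        r = hierarchical_amova(aln, n_perm=0, seed=0)
        diff = [[sum(c1 != c2 for c1, c2 in zip(s1, s2)) for s2 in seqs] for s1 in seqs]
        sa, sb, sc = amova_oracle_3level(diff, pops, regs)
        assert r.sigma2_a == pytest.approx(sa, abs=1e-10)
        assert r.sigma2_b == pytest.approx(sb, abs=1e-10)
        assert r.sigma2_c == pytest.approx(sc, abs=1e-10)
        assert r.phi_st == pytest.approx((sa + sb) / (sa + sb + sc), abs=1e-10)

    def test_total_variance_conservation(self, rng):
        """sigma_a + sigma_b + sigma_c stays close to the unstructured
        mean squared deviation for balanced designs."""
        pops = [f"p{i // 4}" for i in range(16)]
        regs = [f"g{i // 8}" for i in range(16)]
        seqs = random_seqs(rng, 16, 50)
        aln = make_aln(seqs, pops=pops, regs=regs)
        r = hierarchical_amova(aln, n_perm=0, seed=0)
        diff = np.array([[sum(c1 != c2 for c1, c2 in zip(s1, s2))
                          for s2 in seqs] for s1 in seqs], dtype=float)
        # total SSD / (N-1): the single-level variance of the distances
        total_ms = (diff.sum() / (2 * 16)) / 15
        assert r.sigma2_a + r.sigma2_b + r.sigma2_c == pytest.approx(total_ms, rel=0.25)

    def test_permuted_labels_centered_on_zero(self, rng):
        seqs = random_seqs(rng, 12, 80)
        phis = []
        for _ in range(200):
            labels = rng.permutation([f"p{i % 3}" for i in range(12)])
            aln = make_aln(seqs, pops=list(labels), regs=["r"] * 12)
            phis.append(hierarchical_amova(aln, n_perm=0, seed=0).phi_st)
        phis = np.array(phis)
        assert abs(phis.mean()) <= 3 * phis.std(ddof=1) / math.sqrt(len(phis))

    def test_single_population_rejected(self, rng):
        aln = make_aln(random_seqs(rng, 4, 20))
        with pytest.raises(ValueError):
            hierarchical_amova(aln, n_perm=10, seed=0)

    def test_no_permutations_warns(self, rng):
        seqs = random_seqs(rng, 6, 30)
        aln = make_aln(seqs, pops=["a"] * 3 + ["b"] * 3, regs=["r"] * 6)
        with pytest.warns(UserWarning):
            r = hierarchical_amova(aln, n_perm=0, seed=0)
        assert r.p_phi_st is None


def four_gamete_oracle(aln: HaplotypeAlignment):
    """Exhaustive window scan: largest window with no violating pair."""
    L = aln.length
    seqs = aln.sequences
    biallelic = []
    for j in range(L):
        states = {s[j] for s in seqs}
        if len(states) == 2 and states <= set("ACGT"):
            biallelic.append(j)
    bad = set()
    for a, b in itertools.combinations(biallelic, 2):
        gametes = {(s[a], s[b]) for s in seqs}
        if len(gametes) == 4:
            bad.add((a, b))
    best = (0, -1)
    for s in range(L):
        for e in range(s, L):
            if e - s <= best[1] - best[0]:
                continue
            if all(not (s <= a and b <= e) for a, b in bad):
                best = (s, e)
    return best[0] + 1, best[1] + 1


class TestFourGamete:
    def test_no_violation_full_length(self, rng):
        seqs = ["AAAA", "AAAT", "AAAA", "AAAT"]
        assert four_gamete_trim(make_aln(seqs)) == (1, 4)

    def test_single_violation_keeps_right_window(self):
        # all four gametes at sites 10 and 50 (1-based) in L=100
        seqs = []
        for pat in ["AA", "AG", "GA", "GG"]:
            s = list("C" * 100)
            s[9], s[49] = pat[0], pat[1]
            seqs.append("".join(s))
        assert four_gamete_trim(make_aln(seqs)) == (11, 100)  # 90 beats 49

    def test_two_violations_matches_exhaustive_scan(self):
        # violations at (5,95) and (40,60), 1-based
        seqs = []
        for p1, p2 in zip(["AA", "AG", "GA", "GG"], ["TT", "TC", "CT", "CC"]):
            s = list("A" * 100)
            s[4], s[94] = p1[0], p1[1]
            s[39], s[59] = p2[0], p2[1]
            seqs.append("".join(s))
        aln = make_aln(seqs)
        assert four_gamete_trim(aln) == four_gamete_oracle(aln)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_alignments_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, L = 8, 30
        base = rng.choice(list("ACGT"), size=L)
        mat = np.tile(base, (n, 1))
        for j in rng.choice(L, size=10, replace=False):
            alt = rng.choice([b for b in "ACGT" if b != base[j]])
            carriers = rng.choice(n, size=rng.integers(1, n), replace=False)
            mat[carriers, j] = alt
        aln = make_aln(["".join(r) for r in mat])
        assert four_gamete_trim(aln) == four_gamete_oracle(aln)


class TestSubtractAllele:
    def test_simple_ambiguity(self):
        assert subtract_allele("ART", "AAT") == "AGT"

    def test_homozygote_passthrough(self):
        assert subtract_allele("ACGT", "ACGT") == "ACGT"

    def test_inconsistent_code_rejected(self):
        with pytest.raises(ValueError):
            subtract_allele("AWT", "ACT")  # W = {A,T} lacks C

    def test_triple_ambiguity_rejected(self):
        with pytest.raises(ValueError):
            subtract_allele("ANT", "AAT")

    @given(st.lists(st.sampled_from("ACGT"), min_size=5, max_size=30),
           st.data())
    @settings(max_examples=40, deadline=None)
    def test_roundtrip_regenerates_heterozygote(self, bases, data):
        """combine(known, subtract(het, known)) == het."""
        known = "".join(bases)
        alt = list(known)
        # mutate a random subset to create heterozygous positions
        idx = data.draw(st.sets(st.integers(0, len(known) - 1), max_size=5))
        for i in idx:
            alt[i] = data.draw(st.sampled_from([b for b in "ACGT" if b != known[i]]))
        het = combine_alleles(known, "".join(alt))
        recovered = subtract_allele(het, known)
        assert recovered == "".join(alt)
        assert combine_alleles(known, recovered) == het


class TestPopulationSummary:
    def test_table_shape_and_values(self):
        aln = simulate_two_clade_alignment(6, 6, 200, 8, 4, seed=3)
        df = population_summary(aln)
        assert set(df.columns) >= {"population", "region", "n", "S", "pi", "tajimas_d"}
        assert len(df) == 2
        assert (df["n"] == 6).all()
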