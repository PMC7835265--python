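"""Population genetics: frequencies, HWE, diversity, F-statistics."""

import numpy as np
import pytest

from gelkit import popgen as pg
from gelkit.quantify import BandClass, PresenceMatrix


def table(genotype_rows, loci=None, subpops=None):
    """Build a GenotypeTable from {individual: {locus: pair-or-None}} rows."""
    individuals = list(genotype_rows)
    loci = loci or {}
    genotypes = {}
    for ind, by_locus in genotype_rows.items():
        for locus, gt in by_locus.items():
            if locus not in loci:
                loci[locus] = []
            if gt is not None:
                for al in gt:
                    if al not in loci[locus]:
                        loci[locus].append(al)
                gt = tuple(sorted(gt))
            genotypes[(ind, locus)] = gt
    return pg.GenotypeTable(individuals=individuals, subpops=subpops or {},
                            loci=loci, genotypes=genotypes)


def hwe_table(n_aa, n_ab, n_bb, subpop=None, prefix="i"):
    rows = {}
    k = 0
    for count, gt in [(n_aa, ("A", "A")), (n_ab, ("A", "B")),
                      (n_bb, ("B", "B"))]:
        for _ in range(count):
            rows[f"{prefix}{k}"] = {"L": gt}
            k += 1
    subpops = {ind: subpop for ind in rows} if subpop else {}
    return table(rows, subpops=subpops)


class TestInferGenotypes:
    def make_matrix(self, entries):
        return PresenceMatrix(
            band_classes=[BandClass(value=100.0 * (i + 1), members=[])
                          for i in range(len(entries))],
            samples=[f"s{i}" for i in range(len(entries[0]))],
            entries=np.array(entries, dtype=int))

    def test_single_band_is_homozygote(self):
        m = self.make_matrix([[1, 0], [0, 1]])
        g = pg.infer_genotypes(m, {"L": [0, 1]})
        assert g.genotypes[("s0", "L")] == ("100", "100")
        assert g.genotypes[("s1", "L")] == ("200", "200")

    def test_two_bands_are_heterozygote(self):
        m = self.make_matrix([[1, 1], [1, 0]])
        g = pg.infer_genotypes(m, {"L": [0, 1]})
        assert g.genotypes[("s0", "L")] == ("100", "200")

    def test_no_band_is_missing(self):
        m = self.make_matrix([[0, 1], [0, 1]])
        g = pg.infer_genotypes(m, {"L": [0, 1]})
        assert g.genotypes[("s0", "L")] is None

    def test_three_bands_violate_diploidy(self):
        m = self.make_matrix([[1, 1], [1, 1], [1, 0]])
        with pytest.raises(ValueError, match="s0.*L"):
            pg.infer_genotypes(m, {"L": [0, 1, 2]})


class TestAlleleFrequencies:
    def test_fixation(self):
        g = hwe_table(10, 0, 0)
        assert pg.allele_frequencies(g, "L") == {"A": 1.0}

    def test_gene_counting(self):
        g = hwe_table(4, 4, 2)
        freqs = pg.allele_frequencies(g, "L")
        assert freqs["A"] == pytest.approx(0.6)
        assert freqs["B"] == pytest.approx(0.4)

    def test_missing_excluded_from_denominator(self):
        rows = {"i0": {"L": ("A", "A")}, "i1": {"L": ("A", "B")},
                "i2": {"L": None}}
        g = table(rows)
        freqs = pg.allele_frequencies(g, "L")
        assert freqs["A"] == pytest.approx(0.75)

    def test_frequencies_sum_to_one(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 20, 3)
            if counts.sum() == 0:
                continue
            g = hwe_table(*(int(c) for c in counts))
            assert sum(pg.allele_frequencies(g, "L").values()) == \
                pytest.approx(1.0, abs=1e-9)


class TestHweTest:
    def test_perfect_fit_gives_zero_chi_square(self):
        g = hwe_table(25, 50, 25)
        _, expected, chi2, df, p = pg.hwe_test(g, "L")
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)
        assert sum(expected.values()) == pytest.approx(100.0)

    def test_missing_heterozygotes_give_chi_square_n(self):
        g = hwe_table(50, 0, 50)
        _, _, chi2, df, _ = pg.hwe_test(g, "L")
        assert chi2 == pytest.approx(100.0)
        assert df == 1

    def test_three_alleles_have_df_three(self):
        rows = {}
        for i, gt in enumerate([("A", "A"), ("B", "B"), ("C", "C"),
                                ("A", "B"), ("A", "C"), ("B", "C")] * 5):
            rows[f"i{i}"] = {"L": gt}
        g = table(rows)
        with pytest.warns(UserWarning, match="below 5"):
            _, _, _, df, _ = pg.hwe_test(g, "L")
        assert df == 3

    def test_monomorphic_locus_rejected(self):
        g = hwe_table(10, 0, 0)
        with pytest.raises(ValueError, match="monomorphic"):
            pg.hwe_test(g, "L")

    def test_low_expected_counts_warn(self):
        g = hwe_table(9, 1, 0)
        with pytest.warns(UserWarning, match="below 5"):
            pg.hwe_test(g, "L")


class TestDiversity:
    def test_fixed_locus_has_no_diversity(self):
        g = hwe_table(10, 0, 0)
        ho, he, hom, pic = pg.diversity_stats(g, "L")
        assert (ho, he, pic) == (0.0, 0.0, 0.0) and hom == 1.0

    def test_balanced_biallelic_values(self):
        g = hwe_table(25, 50, 25)
        ho, he, hom, pic = pg.diversity_stats(g, "L")
        assert he == pytest.approx(0.5)
        assert pic == pytest.approx(0.375)

    def test_all_heterozygotes_have_ho_one(self):
        g = hwe_table(0, 10, 0)
        ho, _, _, _ = pg.diversity_stats(g, "L")
        assert ho == 1.0

    def test_he_bounds_pic_on_random_tables(self, rng):
        for _ in range(50):
            counts = rng.integers(1, 15, 3)
            g = hwe_table(*(int(c) for c in counts))
            _, he, _, pic = pg.diversity_stats(g, "L")
            assert 0.0 <= pic <= he <= 1.0


def two_subpop_table(counts1, counts2):
    g1 = hwe_table(*counts1, prefix="a")
    rows = {}
    subpops = {}
    k = 0
    for counts, label, prefix in [(counts1, "p1", "a"), (counts2, "p2", "b")]:
        for count, gt in zip(counts, [("A", "A"), ("A", "B"), ("B", "B")]):
            for _ in range(count):
                name = f"{prefix}{k}"
                rows[name] = {"L": gt}
                subpops[name] = label
                k += 1
    return table(rows, subpops=subpops)


class TestFStatistics:
    def test_panmixia_zeroes_all_f(self):
        g = two_subpop_table((25, 50, 25), (25, 50, 25))
        per_locus, avg = pg.f_statistics(g)
        f = per_locus["L"]
        assert f.fis == pytest.approx(0.0, abs=1e-9)
        assert f.fst == pytest.approx(0.0, abs=1e-9)
        assert f.fit == pytest.approx(0.0, abs=1e-9)

    def test_alternative_fixation_gives_fst_one(self):
        g = two_subpop_table((20, 0, 0), (0, 0, 20))
        per_locus, _ = pg.f_statistics(g)
        f = per_locus["L"]
        assert f.hs == 0.0 and f.ht == pytest.approx(0.5)
        assert f.fst == pytest.approx(1.0)

    def test_f_identity_on_random_tables(self, rng):
        checked = 0
        for _ in range(100):
            c1 = tuple(int(x) for x in rng.integers(0, 15, 3))
            c2 = tuple(int(x) for x in rng.integers(0, 15, 3))
            if sum(c1) == 0 or sum(c2) == 0:
                continue
            g = two_subpop_table(c1, c2)
            per_locus, _ = pg.f_statistics(g)
            f = per_locus["L"]
            if any(np.isnan([f.fis, f.fst, f.fit])):
                continue
            assert (1 - f.fis) * (1 - f.fst) == pytest.approx(1 - f.fit,
                                                              abs=1e-9)
            checked += 1
        assert checked > 20

    def test_pooled_he_equals_ht(self, rng):
        c1 = (10, 20, 5)
        c2 = (3, 12, 18)
        g = two_subpop_table(c1, c2)
        per_locus, _ = pg.f_statistics(g)
        _, he_pooled, _, _ = pg.diversity_stats(g, "L")  # whole table
        assert he_pooled == pytest.approx(per_locus["L"].ht, abs=1e-12)

    def test_single_subpopulation_rejected(self):
        g = hwe_table(5, 5, 5, subpop="only")
        with pytest.raises(ValueError):
            pg.f_statistics(g)

    def test_island_model_mean_fst_matches_analytic_gst(self, rng):
        """Two demes at p = 0.5 +/- delta: GST = 4 delta^2 / (1 - ... )."""
        delta = 0.2
        p1, p2 = 0.5 + delta, 0.5 - delta
        n = 200
        n_loci = 50
        fsts = []
        for locus in range(n_loci):
            rows, subpops = {}, {}
            for label, p, prefix in [("p1", p1, "a"), ("p2", p2, "b")]:
                gts = rng.choice(["AA", "AB", "BB"], size=n,
                                 p=[p * p, 2 * p * (1 - p), (1 - p) ** 2])
                for i, code in enumerate(gts):
                    name = f"{prefix}{locus}_{i}"
                    rows[name] = {"L": tuple(code)}
                    subpops[name] = label
            g = table(rows, subpops=subpops)
            per_locus, _ = pg.f_statistics(g)
            fsts.append(per_locus["L"].fst)
        fsts = np.array(fsts)
        # analytic GST for the generating frequencies
        hs = 0.5 * (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2))
        ht = 1.0 - 0.5 ** 2 - 0.5 ** 2
        gst = (ht - hs) / ht
        se = fsts.std(ddof=1) / np.sqrt(n_loci)
        assert abs(fsts.mean() - gst) <= 3 * se


class TestDominantMode:
    def test_null_allele_from_absent_fraction(self):
        m = PresenceMatrix(
            band_classes=[BandClass(value=500.0, members=[])],
            samples=[f"s{i}" for i in range(4)],
            entries=np.array([[1, 1, 1, 0]]))
        df = pg.dominant_locus_stats(m)
        q = np.sqrt(0.25)
        assert df.loc[0, "q_null"] == pytest.approx(q)
        assert df.loc[0, "He"] == pytest.approx(2 * (1 - q) * q)
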