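"""Hill numbers, partitioning, similarity indices and abundance profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hillpop.containers import MISSING
from hillpop.diversity import (
    AbundanceProfile,
    alpha_profile,
    beta_table,
    hill_number,
    partition,
    similarity_indices,
    snp_abundance,
)
from hillpop.simulate import default_cohort

from conftest import make_matrix


def profile(counts, owner="x", autosome="chr1"):
    counts = np.asarray(counts)
    return AbundanceProfile(
        owner=owner,
        autosome=autosome,
        counts=counts,
        gene_ids=[f"g{i}" for i in range(len(counts))],
    )


random_abundances = st.lists(
    st.integers(min_value=0, max_value=100), min_size=2, max_size=30
).filter(lambda c: sum(c) > 0)


class TestHillNumber:
    @pytest.mark.parametrize("q", [0, 0.5, 1, 2, 4])
    def test_uniform_distribution_equals_richness(self, q):
        assert hill_number(np.full(7, 1 / 7), q) == pytest.approx(7.0)

    def test_q1_is_exponential_shannon(self):
        # H = 1.5 bits = 1.5 ln 2 nats, so 1D = 2^1.5
        assert hill_number(np.array([0.5, 0.25, 0.25]), 1) == pytest.approx(
            2 ** 1.5
        )

    @pytest.mark.parametrize("q", [0, 1, 2, 3])
    def test_single_category(self, q):
        assert hill_number(np.array([1.0]), q) == pytest.approx(1.0)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            hill_number(np.array([0.5, 0.4]), 2)

    @settings(deadline=None, max_examples=200)
    @given(random_abundances)
    def test_monotone_nonincreasing_and_bounded(self, counts):
        p = np.asarray(counts, dtype=float)
        p /= p.sum()
        grid = [0.0, 0.5, 1.0, 2.0, 3.0, 4.0]
        qd = [hill_number(p, q) for q in grid]
        s = (p > 0).sum()
        assert all(a >= b - 1e-9 for a, b in zip(qd, qd[1:]))
        assert all(1.0 - 1e-9 <= v <= s + 1e-9 for v in qd)
        assert qd[0] == pytest.approx(s)

    @settings(deadline=None, max_examples=200)
    @given(random_abundances)
    def test_continuity_at_q_one(self, counts):
        p = np.asarray(counts, dtype=float)
        p /= p.sum()
        exact = hill_number(p, 1.0)
        assert abs(hill_number(p, 1.0 + 1e-6) - exact) < 1e-4
        assert abs(hill_number(p, 1.0 - 1e-6) - exact) < 1e-4


class TestAlphaProfile:
    def test_even_counts_give_flat_profile(self):
        dp = alpha_profile(profile([1, 1, 1, 1]))
        np.testing.assert_allclose(dp.qD, 4.0)

    def test_skewed_counts_collapse_at_high_q(self):
        dp = alpha_profile(profile([97, 1, 1, 1]))
        assert dp.qD[0] == pytest.approx(4.0)
        assert dp.qD[-1] < 1.3  # q = 4

    def test_unusable_profile_raises(self):
        with pytest.raises(ValueError, match="zero total"):
            alpha_profile(profile([0, 0]))


class TestPartition:
    def test_identical_assemblages_have_beta_one(self):
        a = profile([5, 3, 2])
        b = profile([10, 6, 4], owner="y")  # same composition
        for q in (0, 1, 2, 4):
            assert partition([a, b], q).beta == pytest.approx(1.0)

    def test_disjoint_assemblages_have_beta_n(self):
        a = profile([4, 4, 0, 0])
        b = profile([0, 0, 4, 4], owner="y")
        assert partition([a, b], 2).beta == pytest.approx(2.0)
        c = profile([0, 0, 0, 0, 2, 6], owner="z", )
        # three mutually disjoint assemblages
        a3 = profile([4, 4, 0, 0, 0, 0])
        b3 = profile([0, 0, 4, 4, 0, 0], owner="y")
        assert partition([a3, b3, c], 2).beta == pytest.approx(3.0)

    @pytest.mark.parametrize("q", [0.0, 1.0, 2.0, 3.5])
    def test_gamma_equals_alpha_times_beta(self, q):
        rng = np.random.default_rng(0)
        for _ in range(20):
            profs = [
                profile(rng.integers(0, 20, 12), owner=str(k)) for k in range(3)
            ]
            if not all(p.usable for p in profs):
                continue
            part = partition(profs, q)
            assert part.gamma == pytest.approx(part.alpha * part.beta, abs=1e-9)
            assert 1.0 - 1e-9 <= part.beta <= 3.0 + 1e-9

    def test_mismatched_gene_lists_rejected(self):
        a = profile([1, 2])
        b = AbundanceProfile("y", "chr1", np.array([1, 2]), ["h0", "h1"])
        with pytest.raises(ValueError, match="gene list"):
            partition([a, b], 2)


class TestSimilarityIndices:
    @pytest.mark.parametrize("q", [0.0, 1.0, 2.0, 4.0])
    @pytest.mark.parametrize("n", [2, 4])
    def test_all_one_at_beta_one(self, q, n):
        s = similarity_indices(1.0, n, q)
        assert (s.Cq, s.Uq, s.Sq, s.Vq) == (1.0, 1.0, 1.0, 1.0)

    @pytest.mark.parametrize("q", [0.0, 1.0, 2.0, 4.0])
    @pytest.mark.parametrize("n", [2, 4])
    def test_all_zero_at_beta_n(self, q, n):
        s = similarity_indices(float(n), n, q)
        for v in (s.Cq, s.Uq, s.Sq, s.Vq):
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_known_values_at_beta_1p5(self):
        s = similarity_indices(1.5, 2, 2.0)
        assert s.Cq == pytest.approx(1 / 3)
        assert s.Sq == pytest.approx(1 / 3)
        assert s.Vq == pytest.approx(0.5)
        # Uq of order 2 for N = 2: ((1/b)^-1 - 2) / (1 - 2)
        assert s.Uq == pytest.approx(0.5)

    def test_beta_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            similarity_indices(2.5, 2, 2.0)
        with pytest.raises(ValueError):
            similarity_indices(1.5, 1, 2.0)


class TestSnpAbundance:
    def _cohort_matrix(self):
        # 2 genes of 1000 bp; sites at 100 (gene 1), 1500 & 1900 (gene 2),
        # and 2500 (outside every gene)
        d = np.array(
            [[1, 0, 2, 1],
             [0, 1, 1, 0],
             [MISSING, 2, 0, 2]],
            dtype=np.int8,
        )
        g = make_matrix(d, positions=[100, 1500, 1900, 2500])
        import pandas as pd

        from hillpop.containers import GeneIntervals

        intervals = GeneIntervals(
            pd.DataFrame(
                {
                    "chrom": ["chr1", "chr1"],
                    "start": [0, 1000],
                    "end": [1000, 2000],
                    "gene_id": ["g1", "g2"],
                }
            )
        )
        return g, intervals

    def test_allele_counting_per_gene(self):
        g, intervals = self._cohort_matrix()
        p = snp_abundance(g, intervals, "s1", "chr1")
        np.testing.assert_array_equal(p.counts, [1, 2])  # site at 2500 ignored

    def test_missing_contributes_zero(self):
        g, intervals = self._cohort_matrix()
        p = snp_abundance(g, intervals, "s3", "chr1")
        np.testing.assert_array_equal(p.counts, [0, 2])

    def test_pooled_equals_elementwise_sum(self):
        g, intervals = self._cohort_matrix()
        pooled = snp_abundance(g, intervals, ["s1", "s2"], "chr1")
        a = snp_abundance(g, intervals, "s1", "chr1")
        b = snp_abundance(g, intervals, "s2", "chr1")
        np.testing.assert_array_equal(pooled.counts, a.counts + b.counts)

    def test_presence_mode_differs_exactly_at_hom_alt(self):
        g, intervals = self._cohort_matrix()
        for s in g.samples:
            allele = snp_abundance(g, intervals, s, "chr1")
            presence = snp_abundance(g, intervals, s, "chr1", counting="presence")
            diff = allele.counts.sum() - presence.counts.sum()
            row = g.dosages[g.samples.index(s)]
            pos_ok = np.array([True, True, True, False])  # in-gene sites
            assert diff == ((row == 2) & pos_ok).sum()


class TestBetaTables:
    def test_duplicated_individual_gives_beta_one(self):
        import pandas as pd

        from hillpop.containers import GeneIntervals, PopulationMap

        rng = np.random.default_rng(1)
        row = rng.integers(0, 3, 60).astype(np.int8)
        g = make_matrix(np.vstack([row, row]), samples=["a", "b"],
                        positions=np.arange(1, 61) * 100)
        intervals = GeneIntervals(
            pd.DataFrame(
                {"chrom": ["chr1"] * 3, "start": [0, 2000, 4000],
                 "end": [2000, 4000, 6000], "gene_id": ["g1", "g2", "g3"]}
            )
        )
        pm = PopulationMap(
            pd.DataFrame(
                {"sample_id": ["a", "b"], "population": ["A", "B"],
                 "species": ["s", "s"]}
            )
        )
        t = beta_table(g, intervals, pm, mode="between", level="population")
        assert np.allclose(t["beta"], 1.0)
        assert np.allclose(t[["Cq", "Uq", "Sq", "Vq"]], 1.0)

    def test_autosome_average_is_mean_of_per_autosome(self, small_cohort):
        from hillpop.diversity import beta_mean_table

        t = beta_table(
            small_cohort.genotypes, small_cohort.gene_intervals,
            small_cohort.pop_map, mode="between", level="species",
        )
        m = beta_mean_table(t)
        one = t[(t.comparison == m.comparison.iloc[0]) & (t.q == m.q.iloc[0])]
        assert m["beta"].iloc[0] == pytest.approx(one["beta"].mean())

    def test_species_divergence_raises_beta_and_lowers_similarity(self):
        # population pairs from the same weakly-diverged species vs pairs
        # spanning the strongly diverged species
        cohort = default_cohort(seed=41, n_autosomes=2, sites_per_autosome=800)
        t = beta_table(
            cohort.genotypes, cohort.gene_intervals, cohort.pop_map,
            mode="between", level="population",
        )
        species_of_pop = {
            p: cohort.pop_map.species_of(cohort.pop_map.members(p)[0])
            for p in cohort.pop_map.populations
        }
        pair_species = t["comparison"].map(
            lambda c: len({species_of_pop[x] for x in c.split("|")})
        )
        cross = t[(pair_species == 2) & (t.q >= 1)]
        within = t[(pair_species == 1) & (t.q >= 1)]
        assert cross["beta"].mean() > within["beta"].mean()
        for col in ("Cq", "Uq", "Sq", "Vq"):
            assert cross[col].mean() < within[col].mean()

    def test_richness_saturates_at_q0(self):
        # between-species alpha contrast is relatively smaller at q = 0
        # (gene richness saturates) than at q = 4
        from hillpop.diversity import alpha_mean_table, alpha_table

        cohort = default_cohort(seed=42, n_autosomes=2, sites_per_autosome=800)
        alpha = alpha_mean_table(
            alpha_table(cohort.genotypes, cohort.gene_intervals)
        )
        species = {
            s: cohort.pop_map.species_of(s) for s in cohort.genotypes.samples
        }
        alpha["species"] = alpha["sample"].map(species)

        def rel_diff(q):
            sub = alpha[alpha.q == q]
            means = sub.groupby("species")["alpha_mean"].mean()
            return abs(means.iloc[0] - means.iloc[1]) / means.mean()

        assert rel_diff(0.0) <= rel_diff(4.0)
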