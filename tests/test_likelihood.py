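"""Log-likelihood ratios: per-chromosome contributions, genome sums,
moments, misclassification and the assignment machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import segshare as ss
from segshare.likelihood import LRMoments, read_distribution, write_distribution

from conftest import COUNT_DIST_REF, COUNT_DIST_REF_N, table_from_counts


@pytest.fixture(scope="module")
def printed_count_dists():
    return {ab: table_from_counts(ab, counts) for ab, counts in COUNT_DIST_REF.items()}


class TestChromLoglr:
    def test_printed_count_table_examples(self, printed_count_dists):
        """Three shared segments: lambda(UN:HS) ~ ln(0.310/0.243) and
        lambda(UN:GUGN) ~ ln(1.91)."""
        key = ss.OutcomeKey(3, None, None)
        lam_hs = ss.chrom_loglr(key, printed_count_dists["UN"],
                                printed_count_dists["HS"])
        assert lam_hs == pytest.approx(math.log(31041 / 24284))
        assert lam_hs == pytest.approx(0.245, abs=5e-3)
        lam_gugn = ss.chrom_loglr(key, printed_count_dists["UN"],
                                  printed_count_dists["GUGN"])
        assert lam_gugn == pytest.approx(0.645, abs=5e-3)

    def test_identical_distributions_give_zero(self, printed_count_dists):
        d = printed_count_dists["HS"]
        for key in d.support():
            assert ss.chrom_loglr(key, d, d) == 0.0

    def test_zero_cell_substitution(self):
        distA = ss.EmpiricalDistribution("A", 1.0, 4, {
            ss.OutcomeKey(1, 0, 1): 3, ss.OutcomeKey(2, 0, 1): 1})
        distB = ss.EmpiricalDistribution("B", 1.0, 4, {
            ss.OutcomeKey(1, 0, 1): 4})
        lam = ss.chrom_loglr(ss.OutcomeKey(2, 0, 1), distA, distB)
        assert lam == pytest.approx(math.log(0.25) - math.log(1 / 8))
        # symmetric substitution when the truth-side estimate is zero
        lam = ss.chrom_loglr(ss.OutcomeKey(1, 0, 1), distB, distA)
        assert lam == pytest.approx(math.log(1.0) - math.log(3 / 4))

    def test_unseen_under_both_contributes_zero(self, caplog):
        distA = ss.EmpiricalDistribution("A", 1.0, 4, {ss.OutcomeKey(0): 4})
        distB = ss.EmpiricalDistribution("B", 1.0, 4, {ss.OutcomeKey(0): 4})
        with caplog.at_level("WARNING"):
            lam = ss.chrom_loglr(ss.OutcomeKey(3, 1, 2), distA, distB)
        assert lam == 0.0
        assert "unseen under both" in caplog.text


class TestGenomeLoglr:
    def test_additivity_over_identical_chromosomes(self, printed_count_dists):
        dA, dB = printed_count_dists["UN"], printed_count_dists["HS"]
        bankA, bankB = {163: dA}, {163: dB}
        key = ss.OutcomeKey(2, None, None)
        single = ss.chrom_loglr(key, dA, dB)
        profile = [(1.632, key)] * 22
        assert ss.genome_loglr(profile, bankA, bankB) == pytest.approx(22 * single)

    def test_empty_profile_and_permutation_invariance(self, printed_count_dists):
        dA, dB = printed_count_dists["UN"], printed_count_dists["HS"]
        bankA, bankB = {163: dA}, {163: dB}
        assert ss.genome_loglr([], bankA, bankB) == 0.0
        profile = [(1.632, ss.OutcomeKey(n, None, None)) for n in (0, 2, 4)]
        lam = ss.genome_loglr(profile, bankA, bankB)
        assert ss.genome_loglr(profile[::-1], bankA, bankB) == pytest.approx(lam)
        expected = sum(ss.chrom_loglr(k, dA, dB) for _, k in profile)
        assert lam == pytest.approx(expected)

    def test_missing_length_raises(self, printed_count_dists):
        bank = {163: printed_count_dists["UN"]}
        with pytest.raises(KeyError):
            ss.genome_loglr([(0.75, ss.OutcomeKey(0))], bank, bank)


def _one_chrom_genome(l=1.632):
    return ss.GenomeModel("one", (ss.ChromosomeSpec(l, 1),))


class TestMoments:
    def test_same_relationship_has_zero_mean_and_sd(self, printed_count_dists):
        bank = ss.DistributionBank()
        bank.add(printed_count_dists["UN"])
        m = ss.lr_moments("UN", "UN", _one_chrom_genome(), bank, info="n")
        assert m.mean == 0.0 and m.sd == 0.0
        assert math.isnan(m.ratio)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.integers(1, 50), st.integers(1, 50)),
                    min_size=2, max_size=8))
    def test_kl_distance_is_nonnegative_on_shared_support(self, cells):
        """Gibbs' inequality for the empirical plug-in distributions."""
        countsA = {ss.OutcomeKey(i, None, None): a for i, (a, _) in enumerate(cells)}
        countsB = {ss.OutcomeKey(i, None, None): b for i, (_, b) in enumerate(cells)}
        NA, NB = sum(countsA.values()), sum(countsB.values())
        bank = ss.DistributionBank()
        bank.add(ss.EmpiricalDistribution("A", 1.632, NA, countsA, info="n"))
        bank.add(ss.EmpiricalDistribution("B", 1.632, NB, countsB, info="n"))
        m = ss.lr_moments("A", "B", _one_chrom_genome(), bank, info="n")
        # KL(A||B) >= 0 exactly, with equality iff the distributions match
        assert m.mean >= -1e-12

    def test_probabilities_sum_to_one_and_mismatched_counts_rejected(self):
        rng = np.random.default_rng(51)
        d = ss.estimate_distribution("C", 1.25, 5000, rng)
        assert sum(d.counts.values()) == d.N
        assert sum(d.prob(k) for k in d.support()) == pytest.approx(1.0)
        with pytest.raises(ValueError, match="counts sum"):
            ss.EmpiricalDistribution("C", 1.25, 10, {ss.OutcomeKey(0): 5})

    def test_equal_length_model_approximates_five_length_model(
            self, human5_bank, equal22_bank):
        """E(lambda)/SD(lambda) barely changes when the five chromosome
        length classes are replaced by 22 chromosomes of the average
        length (~2% for ratios near or above 1, plus sampling noise)."""
        for truth, hyp in [("UN", "HS"), ("HS", "UN")]:
            r5 = ss.lr_moments(truth, hyp, ss.make_genome("human5"),
                               human5_bank).ratio
            r22 = ss.lr_moments(truth, hyp, ss.make_genome("equal22"),
                                equal22_bank).ratio
            assert abs(r5 - r22) / r5 < 0.03, (truth, hyp)

    def test_cumulants_add_over_chromosomes(self, printed_count_dists):
        bank = ss.DistributionBank()
        bank.add(printed_count_dists["UN"])
        bank.add(printed_count_dists["HS"])
        one = ss.lr_moments("UN", "HS", _one_chrom_genome(), bank, info="n")
        genome22 = ss.GenomeModel("e22", (ss.ChromosomeSpec(1.632, 22),))
        m22 = ss.lr_moments("UN", "HS", genome22, bank, info="n")
        assert m22.mean == pytest.approx(22 * one.mean)
        assert m22.sd == pytest.approx(math.sqrt(22) * one.sd)
        assert m22.skew == pytest.approx(one.skew / math.sqrt(22))
        assert m22.excess_kurtosis == pytest.approx(one.excess_kurtosis / 22)


class TestMisclassification:
    def test_printed_normal_quantiles(self):
        m_ab = LRMoments(2.22, 1.0, 0, 0, 2.22)
        m_ba = LRMoments(2.14, 1.0, 0, 0, 2.14)
        p_ab, p_ba = ss.misclassification(m_ab, m_ba)
        assert p_ab == pytest.approx(0.013, abs=5e-4)
        assert p_ba == pytest.approx(0.016, abs=5e-4)

    def test_zero_ratio_is_a_coin_flip(self):
        m = LRMoments(0.0, 1.0, 0, 0, 0.0)
        assert ss.misclassification(m, m) == (0.5, 0.5)

    def test_zero_sd_rejected(self):
        m = LRMoments(0.0, 0.0, 0, 0, float("nan"))
        with pytest.raises(ValueError):
            ss.misclassification(m, m)


class TestEstimateDistribution:
    def test_single_replicate_gives_single_outcome(self):
        rng = np.random.default_rng(52)
        d = ss.estimate_distribution("HS", 1.632, 1, rng)
        assert d.N == 1 and list(d.counts.values()) == [1]

    def test_collapse_rule_on_keys(self):
        rng = np.random.default_rng(53)
        d = ss.estimate_distribution("UN", 2.75, 30_000, rng)
        for key in d.support():
            if key.n_s == 0:
                assert key.p_s is None and key.t_s is None
            elif 1 <= key.n_s <= 4:
                assert key.p_s is not None and key.t_s is not None
            else:
                assert key.p_s is not None and key.t_s is None

    def test_marginals_are_consistent(self):
        rng = np.random.default_rng(54)
        d = ss.estimate_distribution("C", 1.632, 20_000, rng)
        dn = d.marginal("n")
        assert sum(dn.counts.values()) == d.N
        n2 = sum(c for k, c in d.counts.items() if k.n_s == 2)
        assert dn.counts[ss.OutcomeKey(2, None, None)] == n2
        with pytest.raises(ValueError):
            dn.marginal("npt")


class TestBankIO:
    def test_round_trip_is_bit_exact(self, tmp_path):
        rng = np.random.default_rng(55)
        bank = ss.DistributionBank.build(["HS", "GPO"], [0.75, 1.632], 2000, rng)
        d1 = tmp_path / "a"
        paths = bank.save(d1, seed=55)
        assert len(paths) == 4
        reloaded = ss.DistributionBank.load(d1)
        d2 = tmp_path / "b"
        reloaded.save(d2, seed=55)
        for p1, p2 in zip(sorted(d1.iterdir()), sorted(d2.iterdir())):
            assert p1.read_bytes() == p2.read_bytes()
        assert reloaded.get("HS", 1.632).counts == bank.get("HS", 1.632).counts

    def test_distribution_file_headers(self, tmp_path):
        rng = np.random.default_rng(56)
        d = ss.estimate_distribution("UN", 1.25, 100, rng)
        path = tmp_path / "bank_UN_125cM.tsv"
        write_distribution(d, path, seed=56)
        head = path.read_text().splitlines()[0]
        for token in ("relationship=UN", "length_cM=125", "N=100", "seed=56"):
            assert token in head
        assert read_distribution(path).counts == d.counts


class TestHeldOutSampling:
    def test_assignment_between_identical_relationships_is_chance(self, human5_bank):
        rng = np.random.default_rng(57)
        genome = ss.make_genome("human5")
        ra, rb = ss.assignment_experiment("C", "C", genome, human5_bank, 2000, rng)
        se = math.sqrt(0.25 / 2000)
        assert abs(ra - 0.5) < 4 * se and abs(rb - 0.5) < 4 * se

    def test_standardized_lr_sample_matches_moments(self, human5_bank):
        rng = np.random.default_rng(58)
        genome = ss.make_genome("human5")
        z = ss.distribution_of_lr("UN", "HS", genome, human5_bank, 4000, rng)
        mom = ss.lr_moments("UN", "HS", genome, human5_bank)
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=0.08)
        assert z.mean() == pytest.approx(mom.ratio, abs=4 * 1.0 / math.sqrt(4000))

    def test_identical_relationships_give_all_zero_lr(self, human5_bank):
        rng = np.random.default_rng(59)
        genome = ss.make_genome("human5")
        z = ss.distribution_of_lr("HS", "HS", genome, human5_bank, 50, rng)
        assert np.all(z == 0.0)
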