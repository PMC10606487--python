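"""Sib-pair IBD likelihoods and posteriors against the parental-enumeration
oracle, plus allele-frequency estimation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edsp import ibd
from edsp.models import EdspError, MarkerDef, MarkerMap
from edsp.oracles import ibd_oracle
from edsp.synthetic_data import mask_parents, simulate_families

from conftest import make_sib


def unordered_genotypes(alleles):
    return [tuple(sorted(g))
            for g in itertools.combinations_with_replacement(alleles, 2)]


class TestAlleleFrequencies:
    def test_gene_counting(self):
        m = MarkerMap([MarkerDef(name="A", n_alleles=2)])
        recs = [make_sib(iid="S1", genotypes=[(1, 1)]),
                make_sib(iid="S2", genotypes=[(1, 2)])]
        (freqs,) = ibd.estimate_allele_frequencies(recs, m)
        assert freqs == {1: 0.75, 2: 0.25}

    def test_missing_genotypes_ignored(self):
        m = MarkerMap([MarkerDef(name="A", n_alleles=2)])
        recs = [make_sib(iid="S1", genotypes=[(1, 2)]),
                make_sib(iid="S2", genotypes=[(0, 0)])]
        (freqs,) = ibd.estimate_allele_frequencies(recs, m)
        assert freqs == {1: 0.5, 2: 0.5}

    def test_all_missing_marker_named_in_error(self):
        m = MarkerMap([MarkerDef(name="D17S250", n_alleles=2)])
        recs = [make_sib(genotypes=[(0, 0)])]
        with pytest.raises(EdspError, match="D17S250"):
            ibd.estimate_allele_frequencies(recs, m)

    def test_recovery_on_simulated_cohort(self, default_model,
                                          linked_marker):
        # 8 equifrequent alleles, 250 families = 500 genotyped sibs
        cohort = simulate_families(250, default_model, [linked_marker],
                                   seed=21)
        (freqs,) = ibd.estimate_allele_frequencies(
            cohort.offspring(), cohort.marker_map)
        assert len(freqs) == 8
        for f in freqs.values():
            assert abs(f - 0.125) < 0.02


class TestPairLikelihoods:
    def test_shared_heterozygote_case(self):
        f = {1: 0.5, 2: 0.5}
        assert ibd.pair_likelihoods_given_ibd((1, 2), (1, 2), f) == \
            pytest.approx((0.25, 0.25, 0.5))

    def test_disjoint_homozygotes_force_ibd_zero(self):
        f = {1: 0.3, 2: 0.7}
        l0, l1, l2 = ibd.pair_likelihoods_given_ibd((1, 1), (2, 2), f)
        assert l0 == pytest.approx(0.3**2 * 0.7**2)
        assert l1 == 0.0
        assert l2 == 0.0

    def test_monomorphic_marker_uninformative(self):
        f = {1: 1.0}
        assert ibd.pair_likelihoods_given_ibd((1, 1), (1, 1), f) == \
            pytest.approx((1.0, 1.0, 1.0))

    def test_missing_genotype_signals_uninformative(self):
        assert ibd.pair_likelihoods_given_ibd((0, 0), (1, 1),
                                              {1: 1.0}) is None

    def test_unknown_allele_rejected(self):
        with pytest.raises(EdspError, match="absent"):
            ibd.pair_likelihoods_given_ibd((1, 3), (1, 1), {1: 0.5, 2: 0.5})

    @pytest.mark.parametrize("n_alleles", [2, 3, 4])
    def test_exhaustive_oracle_agreement(self, n_alleles, rng):
        """Closed forms match parental enumeration for every unordered
        genotype pair at a random frequency vector."""
        raw = rng.dirichlet(np.ones(n_alleles))
        freqs = {i + 1: float(f) for i, f in enumerate(raw)}
        genos = unordered_genotypes(list(freqs))
        for g1 in genos:
            for g2 in genos:
                main = ibd.pair_likelihoods_given_ibd(g1, g2, freqs)
                orac = ibd_oracle(g1, g2, freqs)
                np.testing.assert_allclose(main, orac, atol=1e-12)

    @pytest.mark.parametrize("n_alleles", [2, 3])
    def test_likelihoods_normalise_over_genotype_pairs(self, n_alleles, rng):
        raw = rng.dirichlet(np.ones(n_alleles))
        freqs = {i + 1: float(f) for i, f in enumerate(raw)}
        genos = unordered_genotypes(list(freqs))
        totals = np.zeros(3)
        for g1 in genos:
            for g2 in genos:
                totals += ibd.pair_likelihoods_given_ibd(g1, g2, freqs)
        np.testing.assert_allclose(totals, [1.0, 1.0, 1.0], atol=1e-12)


class TestPosterior:
    def test_shared_heterozygote_posterior(self):
        f = {1: 0.5, 2: 0.5}
        post = ibd.ibd_posterior((1, 2), (1, 2), f)
        assert (post.f0, post.f1, post.f2) == pytest.approx((0.2, 0.4, 0.4))
        assert post.pihat == pytest.approx(0.6)
        assert post.expected_shared == pytest.approx(1.2)

    def test_monomorphic_posterior_is_prior(self):
        post = ibd.ibd_posterior((1, 1), (1, 1), {1: 1.0})
        assert (post.f0, post.f1, post.f2) == pytest.approx((0.25, 0.5, 0.25))
        assert post.pihat == pytest.approx(0.5)

    def test_zero_ibs_pair(self):
        post = ibd.ibd_posterior((1, 1), (2, 2), {1: 0.5, 2: 0.5})
        assert (post.f0, post.f1, post.f2) == (1.0, 0.0, 0.0)
        assert post.pihat == 0.0

    def test_impossible_genotypes_raise(self):
        # allele 2 has frequency zero -> all likelihoods vanish
        with pytest.raises(ibd.ImpossibleGenotypeError):
            ibd.ibd_posterior((2, 2), (1, 1), {1: 1.0, 2: 0.0})

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_swap_and_relabel_invariance(self, data):
        n_alleles = data.draw(st.integers(2, 4))
        weights = data.draw(st.lists(
            st.floats(0.05, 1.0), min_size=n_alleles, max_size=n_alleles))
        total = sum(weights)
        freqs = {i + 1: w / total for i, w in enumerate(weights)}
        alleles = list(freqs)
        g1 = tuple(sorted(data.draw(
            st.tuples(st.sampled_from(alleles), st.sampled_from(alleles)))))
        g2 = tuple(sorted(data.draw(
            st.tuples(st.sampled_from(alleles), st.sampled_from(alleles)))))
        post = ibd.ibd_posterior(g1, g2, freqs)
        swapped = ibd.ibd_posterior(g2, g1, freqs)
        assert (post.f0, post.f1, post.f2) == pytest.approx(
            (swapped.f0, swapped.f1, swapped.f2))
        # relabel allele codes by a shift
        shift = 10
        relabel = {a + shift: f for a, f in freqs.items()}
        post_rel = ibd.ibd_posterior(tuple(a + shift for a in g1),
                                     tuple(a + shift for a in g2), relabel)
        assert (post.f0, post.f1, post.f2) == pytest.approx(
            (post_rel.f0, post_rel.f1, post_rel.f2))


class TestSharingProfile:
    def test_profile_tracks_truth_and_mean_pihat(self, default_model,
                                                 linked_marker,
                                                 unlinked_marker):
        cohort = simulate_families(1000, default_model,
                                   [linked_marker, unlinked_marker], seed=22)
        freqs = ibd.estimate_allele_frequencies(cohort.offspring(),
                                                cohort.marker_map)
        pihats, truths = [], []
        for pair in cohort.sib_pairs:
            profile = ibd.pair_sharing_profile(pair, cohort.marker_map,
                                               freqs)
            assert len(profile) == 2
            pihats.append(profile[0].pihat)
            truths.append(pair.true_ibd_markers[0] / 2)
        pihats = np.asarray(pihats)
        # unselected pairs: mean pihat near 1/2
        assert abs(pihats.mean() - 0.5) < 3 * math.sqrt(0.125 / 1000)
        # posterior tracks the truth at a polymorphic marker
        assert np.corrcoef(pihats, truths)[0, 1] >= 0.8

    def test_masking_parents_leaves_posteriors_unchanged(self,
                                                         default_model,
                                                         linked_marker):
        """IBD estimation uses sib genotypes only, so posteriors are
        identical with or without parents in the cohort."""
        cohort = simulate_families(50, default_model, [linked_marker],
                                   seed=23)
        freqs = ibd.estimate_allele_frequencies(cohort.offspring(),
                                                cohort.marker_map)
        before = [ibd.pair_sharing_profile(p, cohort.marker_map, freqs)
                  for p in cohort.sib_pairs]
        masked = mask_parents(cohort)
        after = [ibd.pair_sharing_profile(p, masked.marker_map, freqs)
                 for p in masked.sib_pairs]
        for b, a in zip(before, after):
            assert b[0].pihat == a[0].pihat

    def test_missing_markers_flagged_uninformative(self, default_model,
                                                   linked_marker):
        cohort = simulate_families(5, default_model, [linked_marker],
                                   seed=24)
        pair = cohort.sib_pairs[0]
        pair.sib1.genotypes[0] = (0, 0)
        freqs = ibd.estimate_allele_frequencies(cohort.offspring(),
                                                cohort.marker_map)
        (post,) = ibd.pair_sharing_profile(pair, cohort.marker_map, freqs)
        assert post is None
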