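import itertools

import numpy as np
import pytest
from scipy import stats

import faebm
from faebm.exceptions import SchemaError, ValidationError
from faebm.mixtures import MixtureFit
from faebm.ordering import (
    EventOrdering,
    cross_validate,
    exhaustive_map,
    greedy_ascent,
    mcmc_sample,
    ordering_log_likelihood,
    positional_variance,
)
from conftest import flat_fits, make_cohort, separated_fits


def _fit_cohort(n_regions=5, seed=0, **kwargs):
    table, truth = make_cohort(n_regions=n_regions, seed=seed, **kwargs)
    fits, _ = faebm.fit_mixture_models(table, B=50, seed=seed)
    return table, truth, fits


class TestLogLikelihood:
    def test_single_region_single_patient_identity(self):
        """With one region and equal event/no-event densities g, the
        stage-marginalized likelihood is (g + g)/2 = g."""
        fit = MixtureFit(mu_h=0.5, sigma_h=0.05, mu_d=0.5, sigma_d=0.05, theta=0.5)
        x = np.array([[0.52]])
        ll = ordering_log_likelihood([0], x, [fit])
        g = stats.norm.pdf(0.52, 0.5, 0.05)
        assert np.isclose(ll, np.log(g))

    def test_symmetric_densities_make_all_orderings_equal(self):
        x = np.random.default_rng(0).normal(0.5, 0.05, (7, 4))
        fits = flat_fits(4)
        lls = {
            perm: ordering_log_likelihood(perm, x, fits)
            for perm in itertools.permutations(range(4))
        }
        assert np.ptp(list(lls.values())) < 1e-12

    def test_matches_brute_force_double_loop(self):
        """Against an independent brute-force sum over stages/patients in
        the probability domain."""
        rng = np.random.default_rng(3)
        x = rng.uniform(0.35, 0.65, (2, 3))
        fits = [
            MixtureFit(mu_h=0.55, sigma_h=0.03, mu_d=0.42, sigma_d=0.04, theta=0.5),
            MixtureFit(mu_h=0.50, sigma_h=0.02, mu_d=0.40, sigma_d=0.03, theta=0.5),
            MixtureFit(mu_h=0.60, sigma_h=0.04, mu_d=0.45, sigma_d=0.02, theta=0.5),
        ]
        for seq in itertools.permutations(range(3)):
            expected = 0.0
            for j in range(2):
                patient_lik = 0.0
                for k in range(4):
                    term = 1.0
                    for pos, region in enumerate(seq):
                        f = fits[region]
                        if pos < k:
                            term *= stats.norm.pdf(x[j, region], f.mu_d, f.sigma_d)
                        else:
                            term *= stats.norm.pdf(x[j, region], f.mu_h, f.sigma_h)
                    patient_lik += term / 4
                expected += np.log(patient_lik)
            assert np.isclose(ordering_log_likelihood(seq, x, fits), expected)

    def test_invariant_to_patient_row_order(self):
        x = np.random.default_rng(5).uniform(0.4, 0.6, (20, 4))
        fits = separated_fits(4)
        seq = (2, 0, 3, 1)
        ll = ordering_log_likelihood(seq, x, fits)
        shuffled = x[np.random.default_rng(1).permutation(20)]
        assert np.isclose(ordering_log_likelihood(seq, shuffled, fits), ll, atol=1e-10)

    def test_permutation_equivariance(self):
        """Relabeling regions and applying the same relabeling to the
        ordering leaves the likelihood unchanged."""
        x = np.random.default_rng(6).uniform(0.4, 0.6, (10, 5))
        fits = [
            MixtureFit(mu_h=0.5 + 0.01 * i, sigma_h=0.02, mu_d=0.42, sigma_d=0.03, theta=0.5)
            for i in range(5)
        ]
        seq = np.array([3, 1, 4, 0, 2])
        relabel = np.array([2, 0, 4, 1, 3])  # new index of each old region
        x2 = np.empty_like(x)
        fits2: list = [None] * 5
        for old in range(5):
            x2[:, relabel[old]] = x[:, old]
            fits2[relabel[old]] = fits[old]
        seq2 = relabel[seq]
        assert np.isclose(
            ordering_log_likelihood(seq, x, fits),
            ordering_log_likelihood(seq2, x2, fits2),
            atol=1e-12,
        )

    def test_control_rows_rejected(self):
        table, _, fits = _fit_cohort(n_regions=3, n_patients=10, n_controls=10)
        with pytest.raises(ValidationError):
            ordering_log_likelihood([0, 1, 2], table, fits)
        ll = ordering_log_likelihood([0, 1, 2], table.patients(), fits)
        assert np.isfinite(ll)

    def test_region_mismatch_is_schema_error(self):
        x = np.random.default_rng(0).uniform(0.4, 0.6, (5, 4))
        with pytest.raises(SchemaError):
            ordering_log_likelihood([0, 1, 2], x, separated_fits(4))


class TestGreedyAscent:
    def test_single_region_trivial(self):
        x = np.array([[0.5], [0.52]])
        assert greedy_ascent(x, separated_fits(1), restarts=1).sequence == (0,)

    def test_equals_exhaustive_argmax(self):
        table, _, fits = _fit_cohort(n_regions=4, seed=2)
        patients = table.patients()
        best = exhaustive_map(patients, fits)
        found = greedy_ascent(patients, fits, restarts=5, seed=0)
        assert found.sequence == best.sequence

    def test_terminates_on_symmetric_data(self):
        x = np.random.default_rng(1).normal(0.5, 0.05, (10, 5))
        result = greedy_ascent(x, flat_fits(5), restarts=2, seed=3)
        assert sorted(result.sequence) == list(range(5))


class TestMCMC:
    def test_single_region_chain(self):
        x = np.array([[0.5], [0.52]])
        post = mcmc_sample(x, separated_fits(1), n_iter=50, burn_in=10, seed=0)
        assert np.all(post.samples == 0)
        assert post.acceptance_rate == 1.0

    def test_uniform_target_positional_distribution(self):
        """All densities equal: the posterior over orderings is uniform,
        so each event should occupy each position with frequency 1/N."""
        n = 5
        x = np.random.default_rng(2).normal(0.5, 0.05, (20, n))
        post = mcmc_sample(x, flat_fits(n), n_iter=30_000, burn_in=2_000, seed=4)
        pvd = positional_variance(post, reference=EventOrdering.identity(n))
        # batch-means Monte-Carlo standard error per cell
        nb = 50
        m = post.samples.shape[0] // nb
        for event in range(n):
            pos = np.argmax(post.samples[: nb * m] == event, axis=1)
            for p in range(n):
                batches = (pos.reshape(nb, m) == p).mean(axis=1)
                se = batches.std(ddof=1) / np.sqrt(nb)
                assert abs(pvd.matrix[event, p] - 1 / n) < 3 * max(se, 1e-3)

    def test_map_equals_exhaustive_argmax(self):
        table, _, fits = _fit_cohort(n_regions=5, seed=7, n_patients=200)
        patients = table.patients()
        best = exhaustive_map(patients, fits)
        init = greedy_ascent(patients, fits, restarts=5, seed=7)
        post = mcmc_sample(patients, fits, init=init, n_iter=5_000, burn_in=500, seed=7)
        assert post.map_ordering.sequence == best.sequence
        assert post.map_log_likelihood >= post.log_likelihoods.max() - 1e-9

    def test_reproducible_from_seed(self):
        x = np.random.default_rng(3).normal(0.5, 0.05, (10, 4))
        fits = separated_fits(4)
        a = mcmc_sample(x, fits, n_iter=500, burn_in=100, seed=9)
        b = mcmc_sample(x, fits, n_iter=500, burn_in=100, seed=9)
        assert np.array_equal(a.samples, b.samples)


class TestPositionalVariance:
    def test_point_mass_gives_identity(self):
        samples = np.tile([2, 0, 1], (40, 1))
        pvd = positional_variance(samples, reference=[2, 0, 1])
        assert np.allclose(pvd.matrix, np.eye(3))

    def test_single_swap_half_mass(self):
        samples = np.array([[0, 1, 2]] * 5 + [[0, 2, 1]] * 5)
        pvd = positional_variance(samples, reference=[0, 1, 2])
        expected = np.array([[1, 0, 0], [0, 0.5, 0.5], [0, 0.5, 0.5]])
        assert np.allclose(pvd.matrix, expected)

    def test_doubly_stochastic_for_random_samples(self):
        rng = np.random.default_rng(11)
        samples = np.array([rng.permutation(6) for _ in range(137)])
        pvd = positional_variance(samples)
        assert np.allclose(pvd.matrix.sum(axis=0), 1.0, atol=1e-12)
        assert np.allclose(pvd.matrix.sum(axis=1), 1.0, atol=1e-12)

    def test_non_permutation_sample_rejected(self):
        with pytest.raises(SchemaError):
            positional_variance(np.array([[0, 0, 1]]))

    def test_row_labels_follow_reference(self):
        samples = np.tile([1, 0], (3, 1))
        pvd = positional_variance(samples, reference=[1, 0], labels=["A", "B"])
        assert pvd.row_labels == ("B", "A")


class TestCrossValidation:
    def test_stable_cohort_gives_permutation_matrix(self):
        table, truth = make_cohort(
            n_regions=4, effect_sds=5.0, n_patients=200, n_controls=150, seed=5
        )
        result = cross_validate(table, B=20, seed=5, restarts=3)
        # strong separation: every replicate recovers the same ordering
        assert np.allclose(np.sort(result.pvd.matrix.ravel()),
                           np.concatenate([np.zeros(12), np.ones(4)]))
        assert result.n_failed == 0

    def test_requires_both_groups(self):
        table, _ = make_cohort(n_regions=3, n_patients=10, n_controls=0)
        with pytest.raises(ValidationError):
            cross_validate(table.patients(), B=2, seed=0)

    def test_default_replicate_count(self):
        import inspect

        assert inspect.signature(cross_validate).parameters["B"].default == 10_000
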