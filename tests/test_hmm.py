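import itertools

import numpy as np
import pytest
from scipy.stats import norm

from metaprog.dataio import AnalysisConfig, log2_transform, to_visit_matrix
from metaprog.hmm import (
    ProgressionHMM,
    align_states,
    bootstrap_fit,
    fit_baum_welch,
    fit_baum_welch_sequences,
    forward_loglik,
    left_to_right_mask,
    occupancy_by_age,
    permute_states,
    posterior_decode,
    state_difference_profile,
    viterbi_decode,
)
from metaprog.synthetic_data import GeneratorSpec, default_truth, simulate_cohort

from conftest import separated_truth


def brute_force_loglik(model: ProgressionHMM, X: np.ndarray) -> float:
    """Oracle: sum the sequence probability over every possible state path."""
    T = len(X)
    total = 0.0
    for path in itertools.product(range(model.K), repeat=T):
        p = model.pi[path[0]]
        for t in range(1, T):
            p *= model.A[path[t - 1], path[t]]
        if p == 0.0:
            continue
        for t, k in enumerate(path):
            p *= np.prod(
                norm.pdf(X[t], model.means[k], np.sqrt(model.variances[k]))
            )
        total += p
    return float(np.log(total))


def toy_model(K=3, d=1) -> ProgressionHMM:
    rng = np.random.default_rng(0)
    A = np.zeros((K, K))
    for k in range(K - 1):
        A[k, k], A[k, k + 1] = 0.7, 0.3
    A[K - 1, K - 1] = 1.0
    pi = np.zeros(K)
    pi[0] = 1.0
    return ProgressionHMM(
        pi, A, rng.normal(0, 2, (K, d)), rng.uniform(0.5, 2.0, (K, d))
    )


class TestForwardLikelihood:
    def test_matches_exhaustive_enumeration(self):
        model = toy_model(K=3, d=1)
        rng = np.random.default_rng(1)
        for T in (1, 2, 4, 5):
            X = rng.normal(0, 2, (T, 1))
            assert forward_loglik(model, X) == pytest.approx(
                brute_force_loglik(model, X), abs=1e-10
            )

    def test_k1_equals_sum_of_gaussian_logpdfs(self):
        model = ProgressionHMM([1.0], [[1.0]], [[0.5, -1.0]], [[1.0, 2.0]])
        X = np.array([[0.1, 0.2], [1.0, -2.0], [0.0, 0.0]])
        expected = norm.logpdf(X, model.means[0], np.sqrt(model.variances[0])).sum()
        assert forward_loglik(model, X) == pytest.approx(expected, abs=1e-10)

    def test_single_visit_closed_form(self):
        model = toy_model(K=3, d=2)
        model.pi = np.array([0.5, 0.3, 0.2])
        x = np.array([[0.3, -0.4]])
        dens = [
            model.pi[k]
            * np.prod(norm.pdf(x[0], model.means[k], np.sqrt(model.variances[k])))
            for k in range(3)
        ]
        assert forward_loglik(model, x) == pytest.approx(np.log(sum(dens)), abs=1e-10)

    def test_dimension_mismatch_rejected(self):
        model = toy_model(K=2, d=3)
        with pytest.raises(ValueError):
            forward_loglik(model, np.zeros((4, 2)))


class TestPosteriorAndViterbi:
    def test_posterior_rows_sum_to_one(self):
        model = toy_model(K=3, d=2)
        X = np.random.default_rng(2).normal(0, 2, (8, 2))
        gamma = posterior_decode(model, X)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-12)

    def test_posterior_k1_all_ones(self):
        model = ProgressionHMM([1.0], [[1.0]], [[0.0]], [[1.0]])
        gamma = posterior_decode(model, np.zeros((5, 1)))
        assert np.allclose(gamma, 1.0)

    def test_viterbi_never_decreases(self):
        model = toy_model(K=3, d=2)
        rng = np.random.default_rng(3)
        for _ in range(10):
            path = viterbi_decode(model, rng.normal(0, 3, (12, 2)))
            assert np.all(np.diff(path) >= 0)

    def test_viterbi_tie_breaks_to_lower_state(self):
        # identical emissions, equal stay/advance probability: [0,0] and [0,1]
        # have the same likelihood, so the lower-state path must be returned
        model = ProgressionHMM(
            [1.0, 0.0], [[0.5, 0.5], [0.0, 1.0]], [[0.0], [0.0]], [[1.0], [1.0]]
        )
        path = viterbi_decode(model, np.zeros((2, 1)))
        assert list(path) == [0, 0]

    def test_zero_noise_recovery(self, planted_cohort):
        spec, dataset, paths = planted_cohort
        truth = spec.truth()["progressor"]
        work = log2_transform(dataset)
        for ind in dataset.individuals_in_group("progressor")[:5]:
            _, X = to_visit_matrix(work, ind)
            gamma = posterior_decode(truth, X)
            assert np.mean(np.argmax(gamma, axis=1) == paths[ind]) > 0.95
            assert np.mean(viterbi_decode(truth, X) == paths[ind]) > 0.95


class TestBaumWelch:
    def test_k1_collapses_to_gaussian_mle(self, planted_cohort):
        _, dataset, _ = planted_cohort
        sub = dataset.subset(dataset.individuals[:4])
        fit = fit_baum_welch(sub, AnalysisConfig(n_states=1))
        work = log2_transform(sub)
        stacked = np.vstack(
            [to_visit_matrix(work, i)[1] for i in sub.individuals]
        )
        assert np.allclose(fit.model.means[0], stacked.mean(axis=0), atol=1e-8)
        assert np.allclose(fit.model.variances[0], stacked.var(axis=0), rtol=1e-6)

    def test_loglik_trace_non_decreasing(self, planted_cohort):
        _, dataset, _ = planted_cohort
        fit = fit_baum_welch(dataset.subset(dataset.individuals[:10]))
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-8 * np.abs(fit.loglik_trace[:-1]))

    def test_structural_zeros_exact(self, planted_cohort):
        _, dataset, _ = planted_cohort
        fit = fit_baum_welch(dataset.subset(dataset.individuals[:8]))
        A = fit.model.A
        assert np.all(A[~left_to_right_mask(3)] == 0.0)
        assert np.allclose(A.sum(axis=1), 1.0)

    def test_recovers_planted_parameters(self, planted_cohort, planted_fits):
        spec, dataset, paths = planted_cohort
        truth = spec.truth()
        for group in ("progressor", "non-progressor"):
            sub = dataset.subset(dataset.individuals_in_group(group))
            fit = planted_fits[group]
            perm = align_states(fit.model, truth[group])
            aligned = permute_states(fit.model, perm)
            rel = np.abs(aligned.means - truth[group].means) / np.abs(
                truth[group].means
            )
            assert rel.max() < 0.10
            inv = np.empty(3, dtype=int)
            inv[perm] = np.arange(3)
            work = log2_transform(sub)
            correct = total = 0
            for ind in sub.individuals:
                _, X = to_visit_matrix(work, ind)
                decoded = inv[viterbi_decode(fit.model, X)]
                correct += int(np.sum(decoded == paths[ind]))
                total += len(decoded)
            assert correct / total >= 0.90

    def test_too_many_states_rejected(self, toy_dataset):
        with pytest.raises(ValueError, match="n_states"):
            fit_baum_welch(toy_dataset, AnalysisConfig(n_states=5))

    def test_zero_noise_exact_mean_recovery(self):
        truth = {
            g: default_truth(4, 3, g, noise_sd=0.0, state_step=2.0)
            for g in ("progressor", "non-progressor")
        }
        spec = GeneratorSpec(
            n_progressors=8,
            n_nonprogressors=8,
            ages=np.arange(3.0, 18.0),
            n_metabolites=4,
            hmm_truth=truth,
            dropout_hazard=0.0,
            noise_sd=0.0,
            seed=6,
        )
        dataset, _ = simulate_cohort(spec)
        sub = dataset.subset(dataset.individuals_in_group("progressor"))
        fit = fit_baum_welch(sub)
        perm = align_states(fit.model, truth["progressor"])
        aligned = permute_states(fit.model, perm)
        assert np.allclose(aligned.means, truth["progressor"].means, atol=1e-6)


class TestOccupancy:
    def test_rows_sum_to_one(self, planted_cohort, planted_fits):
        _, dataset, _ = planted_cohort
        sub = dataset.subset(dataset.individuals_in_group("progressor"))
        occ = occupancy_by_age(planted_fits["progressor"], sub)
        assert np.allclose(np.nansum(occ.P, axis=1), 1.0, atol=1e-9)

    def test_k1_occupancy_is_one(self, planted_cohort):
        _, dataset, _ = planted_cohort
        sub = dataset.subset(dataset.individuals[:4])
        fit = fit_baum_welch(sub, AnalysisConfig(n_states=1))
        occ = occupancy_by_age(fit, sub)
        assert np.allclose(occ.P, 1.0)

    def test_modal_state_progresses_in_order(self):
        # cohort large enough that the average occupancy approximates its
        # expectation; mean dwell ~3 weeks per state on the weekly grid
        noise = 0.25
        truth = {
            g: default_truth(5, 3, g, noise_sd=noise, state_step=1.0)
            for g in ("progressor", "non-progressor")
        }
        spec = GeneratorSpec(
            n_progressors=2,
            n_nonprogressors=60,
            ages=np.arange(3.0, 33.0),
            n_metabolites=5,
            hmm_truth=truth,
            dropout_hazard=0.0,
            noise_sd=noise,
            seed=3,
        )
        dataset, _ = simulate_cohort(spec)
        sub = dataset.subset(dataset.individuals_in_group("non-progressor"))
        fit = fit_baum_welch(sub)
        perm = align_states(fit.model, truth["non-progressor"])
        inv = np.empty(3, dtype=int)
        inv[perm] = np.arange(3)
        occ = occupancy_by_age(fit, sub)
        modal = inv[np.nanargmax(occ.P, axis=1)]
        assert np.all(np.diff(modal) >= 0)
        assert modal[0] == 0 and modal[-1] == 2

    def test_empty_bin_flagged_nan(self, planted_cohort):
        _, dataset, _ = planted_cohort
        sub = dataset.subset(dataset.individuals[:4])
        fit = fit_baum_welch(sub)
        occ = occupancy_by_age(fit, sub, age_bins=np.array([5.0, 100.0]))
        # bin at age 100 attracts no visit (all ages <= 32 map to bin 5)
        assert not np.any(np.isnan(occ.P[0]))


class TestBootstrap:
    def test_identity_resample_returns_point_estimate(self, planted_cohort):
        _, dataset, _ = planted_cohort
        sub = dataset.subset(dataset.individuals[:6])
        config = AnalysisConfig(bootstrap_n=1)
        fit = fit_baum_welch(sub)

        class IdentityRng:
            def integers(self, lo, hi, size):
                return np.arange(size)

        import metaprog.hmm as hmm_mod

        orig = np.random.default_rng
        np.random.default_rng = lambda *_: IdentityRng()
        try:
            models, dropped = bootstrap_fit(sub, config, reference=fit, bootstrap_n=1)
        finally:
            np.random.default_rng = orig
        assert dropped == 0
        # at an EM fixed point, refitting the same sample changes nothing
        assert np.allclose(models[0].means, fit.model.means, atol=1e-4)

    def test_replicates_plus_dropped_conserved(self, planted_cohort):
        _, dataset, _ = planted_cohort
        sub = dataset.subset(dataset.individuals[:8])
        config = AnalysisConfig(bootstrap_n=5, seed=0)
        models, dropped = bootstrap_fit(sub, config, bootstrap_n=5, max_iter=20)
        assert len(models) + dropped == 5

    def test_difference_bands_reproducible_and_flag_planted_shift(self):
        noise = 1.0 / 3.0
        truth = separated_truth(6, noise)
        # plant a clear state-1 decrease in the progressor group
        truth["progressor"].means[0, :2] -= 1.0
        spec = GeneratorSpec(
            n_progressors=15,
            n_nonprogressors=15,
            ages=np.arange(3.0, 28.0),
            n_metabolites=6,
            hmm_truth=truth,
            dropout_hazard=0.0,
            noise_sd=noise,
            seed=13,
        )
        dataset, _ = simulate_cohort(spec)
        config = AnalysisConfig(seed=1)
        table = state_difference_profile(dataset, config, bootstrap_n=60, seed=5)
        again = state_difference_profile(dataset, config, bootstrap_n=60, seed=5)
        assert np.array_equal(table.labels, again.labels)
        assert np.allclose(table.difference, again.difference)
        # the two shifted metabolites in state 1 are flagged as negative
        assert np.all(table.labels[0, :2] != "ns")
        assert np.all(table.upper90[0, :2] < 0)
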