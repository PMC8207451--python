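"""CJS likelihood, analytic cell probabilities, and the ML fitter."""

import numpy as np
import pytest

from pairbond_cjs import (
    ALL_STRUCTURES,
    HistoryCounts,
    ModelStructure,
    SimulationConfig,
    expected_history_probabilities,
    fit_cjs,
    history_probability,
    negative_log_likelihood,
    observable_histories,
    saturated_log_likelihood,
    simulate_dataset,
    structure_from_name,
)
from scipy.special import logit

# Reference cell probabilities for phi=0.7, p=0.8, T=4 (3 decimals).
REFERENCE_CELLS = {
    "1000": 0.351,
    "1001": 0.011,
    "1010": 0.034,
    "1011": 0.044,
    "1100": 0.202,
    "1101": 0.044,
    "1110": 0.138,
    "1111": 0.176,
}


def _counts_from_probs(phi, p, T, scale, groups=("F", "M")):
    probs = expected_history_probabilities(phi, p, T)
    vec = np.array(list(probs.values())) * scale
    return HistoryCounts(T, {g: vec.copy() for g in groups})


class TestHistoryProbability:
    @pytest.mark.parametrize("history, expected", sorted(REFERENCE_CELLS.items()))
    def test_reference_values(self, history, expected):
        assert round(history_probability(history, 0.7, 0.8), 3) == expected

    def test_certain_survival_and_capture(self):
        assert history_probability("1111", 1.0, 1.0) == 1.0

    def test_history_must_start_with_release(self):
        with pytest.raises(ValueError, match="begin with 1"):
            history_probability("0110", 0.7, 0.8)

    @pytest.mark.parametrize("phi, p, T", [(0.7, 0.8, 4), (0.3, 0.5, 5), (0.9, 0.2, 3)])
    def test_cells_sum_to_one(self, phi, p, T):
        probs = expected_history_probabilities(phi, p, T)
        assert len(probs) == 2 ** (T - 1)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_expected_counts_scale(self):
        probs = expected_history_probabilities(0.7, 0.8, 4)
        assert round(200 * probs["1110"], 1) == 27.6
        assert round(100 * probs["1001"], 1) == 1.1


class TestNegativeLogLikelihood:
    def test_single_history_matches_cell_probability(self):
        counts = HistoryCounts(4, {"F": [0, 0, 0, 0, 1, 0, 0, 0]})  # one 1100
        theta = np.array([logit(0.7), logit(0.8)])
        nll = negative_log_likelihood(theta, counts, ModelStructure(False, False))
        assert nll == pytest.approx(-np.log(history_probability("1100", 0.7, 0.8)))

    def test_linear_in_counts(self, small_null_counts):
        structure = ModelStructure(True, True)
        theta = np.array([logit(0.6), logit(0.7), logit(0.8), logit(0.9)])
        single = negative_log_likelihood(theta, small_null_counts, structure)
        doubled = HistoryCounts(
            4, {g: 2 * v for g, v in small_null_counts.counts.items()}
        )
        assert negative_log_likelihood(theta, doubled, structure) == pytest.approx(
            2 * single
        )

    def test_pooled_equals_sex_specific_at_equal_parameters(self, small_null_counts):
        pooled = negative_log_likelihood(
            [logit(0.7), logit(0.8)], small_null_counts, ModelStructure(False, False)
        )
        sex_specific = negative_log_likelihood(
            [logit(0.7), logit(0.7), logit(0.8), logit(0.8)],
            small_null_counts,
            ModelStructure(True, True),
        )
        assert sex_specific == pytest.approx(pooled, abs=1e-10)


class TestSaturatedLogLikelihood:
    def test_point_mass_is_zero(self):
        counts = HistoryCounts(4, {"F": [0, 0, 0, 0, 0, 0, 0, 5]})
        assert saturated_log_likelihood(counts) == 0.0

    def test_uniform_closed_form(self):
        counts = HistoryCounts(4, {"M": [3] * 8})
        assert saturated_log_likelihood(counts) == pytest.approx(24 * np.log(1 / 8))

    def test_dominates_every_fitted_structure(self):
        for seed in range(10):
            data = simulate_dataset(SimulationConfig(n=80, seed=100 + seed))
            counts = HistoryCounts.from_dataset(data)
            sat = saturated_log_likelihood(counts)
            for structure in ALL_STRUCTURES:
                assert fit_cjs(counts, structure).log_lik <= sat + 1e-8


@pytest.fixture(scope="module")
def pooled_grid_oracle():
    """Dense (phi, p) grid of pooled-model log cell probabilities.

    Step 1e-3 over (0,1)^2; independent of the quasi-Newton path.
    """
    from pairbond_cjs.cjs import _cell_logprobs

    axis = np.arange(0.001, 1.0, 0.001)
    phi = axis[:, None]
    p = axis[None, :]
    T = 4
    chi = [None] * (T + 1)
    chi[T] = np.ones_like(phi * p)
    for t in range(T - 1, 0, -1):
        chi[t] = (1 - phi) + phi * (1 - p) * chi[t + 1]
    logs = []
    for h in observable_histories(T):
        x = [int(c) for c in h]
        last = max(i for i, v in enumerate(x) if v) + 1
        caps = sum(x[1:last])
        logs.append(
            (last - 1) * np.log(phi)
            + caps * np.log(p)
            + (last - 1 - caps) * np.log(1 - p)
            + np.log(chi[last])
        )
    return axis, np.array(logs)


class TestFitCJS:
    def test_recovers_generating_parameters_from_expected_counts(self):
        counts = _counts_from_probs(0.7, 0.8, 4, scale=1000.0)
        fit = fit_cjs(counts, ModelStructure(False, False))
        assert fit.converged
        assert fit.estimates["phi"] == pytest.approx(0.7, abs=5e-4)
        assert fit.estimates["p"] == pytest.approx(0.8, abs=5e-4)
        assert fit.deviance == pytest.approx(0.0, abs=1e-6)

    def test_sex_specific_recovery(self):
        probs_f = expected_history_probabilities(0.6, 0.9, 4)
        probs_m = expected_history_probabilities(0.8, 0.7, 4)
        counts = HistoryCounts(
            4,
            {
                "F": np.array(list(probs_f.values())) * 500,
                "M": np.array(list(probs_m.values())) * 500,
            },
        )
        fit = fit_cjs(counts, ModelStructure(True, True))
        assert fit.estimates["phi_f"] == pytest.approx(0.6, abs=1e-3)
        assert fit.estimates["phi_m"] == pytest.approx(0.8, abs=1e-3)
        assert fit.estimates["p_f"] == pytest.approx(0.9, abs=1e-3)
        assert fit.estimates["p_m"] == pytest.approx(0.7, abs=1e-3)

    def test_degenerate_data_hits_boundary(self):
        counts = HistoryCounts(4, {"F": [0, 0, 0, 0, 0, 0, 0, 40]})
        fit = fit_cjs(counts, ModelStructure(False, False))
        assert fit.boundary
        assert fit.estimates["phi"] > 0.999
        assert fit.estimates["p"] > 0.999

    def test_matches_grid_search_oracle(self, pooled_grid_oracle):
        """MLE location agrees with a dense grid search within 2e-3."""
        axis, logs = pooled_grid_oracle
        for seed in range(20):
            rng = np.random.default_rng(seed)
            phi_true = rng.uniform(0.3, 0.9)
            p_true = rng.uniform(0.3, 0.9)
            data = simulate_dataset(
                SimulationConfig(
                    n=50, phi_f=phi_true, phi_m=phi_true, p_f=p_true, p_m=p_true,
                    seed=1000 + seed,
                )
            )
            counts = HistoryCounts.from_dataset(data)
            fit = fit_cjs(counts, ModelStructure(False, False))
            nll_grid = -np.tensordot(counts.pooled(), logs, axes=([0], [0]))
            i, j = np.unravel_index(np.argmin(nll_grid), nll_grid.shape)
            assert fit.estimates["phi"] == pytest.approx(axis[i], abs=2e-3)
            assert fit.estimates["p"] == pytest.approx(axis[j], abs=2e-3)

    def test_interval_contains_estimate(self, small_null_counts):
        fit = fit_cjs(small_null_counts, ModelStructure(True, True))
        for name in fit.structure.parameter_names:
            assert fit.ci_lower[name] <= fit.estimates[name] <= fit.ci_upper[name]

    def test_deviance_additivity_for_shared_saturated_reference(
        self, small_null_counts
    ):
        """Nested sex-grouped fits: deviance gap equals the LRT statistic."""
        general = fit_cjs(small_null_counts, ModelStructure(True, True))
        reduced = fit_cjs(small_null_counts, ModelStructure(True, False))
        g2 = 2 * (general.log_lik - reduced.log_lik)
        assert reduced.deviance - general.deviance == pytest.approx(g2, abs=1e-6)

    def test_df_bookkeeping(self, small_null_counts):
        """df = observed saturated cells - parameters; pooled model pools sexes."""
        observed_per_group = {
            g: int((v > 0).sum()) for g, v in small_null_counts.counts.items()
        }
        pooled_observed = int((small_null_counts.pooled() > 0).sum())
        fit_pooled = fit_cjs(small_null_counts, ModelStructure(False, False))
        assert fit_pooled.df_deviance == pooled_observed - 1 - 2
        fit_full = fit_cjs(small_null_counts, ModelStructure(True, True))
        assert fit_full.df_deviance == sum(
            v - 1 for v in observed_per_group.values()
        ) - 4

    def test_sex_structure_requires_both_sexes(self):
        counts = HistoryCounts(4, {"F": [5, 1, 1, 1, 4, 1, 2, 3]})
        with pytest.raises(ValueError, match="both sexes"):
            fit_cjs(counts, ModelStructure(True, False))

    def test_mean_estimates_unbiased_under_null(self):
        """Light parameter-recovery check across independent replicates."""
        from pairbond_cjs import simulate_replicates

        config = SimulationConfig(n_replicates=150, seed=77)
        phis, ps = [], []
        for data in simulate_replicates(config):
            fit = fit_cjs(HistoryCounts.from_dataset(data), ModelStructure(False, False))
            phis.append(fit.estimates["phi"])
            ps.append(fit.estimates["p"])
        for values, truth in ((np.array(phis), 0.7), (np.array(ps), 0.8)):
            se = values.std(ddof=1) / np.sqrt(values.size)
            assert abs(values.mean() - truth) < 3 * se


class TestModelStructure:
    def test_four_structures(self):
        assert {s.name for s in ALL_STRUCTURES} == {
            "(phi,p)", "(phiG,p)", "(phi,pG)", "(phiG,pG)",
        }

    def test_nesting(self):
        pooled = structure_from_name("(phi,p)")
        full = structure_from_name("(phiG,pG)")
        assert pooled.is_nested_in(full)
        assert not full.is_nested_in(pooled)
        assert not structure_from_name("(phiG,p)").is_nested_in(
            structure_from_name("(phi,pG)")
        )

    def test_parameter_counts(self):
        assert [s.n_parameters for s in ALL_STRUCTURES] == [2, 3, 3, 4]

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            structure_from_name("(phi,pT)")
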