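import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isosim.isoform_choice import (
    CHOICE_MODELS,
    ChoiceModelSpec,
    ChoiceProbabilities,
    GeneChoiceContext,
    beta_params_from_moments,
    cell_choice_probs,
    choose_isoforms,
    choose_isoforms_many,
    inferred_choice_prob,
    weibull_choice_probs,
    weibull_median_frequencies,
)


class TestWeibullChoiceProbs:
    def test_single_isoform(self):
        assert weibull_choice_probs(1) == pytest.approx([1.0])

    def test_reference_four_isoform_vector(self):
        assert np.round(weibull_choice_probs(4), 2).tolist() == [0.55, 0.28, 0.12, 0.05]

    def test_two_isoform_vector(self):
        # by hand: normalize exp(-2.25), exp(-4)
        assert np.round(weibull_choice_probs(2), 3).tolist() == [0.852, 0.148]

    def test_rank_factor_variant(self):
        # median-frequency form keeps its 1/k factor and self-normalizes differently
        assert np.round(weibull_choice_probs(4, include_rank_factor=True), 3).tolist() == [
            0.742, 0.187, 0.055, 0.016]
        mf, H = weibull_median_frequencies(4)
        assert H > 0 and np.all(mf > 0)
        assert np.allclose(mf / mf.sum(), weibull_choice_probs(4, include_rank_factor=True))

    @pytest.mark.parametrize("M", range(2, 12))
    def test_strictly_decreasing_and_normalized(self, M):
        p = weibull_choice_probs(M)
        assert np.all(np.diff(p) < 0)
        assert p.sum() == pytest.approx(1.0)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            weibull_choice_probs(0)


class TestInferredChoiceProb:
    def test_error_free_limit(self):
        assert inferred_choice_prob(0.3, 1.0, 0.0, 0.0) == pytest.approx(0.3)

    def test_hand_evaluation(self):
        # |0.5 - 0.01| / |0.7*0.96 - 0.01| = 0.49 / 0.662
        assert inferred_choice_prob(0.5, 0.7, 0.01, 0.04) == pytest.approx(0.49 / 0.662)

    def test_clamped_to_one(self):
        assert inferred_choice_prob(0.9, 0.5, 0.01, 0.04) == 1.0

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            inferred_choice_prob(0.5, 0.0, 0.0, 0.04)


class TestBetaParamsFromMoments:
    def test_symmetric_case(self):
        assert beta_params_from_moments(0.5, np.sqrt(0.05)) == pytest.approx((2.0, 2.0))

    @given(
        mu=st.floats(0.05, 0.95),
        frac=st.floats(0.05, 0.9),
    )
    @settings(max_examples=100, derandomize=True)
    def test_mean_identity(self, mu, frac):
        """Feasible moments reproduce the beta mean alpha/(alpha+beta) = mu."""
        sigma = frac * np.sqrt(mu * (1 - mu))
        params = beta_params_from_moments(mu, sigma)
        assert params is not None
        a, b = params
        assert a / (a + b) == pytest.approx(mu, rel=1e-9)

    def test_infeasible_moments_fall_back(self):
        assert beta_params_from_moments(0.5, 0.6) is None

    def test_invalid_mu(self):
        with pytest.raises(ValueError):
            beta_params_from_moments(0.0, 0.1)


class TestCellChoiceProbs:
    def test_constant_model(self, interior_gene):
        gene, stats, dropout = interior_gene
        probs = cell_choice_probs(ChoiceModelSpec(model="constant"), gene,
                                  rng=np.random.default_rng(0))
        assert probs.p == pytest.approx([0.25] * 4)
        assert probs.scope == "gene"

    def test_bernoulli_all_zero_weights_fall_back(self, interior_gene):
        gene, *_ = interior_gene
        spec = ChoiceModelSpec(model="bernoulli", bernoulli_p=0.0)
        probs = cell_choice_probs(spec, gene, rng=np.random.default_rng(0))
        assert probs.p == pytest.approx([0.25] * 4)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown choice model"):
            ChoiceModelSpec(model="uniformish")

    @pytest.mark.parametrize("model", CHOICE_MODELS)
    def test_vectors_are_probability_vectors(self, model, interior_gene):
        gene, stats, dropout = interior_gene
        rng = np.random.default_rng(1)
        ctx = GeneChoiceContext(ChoiceModelSpec(model=model), gene, stats, dropout, rng=rng)
        P = ctx.cell_probs(rng, 200)
        assert np.all(P >= 0)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_cell_variability_converges_to_inferred(self, interior_gene):
        """As sigma -> 0 the per-cell vectors collapse onto the inferred model's."""
        gene, stats, dropout = interior_gene
        rng = np.random.default_rng(2)
        inferred = GeneChoiceContext(
            ChoiceModelSpec(model="inferred"), gene, stats, dropout, rng=rng
        ).cell_probs(rng, 1)[0]
        tvs = []
        for sigma in (0.05, 0.01, 0.002):
            ctx = GeneChoiceContext(
                ChoiceModelSpec(model="cell_variability", sigma=sigma),
                gene, stats, dropout, rng=rng,
            )
            P = ctx.cell_probs(rng, 2000)
            tvs.append(0.5 * np.abs(P - inferred).sum(axis=1).mean())
        assert tvs[0] > tvs[-1]
        assert tvs[-1] < 0.005

    @pytest.mark.parametrize("model", ["normal", "bernoulli", "constant"])
    def test_mean_choice_probability_quarter(self, model, interior_gene):
        """The three simple models share per-isoform mean probability 0.25."""
        gene, *_ = interior_gene
        rng = np.random.default_rng(3)
        ctx = GeneChoiceContext(ChoiceModelSpec(model=model), gene, rng=rng)
        n = 10_000
        means = ctx.cell_probs(rng, n).mean(axis=0)
        # normalization within cells correlates entries; 3 x binomial-style SE
        # of the raw weights is a conservative envelope for all three models
        se = 3 * np.sqrt(0.25 * 0.75 / n)
        assert np.all(np.abs(means - 0.25) <= max(se, 0.01))


class TestChooseIsoforms:
    def test_exhaustive_draw(self, interior_gene):
        gene, stats, dropout = interior_gene
        probs = ChoiceProbabilities("G1", gene.isoforms, np.array([0.7, 0.1, 0.1, 0.1]), "gene")
        chosen = choose_isoforms(probs, 4, np.random.default_rng(0))
        assert chosen == set(gene.isoforms)

    def test_degenerate_distribution(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert choose_isoforms([1.0, 0.0, 0.0, 0.0], 1, rng) == {0}

    def test_zero_probability_only_after_positive_exhausted(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            chosen = choose_isoforms([0.5, 0.5, 0.0, 0.0], 3, rng)
            assert {0, 1} <= chosen and len(chosen) == 3

    def test_i_out_of_range(self):
        with pytest.raises(ValueError):
            choose_isoforms([0.5, 0.5], 3, np.random.default_rng(0))

    def test_single_draw_frequencies(self):
        p = np.array([0.55, 0.28, 0.12, 0.05])
        rng = np.random.default_rng(7)
        n = 30_000
        counts = np.zeros(4)
        for _ in range(n):
            (j,) = choose_isoforms(p, 1, rng)
            counts[j] += 1
        freq = counts / n
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(freq - p) <= 3 * se)

    def test_sequential_and_race_routes_agree(self):
        """The vectorized exponential race must match sequential renormalized
        draws: both realize the Plackett-Luce subset distribution, checked
        here against its exact two-draw probabilities."""
        p = np.array([0.5, 0.3, 0.15, 0.05])
        n = 30_000
        exact = {}
        for a, b in itertools.permutations(range(4), 2):
            key = frozenset((a, b))
            exact[key] = exact.get(key, 0.0) + p[a] * p[b] / (1 - p[a])

        rng = np.random.default_rng(11)
        seq_counts = {k: 0 for k in exact}
        for _ in range(n):
            seq_counts[frozenset(choose_isoforms(p, 2, rng))] += 1

        mask = choose_isoforms_many(np.tile(p, (n, 1)), 2, np.random.default_rng(12))
        race_counts = {k: 0 for k in exact}
        for row in mask:
            race_counts[frozenset(np.flatnonzero(row).tolist())] += 1

        for key, prob in exact.items():
            se = np.sqrt(prob * (1 - prob) / n)
            assert abs(seq_counts[key] / n - prob) <= 3 * se
            assert abs(race_counts[key] / n - prob) <= 3 * se

    def test_race_zero_probabilities_last(self):
        P = np.tile([0.6, 0.4, 0.0, 0.0], (500, 1))
        mask = choose_isoforms_many(np.asarray(P), 3, np.random.default_rng(0))
        assert mask.sum(axis=1).tolist() == [3] * 500
        assert np.all(mask[:, 0] & mask[:, 1])  # positive-probability pair always in
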