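"""Deterministic expectation engine: unit conversions, selection growth,
mixture truncation, and the full expectation chain against Monte-Carlo
oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from bsapower import (
    BulkExpectation,
    ExperimentalDesign,
    MutationEffects,
    bulk_mutant_fraction,
    expected_bulk_frequencies,
    grow_frequency,
    mixture_quantile,
    pct_to_sd_units,
)
from bsapower.model_core import _mixture_cdf


def recursion_oracle(p, s, g):
    """Per-generation haploid selection recursion (independent of the
    closed form used in the implementation)."""
    for _ in range(g):
        p = p * (1 - s) / (1 - p * s)
    return p


def mixture_draws(rng, n, p, mu_m, r):
    is_mut = rng.random(n) < p
    x = rng.standard_normal(n)
    x[is_mut] = mu_m + r * x[is_mut]
    return x, is_mut


class TestPctToSdUnits:
    @pytest.mark.parametrize(
        "pct,cv,expected,tol",
        [
            (10.45, 0.07572, 1.38, 0.005),
            (7.21, 0.07572, 0.952, 0.001),
            (0.0, 0.05, 0.0, 0.0),
            (-3.25, 0.07572, -0.429, 0.001),
        ],
    )
    def test_examples(self, pct, cv, expected, tol):
        assert pct_to_sd_units(pct, cv) == pytest.approx(expected, abs=tol)

    def test_nonpositive_cv_rejected(self):
        with pytest.raises(ValueError):
            pct_to_sd_units(5.0, 0.0)


class TestGrowFrequency:
    @pytest.mark.parametrize(
        "p,s,g,expected",
        [
            (0.5, 0.0, 10, 0.5),
            (0.5, 0.1, 10, 0.2585),
            (1.0, 0.2, 30, 1.0),
            (0.0, 0.2, 30, 0.0),
        ],
    )
    def test_examples(self, p, s, g, expected):
        assert grow_frequency(p, s, g) == pytest.approx(expected, abs=1e-4)

    def test_closed_form_matches_recursion(self, rng):
        """The closed form must equal the per-generation recursion."""
        for _ in range(1000):
            p = rng.random()
            s = rng.uniform(-0.5, 0.9)
            g = int(rng.integers(0, 50))
            assert grow_frequency(p, s, g) == pytest.approx(
                recursion_oracle(p, s, g), abs=1e-12
            )

    def test_lethal_selection_rejected(self):
        with pytest.raises(ValueError):
            grow_frequency(0.5, 1.0, 10)


class TestMixtureQuantile:
    def test_collapses_to_normal_quantile(self):
        t = mixture_quantile(0.3, 0.0, 1.0, 0.02, "low")
        assert t == pytest.approx(norm.ppf(0.02), abs=1e-3)
        assert t == pytest.approx(-2.0537, abs=1e-3)

    def test_shifted_mixture_high_tail(self):
        # bisection oracle on a dense CDF grid
        grid = np.linspace(-10, 10, 2_000_001)
        cdf = 0.5 * norm.cdf(grid) + 0.5 * norm.cdf(grid - 0.66)
        t_oracle = grid[np.searchsorted(cdf, 0.95)]
        t = mixture_quantile(0.5, 0.66, 1.0, 0.05, "high")
        assert t == pytest.approx(t_oracle, abs=1e-3)
        assert t == pytest.approx(2.06, abs=0.02)

    def test_median_of_symmetric_mixture(self):
        assert mixture_quantile(0.7, 0.0, 1.0, 0.5, "low") == pytest.approx(
            0.0, abs=1e-9
        )

    @given(
        p=st.floats(0.0, 1.0),
        mu=st.floats(-3.0, 3.0),
        r=st.floats(0.3, 3.0),
        tail=st.floats(0.005, 0.49),
        side=st.sampled_from(["low", "high"]),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_cdf_of_quantile_is_identity(self, p, mu, r, tail, side):
        t = mixture_quantile(p, mu, r, tail, side)
        target = tail if side == "low" else 1 - tail
        assert _mixture_cdf(t, p, mu, r) == pytest.approx(target, abs=1e-8)


class TestBulkMutantFraction:
    def test_indistinguishable_components_leave_frequency(self):
        for p in (0.1, 0.5, 0.9):
            assert bulk_mutant_fraction(p, 0.0, 1.0, 1.3, "high") == pytest.approx(p)
            assert bulk_mutant_fraction(p, 0.0, 1.0, -0.4, "low") == pytest.approx(p)

    def test_pure_mutant_population(self):
        assert bulk_mutant_fraction(1.0, 0.8, 1.2, 2.0, "high") == 1.0

    def test_shifted_high_tail_enrichment(self):
        assert bulk_mutant_fraction(0.5, 0.66, 1.0, 2.06, "high") == pytest.approx(
            0.80, abs=0.02
        )

    def test_against_monte_carlo_oracle(self, rng):
        """Bayes tail fractions match empirical fractions in sampled tails."""
        # one large draw plus a batch of smaller random parameter sets
        cases = [(0.5, 0.66, 1.0, 2.06, "high", 10_000_000)]
        for _ in range(10):
            cases.append(
                (
                    rng.uniform(0.05, 0.95),
                    rng.uniform(-2, 2),
                    rng.uniform(0.5, 2.0),
                    rng.uniform(-1.5, 1.5),
                    "high" if rng.random() < 0.5 else "low",
                    1_000_000,
                )
            )
        for p, mu, r, t, side, n in cases:
            x, is_mut = mixture_draws(rng, n, p, mu, r)
            in_tail = x > t if side == "high" else x < t
            n_tail = in_tail.sum()
            assert n_tail > 0
            frac = is_mut[in_tail].mean()
            se = np.sqrt(frac * (1 - frac) / n_tail) + 1e-9
            assert bulk_mutant_fraction(p, mu, r, t, side) == pytest.approx(
                frac, abs=3 * se + 1e-4
            )

    def test_zero_tail_mass_rejected(self):
        with pytest.raises(ValueError):
            bulk_mutant_fraction(0.0, 0.0, 1.0, 40.0, "high")


class TestExpectedBulkFrequencies:
    def test_null_mutation_gives_half_everywhere(self, mapping_design):
        exp = expected_bulk_frequencies(mapping_design, MutationEffects(0, 1, 0))
        assert exp.p_low == pytest.approx(0.5)
        assert exp.p_high == pytest.approx(0.5)
        assert exp.p_preselection == pytest.approx(0.5)

    def test_fitness_alone_cannot_separate_bulks(self, mapping_design):
        exp = expected_bulk_frequencies(mapping_design, MutationEffects(0, 1, 0.1))
        assert exp.p_low == pytest.approx(exp.p_high)
        assert exp.p_low < 0.5

    def test_strong_mutant_chain_against_full_monte_carlo(self, mapping_design, rng):
        """The whole deterministic chain vs a 10^7-individual simulation
        for the +10.45% / 0.9467 / s=0.127 mutant."""
        effects = MutationEffects(10.45, 0.9467, 0.127)
        exp = expected_bulk_frequencies(mapping_design, effects)

        n = 10_000_000
        p_pre = recursion_oracle(0.5, 0.127, 10)
        mu = 10.45 / 100 / 0.07572
        x, is_mut = mixture_draws(rng, n, p_pre, mu, 0.9467)
        order = np.argsort(x)
        k = int(round(0.02 * n))
        f_low = is_mut[order[:k]].mean()
        f_high = is_mut[order[-k:]].mean()
        p_low_mc = recursion_oracle(f_low, 0.127, 10)
        p_high_mc = recursion_oracle(f_high, 0.127, 10)

        assert exp.p_low == pytest.approx(p_low_mc, abs=5e-4)
        assert exp.p_high == pytest.approx(p_high_mc, abs=5e-3)
        assert exp.p_high == pytest.approx(0.61, abs=0.02)
        assert exp.p_low <= 0.01

    def test_monotone_in_mean_effect(self, mapping_design):
        highs, lows = [], []
        for pct in [0.0, 1.0, 2.0, 5.0, 10.0, 20.0]:
            exp = expected_bulk_frequencies(
                mapping_design, MutationEffects(pct, 1.0, 0.02)
            )
            highs.append(exp.p_high)
            lows.append(exp.p_low)
        assert np.all(np.diff(highs) >= -1e-12)
        assert np.all(np.diff(lows) <= 1e-12)

    def test_sign_flip_swaps_bulks(self, mapping_design):
        a = expected_bulk_frequencies(mapping_design, MutationEffects(6.0, 1.0, 0.0))
        b = expected_bulk_frequencies(mapping_design, MutationEffects(-6.0, 1.0, 0.0))
        assert a.p_high == pytest.approx(b.p_low, abs=1e-9)
        assert a.p_low == pytest.approx(b.p_high, abs=1e-9)


class TestValidation:
    def test_design_invariants(self):
        with pytest.raises(ValueError):
            ExperimentalDesign(cutoff_fraction=0.6)
        with pytest.raises(ValueError):
            ExperimentalDesign(depth=0)
        with pytest.raises(ValueError):
            ExperimentalDesign(population_size=10, cutoff_fraction=0.01)

    def test_effects_invariants(self):
        with pytest.raises(ValueError):
            MutationEffects(sd_ratio=0.0)
        with pytest.raises(ValueError):
            MutationEffects(selection_coefficient=1.0)
        with pytest.raises(ValueError):
            MutationEffects(initial_frequency=1.5)

    def test_bulk_expectation_invariants(self):
        with pytest.raises(ValueError):
            BulkExpectation(p_low=1.2, p_high=0.5, t_low=-1, t_high=1,
                            p_preselection=0.5)
        with pytest.raises(ValueError):
            BulkExpectation(p_low=0.2, p_high=0.5, t_low=1, t_high=-1,
                            p_preselection=0.5)
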