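"""Beta-binomial model, fitting, and multiple-testing adjustment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import special
from statsmodels.stats.multitest import multipletests

from spliceframe.io import add_psi
from spliceframe.model import SpliceframeError
from spliceframe.simulate import simulate_event_counts
from spliceframe.stats import (
    adjust_bh,
    betabin_loglik,
    fit_betabin,
    run_differential_test,
    summarize_event,
)


def betabin_pmf_oracle(y, n, p, phi):
    """Direct beta-function-ratio evaluation of the beta-binomial mass."""
    a = p * (1 - phi) / phi
    b = (1 - p) * (1 - phi) / phi
    return (
        math.comb(n, y)
        * special.beta(y + a, n - y + b)
        / special.beta(a, b)
    )


class TestLogLik:
    def test_binomial_limit(self):
        # phi -> 0: log C(10,3) 0.3^3 0.7^7
        expected = math.log(math.comb(10, 3) * 0.3**3 * 0.7**7)
        beta0 = float(special.logit(0.3))
        ll = betabin_loglik([3], [10], [False], beta0, 0.0, 0.0, 0.0)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_empty_trial_contributes_zero(self):
        beta0 = float(special.logit(0.3))
        base = betabin_loglik([3], [10], [False], beta0, 0.0, 0.05, 0.05)
        with_empty = betabin_loglik([3, 0], [10, 0], [False, True],
                                    beta0, 0.0, 0.05, 0.05)
        assert with_empty == pytest.approx(base)

    def test_matches_direct_mass_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 31))
            y = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.05, 0.95))
            phi = float(rng.uniform(0.005, 0.6))
            ll = betabin_loglik([y], [n], [False],
                                float(special.logit(p)), 0.0, phi, phi)
            assert ll == pytest.approx(
                math.log(betabin_pmf_oracle(y, n, p, phi)), abs=1e-8
            )

    def test_mass_normalizes_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(1, 31))
            p = float(rng.uniform(0.05, 0.95))
            phi = float(rng.uniform(1e-4, 0.8))
            beta0 = float(special.logit(p))
            total = sum(
                math.exp(betabin_loglik([y], [n], [False], beta0, 0, phi, phi))
                for y in range(n + 1)
            )
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_y_above_n_fatal(self):
        with pytest.raises(SpliceframeError):
            betabin_loglik([5], [3], [False], 0.0, 0.0, 0.05, 0.05)


def _event_frame(counts):
    counts = counts.copy()
    counts["event_id"] = "e"
    counts["sample_id"] = counts["group"] + counts["idx"].astype(str)
    counts["psi"] = add_psi(counts, 10)
    return counts


class TestFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        counts = simulate_event_counts(rng, 0.7, 0.3, 0.02, 20, 20, (200, 200))
        fit = fit_betabin(
            counts["reads_iso2"],
            counts["reads_iso1"] + counts["reads_iso2"],
            counts["group"] == "case",
        )
        assert fit.converged
        assert fit.psi_case == pytest.approx(0.7, abs=0.05)
        assert fit.psi_control == pytest.approx(0.3, abs=0.05)

    def test_identical_groups_give_null_result(self):
        y = np.array([30, 40, 50, 35, 45] * 2)
        n = np.full(10, 100)
        case = np.repeat([True, False], 5)
        fit = fit_betabin(y, n, case)
        assert abs(fit.beta1) < 1e-4
        assert fit.p_value > 0.9

    def test_label_swap_negates_effect(self):
        rng = np.random.default_rng(3)
        counts = simulate_event_counts(rng, 0.6, 0.4, 0.05, 12, 12, (50, 200))
        y = counts["reads_iso2"].to_numpy()
        n = (counts["reads_iso1"] + counts["reads_iso2"]).to_numpy()
        case = (counts["group"] == "case").to_numpy()
        fit = fit_betabin(y, n, case)
        flipped = fit_betabin(y, n, ~case)
        assert flipped.beta1 == pytest.approx(-fit.beta1, abs=1e-5)
        assert flipped.p_value == pytest.approx(fit.p_value, abs=1e-6)

    def test_all_zero_counts_never_crash(self):
        y = np.zeros(10)
        n = np.full(10, 50)
        case = np.repeat([True, False], 5)
        fit = fit_betabin(y, n, case)
        assert (not fit.converged) or np.isnan(fit.p_value) or fit.p_value > 0.5

    def test_doubling_counts_sharpens_planted_effect(self):
        rng = np.random.default_rng(9)
        counts = simulate_event_counts(rng, 0.75, 0.25, 0.01, 10, 10, (80, 120))
        y = counts["reads_iso2"].to_numpy()
        n = (counts["reads_iso1"] + counts["reads_iso2"]).to_numpy()
        case = (counts["group"] == "case").to_numpy()
        f1 = fit_betabin(y, n, case)
        f2 = fit_betabin(2 * y, 2 * n, case)
        # PSI is expression-invariant: doubling both counts leaves the group
        # probabilities in place and cannot qualitatively weaken the signal
        # (once between-sample overdispersion dominates, extra coverage adds
        # almost no information, so equality up to optimizer noise is fine)
        assert f2.psi_case == pytest.approx(f1.psi_case, abs=1e-3)
        assert f2.psi_control == pytest.approx(f1.psi_control, abs=1e-3)
        assert f2.p_value <= max(f1.p_value * 1.1, f1.p_value + 1e-8)
        assert f2.p_value < 1e-3 and f1.p_value < 1e-3


class TestAdjustBH:
    def test_hand_worked_step_up(self):
        out = adjust_bh([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert adjust_bh([0.2])[0] == pytest.approx(0.2)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 50))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.max(np.abs(adjust_bh(p) - ref)) < 1e-12

    def test_nan_excluded_from_family(self):
        out = adjust_bh([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        ref = multipletests([0.01, 0.04], method="fdr_bh")[1]
        assert np.allclose(out[[0, 2]], ref)

    def test_out_of_range_fatal(self):
        with pytest.raises(SpliceframeError):
            adjust_bh([0.5, 1.5])


class TestSummaries:
    def test_delta_psi_signed_case_minus_control(self):
        from spliceframe.stats import BetaBinFit

        fit = BetaBinFit("e", 0, 0, 0.05, 0.05, 1.0, 0.5, 0.0, True)
        s = summarize_event([0.55, 0.65], [0.35, 0.45], fit)
        assert s["delta_psi"] == pytest.approx(0.2)

    def test_significance_boundary_strict(self):
        rng = np.random.default_rng(11)
        frames = []
        for i, (pc, ph) in enumerate([(0.8, 0.2), (0.5, 0.5)]):
            c = simulate_event_counts(rng, pc, ph, 0.02, 10, 10, (100, 200))
            c["event_id"] = f"e{i}"
            frames.append(c)
        counts = pd.concat(frames, ignore_index=True)
        counts["sample_id"] = counts["group"] + counts["idx"].astype(str)
        counts["psi"] = add_psi(counts, 10)
        df = run_differential_test(counts, "case", "control", alpha=0.01)
        assert df["p_adj"].min() >= df["p_value"].min()
        assert bool(df.set_index("event_id").loc["e0", "significant"])
        assert not bool(df.set_index("event_id").loc["e1", "significant"])
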