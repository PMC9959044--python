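"""Dissolution-kinetics fitting, mechanism classification, release AUC."""

import numpy as np
import pytest

from beadopt.kinetics import (
    DissolutionProfile,
    classify_release_mechanism,
    dissolution_auc,
    fit_kinetic_model,
    select_best_model,
)
from beadopt.synthetic import gen_dissolution


T = np.arange(1.0, 10.0)


class TestExactRecovery:
    """Each law fitted to its own noiseless data is exact."""

    def test_zero_order(self):
        p = DissolutionProfile(T, 7.0 * T)
        f = fit_kinetic_model(p, "zero")
        assert f.K == pytest.approx(7.0, abs=1e-9)
        assert f.R2 == pytest.approx(1.0, abs=1e-12)

    def test_first_order(self):
        k1 = 0.12
        p = DissolutionProfile(T, 100.0 * (1 - np.exp(-k1 * T)))
        f = fit_kinetic_model(p, "first")
        assert f.K == pytest.approx(k1, abs=1e-9)
        assert f.R2 == pytest.approx(1.0, abs=1e-12)

    def test_higuchi(self):
        p = DissolutionProfile(T, 10.0 * np.sqrt(T))
        f = fit_kinetic_model(p, "higuchi")
        assert f.K == pytest.approx(10.0, abs=1e-9)
        assert f.R2 == pytest.approx(1.0, abs=1e-12)

    def test_korsmeyer_peppas_reported_exponent(self):
        # noiseless power law with the exponent reported for the
        # oil-entrapped optimized beads
        t = np.arange(1.0, 7.0)
        p = DissolutionProfile(t, 100 * 0.05 * t**0.836)
        f = fit_kinetic_model(p, "korsmeyer_peppas")
        assert f.n == pytest.approx(0.836, abs=1e-9)
        assert f.K == pytest.approx(0.05, abs=1e-9)
        assert f.R2 == pytest.approx(1.0, abs=1e-12)

    def test_hixson_crowell(self):
        khc = 0.25
        q = 100.0 - (100.0 ** (1 / 3) - khc * T) ** 3
        p = DissolutionProfile(T, q)
        f = fit_kinetic_model(p, "hixson_crowell")
        assert f.K == pytest.approx(khc, abs=1e-9)
        assert f.R2 == pytest.approx(1.0, abs=1e-12)


class TestFitEdgeCases:
    def test_kp_sixty_percent_cutoff(self):
        # points above 60% release must be excluded from the power-law fit
        t = np.arange(1.0, 13.0)
        q = 100 * 0.15 * t**0.8  # crosses 60% around t = 5.7
        p = DissolutionProfile(t, np.clip(q, 0, 100))
        f = fit_kinetic_model(p, "korsmeyer_peppas")
        assert f.n_points_used == int((q / 100 <= 0.60).sum())

    def test_kp_too_few_points_after_cutoff(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        p = DissolutionProfile(t, np.array([70.0, 80.0, 90.0, 95.0]))
        with pytest.raises(ValueError, match="usable points"):
            fit_kinetic_model(p, "korsmeyer_peppas")

    def test_q_at_100_dropped_from_log_transforms(self):
        t = np.arange(1.0, 7.0)
        q = np.array([30.0, 50.0, 70.0, 85.0, 95.0, 100.0])
        p = DissolutionProfile(t, q)
        with pytest.warns(UserWarning, match="dropped"):
            f = fit_kinetic_model(p, "first")
        assert f.n_points_used == 5

    def test_unknown_model(self):
        p = DissolutionProfile(T, 7.0 * T)
        with pytest.raises(ValueError, match="unknown model"):
            fit_kinetic_model(p, "weibull")

    def test_monotone_violation_flagged_not_resorted(self):
        with pytest.warns(UserWarning, match="decreases"):
            p = DissolutionProfile(
                np.array([1.0, 2.0, 3.0]), np.array([20.0, 18.0, 30.0])
            )
        assert p.monotone_violations.tolist() == [False, True, False]
        assert p.release[1] == 18.0  # kept as measured


class TestModelSelection:
    def test_exact_higuchi_ranked_first(self):
        p = DissolutionProfile(T, 12.0 * np.sqrt(T))
        fits, _ = select_best_model(p)
        assert fits[0].model == "higuchi"

    def test_exact_zero_order_ranked_first(self):
        p = DissolutionProfile(T, 6.0 * T)
        fits, _ = select_best_model(p)
        assert fits[0].model == "zero"

    def test_synthetic_power_law_beats_zero_order(self):
        prof, _ = gen_dissolution(
            "korsmeyer_peppas",
            {"Km": 0.08, "n": 0.7},
            np.arange(1.0, 13.0),
            cv_pct=2.0,
            seed=42,
        )
        fits, _ = select_best_model(prof)
        r2 = {f.model: f.R2 for f in fits}
        assert r2["korsmeyer_peppas"] > r2["zero"]

    def test_exclusions_carry_reasons(self):
        t = np.array([1.0, 2.0, 3.0])
        p = DissolutionProfile(t, np.array([70.0, 80.0, 90.0]))
        fits, excluded = select_best_model(p)
        assert "korsmeyer_peppas" in excluded


class TestMechanism:
    @pytest.mark.parametrize(
        "n, label",
        [
            (0.30, "fickian"),
            (0.45, "fickian"),  # the boundary case is Fickian
            (0.46, "anomalous"),
            (0.70, "anomalous"),
            (0.836, "anomalous"),
            (0.89, "case_II"),
            (1.0, "case_II"),
            (1.2, "super_case_II"),
        ],
    )
    def test_classification_rule(self, n, label):
        assert classify_release_mechanism(n) == label

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            classify_release_mechanism(float("nan"))


class TestDissolutionAUC:
    def test_constant_profile(self):
        t = np.arange(1.0, 13.0)
        p = DissolutionProfile(t, np.full(12, 50.0))
        # origin prepended: triangle 0->50 over [0,1] + 50*11
        assert dissolution_auc(p) == pytest.approx(25.0 + 550.0)
        assert dissolution_auc(p, prepend_origin=False) == pytest.approx(550.0)

    def test_linear_ramp_triangle_area(self):
        t = np.arange(1.0, 13.0)
        p = DissolutionProfile(t, 100.0 * t / 12.0)
        assert dissolution_auc(p) == pytest.approx(600.0)

    def test_dense_grid_oracle(self):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0.5, 12, 15))
        q = np.sort(rng.uniform(0, 95, 15))
        p = DissolutionProfile(t, q)
        # oracle: trapezoid on a dense grid of the linear interpolant
        tt = np.concatenate([[0.0], t])
        qq = np.concatenate([[0.0], q])
        grid = np.union1d(np.linspace(0, t[-1], 200_001), tt)
        dense = np.trapezoid(np.interp(grid, tt, qq), grid)
        assert dissolution_auc(p) == pytest.approx(dense, abs=1e-9 * dense + 1e-9)

    def test_additive_over_partitions_and_collinear_insertion(self):
        t = np.array([1.0, 3.0, 6.0, 12.0])
        q = np.array([10.0, 30.0, 55.0, 90.0])
        p = DissolutionProfile(t, q)
        total = dissolution_auc(p, prepend_origin=False)
        left = np.trapezoid(q[:3], t[:3])
        right = np.trapezoid(q[2:], t[2:])
        assert total == pytest.approx(left + right, rel=1e-12)
        # inserting a collinear midpoint changes nothing
        t2 = np.array([1.0, 2.0, 3.0, 6.0, 12.0])
        q2 = np.array([10.0, 20.0, 30.0, 55.0, 90.0])
        p2 = DissolutionProfile(t2, q2)
        assert dissolution_auc(p2, prepend_origin=False) == pytest.approx(
            total, rel=1e-12
        )

    def test_single_point_raises(self):
        p = DissolutionProfile(np.array([1.0]), np.array([10.0]))
        with pytest.raises(ValueError):
            dissolution_auc(p, prepend_origin=False)


class TestExponentRecoveryUnderNoise:
    @pytest.mark.parametrize("n_true", [0.45, 0.6, 0.836])
    def test_mae_below_002_at_one_percent_noise(self, n_true):
        # 500 seeded replicates at 1% multiplicative noise
        times = np.arange(1.0, 13.0)
        km = 0.55 / 12.0**n_true  # keep the whole profile under the 60% cutoff
        errs = []
        for seed in range(500):
            prof, _ = gen_dissolution(
                "korsmeyer_peppas",
                {"Km": km, "n": n_true},
                times,
                cv_pct=1.0,
                seed=seed,
            )
            f = fit_kinetic_model(prof, "korsmeyer_peppas")
            errs.append(abs(f.n - n_true))
        assert np.mean(errs) < 0.02
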