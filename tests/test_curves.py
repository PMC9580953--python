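"""Tests of accumulation curves and the Heap's-law / offset-exponential fits."""

import itertools

import numpy as np
import pandas as pd
import pytest

from panforge.curves import (
    fit_exp_decay,
    fit_heaps,
    pan_core_curves,
    stabilization_summary,
)
from panforge.matrix import PresenceAbsenceMatrix
from panforge.simulate import generate_curve_data

from conftest import random_matrix


class TestPanCoreCurves:
    def test_identical_genomes_give_flat_curves(self):
        data = pd.DataFrame(
            np.ones((12, 3), dtype=bool),
            index=[f"F{i}" for i in range(12)],
            columns=["g1", "g2", "g3"],
        )
        profile = pan_core_curves(PresenceAbsenceMatrix(data), n_permutations=5)
        assert (profile.pan == 12).all()
        assert (profile.core == 12).all()

    def test_single_genome_pan_equals_core_equals_family_count(self):
        data = pd.DataFrame(
            np.ones((7, 1), dtype=bool),
            index=[f"F{i}" for i in range(7)],
            columns=["g1"],
        )
        profile = pan_core_curves(PresenceAbsenceMatrix(data), n_permutations=1)
        assert profile.pan_curve.tolist() == [7]
        assert profile.core_curve.tolist() == [7]

    @pytest.mark.parametrize("seed", [0, 3])
    def test_exhaustive_mode_matches_independent_enumeration(self, seed):
        m = random_matrix(20, 3, seed=seed)
        profile = pan_core_curves(m, exhaustive=True)
        X = m.data
        # independent enumeration over all 3! genome orderings
        pan, core, new = [], [], []
        for order in itertools.permutations(m.genome_ids):
            seen: set = set()
            prev_len = 0
            p_row, c_row, n_row = [], [], []
            for g_i, g in enumerate(order):
                fams = set(X.index[X[g]])
                seen |= fams
                inall = set(X.index)
                for h in order[: g_i + 1]:
                    inall &= set(X.index[X[h]])
                p_row.append(len(seen))
                c_row.append(len(inall))
                n_row.append(len(seen) - prev_len)
                prev_len = len(seen)
            pan.append(p_row)
            core.append(c_row)
            new.append(n_row)
        assert sorted(map(tuple, profile.pan.tolist())) == sorted(map(tuple, pan))
        np.testing.assert_array_equal(
            profile.pan_curve, np.median(np.array(pan), axis=0)
        )
        np.testing.assert_array_equal(
            profile.core_curve, np.median(np.array(core), axis=0)
        )
        np.testing.assert_array_equal(
            profile.new_curve, np.median(np.array(new), axis=0)
        )

    def test_curve_monotonicity_and_new_gene_bookkeeping(self):
        m = random_matrix(60, 6, seed=4, density=0.4)
        profile = pan_core_curves(m, n_permutations=20, seed=1)
        assert (np.diff(profile.pan, axis=1) >= 0).all()
        assert (np.diff(profile.core, axis=1) <= 0).all()
        np.testing.assert_array_equal(profile.new.sum(axis=1), profile.pan[:, -1])
        np.testing.assert_array_equal(profile.pan[:, 0], profile.core[:, 0])

    def test_same_seed_reproduces_orders(self):
        m = random_matrix(30, 5, seed=2)
        p1 = pan_core_curves(m, n_permutations=10, seed=7)
        p2 = pan_core_curves(m, n_permutations=10, seed=7)
        assert p1.orders == p2.orders
        np.testing.assert_array_equal(p1.pan, p2.pan)

    def test_invalid_permutation_count_rejected(self):
        m = random_matrix(10, 3, seed=0)
        with pytest.raises(ValueError):
            pan_core_curves(m, n_permutations=0)


class TestHeapFit:
    def test_recovers_reported_power_law_exactly(self):
        df = generate_curve_data(
            "heap", {"k": 1848.134, "gamma": 0.156}, range(1, 10)
        )
        fit = fit_heaps(df["N"], df["n"])
        assert fit.gamma == pytest.approx(0.156, abs=1e-6)
        assert fit.k == pytest.approx(1848.134, rel=1e-6)
        assert fit.alpha == pytest.approx(0.844, abs=1e-6)
        assert fit.openness == "open"

    def test_constant_series_sits_on_the_open_closed_boundary(self):
        fit = fit_heaps([1, 2, 3, 4], [100, 100, 100, 100])
        assert fit.gamma == pytest.approx(0.0, abs=1e-9)
        assert fit.openness == "boundary"

    def test_linear_growth_is_exact_power_law_with_exponent_one(self):
        N = np.arange(1, 8)
        fit = fit_heaps(N, 5 * N)
        assert fit.k == pytest.approx(5.0, rel=1e-9)
        assert fit.gamma == pytest.approx(1.0, abs=1e-9)
        assert fit.alpha == pytest.approx(0.0, abs=1e-9)
        assert fit.openness == "open"

    def test_shrinking_series_called_closed(self):
        N = np.arange(1, 8)
        fit = fit_heaps(N, 100.0 * N ** -0.2)
        assert fit.openness == "closed"

    @pytest.mark.parametrize("k", [50.0, 1848.134])
    @pytest.mark.parametrize("gamma", [0.0, 0.156, 0.5, 1.0])
    def test_noise_free_recovery_across_parameter_grid(self, k, gamma):
        df = generate_curve_data("heap", {"k": k, "gamma": gamma}, range(1, 10))
        fit = fit_heaps(df["N"], df["n"])
        assert fit.k == pytest.approx(k, rel=1e-6)
        assert fit.gamma == pytest.approx(gamma, abs=1e-6)

    def test_invalid_series_rejected(self):
        with pytest.raises(ValueError):
            fit_heaps([1], [5])
        with pytest.raises(ValueError):
            fit_heaps([1, 2], [5, 0])


class TestExpDecayFit:
    def test_recovers_reported_core_genome_model(self):
        df = generate_curve_data(
            "expdecay",
            {"k": 465.995, "t": 4.839, "tg_theta": 1182.675},
            range(1, 10),
        )
        fit = fit_exp_decay(df["N"], df["n"])
        assert fit.tg_theta == pytest.approx(1182.675, abs=0.5)
        assert fit.t == pytest.approx(4.839, rel=1e-3)
        assert fit.k == pytest.approx(465.995, rel=1e-3)

    def test_recovers_reported_new_gene_model(self):
        df = generate_curve_data(
            "expdecay",
            {"k": 219.676, "t": 4.356, "tg_theta": 24.813},
            range(1, 10),
        )
        fit = fit_exp_decay(df["N"], df["n"])
        assert fit.tg_theta == pytest.approx(24.813, abs=0.1)

    def test_constant_series_flagged_unidentifiable(self):
        fit = fit_exp_decay([1, 2, 3, 4], [7.0, 7.0, 7.0, 7.0])
        assert fit.k == 0.0
        assert fit.tg_theta == 7.0
        assert not fit.identifiable

    @pytest.mark.parametrize("t", [0.5, 2.0, 4.839, 20.0])
    @pytest.mark.parametrize("tg", [0.0, 24.813, 1182.675])
    def test_noise_free_recovery_across_parameter_grid(self, t, tg):
        k = 300.0
        df = generate_curve_data(
            "expdecay", {"k": k, "t": t, "tg_theta": tg}, range(1, 10)
        )
        fit = fit_exp_decay(df["N"], df["n"])
        assert fit.t == pytest.approx(t, rel=1e-3)
        assert fit.tg_theta == pytest.approx(tg, abs=max(1e-3, 1e-3 * abs(tg)))
        assert fit.k == pytest.approx(k, rel=1e-3)

    def test_noisy_estimates_unbiased_within_monte_carlo_error(self):
        k, t, tg, sd, reps = 465.995, 4.839, 1182.675, 5.0, 200
        est = []
        for seed in range(reps):
            df = generate_curve_data(
                "expdecay", {"k": k, "t": t, "tg_theta": tg},
                range(1, 10), noise_sd=sd, seed=seed,
            )
            est.append(fit_exp_decay(df["N"], df["n"]).tg_theta)
        sem = np.std(est, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(est) - tg) < 4 * sem + 0.5

    def test_invalid_series_rejected(self):
        with pytest.raises(ValueError):
            fit_exp_decay([1, 2], [3.0, 4.0])
        with pytest.raises(ValueError):
            fit_exp_decay([2, 2, 2], [3.0, 4.0, 5.0])


class TestStabilizationSummary:
    def test_reports_plateau_and_new_gene_rate_as_whole_genes(self):
        core = fit_exp_decay(
            *generate_curve_data(
                "expdecay", {"k": 465.995, "t": 4.839, "tg_theta": 1182.675},
                range(1, 10),
            ).T.values
        )
        single = fit_exp_decay(
            *generate_curve_data(
                "expdecay", {"k": 219.676, "t": 4.356, "tg_theta": 24.813},
                range(1, 10),
            ).T.values
        )
        summary = stabilization_summary(core, single)
        assert summary["core_plateau_genes"] == 1182
        assert summary["new_genes_per_genome_genes"] == 24
        assert summary["core_plateau"] == pytest.approx(1182.675, abs=0.5)
        assert summary["new_genes_per_genome"] == pytest.approx(24.813, abs=0.1)

    def test_degenerate_fit_reports_constant_level(self):
        flat = fit_exp_decay([1, 2, 3], [42.0, 42.0, 42.0])
        summary = stabilization_summary(flat, flat)
        assert summary["core_plateau"] == 42.0
        assert not summary["core_identifiable"]
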