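"""Survival models, OER, and the three death cascades."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spheroidca as sc


class TestOER:
    @pytest.mark.parametrize("po2,expected", [(0.0, 3.0), (11.0, 1.0), (5.5, 2.0), (50.0, 1.0)])
    def test_reference_values(self, po2, expected):
        assert sc.oer(po2) == pytest.approx(expected)

    def test_negative_po2_rejected(self):
        with pytest.raises(ValueError):
            sc.oer(-0.1)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(a=st.floats(0, 300), b=st.floats(0, 300))
    def test_bounded_and_non_increasing(self, a, b):
        lo, hi = sorted((a, b))
        assert 1.0 <= sc.oer(hi) <= sc.oer(lo) <= 3.0


class TestSurvivalRT:
    P = sc.RTParams(alpha_per_gy=0.2, beta_per_gy2=0.02)

    def test_zero_dose_is_unity(self):
        assert sc.survival_rt(0.0, 100.0, sc.Phase.G1, self.P) == 1.0

    def test_hand_evaluated_normoxic(self):
        assert sc.survival_rt(2.0, 100.0, sc.Phase.G1, self.P) == pytest.approx(
            np.exp(-0.48), rel=1e-9
        )

    def test_anoxic_radioresistance(self):
        s = sc.survival_rt(2.0, 0.0, sc.Phase.G1, self.P)
        assert s == pytest.approx(np.exp(-(0.2 * 2 / 3 + 0.02 * (2 / 3) ** 2)), rel=1e-9)
        assert s > sc.survival_rt(2.0, 100.0, sc.Phase.G1, self.P)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            sc.survival_rt(-1.0, 100.0, sc.Phase.G1, self.P)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(d=st.floats(0, 20), d2=st.floats(0, 20), po2=st.floats(0, 100))
    def test_dose_monotone_and_hypoxic_protection(self, d, d2, po2):
        lo, hi = sorted((d, d2))
        assert sc.survival_rt(hi, po2, 0, self.P) <= sc.survival_rt(lo, po2, 0, self.P) + 1e-12
        assert sc.survival_rt(hi, 0.0, 0, self.P) >= sc.survival_rt(hi, 100.0, 0, self.P) - 1e-12


class TestSurvivalHT:
    P = sc.HTParams(
        alpha0_per_cem43=0.1,
        beta_ht_per_cem43_2=0.001,
        gamma_ht_by_phase=(1, 1, 1, 1, 1),
    )

    def test_zero_dose_is_unity(self):
        assert sc.survival_ht_monolayer(0.0, self.P) == 1.0

    def test_hand_evaluated_both_branches(self):
        # D_T = 50: quadratic branch at 40, linear branch at 100
        assert sc.survival_ht_monolayer(40.0, self.P) == pytest.approx(np.exp(-1.6), rel=1e-9)
        assert sc.survival_ht_monolayer(100.0, self.P) == pytest.approx(np.exp(-7.5), rel=1e-9)

    def test_branches_continuous_in_value_and_slope(self):
        d_t = 0.1 / (2 * 0.001)
        eps = 1e-6
        below = -np.log(sc.survival_ht_monolayer(d_t - eps, self.P))
        above = -np.log(sc.survival_ht_monolayer(d_t + eps, self.P))
        assert below == pytest.approx(above, abs=1e-4)
        slope_below = (
            -np.log(sc.survival_ht_monolayer(d_t, self.P))
            + np.log(sc.survival_ht_monolayer(d_t - 1e-3, self.P))
        ) / 1e-3
        slope_above = (
            -np.log(sc.survival_ht_monolayer(d_t + 1e-3, self.P))
            + np.log(sc.survival_ht_monolayer(d_t, self.P))
        ) / 1e-3
        assert slope_below == pytest.approx(slope_above, rel=1e-2)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(a0=st.floats(0.01, 0.5), b=st.floats(1e-4, 0.01))
    def test_continuity_holds_for_any_parameters(self, a0, b):
        p = sc.HTParams(
            alpha0_per_cem43=a0, beta_ht_per_cem43_2=b, gamma_ht_by_phase=(1, 1, 1, 1, 1)
        )
        d_t = a0 / (2 * b)
        lo = sc.survival_ht_monolayer(d_t * (1 - 1e-9), p)
        hi = sc.survival_ht_monolayer(d_t * (1 + 1e-9), p)
        assert lo == pytest.approx(hi, rel=1e-6)

    def test_degenerate_parameters_rejected(self):
        p = sc.HTParams(alpha0_per_cem43=0.1, beta_ht_per_cem43_2=0.0)
        with pytest.raises(ValueError):
            sc.survival_ht_monolayer(10.0, p)

    def test_spheroid_plateau(self):
        p = sc.HTParams()
        assert sc.survival_ht_spheroid(240.0, p) == 0.0005
        assert sc.survival_ht_spheroid(0.0, p) == 1.0
        # discontinuity at the threshold is permitted
        left = sc.survival_ht_spheroid(160.0, p, sc.Phase.G1)
        right = sc.survival_ht_spheroid(160.0 + 1e-9, p, sc.Phase.G1)
        assert left == pytest.approx(sc.survival_ht_monolayer(160.0, p, sc.Phase.G1))
        assert right == 0.0005

    def test_g0_three_fold_resistance_on_exponent(self):
        p = sc.HTParams()
        nls_cycling = [-np.log(sc.survival_ht_monolayer(40.0, p, ph)) for ph in range(4)]
        nls_g0 = -np.log(sc.survival_ht_monolayer(40.0, p, int(sc.Phase.G0)))
        assert nls_g0 == pytest.approx(np.mean(nls_cycling) / 3.0, rel=1e-9)

    def test_cycling_gamma_ratio(self):
        g = sc.HTParams().gamma_ht_by_phase
        assert g[0] / g[1] == pytest.approx(1.5)
        assert g[1] / g[2] == pytest.approx(1.5)


class TestRadiationCascade:
    def test_zero_dose_labels_nothing(self, oxic_field, rng):
        grid = sc.dense_sphere_grid(60.0)
        sc.apply_radiation(grid, 0.0, sc.RTParams(), oxic_field(grid), rng)
        assert not (grid.fate == int(sc.Fate.DYING_RT)).any()

    def test_lethal_dose_labels_everything(self, oxic_field, rng):
        grid = sc.dense_sphere_grid(60.0)
        p = sc.RTParams(alpha_per_gy=100.0)
        sc.apply_radiation(grid, 10.0, p, oxic_field(grid), rng)
        assert (grid.fate[grid.occupied] == int(sc.Fate.DYING_RT)).all()

    def test_labelled_count_is_binomial(self, oxic_field, rng):
        # ~1e4 cells at a uniform surviving fraction
        grid = sc.dense_sphere_grid(170.0)
        n = grid.n_cells
        assert n >= 10_000
        p = sc.RTParams(alpha_per_gy=0.15, beta_per_gy2=0.01)
        d = 2.0
        s = sc.survival_rt(d, 100.0, sc.Phase.G1, p)
        sc.apply_radiation(grid, d, p, oxic_field(grid), rng)
        labelled = int((grid.fate == int(sc.Fate.DYING_RT)).sum())
        sd = np.sqrt(n * s * (1 - s))
        assert abs(labelled - n * (1 - s)) <= 4 * sd

    def test_partition_preserved(self, oxic_field, rng):
        grid = sc.dense_sphere_grid(80.0)
        n = grid.n_cells
        sc.apply_radiation(grid, 5.0, sc.RTParams(), oxic_field(grid), rng)
        occ = grid.occupied
        assert int(occ.sum()) == n  # labelling kills nobody immediately


class TestMitoticFate:
    def test_certain_death_and_certain_division(self, rng):
        p1 = sc.RTParams(p_mitotic_death_early=1.0, p_mitotic_death_late=1.0)
        assert sc.resolve_mitotic_fate(1.0, p1, rng) == "death"
        p0 = sc.RTParams(p_mitotic_death_early=0.0, p_mitotic_death_late=0.0)
        assert sc.resolve_mitotic_fate(1.0, p0, rng) == "division"

    def test_two_stage_switch_at_delay(self, rng):
        p = sc.RTParams()
        assert p.p_mitotic_death(3.4) == 0.44
        assert p.p_mitotic_death(3.6) == 0.59

    def test_attempts_before_death_are_geometric(self, rng):
        # late-stage value 0.59: mean attempts 1/0.59 over 1e4 lineages
        p = sc.RTParams()
        n = 10_000
        attempts = np.empty(n)
        for i in range(n):
            k = 1
            while sc.resolve_mitotic_fate(10.0, p, rng) == "division":
                k += 1
            attempts[i] = k
        mean = attempts.mean()
        pd = p.p_mitotic_death_late
        sd_mean = np.sqrt((1 - pd) / pd**2 / n)
        assert abs(mean - 1 / pd) <= 4 * sd_mean


class TestHyperthermiaCascade:
    def test_zero_dose_no_labels_no_arrest(self, rng):
        grid = sc.dense_sphere_grid(60.0)
        sc.apply_hyperthermia(grid, 0.0, sc.HTParams(), rng)
        assert not (grid.fate == int(sc.Fate.DYING_HT)).any()
        assert not (grid.arrest > 0).any()

    def test_death_delay_mean_96h(self, rng):
        grid = sc.dense_sphere_grid(100.0)  # ~2.4e3 cells
        p = sc.HTParams()
        sc.apply_hyperthermia(grid, 240.0, p, rng)  # plateau: nearly all labelled
        delays = grid.delay[grid.fate == int(sc.Fate.DYING_HT)]
        assert delays.size >= 1000
        sd_mean = p.delay_sd_h / np.sqrt(delays.size)
        assert abs(delays.mean() - 96.0) <= 4 * sd_mean

    def test_arrest_mean_30h(self, rng):
        grid = sc.dense_sphere_grid(100.0)
        p = sc.HTParams()
        sc.apply_hyperthermia(grid, 20.0, p, rng)  # mild dose: most survive
        arrests = grid.arrest[(grid.fate == int(sc.Fate.VIABLE)) & grid.occupied]
        arrests = arrests[arrests > 0]
        assert arrests.size >= 1000
        sd_mean = (60.0 / np.sqrt(12.0)) / np.sqrt(arrests.size)
        assert abs(arrests.mean() - 30.0) <= 4 * sd_mean

    def test_partition_preserved(self, rng):
        grid = sc.dense_sphere_grid(80.0)
        n = grid.n_cells
        sc.apply_hyperthermia(grid, 80.0, sc.HTParams(), rng)
        dying = int((grid.fate == int(sc.Fate.DYING_HT)).sum())
        survivors = int(((grid.fate == int(sc.Fate.VIABLE)) & grid.occupied).sum())
        assert dying + survivors == n


class TestCombinationCascade:
    CP = sc.RTHTParams()
    RP = sc.RTParams()
    HP = sc.HTParams(gamma_ht_by_phase=(1, 1, 1, 1, 1))

    def test_partition_and_product_law(self, oxic_field, rng):
        grid = sc.dense_sphere_grid(170.0)  # >= 1e4 cells, all G1
        n = grid.n_cells
        d, t43 = 1.5, 100.0
        sc.apply_combination(grid, d, t43, self.RP, self.HP, self.CP, oxic_field(grid), rng)
        rp_t = self.RP.model_copy(
            update={"alpha_per_gy": self.CP.alpha(t43), "beta_per_gy2": self.CP.beta(t43)}
        )
        s_rtht = sc.survival_rt(d, 100.0, sc.Phase.G1, rp_t)
        s_ht = sc.survival_ht_spheroid(t43, self.HP, sc.Phase.G1)
        n_rt = int((grid.fate == int(sc.Fate.DYING_RT)).sum())
        n_ht = int((grid.fate == int(sc.Fate.DYING_HT)).sum())
        n_surv = int(((grid.fate == int(sc.Fate.VIABLE)) & grid.occupied).sum())
        assert n_rt + n_ht + n_surv == n
        assert abs(n_rt - n * (1 - s_rtht)) <= 4 * np.sqrt(n * s_rtht * (1 - s_rtht))
        p_surv = s_rtht * s_ht
        assert abs(n_surv - n * p_surv) <= 4 * np.sqrt(n * p_surv * (1 - p_surv))

    def test_degenerates_to_radiation_at_zero_thermal_dose(self, oxic_field, rng):
        grid = sc.dense_sphere_grid(120.0)
        n = grid.n_cells
        d = 2.0
        sc.apply_combination(grid, d, 0.0, self.RP, self.HP, self.CP, oxic_field(grid), rng)
        s = sc.survival_rt(d, 100.0, sc.Phase.G1, self.RP)
        n_rt = int((grid.fate == int(sc.Fate.DYING_RT)).sum())
        assert abs(n_rt - n * (1 - s)) <= 4 * np.sqrt(n * s * (1 - s))
        assert not (grid.fate == int(sc.Fate.DYING_HT)).any()
        assert not (grid.arrest > 0).any()  # S_HT(0) = 1: no heat arrest drawn

    def test_degenerates_to_hyperthermia_at_zero_dose(self, oxic_field, rng):
        grid = sc.dense_sphere_grid(120.0)
        n = grid.n_cells
        t43 = 80.0
        sc.apply_combination(grid, 0.0, t43, self.RP, self.HP, self.CP, oxic_field(grid), rng)
        s = sc.survival_ht_spheroid(t43, self.HP, sc.Phase.G1)
        n_ht = int((grid.fate == int(sc.Fate.DYING_HT)).sum())
        assert not (grid.fate == int(sc.Fate.DYING_RT)).any()
        assert abs(n_ht - n * (1 - s)) <= 4 * np.sqrt(n * s * (1 - s))

    def test_inconsistent_zero_dose_tables_rejected(self, oxic_field, rng):
        grid = sc.dense_sphere_grid(40.0)
        bad = sc.RTHTParams(alpha_values=(0.3, 0.3, 0.33, 0.47, 0.6))
        with pytest.raises(ValueError):
            sc.apply_combination(grid, 1.0, 10.0, self.RP, self.HP, bad, oxic_field(grid), rng)
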