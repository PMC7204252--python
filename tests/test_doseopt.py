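"""Effect normalisation, dose-reduction factors and effective IC50."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from tkicombo.doseopt import (
    CombinationDesign,
    dose_reduction_factor,
    effective_ic50,
    mutant_sensitivity_profile,
    normalize_dose,
    normalized_ratio_profile,
    scale_to_effect,
    scan_combination,
)
from tkicombo.errors import InputError
from tkicombo.inhibition import InteractionMode

EX = InteractionMode.EXCLUSIVE
NE = InteractionMode.NONEXCLUSIVE
CONST = np.ones(1000)


class TestScaleToEffect:
    def test_constant_profile_m2_target_01_is_three_ic50(self):
        # 1 / (1 + r^2) = 0.1  =>  r = 3
        assert scale_to_effect(CONST, 0.1, m=2.0) == pytest.approx(3.0, rel=1e-9)

    def test_constant_profile_m1_target_05_is_ic50(self):
        assert scale_to_effect(CONST, 0.5, m=1.0) == pytest.approx(1.0, rel=1e-9)

    def test_pk_profile_scale_matches_bisection_oracle(self, pk_table, norm_potencies):
        im = pk_table["imatinib"]
        pot = norm_potencies["imatinib"]
        scale = normalize_dose(im, pot, effect_target=0.1, m=2.0)
        r = normalized_ratio_profile(im, pot, 0.1, 2.0)
        assert np.mean(1.0 / (1.0 + r ** 2)) == pytest.approx(0.1, abs=1e-9)

        # independent bisection oracle on the same daily profile
        from tkicombo.pk import profile_on_grid
        raw = profile_on_grid(im, 1000).values / pot.ic50

        def effect(s):
            return np.mean(1.0 / (1.0 + (s * raw) ** 2)) - 0.1

        lo, hi = 1e-9, 1e9
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if effect(mid) > 0:
                lo = mid
            else:
                hi = mid
        assert scale == pytest.approx(0.5 * (lo + hi), rel=1e-8)

    def test_unreachable_target_rejected(self):
        with pytest.raises(InputError):
            scale_to_effect(CONST, 1.5)


class TestDoseReductionFactor:
    @pytest.mark.parametrize("x", [0.0, 1.0])
    def test_boundary_ratios_need_no_reduction(self, x):
        assert dose_reduction_factor(x, 3 * CONST, 3 * CONST, NE) == 1.0

    def test_identical_constant_drugs_nonexclusive_matches_quadratic(self):
        # inner term 3 zeta + (3/2)^2 zeta^2 = 3 at x = 0.5
        zeta = dose_reduction_factor(0.5, 3 * CONST, 3 * CONST, NE, m=2.0, effect_target=0.1)
        oracle = brentq(lambda z: 2.25 * z * z + 3 * z - 3, 0, 2, xtol=1e-14)
        assert zeta == pytest.approx(oracle, rel=1e-9)
        assert zeta == pytest.approx(2.0 / 3.0, rel=1e-9)

    def test_dense_grid_scan_oracle(self):
        """Root agrees with a brute-force scan of the effect curve at 1e-4 resolution."""
        r_a = 3 * CONST
        r_b = np.roll(3 * np.linspace(0.5, 1.5, 1000), 500)
        r_b *= scale_to_effect(r_b, 0.1, 2.0)
        zeta = dose_reduction_factor(0.4, r_a, r_b, NE, m=2.0, effect_target=0.1)
        grid = np.arange(1e-4, 1.5, 1e-4)
        effects = [
            np.mean(1.0 / (1.0 + (0.4 * z * r_a + 0.6 * z * r_b + 0.24 * z * z * r_a * r_b) ** 2))
            for z in grid
        ]
        best = grid[np.argmin(np.abs(np.array(effects) - 0.1))]
        assert zeta == pytest.approx(best, abs=1e-4)

    def test_exclusive_identical_profiles_cannot_reduce(self):
        r = 3 * CONST
        for x in (0.1, 0.35, 0.5, 0.8):
            assert dose_reduction_factor(x, r, r, EX) == pytest.approx(1.0, rel=1e-9)

    def test_nonexclusive_beats_exclusive(self, pk_table, norm_potencies):
        r_a = normalized_ratio_profile(pk_table["imatinib"], norm_potencies["imatinib"], 0.1, 2.0)
        r_b = normalized_ratio_profile(pk_table["asciminib"], norm_potencies["asciminib"], 0.1, 2.0)
        z_ex = dose_reduction_factor(0.5, r_a, r_b, EX)
        z_ne = dose_reduction_factor(0.5, r_a, r_b, NE)
        assert z_ne < z_ex


def test_best_zeta_monotone_in_hill_coefficient():
    """Smaller Hill coefficients allow stronger dose reduction."""
    best = []
    for m in (0.5, 1.0, 2.0):
        target_r = scale_to_effect(CONST, 0.1, m)
        r = target_r * CONST
        zetas = [dose_reduction_factor(x, r, r, NE, m=m) for x in np.linspace(0, 1, 11)]
        best.append(min(zetas))
    assert best[0] < best[1] < best[2]


@pytest.fixture(scope="module")
def scan(pk_table, norm_potencies):
    return scan_combination(
        pk_table["imatinib"], norm_potencies["imatinib"],
        pk_table["asciminib"], norm_potencies["asciminib"],
    )


class TestScanCombination:
    def test_surface_shape_and_boundaries(self, scan):
        assert len(scan.table) == 21 * 24
        edges = scan.table[scan.table["dose_ratio"].isin([0.0, 1.0])]
        assert np.allclose(edges["zeta"], 1.0)

    def test_swap_symmetry(self, pk_table, norm_potencies):
        """Swapping the drugs maps x -> 1 - x and offset -> -offset."""
        fwd = scan_combination(
            pk_table["imatinib"], norm_potencies["imatinib"],
            pk_table["asciminib"], norm_potencies["asciminib"],
            n_ratios=5, n_offsets=6,
        ).table
        rev = scan_combination(
            pk_table["asciminib"], norm_potencies["asciminib"],
            pk_table["imatinib"], norm_potencies["imatinib"],
            n_ratios=5, n_offsets=6,
        ).table
        for _, row in fwd.iterrows():
            x, off = row["dose_ratio"], row["offset_h"]
            mirrored = rev[
                (rev["dose_ratio"] == 1.0 - x) & (rev["offset_h"] == (-off) % 24)
            ]
            assert mirrored["zeta"].iloc[0] == pytest.approx(row["zeta"], rel=1e-7)

    def test_grid_argmin_stable_under_refinement(self, scan, pk_table, norm_potencies):
        """A 10x finer scan along each axis stays within one coarse cell."""
        best = scan.best
        fine_x = scan_combination(
            pk_table["imatinib"], norm_potencies["imatinib"],
            pk_table["asciminib"], norm_potencies["asciminib"],
            n_ratios=201, n_offsets=24,
        ).best
        assert abs(fine_x.dose_ratio - best.dose_ratio) <= 0.05
        assert abs(fine_x.administration_offset - best.administration_offset) * 24 <= 1.0


class TestEffectiveIc50:
    def test_pure_drug_limits(self):
        for mode in (EX, NE):
            assert effective_ic50(1.0, 3.0, 7.0, mode) == pytest.approx(3.0)
            assert effective_ic50(0.0, 3.0, 7.0, mode) == pytest.approx(7.0)

    def test_exclusive_even_split_of_equals(self):
        assert effective_ic50(0.5, 4.0, 4.0, EX) == pytest.approx(4.0)

    def test_nonexclusive_even_split_quadratic_root(self):
        # 0.25 C^2 + C - 1 = 0  =>  C = 2 (sqrt(2) - 1)
        got = effective_ic50(0.5, 1.0, 1.0, NE)
        assert got == pytest.approx(2 * (np.sqrt(2) - 1), rel=1e-12)
        oracle = np.roots([0.25, 1.0, -1.0]).max()
        assert got == pytest.approx(oracle, rel=1e-9)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(x=st.floats(0, 1), a=st.floats(0.01, 100), b=st.floats(0.01, 100))
    def test_exclusive_bounds_and_mode_ordering(self, x, a, b):
        ex = effective_ic50(x, a, b, EX)
        ne = effective_ic50(x, a, b, NE)
        assert min(a, b) - 1e-9 <= ex <= max(a, b) + 1e-9
        assert ne <= ex + 1e-9

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(x=st.floats(0.01, 0.99), a=st.floats(0.1, 50), b=st.floats(0.1, 50))
    def test_nonexclusive_root_satisfies_half_effect(self, x, a, b):
        c = effective_ic50(x, a, b, NE)
        inner = c * x / a + c * (1 - x) / b + c * c * x * (1 - x) / (a * b)
        assert inner == pytest.approx(1.0, rel=1e-9)


class TestMutantSensitivity:
    @pytest.fixture
    def design(self):
        return CombinationDesign("drug_a", "drug_b", dose_ratio=0.5,
                                 administration_offset=0.0, mode=NE,
                                 dose_reduction=2.0 / 3.0, effect_target=0.1)

    def test_wildtype_equivalent_mutant(self, design):
        import pandas as pd
        table = pd.DataFrame({"drug_a": [1.0], "drug_b": [1.0]}, index=["WT-like"])
        out = mutant_sensitivity_profile(design, 3 * CONST, 3 * CONST, table)
        assert out.loc["WT-like", "effective_relative_ic50"] == pytest.approx(1.0)
        assert not out.loc["WT-like", "shape_enhanced"]

    def test_single_drug_resistance_interpolates(self):
        import pandas as pd
        design = CombinationDesign("drug_a", "drug_b", 0.5, 0.0, EX, 1.0, 0.1)
        table = pd.DataFrame({"drug_a": [100.0], "drug_b": [1.0]}, index=["res-A"])
        out = mutant_sensitivity_profile(design, 3 * CONST, 3 * CONST, table)
        val = out.loc["res-A", "effective_relative_ic50"]
        assert 1.0 < val < 100.0

    def test_symmetric_moderate_resistance_is_shape_enhanced(self, design):
        """Both drugs ~10x resistant at a 90% target: the reduced-dose combination
        inhibits the mutant less than either full-dose monodrug would."""
        import pandas as pd
        table = pd.DataFrame({"drug_a": [10.0], "drug_b": [10.0]}, index=["res-AB"])
        out = mutant_sensitivity_profile(design, 3 * CONST, 3 * CONST, table)
        assert bool(out.loc["res-AB", "shape_enhanced"])
        # direct check of the criterion with the two monodrug growth values
        fv_mono = 1.0 / (1.0 + 0.3 ** 2)
        x, z = design.dose_ratio, design.dose_reduction
        inner = 0.3 * z + x * (1 - x) * z * z * 0.09
        fv_combo = 1.0 / (1.0 + inner ** 2)
        assert fv_combo > fv_mono

    def test_missing_data_retained_not_dropped(self, design, mutant_table):
        design = CombinationDesign("imatinib", "asciminib", 0.5, 0.0, NE, 0.6, 0.1)
        out = mutant_sensitivity_profile(design, 3 * CONST, 3 * CONST, mutant_table)
        assert set(out.index) == set(mutant_table.index)
        assert out["available"].all()  # both columns complete for this pair
        design_ax = CombinationDesign("axitinib", "asciminib", 0.5, 0.0, NE, 0.6, 0.1)
        out_ax = mutant_sensitivity_profile(design_ax, 3 * CONST, 3 * CONST, mutant_table)
        assert not out_ax.loc["A337V", "available"]
        assert np.isnan(out_ax.loc["A337V", "effective_relative_ic50"])
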