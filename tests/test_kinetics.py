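"""Glucuronidation kinetics: outlier exclusion, rate laws, fitting, scaling."""

import math

import numpy as np
import pytest

from bispbk.fixtures import fit_depletion, generate_depletion_fixture
from bispbk.kinetics import (
    DepletionSeries,
    KineticFit,
    depletion_to_rates,
    fit_michaelis_menten,
    fit_substrate_inhibition,
    michaelis_menten_rate,
    nalimov_filter,
    ontogeny_sfg,
    scale_to_liver,
    select_best_fit,
    substrate_inhibition_rate,
)


class TestNalimov:
    def test_gross_outlier_excluded(self):
        # hand oracle: q(12.0) = 8.25*sqrt(4/3)/5.5006 = 1.732 > 1.645 (n=4, 95%)
        retained, excluded = nalimov_filter([1.0, 1.1, 0.9, 12.0])
        assert excluded == [3]
        assert sorted(retained) == pytest.approx([0.9, 1.0, 1.1])

    def test_constant_sample_keeps_everything(self):
        retained, excluded = nalimov_filter([5.0, 5.0, 5.0, 5.0])
        assert excluded == []
        assert len(retained) == 4

    def test_clean_sample_untouched(self):
        retained, excluded = nalimov_filter([1.0, 1.1, 0.9, 1.05])
        assert excluded == []

    def test_below_minimum_n_rejected(self):
        with pytest.raises(ValueError):
            nalimov_filter([1.0, 2.0])


class TestDepletionToRates:
    def test_forced_arithmetic(self):
        # 10 -> 8 uM over 10 min at 1 mg/mL: rate 0.2 nmol/min/mg at S = 9 uM
        series = DepletionSeries([0.0, 10 / 60], [10.0, 8.0], protein_conc=1.0)
        s, v = depletion_to_rates(series)
        assert s == pytest.approx([9.0])
        assert v == pytest.approx([0.2])

    def test_flat_series_zero_rates(self):
        series = DepletionSeries([0.0, 0.1, 0.2], [5.0, 5.0, 5.0], protein_conc=2.0)
        _, v = depletion_to_rates(series)
        assert np.all(v == 0)

    def test_single_point_rejected(self):
        series = DepletionSeries([0.0], [10.0], protein_conc=1.0)
        with pytest.raises(ValueError):
            depletion_to_rates(series)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            DepletionSeries([0.0, 0.1, 0.1], [3, 2, 1], protein_conc=1.0)


class TestMichaelisMentenFit:
    def test_noiseless_exact_recovery(self):
        s = np.array([1, 2, 5, 10, 25, 50, 100], float)
        v = michaelis_menten_rate(s, 1.0, 5.0)
        fit = fit_michaelis_menten(s, v)
        assert fit.vmax == pytest.approx(1.0, rel=1e-6)
        assert fit.km == pytest.approx(5.0, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_half_vmax_at_km(self):
        s = np.array([1, 2, 5, 10, 25, 50], float)
        fit = fit_michaelis_menten(s, michaelis_menten_rate(s, 2.0, 8.0))
        assert fit.rate(fit.km) == pytest.approx(fit.vmax / 2)

    def test_noisy_fit_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        s = np.array([1, 2, 5, 10, 25, 50, 100, 200], float)
        v = michaelis_menten_rate(s, 1.0, 5.0) * (1 + 0.05 * rng.standard_normal(s.size))
        fit = fit_michaelis_menten(s, v)
        # brute-force SSE grid search as the independent oracle
        vg, kg = np.meshgrid(np.linspace(0.5, 1.5, 401), np.linspace(1, 15, 561))
        sse = ((v[None, None, :] - vg[..., None] * s / (kg[..., None] + s)) ** 2).sum(-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert fit.vmax == pytest.approx(vg[i, j], rel=0.01)
        assert fit.km == pytest.approx(kg[i, j], rel=0.05)

    def test_degenerate_substrate_rejected(self):
        with pytest.raises(ValueError):
            fit_michaelis_menten([5, 5, 5], [1, 1, 1])


class TestSubstrateInhibitionFit:
    def test_noiseless_exact_recovery(self):
        s = np.array([0.5, 1, 2, 5, 10, 25, 50, 100], float)
        v = substrate_inhibition_rate(s, 2.0, 3.0, 50.0)
        fit = fit_substrate_inhibition(s, v)
        assert fit.vmax == pytest.approx(2.0, rel=1e-5)
        assert fit.km == pytest.approx(3.0, rel=1e-5)
        assert fit.ki == pytest.approx(50.0, rel=1e-4)

    def test_large_ki_limit_reproduces_mm(self):
        s = np.linspace(1, 100, 50)
        mm = michaelis_menten_rate(s, 1.0, 5.0)
        si = substrate_inhibition_rate(s, 1.0, 5.0, 1e12)
        assert np.allclose(mm, si, rtol=1e-9)

    def test_curve_maximum_at_sqrt_km_ki(self):
        km, ki = 4.0, 100.0
        s = np.linspace(0.1, 200, 20001)
        v = substrate_inhibition_rate(s, 1.0, km, ki)
        assert s[np.argmax(v)] == pytest.approx(math.sqrt(km * ki), rel=1e-2)

    def test_nested_model_never_fits_worse_than_mm(self):
        rng = np.random.default_rng(7)
        s = np.array([1, 2, 5, 10, 25, 50, 100], float)
        v = michaelis_menten_rate(s, 1.0, 5.0) * (1 + 0.03 * rng.standard_normal(s.size))
        mm = fit_michaelis_menten(s, v)
        si = fit_substrate_inhibition(s, v)
        assert si.r2 >= mm.r2 - 1e-6


class TestSelectBestFit:
    def _fit(self, model, r2):
        ki = 50.0 if model == "substrate_inhibition" else None
        return KineticFit(model, 1.0, 5.0, ki, r2)

    @pytest.mark.parametrize(
        "r2_mm,r2_si,winner",
        [(0.99, 0.95, "MM"), (0.90, 0.97, "substrate_inhibition"), (0.95, 0.95, "MM")],
    )
    def test_max_r2_with_parsimony_tie_break(self, r2_mm, r2_si, winner):
        best = select_best_fit(
            [self._fit("MM", r2_mm), self._fit("substrate_inhibition", r2_si)]
        )
        assert best.model == winner

    def test_all_failed_rejected(self):
        with pytest.raises(ValueError):
            select_best_fit([None, None])


class TestScaling:
    def test_whole_liver_arithmetic(self):
        fit = KineticFit("MM", 1.0, 5.0, None, 1.0, system="human_S9")
        scale_to_liver(fit, liver_mass_g=1800.0)
        assert fit.scaled_vmax_liver == pytest.approx(1.0 * 107.3 * 1800)

    def test_system_mismatch_rejected(self):
        fit = KineticFit("MM", 1.0, 5.0, None, 1.0, system="human_microsome")
        with pytest.raises(ValueError, match="does not match system"):
            scale_to_liver(fit, 1800.0, protein_yield=107.3)

    def test_nonpositive_yield_rejected(self):
        fit = KineticFit("MM", 1.0, 5.0, None, 1.0, system="custom")
        with pytest.raises(ValueError):
            scale_to_liver(fit, 1800.0, protein_yield=0.0)

    @pytest.mark.parametrize(
        "age,adult,expected", [(8.0, 8.0, 1.0), (2.0, 8.0, 0.25)]
    )
    def test_ontogeny_ratio(self, age, adult, expected):
        assert ontogeny_sfg(age, adult) == pytest.approx(expected)

    def test_ontogeny_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ontogeny_sfg(2.0, 0.0)


class TestFullChainRecovery:
    def test_noiseless_chain_recovers_generating_parameters(self):
        # dense sampling keeps the finite-difference bias below 0.1%
        times = tuple(np.arange(0, 10.0001, 0.5) / 60)
        series = generate_depletion_fixture(5.0, 45.0, times=times, noise_sd=0.0)
        fit = fit_depletion(series, try_substrate_inhibition=False)
        assert fit.vmax == pytest.approx(5.0, rel=1e-3)
        assert fit.km == pytest.approx(45.0, rel=1e-3)

    def test_noiseless_si_chain_selects_si(self):
        times = tuple(np.arange(0, 10.0001, 0.25) / 60)
        series = generate_depletion_fixture(
            2.0, 3.0, ki=50.0, s0_levels=(1, 2, 5, 10, 20, 40, 80), times=times
        )
        fit = fit_depletion(series)
        assert fit.model == "substrate_inhibition"
        assert fit.vmax == pytest.approx(2.0, rel=5e-3)
        assert fit.km == pytest.approx(3.0, rel=5e-3)
        assert fit.ki == pytest.approx(50.0, rel=2e-2)
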