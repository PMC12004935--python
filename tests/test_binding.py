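"""Langmuir-Boltzmann binding model: closed forms, inversions, fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vescharge.binding import (
    boltzmann_adjust,
    delta_eps_from_kb,
    fit_charge_law,
    fit_isotherm,
    langmuir_bound,
    per_vesicle_kb,
)
from vescharge.synthetic import GroundTruth, generate_population

from conftest import DOPC_LEVELS, PCPG_LEVELS


class TestLangmuirBound:
    @pytest.mark.parametrize(
        "dna_adj, k_b, dna_max, expected",
        [
            (0.0, 4.7, 0.37, 0.0),
            (1 / 4.7, 4.7, 0.37, 0.37 / 2),          # half-saturation
            (1.0, 4.7, 0.37, 0.37 * 4.7 / 5.7),       # ~0.305 mol %
        ],
    )
    def test_closed_form(self, dna_adj, k_b, dna_max, expected):
        assert langmuir_bound(dna_adj, k_b, dna_max) == pytest.approx(expected, rel=1e-12)

    def test_monotone_saturating(self):
        x = np.logspace(-3, 3, 200)
        y = langmuir_bound(x, 2.0, 0.4)
        assert np.all(np.diff(y) > 0)
        assert y[-1] < 0.4 and y[-1] == pytest.approx(0.4, rel=1e-2)


class TestBoltzmannAdjust:
    def test_zero_energy_identity(self):
        assert boltzmann_adjust(1.7, 0.0) == 1.7

    def test_ln2_halves(self):
        assert boltzmann_adjust(2.0, np.log(2.0)) == pytest.approx(1.0, rel=1e-12)

    def test_effective_constant_identity(self):
        # adjusting the concentration equals scaling the binding constant:
        # Langmuir(free * e^-eps, K_int) == Langmuir(free, K_int * e^-eps)
        free = np.logspace(-2, 1, 7)
        for eps in (0.0, 0.5, 1.75, 3.0):
            via_adjust = langmuir_bound(boltzmann_adjust(free, eps), 4.7, 0.37)
            via_k_eff = langmuir_bound(free, 4.7 * np.exp(-eps), 0.37)
            np.testing.assert_allclose(via_adjust, via_k_eff, rtol=1e-12)


class TestPerVesicleKb:
    def test_zero_bound_gives_zero(self):
        assert per_vesicle_kb(0.0, 0.5, 0.4) == 0.0

    def test_half_saturation_inverse(self):
        assert per_vesicle_kb(0.2, 0.5, 0.4) == pytest.approx(1 / 0.5, rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        k=st.floats(0.01, 50.0),
        x=st.floats(1e-3, 50.0),
        m=st.floats(0.05, 5.0),
    )
    def test_roundtrip_inverts_langmuir(self, k, x, m):
        bound = langmuir_bound(x, k, m)
        assert per_vesicle_kb(bound, x, m) == pytest.approx(k, rel=1e-10)

    def test_saturated_scalar_raises(self):
        with pytest.raises(ValueError, match="saturated"):
            per_vesicle_kb(0.4, 0.5, 0.4)

    def test_array_flags_bad_records_as_nan(self):
        kb = per_vesicle_kb(np.array([0.2, 0.45, 0.1]), np.array([0.5, 0.5, 0.0]), 0.4)
        assert np.isfinite(kb[0])
        assert np.isnan(kb[1]) and np.isnan(kb[2])


def _noise_free_population(k_b, dna_max, levels):
    truth = GroundTruth(n_pg=0.0, k_b_true=k_b, dna_max_true=dna_max,
                        cv_vesicle=0.0, seed=0)
    return generate_population(truth, levels, 5)


class TestFitIsotherm:
    @pytest.mark.parametrize(
        "k_b, dna_max, levels",
        [(4.7, 0.37, DOPC_LEVELS), (0.82, 0.4, PCPG_LEVELS)],
        ids=["zwitterionic", "anionic-1to1"],
    )
    def test_exact_curve_recovery(self, k_b, dna_max, levels):
        pop = _noise_free_population(k_b, dna_max, levels)
        fit = fit_isotherm(pop, n_bootstrap=0, seed=0)
        assert fit.k_b == pytest.approx(k_b, abs=1e-6)
        assert fit.dna_max == pytest.approx(dna_max, abs=1e-6)

    def test_matches_dense_grid_search(self, rng):
        # independent brute-force oracle: 2-parameter grid at 1 % steps
        truth = GroundTruth(k_b_true=2.0, dna_max_true=0.5, cv_vesicle=0.2, seed=5)
        pop = generate_population(truth, [0.2, 0.5, 1.0, 2.0], 50)
        fit = fit_isotherm(pop, n_bootstrap=0, seed=0)

        means = pop.groupby("dna_added_uM")["dna_mem_molpct"].mean()
        x = means.index.to_numpy()
        y = means.to_numpy()
        ks = fit.k_b * np.linspace(0.8, 1.2, 41)
        ms = fit.dna_max * np.linspace(0.8, 1.2, 41)
        sse = np.array(
            [[np.sum((langmuir_bound(x, k, m) - y) ** 2) for m in ms] for k in ks]
        )
        ik, im = np.unravel_index(np.argmin(sse), sse.shape)
        assert ks[ik] == pytest.approx(fit.k_b, rel=0.011)
        assert ms[im] == pytest.approx(fit.dna_max, rel=0.011)

    def test_too_few_levels_raises(self):
        pop = _noise_free_population(4.7, 0.37, [0.2, 1.0])
        with pytest.raises(ValueError, match="3 distinct"):
            fit_isotherm(pop, n_bootstrap=0)

    def test_mean_per_vesicle_kb_matches_population_fit(self):
        # zero noise, zero CV: the per-vesicle inversion and the population
        # isotherm must agree exactly
        pop = _noise_free_population(4.7, 0.37, DOPC_LEVELS)
        fit = fit_isotherm(pop, n_bootstrap=0)
        kb_i = per_vesicle_kb(
            pop["dna_mem_molpct"].to_numpy(), pop["dna_free_uM"].to_numpy(), fit.dna_max
        )
        assert np.nanmean(kb_i) == pytest.approx(fit.k_b, abs=1e-6)

    def test_le_chatelier_bound_increases_with_added(self, dopc_population):
        means = dopc_population.groupby("dna_added_uM")["dna_mem_molpct"].mean()
        assert means.is_monotonic_increasing


class TestChargeLaw:
    def test_exact_exponential_recovery(self):
        n_pg = np.array([0.0, 0.1, 0.25, 0.375, 0.5])
        kb = 4.7 * np.exp(-3.2 * n_pg)
        law = fit_charge_law(n_pg, kb)
        assert law.b == pytest.approx(3.2, abs=1e-9)
        assert law.k_b0 == pytest.approx(4.7, abs=1e-9)

    def test_e_fold_over_half_gives_two(self):
        n_pg = np.array([0.0, 0.25, 0.5])
        kb = 3.0 * np.exp(-2.0 * n_pg)  # K(0.5) = K0 / e
        law = fit_charge_law(n_pg, kb)
        assert law.b == pytest.approx(2.0, abs=1e-9)

    def test_log_linear_equals_nonlinear_fit(self):
        from scipy.optimize import curve_fit

        n_pg = np.array([0.0, 0.1, 0.25, 0.375, 0.5])
        kb = 5.1 * np.exp(-2.7 * n_pg)
        law = fit_charge_law(n_pg, kb)
        popt, _ = curve_fit(lambda x, k0, b: k0 * np.exp(-b * x), n_pg, kb,
                            p0=(1.0, 1.0))
        assert law.k_b0 == pytest.approx(popt[0], rel=1e-6)
        assert law.b == pytest.approx(popt[1], abs=1e-6)

    def test_nonpositive_kb_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_charge_law([0.0, 0.2, 0.4], [1.0, 0.0, -0.5])

    def test_requires_zero_reference(self):
        with pytest.raises(ValueError, match="n_PG = 0"):
            fit_charge_law([0.1, 0.25, 0.5], [1.0, 0.8, 0.5])


class TestDeltaEps:
    def test_reference_is_zero(self):
        assert delta_eps_from_kb(3.3, 3.3).delta_eps_kT == 0.0

    def test_e_fold_is_one_kT(self):
        est = delta_eps_from_kb(3.3 / np.e, 3.3)
        assert est.delta_eps_kT == pytest.approx(1.0, rel=1e-12)

    def test_anionic_vs_zwitterionic_reference_values(self):
        # the measured order-of-magnitude K_B drop corresponds to ~1.75 kT
        est = delta_eps_from_kb(0.82, 4.7)
        assert est.delta_eps_kT == pytest.approx(np.log(4.7 / 0.82), rel=1e-12)
        assert est.delta_eps_kT == pytest.approx(1.746, abs=5e-4)

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            delta_eps_from_kb(-1.0, 2.0)


def test_fitted_kb_monotone_in_anionic_fraction():
    """Synthetic populations with increasing n_PG yield decreasing K_B."""
    n_pg = [0.0, 0.1, 0.25, 0.375, 0.5]
    fitted = []
    for i, n in enumerate(n_pg):
        truth = GroundTruth(n_pg=n, k_b_true=4.7 * np.exp(-3.2 * n),
                            dna_max_true=0.4, cv_vesicle=0.2, seed=100 + i)
        pop = generate_population(truth, [0.1, 0.3, 1.0, 3.0], 150)
        fitted.append(fit_isotherm(pop, n_bootstrap=0, seed=0).k_b)
    assert np.all(np.diff(fitted) < 0)


def test_dna_max_stable_across_compositions():
    """Equal true saturation at n_PG 0 and 0.5 is recovered within joint CIs."""
    fits = []
    # each composition is titrated over a grid bracketing its own 1/K_B
    for n, k, seed, levels in [(0.0, 4.7, 7, DOPC_LEVELS),
                               (0.5, 0.95, 8, PCPG_LEVELS)]:
        truth = GroundTruth(n_pg=n, k_b_true=k, dna_max_true=0.4,
                            cv_vesicle=0.3, seed=seed)
        pop = generate_population(truth, levels, 200)
        fits.append(fit_isotherm(pop, n_bootstrap=100, seed=seed))
    diff = abs(fits[0].dna_max - fits[1].dna_max)
    joint = np.hypot(fits[0].se_dna_max, fits[1].se_dna_max)
    assert diff < 3 * joint
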