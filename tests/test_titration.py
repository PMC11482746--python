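import math

import numpy as np
import pytest
from scipy.special import logsumexp

import medoc as m
from medoc.pipeline import random_instance
from medoc.sequence import Mesostate
from medoc.thermo import LN10


def single_site_mesostates(pka, thermo):
    return [
        Mesostate(n_released=0, net_charge=0, G=0.0),
        Mesostate(n_released=1, net_charge=-1, G=thermo.pka_to_energy(pka)),
    ]


class TestPHFreeEnergy:
    def test_reference_mesostate_is_ph_independent(self, thermo):
        assert m.pH_free_energy(2.5, 0, 7.0, thermo) == 2.5

    def test_henderson_hasselbalch_midpoint(self, thermo):
        meso = single_site_mesostates(6.0, thermo)
        pops = m.mesostate_populations(meso, 6.0, thermo)
        assert pops[0] == pytest.approx(0.5, rel=1e-12)

    def test_one_unit_above_pka(self, thermo):
        meso = single_site_mesostates(6.0, thermo)
        pops = m.mesostate_populations(meso, 7.0, thermo)
        assert pops[0] == pytest.approx(1 / 11, rel=1e-10)


class TestMesostatePopulations:
    def test_no_sites(self, thermo):
        pops = m.mesostate_populations([Mesostate(0, 0, 0.0)], 7.0, thermo)
        assert pops.tolist() == [1.0]

    def test_equal_ph_dependent_free_energies_split_evenly(self, thermo):
        # two mesostates tuned to be isoenergetic at pH 5
        meso = [Mesostate(0, 0, 0.0), Mesostate(1, -1, thermo.pka_to_energy(5.0))]
        pops = m.mesostate_populations(meso, 5.0, thermo)
        assert np.allclose(pops, [0.5, 0.5], atol=1e-12)

    def test_matches_brute_force_boltzmann(self, rng, thermo):
        rec, db = random_instance(rng, max_sites=9)
        ens = m.brute_force_ensemble(db, rec)
        meso = m.global_mesostate_free_energies(db, rec, thermo).mesostates
        for pH in np.linspace(1, 13, 10):
            logw = -ens.G / thermo.RT + LN10 * pH * ens.n_released
            w = np.exp(logw - logsumexp(logw))
            ref = np.bincount(ens.n_released, weights=w, minlength=rec.n_sites + 1)
            got = m.mesostate_populations(meso, pH, thermo)
            assert got.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.allclose(got, ref, atol=1e-10)


class TestGlobalCurves:
    def test_low_ph_limit_fully_protonated(self, coupled_db, thermo):
        rec = m.parse_sequence("s", "EKDEH")
        meso = m.global_mesostate_free_energies(coupled_db, rec, thermo).mesostates
        f_tot, net = m.global_curves(meso, rec, [-6.0], thermo)
        assert f_tot[0] == pytest.approx(1.0, abs=1e-8)
        assert net[0] == pytest.approx(rec.q_max, abs=1e-7)

    def test_mean_released_protons_monotone(self, rng, thermo):
        grid = np.linspace(0, 14, 57)
        for _ in range(8):
            rec, db = random_instance(rng, max_sites=10)
            meso = m.global_mesostate_free_energies(db, rec, thermo).mesostates
            _, net = m.global_curves(meso, rec, grid, thermo)
            released = rec.q_max - net
            assert np.all(np.diff(released) >= -1e-10)

    def test_single_glu_midpoint_charge(self, zero_db, thermo):
        rec = m.parse_sequence("s", "E")
        meso = m.global_mesostate_free_energies(zero_db, rec, thermo).mesostates
        _, net = m.global_curves(meso, rec, [4.34], thermo)
        assert net[0] == pytest.approx(-0.5, rel=1e-10)

    def test_no_sites_emits_warning_and_empty_f(self, thermo):
        rec = m.parse_sequence("s", "GGG")
        with pytest.warns(UserWarning, match="no ionizable sites"):
            f_tot, net = m.global_curves([Mesostate(0, 0, 0.0)], rec, [7.0], thermo)
        assert f_tot.size == 0


class TestSiteCurves:
    def test_zero_coupling_sites_are_henderson_hasselbalch(self, flat_db, thermo):
        rec = m.parse_sequence("s", "DEKH")
        res = m.site_mesostate_free_energies(flat_db, rec, thermo)
        grid = np.linspace(0, 14, 29)
        fractions = m.site_curves(res, grid, thermo)
        for p, site in enumerate(rec.sites):
            pka = thermo.energy_to_pka(flat_db.intrinsic[site.residue_type])
            hh = 1.0 / (1.0 + 10 ** (grid - pka))
            assert np.allclose(fractions[p], hh, atol=1e-12)

    def test_matches_brute_force_site_average(self, rng, thermo):
        rec, db = random_instance(rng, max_sites=9)
        res = m.site_mesostate_free_energies(db, rec, thermo)
        grid = np.linspace(1, 13, 10)
        fractions = m.site_curves(res, grid, thermo)
        ens = m.brute_force_ensemble(db, rec)
        logw = -ens.G / thermo.RT + LN10 * np.outer(grid, ens.n_released)
        w = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
        ref = (w @ (1 - ens.states)).T
        assert np.allclose(fractions, ref, atol=1e-10)

    def test_released_proton_accounting_identity(self, coupled_db, thermo):
        """Sum over sites of (1 - fraction protonated) equals the mean number
        of released protons at every pH."""
        rec = m.parse_sequence("s", "EEKDHC")
        res = m.site_mesostate_free_energies(coupled_db, rec, thermo)
        grid = np.linspace(0, 14, 29)
        fractions = m.site_curves(res, grid, thermo)
        meso = [Mesostate(q, rec.q_max - q, g) for q, g in enumerate(res.global_G)]
        _, net = m.global_curves(meso, rec, grid, thermo)
        released = rec.q_max - net
        assert np.allclose((1 - fractions).sum(axis=0), released, atol=1e-10)


class TestApparentPKa:
    def test_isolated_site(self, zero_db, thermo):
        rec = m.parse_sequence("s", "E")
        res = m.compute_titration(zero_db, rec, thermo=thermo)
        pka = res.apparent_pKas[0]
        assert not pka.nonsigmoidal
        assert pka.value == pytest.approx(4.34, abs=1e-6)

    def test_uniform_destabilization_shifts_pka(self, thermo):
        """Destabilizing the deprotonated state by delta shifts the apparent
        pKa by delta / (RT ln 10)."""
        grid = m.DEFAULT_PH_GRID
        delta = 0.8  # kcal/mol
        for pka0 in (4.0, 9.0):
            g = thermo.pka_to_energy(pka0)
            curve0 = 1 / (1 + np.exp(-(g - thermo.RT * LN10 * grid) / thermo.RT))
            curve1 = 1 / (1 + np.exp(-(g + delta - thermo.RT * LN10 * grid) / thermo.RT))
            shift = m.apparent_pKa(curve1, grid).value - m.apparent_pKa(curve0, grid).value
            assert shift == pytest.approx(delta / (thermo.RT * LN10), abs=1e-6)

    def test_monotone_single_crossing_not_flagged(self):
        grid = np.linspace(0, 14, 141)
        curve = 1 / (1 + 10 ** (grid - 7.0))
        res = m.apparent_pKa(curve, grid)
        assert not res.nonsigmoidal and res.n_crossings == 1

    def test_multiple_crossings_flagged_median(self):
        grid = np.linspace(0, 14, 281)
        # synthetic wiggly curve crossing 0.5 three times
        curve = 0.5 + 0.4 * np.cos(LN10 * (grid - 7.0)) * np.exp(-0.1 * (grid - 7) ** 2)
        res = m.apparent_pKa(curve, grid)
        assert res.nonsigmoidal
        assert res.n_crossings >= 3
        assert res.value is not None

    def test_no_crossing_flagged_without_value(self):
        grid = np.linspace(0, 6, 20)
        res = m.apparent_pKa(np.full(20, 0.9), grid)
        assert res.value is None and res.nonsigmoidal


class TestChargeHeterogeneity:
    def test_single_mesostate_zero_variance(self, thermo):
        var, _ = m.charge_heterogeneity(
            [Mesostate(0, 0, 0.0)], m.parse_sequence("s", "G"), 7.0, thermo
        )
        assert var == pytest.approx(0.0, abs=1e-12)

    def test_single_site_midpoint_variance(self, zero_db, thermo):
        rec = m.parse_sequence("s", "E")
        meso = m.global_mesostate_free_energies(zero_db, rec, thermo).mesostates
        var, slope = m.charge_heterogeneity(meso, rec, 4.34, thermo)
        assert var == pytest.approx(0.25, rel=1e-9)  # Bernoulli(1/2)
        assert slope < 0  # acids lose charge as pH rises


def test_compute_titration_normalization_and_consistency(coupled_db, thermo):
    rec = m.parse_sequence("s", "EDKH")
    res = m.compute_titration(coupled_db, rec, thermo=thermo, mode="both")
    assert np.allclose(res.mesostate_populations.sum(axis=1), 1.0, atol=1e-12)
    assert np.all((res.f_tot >= 0) & (res.f_tot <= 1))
    assert np.all(res.net_charge <= rec.q_max + 1e-9)
    assert np.all(res.net_charge >= rec.q_min - 1e-9)
    assert np.all((res.site_fraction_protonated >= 0) & (res.site_fraction_protonated <= 1))
    # frames are well-formed
    assert len(res.global_frame()) == len(res.pH_grid)
    assert len(res.site_frame()) == rec.n_sites * len(res.pH_grid)
    assert len(res.summary_frame()) == rec.n_sites
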