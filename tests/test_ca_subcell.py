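"""Subcellular Ca cycling: release law, stochastic uptake, conservation and
sarcomere-chain coupling."""

import numpy as np
import pytest

from discordans._engine import Lattice
from discordans._params import NOISE_FRAME_MS
from discordans.ca_subcell import (CaCyclingParams, CellCaState,
                                   SarcomereCaState, cell_ca_step,
                                   ryr_release_flux, sarcomere_step,
                                   serca_uptake)

from conftest import pace_lattice


class TestRyrReleaseFlux:
    def test_empty_jsr_releases_nothing(self, ca_quiet):
        s = SarcomereCaState(c_jsr=0.0)
        assert ryr_release_flux(s, 0.1, ca_quiet) == 0.0

    def test_fully_refractory_releases_nothing(self, ca_quiet):
        s = SarcomereCaState(r_gate=0.0)
        assert ryr_release_flux(s, 0.1, ca_quiet) == 0.0

    def test_no_trigger_no_release(self, ca_quiet):
        s = SarcomereCaState(c_jsr=150.0)
        assert ryr_release_flux(s, 0.0, ca_quiet) == 0.0

    def test_negative_trigger_rejected(self, ca_quiet):
        with pytest.raises(ValueError):
            ryr_release_flux(SarcomereCaState(), -1.0, ca_quiet)

    def test_monotone_sigmoid_in_load_steeper_with_gain(self, ca_quiet):
        """Tabulated flux over a JSR-load grid rises monotonically, and the
        high/low-load flux ratio grows with the release gain u."""
        grid = np.linspace(20.0, 300.0, 60)
        ratios = []
        for u in (1.5, 3.0, 4.0, 6.0):
            p = ca_quiet.with_(u_release=u)
            flux = np.array([
                ryr_release_flux(SarcomereCaState(c_jsr=cj), 0.2, p)
                for cj in grid])
            assert np.all(np.diff(flux) >= 0)
            ratios.append(flux[-1] / flux[5])
        assert np.all(np.diff(ratios) > 0)


class TestSercaUptake:
    def test_no_substrate_no_flux_no_noise(self, ca_quiet):
        assert serca_uptake(0.0, ca_quiet, dt=0.1, rng_draw=3.0) == 0.0

    def test_nonpositive_dt_rejected(self, ca):
        with pytest.raises(ValueError):
            serca_uptake(0.5, ca, dt=0.0)

    def test_noise_off_returns_hill_flux_exactly(self, ca_quiet):
        c = 0.5
        expect = ca_quiet.v_up_max * c**2 / (ca_quiet.k_up**2 + c**2)
        assert serca_uptake(c, ca_quiet, rng_draw=5.0) == expect

    def test_sample_mean_matches_deterministic_flux(self, ca):
        """Monte-Carlo mean over 1e5 draws equals J_det within 3 SE."""
        rng = np.random.default_rng(7)
        c = 0.4
        draws = rng.standard_normal(100_000)
        samples = np.array([serca_uptake(c, ca, 0.1, x) for x in draws[:200]])
        # vectorised equivalent for the full sample
        jdet = ca.v_up_max * c**2 / (ca.k_up**2 + c**2)
        full = jdet * (1.0 + ca.sigma_step * draws)
        se = full.std() / np.sqrt(len(full))
        assert abs(full.mean() - jdet) < 3 * se
        assert np.allclose(samples, jdet * (1.0 + ca.sigma_step * draws[:200]))

    def test_variance_scales_inversely_with_pump_count(self, ca):
        """Doubling n_pumps halves the uptake variance (Monte-Carlo)."""
        rng = np.random.default_rng(11)
        draws = rng.standard_normal(50_000)
        c = 0.4
        var = []
        for n in (ca.n_pumps, 2 * ca.n_pumps):
            p = ca.with_(n_pumps=n)
            jdet = p.v_up_max * c**2 / (p.k_up**2 + c**2)
            var.append(np.var(jdet * (1.0 + p.sigma_step * draws)))
        assert var[0] / var[1] == pytest.approx(2.0, rel=0.01)

    def test_dt_scaling_keeps_integrated_fluctuation_consistent(self, ca):
        """std ∝ 1/sqrt(dt): the per-step fluctuation integrates to a
        dt-independent variance (Euler–Maruyama consistency)."""
        s1 = serca_uptake(0.4, ca, dt=0.1, rng_draw=1.0)
        s2 = serca_uptake(0.4, ca, dt=0.025, rng_draw=1.0)
        jdet = serca_uptake(0.4, ca.with_(noise_source="none"), dt=0.1)
        assert (s2 - jdet) == pytest.approx(2.0 * (s1 - jdet), rel=1e-9)


def total_ca(cell, p):
    return cell.total_ca(p)


class TestSarcomereStep:
    def test_equilibrated_state_is_a_fixed_point(self, ion, ca_quiet):
        """With membrane fluxes off the Ca subsystem relaxes to an internal
        equilibrium that a further step leaves unchanged to tolerance."""
        from discordans._params import free_from_total
        lat = Lattice(ion, ca_quiet, m=1, seed=0, fixed_dt=0.1)
        for _ in range(40_000):
            lat.step_one_frame(mem_flux=0.0)
        s = SarcomereCaState(
            c_i=float(free_from_total(lat.ci[0, 0], ca_quiet.buf_b,
                                      ca_quiet.buf_k)),
            c_s=float(free_from_total(lat.cs[0, 0], ca_quiet.buf_b,
                                      ca_quiet.buf_k)),
            c_nsr=float(lat.cnsr[0, 0]), c_jsr=float(lat.cjsr[0, 0]),
            r_gate=float(lat.rgate[0, 0]), q_rel=float(lat.qrel[0, 0]))
        s2 = sarcomere_step(s, -85.0, ca_quiet, dt=0.1, ion=ion,
                            membrane_fluxes=False)
        for f in ("c_i", "c_s", "c_nsr", "c_jsr"):
            assert getattr(s2, f) == pytest.approx(getattr(s, f), rel=1e-6)

    def test_total_ca_conserved_without_membrane_fluxes(self, ion, ca_quiet):
        s = SarcomereCaState(c_i=0.4, c_s=1.2, c_nsr=150.0, c_jsr=90.0,
                             r_gate=0.7, q_rel=0.05)
        cell = CellCaState.uniform(1, s)
        t0 = total_ca(cell, ca_quiet)
        out = cell_ca_step(cell, -20.0, ca_quiet, dt=0.1, ion=ion,
                           membrane_fluxes=False)
        assert total_ca(out, ca_quiet) == pytest.approx(t0, rel=1e-10)

    def test_dt_outside_adaptive_range_rejected(self, ion, ca_quiet):
        with pytest.raises(ValueError):
            sarcomere_step(SarcomereCaState(), -85.0, ca_quiet, dt=0.5,
                           ion=ion)

    def test_dt_refinement_changes_transient_peak_below_one_percent(
            self, ion, ca_quiet):
        """Halving the step changes the one-beat Ca-transient peak < 1%."""
        peaks = {}
        for dt in (0.1, 0.05):
            lat = Lattice(ion, ca_quiet, m=1, seed=0, fixed_dt=dt)
            pk = pace_lattice(lat, 600.0, 25)
            peaks[dt] = pk[-1, 0, 0]
        assert abs(peaks[0.05] - peaks[0.1]) / peaks[0.05] < 0.01


class TestCellCaStep:
    def test_uniform_chain_stays_uniform(self, ion, ca_quiet):
        """Noise off + identical sarcomeres: the diffusive exchange cancels
        exactly and all sarcomeres remain bitwise identical."""
        cell = CellCaState.uniform(20, SarcomereCaState(c_jsr=140.0))
        out = cell
        for _ in range(200):
            out = cell_ca_step(out, -20.0, ca_quiet, dt=0.1, ion=ion)
        for f in ("c_i", "c_s", "c_nsr", "c_jsr"):
            arr = getattr(out, f)
            assert np.all(arr == arr[0])

    def test_total_cell_ca_conserved_with_perturbed_profile(self, ion,
                                                            ca_quiet):
        cell = CellCaState.uniform(15, SarcomereCaState(c_nsr=120.0,
                                                        c_jsr=120.0))
        cell.c_i[4] += 3.0
        cell.c_nsr[9] += 40.0
        t0 = total_ca(cell, ca_quiet)
        out = cell
        for _ in range(50):
            out = cell_ca_step(out, -85.0, ca_quiet, dt=0.1, ion=ion,
                               membrane_fluxes=False)
        assert total_ca(out, ca_quiet) == pytest.approx(t0, rel=1e-9)

    def test_perturbation_spreads_at_the_configured_diffusivity(self, ion,
                                                                ca_quiet):
        """A point release of cytosolic Ca spreads with variance growing as
        2 D_eff t where D_eff = dx²/tau_diff_cyto on the sarcomere lattice."""
        # quiet all reactions so only the diffusive exchange acts
        p = ca_quiet.with_(v_up_max=1e-12, g_sr_leak=1e-15, tau_tr=1e9,
                           tau_sm=1e9, buf_b=1e-9)
        m = 61
        cell = CellCaState.uniform(m, SarcomereCaState(c_i=0.0, c_s=0.0,
                                                       c_nsr=0.0, c_jsr=0.0))
        cell.c_i[m // 2] = 1.0
        out = cell
        n_steps, dt = 300, 0.1
        for _ in range(n_steps):
            out = cell_ca_step(out, -85.0, p, dt=dt, ion=ion,
                               membrane_fluxes=False)
        x = np.arange(m, dtype=float)
        w = out.c_i / out.c_i.sum()
        var = np.sum(w * (x - m // 2) ** 2)
        d_lattice = 1.0 / p.tau_diff_cyto  # sarcomere² per ms
        # discrete random walk: variance = 2 D t (lattice units)
        assert var == pytest.approx(2 * d_lattice * n_steps * dt, rel=0.05)


class TestConservationLongRun:
    def test_no_drift_over_one_hundred_thousand_steps(self, ion, ca_quiet):
        """Membrane fluxes and noise off: total cell Ca is constant to a
        relative drift far below 1e-6 over 1e5 steps."""
        lat = Lattice(ion, ca_quiet, m=5, seed=0, fixed_dt=0.1)
        lat.cjsr[...] = 140.0
        lat.cnsr[...] = 100.0
        p = ca_quiet

        def tot():
            from discordans._params import free_from_total
            ci = lat.ci.sum()
            cs = lat.cs.sum()
            return ci + p.nu_s * cs + p.nu_n * lat.cnsr.sum() \
                + p.nu_j * lat.cjsr.sum()

        t0 = tot()
        for _ in range(100_000):
            lat.step_one_frame(mem_flux=0.0)
        assert abs(tot() - t0) / t0 < 1e-9
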