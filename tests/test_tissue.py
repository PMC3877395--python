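"""Cable/sheet electrotonics: operator splitting, diffusion limits,
decoupling, conduction velocity, and the shared-voltage multi-cell group."""

import numpy as np
import pytest

from discordans._engine import Lattice
from discordans.analytics import activation_map, apd80
from discordans.ca_subcell import CellCaState, SarcomereCaState
from discordans.membrane import MembraneState
from discordans.tissue import (PropagationError, TissueGeometry, TissueState,
                               measure_cv, multicell_step, tissue_step)

from conftest import pace_lattice


def quiet_ion(ion):
    """Membrane with all reactions effectively off below threshold."""
    return ion.with_(tau_0=1e12, g_ncx_v=0.0)


class TestGeometry:
    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            TissueGeometry(dims=3).validate()
        with pytest.raises(ValueError):
            TissueGeometry(dims=1, n_x=0).validate()
        with pytest.raises(ValueError):
            TissueGeometry(dims=1, n_y=4).validate()


class TestDiffusionSubstep:
    def test_uniform_voltage_unaffected_by_diffusion(self, ion, ca_quiet):
        """The Laplacian of a constant field is zero: with and without
        electrotonic coupling a uniform cable evolves identically."""
        states = []
        for d_v in (0.0, 1e-3):
            ts = TissueState(TissueGeometry(dims=1, n_x=12, d_v=d_v),
                             ion=ion, ca=ca_quiet, m=1, seed=0,
                             fixed_dt=0.05)
            tissue_step(ts, n_frames=200)
            states.append(ts.lattice.V.copy())
        assert (states[0] == states[1]).all()

    def test_gaussian_bump_variance_grows_as_2dt(self, ion, ca_quiet):
        """Sub-threshold voltage diffuses as a pure heat kernel: the spatial
        variance of a Gaussian bump grows by 2 D_v t within 1%."""
        g = TissueGeometry(dims=1, n_x=301, d_v=1e-3)
        ts = TissueState(g, ion=quiet_ion(ion), ca=ca_quiet, m=1, seed=0,
                         fixed_dt=0.05)
        lat = ts.lattice
        x = np.arange(g.n_x) * g.dx
        x0, sig0 = x[g.n_x // 2], 0.03
        lat.V[:] = ion.v_rest + 8.0 * np.exp(-(x - x0) ** 2 / (2 * sig0 ** 2))
        t_run = 40.0
        tissue_step(ts, n_frames=int(t_run / 0.1))
        w = lat.V - ion.v_rest
        w /= w.sum()
        var = np.sum(w * (x - np.sum(w * x)) ** 2)
        assert var - sig0 ** 2 == pytest.approx(2 * g.d_v * t_run, rel=0.01)

    def test_integral_of_v_conserved_by_the_diffusion_substep(self):
        """Zero-flux boundaries: the diffusion substep conserves ∫V dx
        exactly, in 1D (FTCS) and 2D (ADI)."""
        from discordans import _kernels
        rng = np.random.default_rng(0)
        v = rng.uniform(-85.0, -60.0, 80)
        q0 = v.sum()
        work = np.empty_like(v)
        for _ in range(300):
            _kernels._diffuse_v_1d(v, 1e-3, 0.015, 0.1, work)
        assert v.sum() == pytest.approx(q0, rel=1e-13)
        nx, ny = 12, 9
        v2 = rng.uniform(-85.0, -60.0, nx * ny)
        q0 = v2.sum()
        vhalf = np.empty_like(v2)
        line = np.empty(max(nx, ny))
        for _ in range(200):
            _kernels._diffuse_v_adi(v2, nx, ny, 1e-3, 0.015, 0.1, vhalf,
                                    line.copy(), line.copy(), line.copy(),
                                    line.copy())
        assert v2.sum() == pytest.approx(q0, rel=1e-12)

    def test_2d_adi_matches_1d_profile_for_a_planar_field(self, ion,
                                                          ca_quiet):
        """A y-uniform field in 2D must evolve exactly like the 1D cable."""
        n = 40
        ts1 = TissueState(TissueGeometry(dims=1, n_x=n, d_v=1e-3),
                          ion=quiet_ion(ion), ca=ca_quiet, m=1, seed=0,
                          fixed_dt=0.05)
        ts2 = TissueState(TissueGeometry(dims=2, n_x=n, n_y=6, d_v=1e-3),
                          ion=quiet_ion(ion), ca=ca_quiet, m=1, seed=0,
                          fixed_dt=0.05)
        prof = ion.v_rest + 8.0 * np.exp(-((np.arange(n) - n / 2) / 5.0) ** 2)
        ts1.lattice.V[:] = prof
        ts2.lattice.V[:] = np.tile(prof, 6)
        tissue_step(ts1, n_frames=300)
        tissue_step(ts2, n_frames=300)
        assert np.allclose(ts2.v[3], ts1.lattice.V, atol=1e-3)


class TestDecouplingLimit:
    def test_zero_coupling_reproduces_isolated_cells_bitwise(self, ion, ca):
        """D_v = 0 tissue with per-cell noise streams equals the same cells
        run in isolation, bitwise (same seed, same fixed step)."""
        n = 3
        ts = TissueState(TissueGeometry(dims=1, n_x=n, d_v=0.0), ion=ion,
                         ca=ca, m=5, seed=42, fixed_dt=0.1)
        for _ in range(4):
            ts.lattice.run_beat(300.0, stim_amp=40.0, collect_v=False)
        for i in range(n):
            solo = Lattice(ion, ca, m=5, seed=42, cell_index0=i,
                           fixed_dt=0.1)
            for _ in range(4):
                solo.run_beat(300.0, stim_amp=40.0, collect_v=False)
            assert (solo.V[0] == ts.lattice.V[i])
            assert (solo.ci[0] == ts.lattice.ci[i]).all()
            assert (solo.cjsr[0] == ts.lattice.cjsr[i]).all()


class TestConductionVelocity:
    def _cv(self, ion, ca_quiet, d_v, n=80, right=False):
        ts = TissueState(TissueGeometry(dims=1, n_x=n, d_v=d_v), ion=ion,
                         ca=ca_quiet, m=1, seed=0)
        stim = np.zeros(n)
        idx = slice(-3, None) if right else slice(0, 3)
        stim[idx] = 40.0
        v_hist = []
        for f in range(1200):
            ts.lattice.step_one_frame(stim=stim if f < 10 else None)
            if f % 10 == 0:
                v_hist.append(ts.lattice.V.copy())
        act = activation_map(np.array(v_hist), dt_ms=1.0)
        return measure_cv(act, ts.geometry.dx)

    def test_left_and_right_edge_pacing_give_equal_cv(self, ion, ca_quiet):
        cv_l = self._cv(ion, ca_quiet, 1e-3)
        cv_r = self._cv(ion, ca_quiet, 1e-3, right=True)
        assert cv_l == pytest.approx(cv_r, rel=1e-6)

    def test_cv_scales_as_sqrt_of_coupling(self, ion, ca_quiet):
        """Cable theory: CV ∝ sqrt(D_v); doubling D_v gives ×sqrt(2)
        within 5%."""
        cv1 = self._cv(ion, ca_quiet, 5e-4)
        cv2 = self._cv(ion, ca_quiet, 1e-3)
        assert cv2 / cv1 == pytest.approx(np.sqrt(2.0), rel=0.05)

    def test_planar_wave_in_2d_matches_1d_cv(self, ion, ca_quiet):
        cv1 = self._cv(ion, ca_quiet, 1e-3, n=60)
        n, ny = 60, 8
        ts = TissueState(TissueGeometry(dims=2, n_x=n, n_y=ny, d_v=1e-3),
                         ion=ion, ca=ca_quiet, m=1, seed=0)
        stim = np.zeros((ny, n))
        stim[:, :3] = 40.0
        v_hist = []
        for f in range(1200):
            ts.lattice.step_one_frame(stim=stim.ravel() if f < 10 else None)
            if f % 10 == 0:
                v_hist.append(ts.v[ny // 2].copy())
        act = activation_map(np.array(v_hist), dt_ms=1.0)
        cv2 = measure_cv(act, ts.geometry.dx)
        assert cv2 == pytest.approx(cv1, rel=0.02)

    def test_no_propagation_raises(self):
        with pytest.raises(PropagationError):
            measure_cv(np.full(50, np.nan), 0.015)


class TestTimestepConvergence:
    def test_halving_dt_changes_apd_below_half_ms(self, ion, ca_quiet):
        apds = {}
        for dt in (0.1, 0.05):
            lat = Lattice(ion, ca_quiet, m=1, seed=0, fixed_dt=dt)
            for _ in range(20):
                rec = lat.run_beat(600.0, stim_amp=40.0)
            apds[dt] = apd80(rec["v"][:, 0], 1.0)
        assert abs(apds[0.1] - apds[0.05]) < 0.5


class TestMulticell:
    def test_group_size_bounds(self, ion, ca_quiet):
        cells = [CellCaState.uniform(3)]
        with pytest.raises(ValueError):
            multicell_step(cells, MembraneState(), ion=ion, ca=ca_quiet)

    def test_identical_cells_match_single_cell_voltage(self, ion, ca_quiet):
        """N identical cells sharing a membrane produce exactly the single
        cell's voltage trajectory (the averaged currents coincide)."""
        m = 5
        single = Lattice(ion, ca_quiet, m=m, seed=0, fixed_dt=0.1)
        group = Lattice(ion, ca_quiet, m=m, cells_per_site=3, seed=0,
                        fixed_dt=0.1)
        for _ in range(2):
            single.run_beat(400.0, stim_amp=40.0, collect_v=False)
            group.run_beat(400.0, stim_amp=40.0, collect_v=False)
        assert single.V[0] == pytest.approx(group.V[0], abs=1e-9)

    def test_opposite_phase_pair_cancels_in_the_voltage(self, ion, ca_quiet):
        """Two cells initialised in exactly opposite alternans phase with
        equal amplitude: their Ca-sensitive currents cancel, so the shared
        APD shows no alternans initially."""
        lat = Lattice(ion, ca_quiet, m=5, seed=0)
        pace_lattice(lat, 300.0, 40)
        lat.cjsr[...] *= 1.05   # seed the (deterministic) alternans
        pace_lattice(lat, 300.0, 90)
        snapA = lat.snapshot()
        lat.run_beat(300.0, stim_amp=40.0, collect_v=False)
        snapB = lat.snapshot()
        group = Lattice(ion, ca_quiet, m=5, cells_per_site=2, seed=0)
        for f in ("ci", "cs", "cnsr", "cjsr", "rgate", "qrel"):
            getattr(group, f)[0, :5] = snapA[f][0]
            getattr(group, f)[0, 5:] = snapB[f][0]
        group.V[:] = snapB["V"]
        group.vgate[:] = snapB["vgate"]
        group.wgate[:] = snapB["wgate"]
        group.fgate[:] = snapB["fgate"]
        apds = []
        for _ in range(8):
            rec = group.run_beat(300.0, stim_amp=40.0)
            apds.append(apd80(rec["v"][:, 0], 1.0))
        da = np.abs(np.diff(apds)).mean() / 2
        assert da < 0.6
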