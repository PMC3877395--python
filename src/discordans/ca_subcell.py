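"""Subcellular Ca cycling: four-compartment sarcomere states, the RyR
release and stochastic SERCA uptake laws, and single-step integration of one
sarcomere or a chain of diffusively coupled sarcomeres.

Release model
-------------
Release is spark-like: a brief L-type trigger recruits a release flux whose
amplitude is set ("latched") by the JSR load at trigger time through

    gain(c_jsr) = u_release * (g_rel_lin + (u_release / u_scale) * σ(c_jsr)),

with σ a sigmoid centred at ``c_jsr_thresh``.  The recruited flux then decays
with the spark lifetime ``tau_spark``.  The steep, u_release-controlled load
dependence is the alternans engine of the whole model.

Cytosolic and submembrane Ca are buffered: the engine integrates total Ca
and all rate laws act on the free concentration; this module's state classes
expose the free concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from ._engine import IntegrationError, Lattice
from ._params import (CaCyclingParams, IonicParams, NoiseSource,
                      NOISE_FRAME_MS, free_from_total, pack_params,
                      total_from_free)

__all__ = [
    "CaCyclingParams", "NoiseSource", "SarcomereCaState", "CellCaState",
    "ryr_release_flux", "serca_uptake", "sarcomere_step", "cell_ca_step",
    "IntegrationError",
]


@dataclass
class SarcomereCaState:
    """Free Ca concentrations (µM) of one sarcomere plus release gating.

    ``r_gate`` is the recovered fraction of the release machinery in [0, 1];
    ``q_rel`` is the currently recruited spark flux (µM/ms, internal state of
    the latch-release model, 0 at rest).
    """

    c_i: float = 0.1
    c_s: float = 0.1
    c_nsr: float = 85.0
    c_jsr: float = 85.0
    r_gate: float = 1.0
    q_rel: float = 0.0

    def validate(self) -> None:
        for name in ("c_i", "c_s", "c_nsr", "c_jsr"):
            if getattr(self, name) < 0:
                raise ValueError(f"SarcomereCaState.{name} must be >= 0")
        if not 0.0 <= self.r_gate <= 1.0:
            raise ValueError("SarcomereCaState.r_gate must be in [0, 1]")


@dataclass
class CellCaState:
    """Ordered chain of M sarcomeres (arrays of shape (M,), free µM)."""

    c_i: np.ndarray
    c_s: np.ndarray
    c_nsr: np.ndarray
    c_jsr: np.ndarray
    r_gate: np.ndarray
    q_rel: np.ndarray

    @classmethod
    def uniform(cls, m: int = 75, state: SarcomereCaState | None = None):
        if m < 1:
            raise ValueError("M must be >= 1")
        s = state or SarcomereCaState()
        s.validate()
        return cls(*(np.full(m, getattr(s, f)) for f in
                     ("c_i", "c_s", "c_nsr", "c_jsr", "r_gate", "q_rel")))

    @property
    def m(self) -> int:
        return len(self.c_i)

    def sarcomere(self, k: int) -> SarcomereCaState:
        return SarcomereCaState(*(float(getattr(self, f)[k]) for f in
                                  ("c_i", "c_s", "c_nsr", "c_jsr", "r_gate",
                                   "q_rel")))

    def total_ca(self, p: CaCyclingParams) -> float:
        """Volume-weighted total cell Ca (µM of cytosolic volume), including
        buffer-bound Ca in the cytosolic and submembrane compartments."""
        ti = total_from_free(self.c_i, p.buf_b, p.buf_k)
        ts = total_from_free(self.c_s, p.buf_b, p.buf_k)
        return float(np.sum(ti + p.nu_s * ts + p.nu_n * self.c_nsr
                            + p.nu_j * self.c_jsr))


# ---------------------------------------------------------------------------
# flux laws

def ryr_release_flux(state: SarcomereCaState, i_ca_trigger: float,
                     p: CaCyclingParams) -> float:
    """Steady recruited RyR release flux (µM/ms, cytosol-referred) for a
    given trigger influx.

    The trigger is the L-type Ca influx (µM/ms); it is normalised by the
    influx gain ``g_ca_influx`` so a fully open trigger has strength ~1.
    The flux is graded in the trigger, proportional to ``r_gate``, and a
    monotone sigmoidal function of ``c_jsr`` whose steepness grows with
    ``u_release``; it vanishes when the JSR is empty or fully refractory.
    """
    if i_ca_trigger < 0:
        raise ValueError("i_ca_trigger must be >= 0")
    state.validate()
    p.validate()
    trig = i_ca_trigger / p.g_ca_influx
    sgm = 1.0 / (1.0 + np.exp(-(state.c_jsr - p.c_jsr_thresh) / p.c_jsr_slope))
    gain = p.u_release * (p.g_rel_lin + (p.u_release / p.u_scale) * sgm)
    recr = p.nu_j * p.g_trig * state.r_gate * trig * gain * state.c_jsr
    return float(p.tau_spark * recr)


def serca_uptake(c_i: float, p: CaCyclingParams, dt: float = NOISE_FRAME_MS,
                 rng_draw: float = 0.0) -> float:
    """Stochastic SERCA uptake flux (µM/ms) at free cytosolic Ca ``c_i``.

    Returns ``J_det (1 + sigma ξ)`` with Hill-2 deterministic uptake
    ``J_det = v_up_max c_i²/(k_up² + c_i²)`` and Euler–Maruyama noise
    ``sigma = sigma_rel · sqrt(n_pumps_ref/n_pumps) · sqrt(dt_ref/dt)``
    (dt_ref = 0.1 ms), so the per-step variance scales as 1/(n_pumps·dt).
    With ``noise_source="none"`` the deterministic flux is returned exactly.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if c_i < 0:
        raise ValueError("c_i must be >= 0")
    jdet = p.v_up_max * c_i * c_i / (p.k_up * p.k_up + c_i * c_i)
    if NoiseSource(p.noise_source) is not NoiseSource.SERCA:
        return float(jdet)
    sigma = p.sigma_step * np.sqrt(NOISE_FRAME_MS / dt)
    return float(jdet * (1.0 + sigma * rng_draw))


# ---------------------------------------------------------------------------
# stepping

def _lattice_for(cell: CellCaState, v_m: float, p: CaCyclingParams,
                 ion: IonicParams | None, seed: int = 0) -> Lattice:
    ion = ion or IonicParams()
    lat = Lattice(ion, p, m=cell.m, seed=seed)
    lat.V[:] = v_m
    lat.ci[0] = total_from_free(cell.c_i, p.buf_b, p.buf_k)
    lat.cs[0] = total_from_free(cell.c_s, p.buf_b, p.buf_k)
    lat.cnsr[0] = cell.c_nsr
    lat.cjsr[0] = cell.c_jsr
    lat.rgate[0] = cell.r_gate
    lat.qrel[0] = cell.q_rel
    return lat


def _cell_from_lattice(lat: Lattice, p: CaCyclingParams) -> CellCaState:
    return CellCaState(
        c_i=free_from_total(lat.ci[0], p.buf_b, p.buf_k),
        c_s=free_from_total(lat.cs[0], p.buf_b, p.buf_k),
        c_nsr=lat.cnsr[0].copy(), c_jsr=lat.cjsr[0].copy(),
        r_gate=lat.rgate[0].copy(), q_rel=lat.qrel[0].copy())


def _check_dt(dt, allow_any):
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not allow_any and not 0.01 <= dt <= 0.1 + 1e-12:
        raise ValueError("dt outside [0.01, 0.1] ms (pass allow_any_dt=True "
                         "to override)")


def cell_ca_step(cell: CellCaState, v_m: float, p: CaCyclingParams,
                 dt: float = 0.1, rng=None, *, ion: IonicParams | None = None,
                 membrane_fluxes: bool = True,
                 allow_any_dt: bool = False) -> CellCaState:
    """Advance all sarcomeres of a cell one step at clamped voltage ``v_m``.

    Each sarcomere is stepped (release, uptake, JSR↔NSR transfer,
    submembrane↔cytosol exchange, membrane fluxes), then nearest-neighbour
    diffusive exchange of cytosolic and NSR Ca is applied in exact
    antisymmetric flux form (zero-flux ends), which conserves total cell Ca
    to rounding.  The membrane currents driving the trigger are computed
    internally from ``v_m`` and the state.  ``rng`` is a numpy Generator for
    the per-sarcomere noise variates (ignored when noise is off).
    """
    _check_dt(dt, allow_any_dt)
    lat = _lattice_for(cell, v_m, p, ion)
    xi = np.zeros((1, cell.m))
    mode = NoiseSource(p.noise_source)
    if rng is not None and mode is not NoiseSource.NONE:
        if mode is NoiseSource.SR_RELEASE:
            xi[0] = p.sigma_rel * rng.uniform(-1.0, 1.0, cell.m)
        else:
            xi[0] = rng.standard_normal(cell.m)
    clamp = np.full(1, float(v_m))
    maxdv, n_clip, err = _kernels.step_frame(
        lat.V, lat.vgate, lat.wgate, lat.fgate,
        lat.ci, lat.cs, lat.cnsr, lat.cjsr, lat.rgate, lat.qrel,
        xi, lat._zero_stim, lat.edge_open, 1, float(dt), lat.P,
        1, clamp, 1.0 if membrane_fluxes else 0.0,
        0, 1, 1, 0.0, lat.dx,
        lat._work_m, lat._work_m2, lat._work_v, lat._work_v2,
        lat._line_rhs, lat._line_out, lat._cp, lat._dp)
    if err != _kernels.ERR_OK:
        raise IntegrationError(
            f"integration failure in {_kernels.ERR_NAMES[err]}")
    return _cell_from_lattice(lat, p)


def sarcomere_step(state: SarcomereCaState, v_m: float, p: CaCyclingParams,
                   dt: float = 0.1, rng=None, *,
                   ion: IonicParams | None = None,
                   membrane_fluxes: bool = True,
                   allow_any_dt: bool = False) -> SarcomereCaState:
    """Advance a single sarcomere one step at clamped voltage (M = 1 case of
    :func:`cell_ca_step`; see there for the flux balance and noise)."""
    state.validate()
    cell = CellCaState.uniform(1, state)
    out = cell_ca_step(cell, v_m, p, dt, rng, ion=ion,
                       membrane_fluxes=membrane_fluxes,
                       allow_any_dt=allow_any_dt)
    return out.sarcomere(0)
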