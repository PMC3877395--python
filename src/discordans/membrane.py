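"""Membrane voltage dynamics of a whole cell.

The membrane carries non-Ca-sensitive currents (fast inward sodium-like and
outward potassium-like, shared across sarcomeres) and, per sarcomere, the
Ca-sensitive pair: an L-type-like slow inward current with Ca-induced
inactivation and an NCX-like inward current proportional to submembrane Ca
occupancy.  All sarcomeres see the same voltage; per-sarcomere currents are
normalised by 1/M so whole-cell magnitudes are M-independent.

The NCX pathway dominates the Ca→voltage coupling, so a larger Ca transient
prolongs the action potential (positive coupling / electromechanical
concordance); Ca-induced inactivation of the slow inward current provides
the weaker opposing pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._engine import IntegrationError, Lattice
from ._params import (CaCyclingParams, IonicParams, NoiseSource,
                      NOISE_FRAME_MS, free_from_total, total_from_free)
from .ca_subcell import CellCaState, _cell_from_lattice, _check_dt

__all__ = [
    "IonicParams", "MembraneState", "APClampWaveform",
    "ionic_current_total", "cell_step", "ap_clamp_step", "resting_state",
]


@dataclass
class MembraneState:
    """Voltage (mV) and gating variables, each gate in [0, 1].

    ``v_gate``: fast-inward availability; ``w_gate``: slow-inward
    availability; ``f_gate``: L-type trigger latch availability.
    """

    v: float = -85.0
    v_gate: float = 1.0
    w_gate: float = 1.0
    f_gate: float = 1.0

    def validate(self) -> None:
        if not -100.0 <= self.v <= 80.0:
            raise ValueError("MembraneState.v outside [-100, 80] mV")
        for g in ("v_gate", "w_gate", "f_gate"):
            if not 0.0 <= getattr(self, g) <= 1.0:
                raise ValueError(f"MembraneState.{g} must be in [0, 1]")


def resting_state() -> MembraneState:
    return MembraneState()


@dataclass
class APClampWaveform:
    """A sampled AP-clamp waveform, periodically extended.

    ``times`` (ms, strictly increasing, starting at 0) and ``voltages`` (mV)
    sample one full cycle for mode "periodic", or two consecutive cycles
    (long+short or short+long) for the alternating modes "LSLS" / "SLSL".
    """

    times: np.ndarray
    voltages: np.ndarray
    mode: str = "periodic"
    period: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.mode not in ("periodic", "LSLS", "SLSL"):
            raise ValueError("mode must be periodic, LSLS or SLSL")
        if len(self.times) < 2 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing, length >= 2")
        if self.period is None:
            self.period = float(self.times[-1] - self.times[0])

    def __call__(self, t: float) -> float:
        """Voltage at time t (ms), periodic extension."""
        tr = (t - self.times[0]) % self.period + self.times[0]
        return float(np.interp(tr, self.times, self.voltages))

    def mirrored(self) -> "APClampWaveform":
        """Swap the LSLS/SLSL phase by shifting half a period."""
        if self.mode == "periodic":
            return self
        half = self.period / 2.0
        t = self.times
        v = np.array([self(x + half) for x in t])
        mode = "SLSL" if self.mode == "LSLS" else "LSLS"
        return APClampWaveform(t.copy(), v, mode, self.period)

    @classmethod
    def from_beats(cls, long_trace, short_trace, dt_ms: float, mode: str):
        """Build an alternating waveform from two recorded single-beat
        voltage traces (arrays sampled at ``dt_ms``)."""
        a, b = (np.asarray(long_trace), np.asarray(short_trace))
        if mode == "SLSL":
            a, b = b, a
        v = np.concatenate([a, b])
        t = np.arange(len(v)) * dt_ms
        return cls(t, v, mode, period=len(v) * dt_ms)


# ---------------------------------------------------------------------------

def _currents_norm(m: MembraneState, cell: CellCaState, ion: IonicParams,
                   ca: CaCyclingParams):
    """Normalised (1/ms) currents; returns (i_fi, i_so, i_si_k, i_ncx_k)."""
    u = (m.v - ion.v_rest) / ion.v_amp
    p = 1.0 if u >= ion.u_c else 0.0
    i_fi = -m.v_gate * p * (1.0 - u) * (u - ion.u_c) / ion.tau_d
    i_so = (u * (1.0 - p) / ion.tau_0
            + p * (1.0 + 3.0 * max(u - 1.0, 0.0)) / ion.tau_r)
    s_inf = 0.5 * (1.0 + np.tanh(ion.k_si * (u - ion.u_csi)))
    fca = 1.0 / (1.0 + (np.asarray(cell.c_i) / ion.c_fca) ** 2)
    i_si_k = -m.w_gate * s_inf * fca / ion.tau_si
    occ = np.asarray(cell.c_s) / (np.asarray(cell.c_s) + ion.k_ncx)
    i_ncx_k = -ion.g_ncx_v * occ
    return i_fi, i_so, i_si_k, i_ncx_k


def ionic_current_total(m: MembraneState, cell: CellCaState,
                        ion: IonicParams | None = None,
                        ca: CaCyclingParams | None = None):
    """Total transmembrane current I_ion (µA/cm²) plus the per-sarcomere
    Ca-sensitive currents.

    I_ion = I_fast_in + I_out + (1/M) Σ_k (I_si,k + I_NCX,k); the per-
    sarcomere terms are returned in µA/cm² (already scaled by 1/M) so their
    sum plus the shared currents reproduces I_ion.  Inward currents are
    negative.
    """
    ion = ion or IonicParams()
    ca = ca or CaCyclingParams()
    m.validate()
    i_fi, i_so, i_si_k, i_ncx_k = _currents_norm(m, cell, ion, ca)
    scale = ion.c_m * ion.v_amp  # µA/cm² per (1/ms)
    mm = cell.m
    per_si = scale * i_si_k / mm
    per_ncx = scale * i_ncx_k / mm
    i_ion = scale * (i_fi + i_so) + per_si.sum() + per_ncx.sum()
    return float(i_ion), {"i_ca": per_si, "i_naca": per_ncx}


# ---------------------------------------------------------------------------

def _lattice_from(m: MembraneState, cell: CellCaState, ion: IonicParams,
                  ca: CaCyclingParams, seed: int = 0) -> Lattice:
    lat = Lattice(ion, ca, m=cell.m, seed=seed)
    lat.V[:] = m.v
    lat.vgate[:] = m.v_gate
    lat.wgate[:] = m.w_gate
    lat.fgate[:] = m.f_gate
    lat.ci[0] = total_from_free(cell.c_i, ca.buf_b, ca.buf_k)
    lat.cs[0] = total_from_free(cell.c_s, ca.buf_b, ca.buf_k)
    lat.cnsr[0] = cell.c_nsr
    lat.cjsr[0] = cell.c_jsr
    lat.rgate[0] = cell.r_gate
    lat.qrel[0] = cell.q_rel
    return lat


def cell_step(m: MembraneState, cell: CellCaState, dt: float = 0.1,
              stimulus: float = 0.0, rng=None, *,
              ion: IonicParams | None = None,
              ca: CaCyclingParams | None = None,
              allow_any_dt: bool = False):
    """Advance voltage, gates and the whole Ca subsystem one step.

    dV/dt = -(I_ion - I_stim)/C_m with the closed feedback loop
    V → I_si/I_NCX → Ca → I_NCX/I_si.  Returns (MembraneState, CellCaState).
    """
    ion = ion or IonicParams()
    ca = ca or CaCyclingParams()
    _check_dt(dt, allow_any_dt)
    m.validate()
    lat = _lattice_from(m, cell, ion, ca)
    xi = _draw_noise(ca, cell.m, rng)
    stim = np.full(1, float(stimulus))
    from . import _kernels
    maxdv, n_clip, err = _kernels.step_frame(
        lat.V, lat.vgate, lat.wgate, lat.fgate,
        lat.ci, lat.cs, lat.cnsr, lat.cjsr, lat.rgate, lat.qrel,
        xi, stim, lat.edge_open, 1, float(dt), lat.P,
        0, lat._zero_clamp, 1.0,
        0, 1, 1, 0.0, lat.dx,
        lat._work_m, lat._work_m2, lat._work_v, lat._work_v2,
        lat._line_rhs, lat._line_out, lat._cp, lat._dp)
    if err != _kernels.ERR_OK:
        raise IntegrationError(
            f"integration failure in {_kernels.ERR_NAMES[err]}")
    m2 = MembraneState(float(lat.V[0]), float(lat.vgate[0]),
                       float(lat.wgate[0]), float(lat.fgate[0]))
    return m2, _cell_from_lattice(lat, ca)


def ap_clamp_step(waveform: APClampWaveform, t: float, cell: CellCaState,
                  dt: float = 0.1, rng=None, *,
                  ion: IonicParams | None = None,
                  ca: CaCyclingParams | None = None,
                  membrane: MembraneState | None = None,
                  allow_any_dt: bool = False):
    """Advance the Ca subsystem one step under an imposed voltage.

    The voltage is read from the waveform at time ``t`` (periodic extension);
    gates still evolve so the trigger sees physiologic kinetics.  Returns
    (MembraneState, CellCaState).
    """
    ion = ion or IonicParams()
    ca = ca or CaCyclingParams()
    _check_dt(dt, allow_any_dt)
    v = waveform(t)
    m = membrane or MembraneState(v=v)
    lat = _lattice_from(m, cell, ion, ca)
    xi = _draw_noise(ca, cell.m, rng)
    clamp = np.full(1, v)
    from . import _kernels
    maxdv, n_clip, err = _kernels.step_frame(
        lat.V, lat.vgate, lat.wgate, lat.fgate,
        lat.ci, lat.cs, lat.cnsr, lat.cjsr, lat.rgate, lat.qrel,
        xi, lat._zero_stim, lat.edge_open, 1, float(dt), lat.P,
        1, clamp, 1.0,
        0, 1, 1, 0.0, lat.dx,
        lat._work_m, lat._work_m2, lat._work_v, lat._work_v2,
        lat._line_rhs, lat._line_out, lat._cp, lat._dp)
    if err != _kernels.ERR_OK:
        raise IntegrationError(
            f"integration failure in {_kernels.ERR_NAMES[err]}")
    m2 = MembraneState(float(lat.V[0]), float(lat.vgate[0]),
                       float(lat.wgate[0]), float(lat.fgate[0]))
    return m2, _cell_from_lattice(lat, ca)


def _draw_noise(ca: CaCyclingParams, m: int, rng):
    xi = np.zeros((1, m))
    mode = NoiseSource(ca.noise_source)
    if rng is not None and mode is not NoiseSource.NONE:
        if mode is NoiseSource.SR_RELEASE:
            xi[0] = ca.sigma_rel * rng.uniform(-1.0, 1.0, m)
        else:
            xi[0] = rng.standard_normal(m)
    return xi
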