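"""Electrotonically coupled tissue: 1D cables and 2D sheets of cells (each
carrying the full 75-sarcomere subcellular model), plus the small multi-cell
group that shares a single membrane voltage.

Voltage obeys the monodomain cable equation
∂V/∂t = -I_ion/C_m + D_V ∇²V, integrated by operator splitting: a reaction
substep (every cell's membrane + Ca) followed by a diffusion substep (FTCS
in 1D, Peaceman–Rachford ADI in 2D) with zero-flux boundaries.  Ca does not
diffuse between cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._engine import IntegrationError, Lattice
from ._params import CaCyclingParams, IonicParams, NOISE_FRAME_MS
from .ca_subcell import CellCaState, _cell_from_lattice
from .membrane import MembraneState
from ._params import total_from_free

__all__ = ["TissueGeometry", "TissueState", "tissue_step", "multicell_step",
           "measure_cv", "PropagationError"]


class PropagationError(RuntimeError):
    """No propagating wavefront found."""


@dataclass
class TissueGeometry:
    """Lattice geometry and electrotonic coupling.

    dx = 0.015 cm is the lattice spacing (one cell per site); D_v in cm²/ms
    (default 1e-3).  The explicit 1D diffusion substep requires
    dt <= 0.4 dx²/D_v, which the engine checks; the 2D ADI substep is
    unconditionally stable.
    """

    dims: int = 1
    n_x: int = 100
    n_y: int = 1
    dx: float = 0.015
    d_v: float = 1e-3

    def validate(self) -> None:
        if self.dims not in (1, 2):
            raise ValueError("dims must be 1 or 2")
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("n_x, n_y must be >= 1")
        if self.dims == 1 and self.n_y != 1:
            raise ValueError("1D cable must have n_y == 1")
        if self.dx <= 0 or self.d_v < 0:
            raise ValueError("dx must be > 0 and D_v >= 0")

    @property
    def n_sites(self) -> int:
        return self.n_x * self.n_y

    @property
    def length_cm(self) -> float:
        return self.n_x * self.dx


class TissueState:
    """Lattice of cells with one voltage per site; thin wrapper over the
    shared simulation engine."""

    def __init__(self, geometry: TissueGeometry,
                 ion: IonicParams | None = None,
                 ca: CaCyclingParams | None = None,
                 m: int = 75, seed: int = 0, **engine_opts):
        geometry.validate()
        self.geometry = geometry
        self.ion = ion or IonicParams()
        self.ca = ca or CaCyclingParams()
        self.lattice = Lattice(self.ion, self.ca,
                               n_x=geometry.n_x, n_y=geometry.n_y,
                               dims=geometry.dims, m=m, seed=seed,
                               d_v=geometry.d_v, dx=geometry.dx,
                               **engine_opts)

    @property
    def t(self) -> float:
        return self.lattice.t

    @property
    def v(self) -> np.ndarray:
        """Voltage per site, shape (n_y, n_x) for 2D, (n_x,) for 1D."""
        V = self.lattice.V
        if self.geometry.dims == 2:
            return V.reshape(self.geometry.n_y, self.geometry.n_x)
        return V


def tissue_step(ts: TissueState, stim_map=None, n_frames: int = 1) -> TissueState:
    """Advance the tissue ``n_frames`` 0.1-ms frames (each split into a
    reaction substep per site and a voltage-diffusion substep; the substep
    size adapts to 0.01 ms during upstrokes).  ``stim_map`` is a per-site
    stimulus in µA/cm² (flat array of n_sites, or the 2D shape)."""
    stim = None
    if stim_map is not None:
        stim = np.asarray(stim_map, dtype=float).ravel()
    for _ in range(n_frames):
        ts.lattice.step_one_frame(stim=stim)
    return ts


def multicell_step(cells: list[CellCaState], shared: MembraneState,
                   dt: float = 0.1, stimulus: float = 0.0, rng=None, *,
                   ion: IonicParams | None = None,
                   ca: CaCyclingParams | None = None):
    """One step of a small (2-5 cell) group sharing a single voltage.

    The shared membrane integrates I_ion averaged over all cells' sarcomeres
    (per unit membrane area); Ca never crosses cell boundaries.  Returns
    (MembraneState, [CellCaState, ...]).
    """
    if not 2 <= len(cells) <= 5:
        raise ValueError("multi-cell group must have 2-5 cells")
    ion = ion or IonicParams()
    ca = ca or CaCyclingParams()
    m = cells[0].m
    if any(c.m != m for c in cells):
        raise ValueError("all cells must have the same sarcomere count")
    lat = Lattice(ion, ca, m=m, cells_per_site=len(cells))
    lat.V[:] = shared.v
    lat.vgate[:] = shared.v_gate
    lat.wgate[:] = shared.w_gate
    lat.fgate[:] = shared.f_gate
    for i, c in enumerate(cells):
        sl = slice(i * m, (i + 1) * m)
        lat.ci[0, sl] = total_from_free(c.c_i, ca.buf_b, ca.buf_k)
        lat.cs[0, sl] = total_from_free(c.c_s, ca.buf_b, ca.buf_k)
        lat.cnsr[0, sl] = c.c_nsr
        lat.cjsr[0, sl] = c.c_jsr
        lat.rgate[0, sl] = c.r_gate
        lat.qrel[0, sl] = c.q_rel
    from . import _kernels
    from .membrane import _draw_noise
    xi = _draw_noise(ca, m * len(cells), rng)
    stim = np.full(1, float(stimulus))
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
    out = []
    for i in range(len(cells)):
        out.append(CellCaState(
            c_i=_free(lat.ci[0, i * m:(i + 1) * m], ca),
            c_s=_free(lat.cs[0, i * m:(i + 1) * m], ca),
            c_nsr=lat.cnsr[0, i * m:(i + 1) * m].copy(),
            c_jsr=lat.cjsr[0, i * m:(i + 1) * m].copy(),
            r_gate=lat.rgate[0, i * m:(i + 1) * m].copy(),
            q_rel=lat.qrel[0, i * m:(i + 1) * m].copy()))
    return m2, out


def _free(total, ca):
    from ._params import free_from_total
    return free_from_total(total, ca.buf_b, ca.buf_k)


def measure_cv(activation_times_ms, dx_cm: float,
               interior_frac: float = 0.6) -> float:
    """Conduction velocity (cm/ms) from a linear fit of activation time vs
    position over the cable interior (central ``interior_frac`` of sites).

    Raises :class:`PropagationError` when fewer than 4 interior sites
    activated or the wave did not progress monotonically in time."""
    act = np.asarray(activation_times_ms, dtype=float).ravel()
    n = len(act)
    lo = int(round(n * (1 - interior_frac) / 2))
    hi = n - lo
    x = np.arange(lo, hi) * dx_cm
    t = act[lo:hi]
    ok = ~np.isnan(t)
    if ok.sum() < 4:
        raise PropagationError("no propagating wavefront in the interior")
    slope = np.polyfit(t[ok], x[ok], 1)[0]
    if not np.isfinite(slope) or slope == 0:
        raise PropagationError("degenerate activation profile")
    return float(abs(slope))
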