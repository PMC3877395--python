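"""Internal simulation engine: state arrays, seeded noise streams and the
frame loop shared by the cell, multi-cell and tissue front ends.

Time is discretised into *frames* of ``NOISE_FRAME_MS`` (0.1 ms).  Each frame
is integrated with 1 substep (dt = 0.1 ms) or, while any membrane is in its
upstroke, 10 substeps (dt = 0.01 ms); one noise variate per sarcomere is
drawn per frame, so the realised noise path does not depend on the substep
choice.

Noise streams are Philox-counter generators keyed by ``(seed, global cell
index)``: every cell owns an independent, reproducible stream, and a cell
simulated in isolation sees exactly the same draws as the same cell inside a
decoupled tissue.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from ._params import (CaCyclingParams, IonicParams, NoiseSource,
                      NOISE_FRAME_MS, free_from_total, pack_params,
                      total_from_free)

__all__ = ["Lattice", "IntegrationError"]

_NOISE_CHUNK = 256  # frames of noise drawn per generator call


class IntegrationError(RuntimeError):
    """Raised when the integrator produces NaN / out-of-range state; the
    message names the failing field."""


class Lattice:
    """A lattice of membrane sites, each carrying ``cells_per_site`` cells of
    ``m`` sarcomeres (``cells_per_site > 1`` models the shared-voltage
    multi-cell group; Ca never diffuses across cell boundaries)."""

    def __init__(self, ion: IonicParams, ca: CaCyclingParams, *,
                 n_x: int = 1, n_y: int = 1, dims: int = 0, m: int = 75,
                 cells_per_site: int = 1, d_v: float = 0.0, dx: float = 0.015,
                 seed: int = 0, cell_index0: int = 0,
                 dt_min: float = 0.01, dt_max: float = 0.1,
                 dvdt_switch: float = 5.0, fixed_dt: float | None = None):
        if n_x < 1 or n_y < 1 or m < 1 or cells_per_site < 1:
            raise ValueError("lattice dimensions must be >= 1")
        if dims == 1 and d_v > 0:
            # FTCS stability bound for the 1D diffusion substep
            cfl = 0.5 * dx * dx / d_v
            if dt_max > cfl:
                dt_max = cfl
            if fixed_dt is not None and fixed_dt > cfl:
                raise ValueError(
                    f"fixed_dt={fixed_dt} violates FTCS stability "
                    f"(need <= {cfl:.4g} ms for D_v={d_v}, dx={dx})")
        self.ion = ion
        self.ca = ca
        self.P = pack_params(ion, ca)
        self.n_x, self.n_y, self.dims = n_x, n_y, dims
        self.m, self.cells_per_site = m, cells_per_site
        self.S = n_x * n_y
        self.Mt = m * cells_per_site
        self.n_cells = self.S * cells_per_site
        self.d_v, self.dx = float(d_v), float(dx)
        self.seed = int(seed)
        self.cell_index0 = int(cell_index0)
        self.dt_min, self.dt_max = float(dt_min), float(dt_max)
        self.dvdt_switch = float(dvdt_switch)
        self.fixed_dt = fixed_dt
        self.t = 0.0
        self.n_clip_total = 0
        self.n_step_total = 0

        S, Mt = self.S, self.Mt
        self.V = np.full(S, ion.v_rest)
        self.vgate = np.ones(S)
        self.wgate = np.ones(S)
        self.fgate = np.ones(S)
        ctot0 = float(total_from_free(0.1, ca.buf_b, ca.buf_k))
        self.ci = np.full((S, Mt), ctot0)   # total (free + buffered) Ca
        self.cs = np.full((S, Mt), ctot0)
        self.cnsr = np.full((S, Mt), 85.0)
        self.cjsr = np.full((S, Mt), 85.0)
        self.rgate = np.ones((S, Mt))
        self.qrel = np.zeros((S, Mt))

        # intra-site diffusion edges; closed at cell boundaries
        self.edge_open = np.ones(max(Mt - 1, 1))
        for k in range(1, cells_per_site):
            self.edge_open[k * m - 1] = 0.0

        # workspaces
        self._work_m = np.empty((S, Mt))
        self._work_m2 = np.empty((S, Mt))
        self._work_v = np.empty(S)
        self._work_v2 = np.empty(S)
        nline = max(n_x, n_y)
        self._line_rhs = np.empty(nline)
        self._line_out = np.empty(nline)
        self._cp = np.empty(nline)
        self._dp = np.empty(nline)
        self._zero_stim = np.zeros(S)
        self._zero_clamp = np.zeros(S)

        self._last_maxdv = 0.0
        self._last_clamp_v = float(ion.v_rest)
        self._init_noise()

    # ------------------------------------------------------------------ noise
    def _init_noise(self):
        mode = NoiseSource(self.ca.noise_source)
        self._noise_on = mode is not NoiseSource.NONE
        self._uniform = mode is NoiseSource.SR_RELEASE
        self._gens = [
            np.random.Generator(np.random.Philox(
                key=np.array([self.seed & 0xFFFFFFFFFFFFFFFF,
                              self.cell_index0 + g], dtype=np.uint64)))
            for g in range(self.n_cells)
        ]
        self._xi = np.zeros((self.S, self.Mt))
        self._chunk = None
        self._chunk_pos = 0

    def _refill_chunk(self):
        m, cps = self.m, self.cells_per_site
        chunk = np.empty((_NOISE_CHUNK, self.S, self.Mt))
        for g, gen in enumerate(self._gens):
            s, c = divmod(g, cps)
            if self._uniform:
                blk = self.ca.sigma_rel * gen.uniform(-1.0, 1.0,
                                                      size=(_NOISE_CHUNK, m))
            else:
                blk = gen.standard_normal(size=(_NOISE_CHUNK, m))
            chunk[:, s, c * m:(c + 1) * m] = blk
        self._chunk = chunk
        self._chunk_pos = 0

    def _next_noise(self):
        if not self._noise_on:
            return self._xi  # zeros
        if self._chunk is None or self._chunk_pos >= _NOISE_CHUNK:
            self._refill_chunk()
        xi = self._chunk[self._chunk_pos]
        self._chunk_pos += 1
        return xi

    # ------------------------------------------------------------------ core
    def _frame_dt(self, clamp_v):
        if self.fixed_dt is not None:
            dt = self.fixed_dt
        else:
            fast = self._last_maxdv > self.dvdt_switch
            if clamp_v is not None:
                slope = abs(float(np.max(clamp_v)) - self._last_clamp_v) / NOISE_FRAME_MS
                fast = fast or slope > self.dvdt_switch
            dt = self.dt_min if fast else self.dt_max
        n_sub = max(1, int(np.ceil(NOISE_FRAME_MS / dt - 1e-9)))
        return NOISE_FRAME_MS / n_sub, n_sub

    def step_one_frame(self, stim=None, clamp_v=None, mem_flux: float = 1.0):
        """Advance one 0.1 ms frame.  ``stim`` is µA/cm² per site; if
        ``clamp_v`` is given the voltage is imposed rather than integrated."""
        dt, n_sub = self._frame_dt(clamp_v)
        xi = self._next_noise()
        if stim is None:
            stim = self._zero_stim
        if clamp_v is None:
            cflag, cvec = 0, self._zero_clamp
        else:
            cflag = 1
            cvec = np.asarray(clamp_v, dtype=np.float64)
            if cvec.ndim == 0:
                cvec = np.full(self.S, float(cvec))
            self._last_clamp_v = float(np.max(cvec))
        maxdv, n_clip, err = _kernels.step_frame(
            self.V, self.vgate, self.wgate, self.fgate,
            self.ci, self.cs, self.cnsr, self.cjsr, self.rgate, self.qrel,
            xi, stim, self.edge_open, n_sub, dt, self.P,
            cflag, cvec, mem_flux,
            self.dims, self.n_x, self.n_y, self.d_v, self.dx,
            self._work_m, self._work_m2, self._work_v, self._work_v2,
            self._line_rhs, self._line_out, self._cp, self._dp)
        if err != _kernels.ERR_OK:
            raise IntegrationError(
                f"integration failure in {_kernels.ERR_NAMES[err]} at t={self.t:.2f} ms")
        self._last_maxdv = maxdv
        self.n_clip_total += n_clip
        self.n_step_total += n_sub
        if self.n_step_total > 1000 and self.n_clip_total > 0.001 * self.n_step_total * self.S * self.Mt:
            raise IntegrationError(
                "negative-concentration clips exceeded 0.1% of steps; "
                "reduce the time step or the noise amplitude")
        self.t += NOISE_FRAME_MS
        return maxdv

    # ------------------------------------------------------------- beat level
    def run_beat(self, cl_ms: float, stim_amp: float = 0.0,
                 stim_mask=None, stim_dur_ms: float = 1.0,
                 sample_ms: float = 1.0, collect_v: bool = True,
                 clamp_fn=None, mem_flux: float = 1.0):
        """Run one pacing interval of ``cl_ms`` and record it.

        Returns a dict with ``v`` (samples × sites, if collected), ``ca_peak``
        (sites × Mt running maximum of cytosolic Ca), and the frame-resolution
        sample times.
        """
        n_frames = int(round(cl_ms / NOISE_FRAME_MS))
        bb, bk = self.ca.buf_b, self.ca.buf_k
        stride = max(1, int(round(sample_ms / NOISE_FRAME_MS)))
        n_samples = n_frames // stride
        v_buf = np.empty((n_samples, self.S)) if collect_v else None
        ca_peak = free_from_total(self.ci, bb, bk)
        cj_min = np.array(self.cjsr, copy=True)
        stim_frames = int(round(stim_dur_ms / NOISE_FRAME_MS))
        stim_vec = None
        if stim_amp != 0.0:
            stim_vec = np.zeros(self.S)
            if stim_mask is None:
                stim_vec[:] = stim_amp
            else:
                stim_vec[np.asarray(stim_mask)] = stim_amp
        t0 = self.t
        isamp = 0
        for f in range(n_frames):
            stim = stim_vec if (stim_vec is not None and f < stim_frames) else None
            clamp_v = clamp_fn(self.t - t0) if clamp_fn is not None else None
            self.step_one_frame(stim=stim, clamp_v=clamp_v, mem_flux=mem_flux)
            if (f + 1) % stride == 0:
                if collect_v:
                    v_buf[isamp] = self.V
                isamp += 1
                np.maximum(ca_peak, free_from_total(self.ci, bb, bk),
                           out=ca_peak)
                np.minimum(cj_min, self.cjsr, out=cj_min)
        return {"v": v_buf, "ca_peak": ca_peak, "cj_min": cj_min,
                "sample_ms": sample_ms, "t0": t0, "cl": cl_ms}

    # ------------------------------------------------------------- snapshots
    _STATE_FIELDS = ("V", "vgate", "wgate", "fgate", "ci", "cs", "cnsr",
                     "cjsr", "rgate", "qrel")

    def snapshot(self) -> dict:
        st = {f: np.array(getattr(self, f), copy=True) for f in self._STATE_FIELDS}
        st["t"] = self.t
        return st

    def restore(self, st: dict) -> None:
        for f in self._STATE_FIELDS:
            getattr(self, f)[...] = st[f]
        if "t" in st:
            self.t = float(st["t"])
        self._last_maxdv = 0.0

    def cell_ca_view(self, field: str = "ci") -> np.ndarray:
        """Ca array reshaped to (n_cells, m)."""
        arr = getattr(self, field)
        return arr.reshape(self.n_cells, self.m)

    def free_ci(self) -> np.ndarray:
        """Free cytosolic Ca (µM), shape (S, Mt)."""
        return free_from_total(self.ci, self.ca.buf_b, self.ca.buf_k)

    def free_cs(self) -> np.ndarray:
        """Free submembrane Ca (µM), shape (S, Mt)."""
        return free_from_total(self.cs, self.ca.buf_b, self.ca.buf_k)
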