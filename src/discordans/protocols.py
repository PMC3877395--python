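"""Pacing protocols and scenario presets.

A :class:`PacingProtocol` is an ordered list of (cycle length, beat count)
stages delivered to one of the model scopes (single sarcomere, whole cell,
shared-voltage multi-cell group, 1D cable, 2D sheet).  :func:`run_protocol`
executes it and returns an :class:`~discordans.analytics.AlternansRecord`
with per-beat Ca-transient peaks (per sarcomere) and APD (per membrane
site).  Scenario presets reproduce the standard experiments: alternans
development after a rate step, subcellular node dynamics under AP clamp,
multi-cell synchronisation, cable and sheet SDA formation, edge pacing with
a rate down-step, and the S1-S2 wavebreak test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._engine import Lattice
from ._params import CaCyclingParams, IonicParams, NOISE_FRAME_MS
from .analytics import AlternansRecord, alternans_amplitude, apd80, \
    activation_map, block_sites, detect_nodes, DegenerateProfileError
from .membrane import APClampWaveform

__all__ = [
    "ModelSpec", "PacingProtocol", "RunResult", "run_protocol",
    "run_ap_clamp", "run_s1s2", "build_clamp_inputs", "preset", "PRESETS",
    "STIM_AMP", "STIM_MS",
]

#: Default stimulus: ~2x the diastolic threshold, 1 ms duration.
STIM_AMP = 40.0
STIM_MS = 1.0


@dataclass
class ModelSpec:
    """What is being paced.

    kind: sarcomere | cell | multicell | cable | sheet.  ``m`` is the
    sarcomere count per cell (1 for kind="sarcomere"); ``n_cells`` only
    applies to multicell; ``n_x``/``n_y`` to tissue; ``d_v``/``dx`` set the
    electrotonic coupling.
    """

    kind: str = "cell"
    m: int = 75
    n_cells: int = 5
    n_x: int = 100
    n_y: int = 1
    d_v: float = 1e-3
    dx: float = 0.015

    @classmethod
    def parse(cls, text: str) -> "ModelSpec":
        """Shorthand: "sarcomere", "cell", "multicell:5", "cable:100",
        "sheet:50x50"."""
        if isinstance(text, cls):
            return text
        kind, _, arg = text.partition(":")
        spec = cls(kind=kind)
        if kind == "sarcomere":
            spec.m = 1
        elif kind == "multicell" and arg:
            spec.n_cells = int(arg)
        elif kind == "cable" and arg:
            spec.n_x = int(arg)
        elif kind == "sheet" and arg:
            nx, _, ny = arg.partition("x")
            spec.n_x, spec.n_y = int(nx), int(ny or nx)
        return spec

    def build(self, ion=None, ca=None, seed: int = 0, **opts) -> Lattice:
        ion = ion or IonicParams()
        ca = ca or CaCyclingParams()
        k = self.kind
        if k == "sarcomere":
            return Lattice(ion, ca, m=1, seed=seed, **opts)
        if k == "cell":
            return Lattice(ion, ca, m=self.m, seed=seed, **opts)
        if k == "multicell":
            if not 2 <= self.n_cells <= 5:
                raise ValueError("multicell supports 2-5 cells")
            return Lattice(ion, ca, m=self.m, cells_per_site=self.n_cells,
                           seed=seed, **opts)
        if k == "cable":
            return Lattice(ion, ca, n_x=self.n_x, dims=1, m=self.m,
                           d_v=self.d_v, dx=self.dx, seed=seed, **opts)
        if k == "sheet":
            return Lattice(ion, ca, n_x=self.n_x, n_y=self.n_y, dims=2,
                           m=self.m, d_v=self.d_v, dx=self.dx, seed=seed,
                           **opts)
        raise ValueError(f"unknown model kind {k!r}")


@dataclass
class PacingProtocol:
    """Stimulus schedule: ordered (CL ms, n_beats) stages, the stimulated
    sites, and an optional premature S2 extra stimulus."""

    stages: list = field(default_factory=list)
    stim_sites: object = "all"   # "all" | ("left_edge", k) | explicit indices
    stim_amp: float = STIM_AMP
    stim_dur_ms: float = STIM_MS
    s2: tuple | None = None      # (coupling interval ms, sites)

    def validate(self) -> None:
        for cl, n in self.stages:
            if cl <= 0:
                raise ValueError(f"cycle length must be > 0, got {cl}")
            if n < 1:
                raise ValueError(f"n_beats must be >= 1, got {n}")

    def total_beats(self) -> int:
        return sum(n for _, n in self.stages)


def _stim_mask(proto: PacingProtocol, lat: Lattice):
    sites = proto.stim_sites
    if sites == "all" or sites is None:
        return None
    if isinstance(sites, tuple) and sites and sites[0] == "left_edge":
        k = int(sites[1])
        if lat.dims == 2:
            idx = [iy * lat.n_x + ix for iy in range(lat.n_y)
                   for ix in range(k)]
        else:
            idx = list(range(k))
        return np.asarray(idx, dtype=int)
    return np.asarray(sites, dtype=int)


@dataclass
class RunResult:
    record: AlternansRecord
    lattice: Lattice
    v_traces: dict = field(default_factory=dict)   # beat index -> (samples, S)


def run_protocol(model, proto: PacingProtocol, seed: int = 0, *,
                 ion: IonicParams | None = None,
                 ca: CaCyclingParams | None = None,
                 snapshot: dict | None = None,
                 keep_v_beats=(), sample_ms: float = 1.0,
                 engine_opts: dict | None = None) -> RunResult:
    """Execute the protocol stages in order and record every beat.

    ``snapshot`` restores a previously saved steady state (e.g. after slow
    pacing) before the first stage.  Identical (model, protocol, parameters,
    seed) give identical records.  A stimulus that fails to elicit an action
    potential is flagged in ``record.capture`` (APD = NaN), not fatal.
    ``keep_v_beats`` selects beat indices whose voltage traces are returned.
    """
    spec = ModelSpec.parse(model)
    proto.validate()
    ion = ion or IonicParams()
    ca = ca or CaCyclingParams()
    lat = spec.build(ion, ca, seed=seed, **(engine_opts or {}))
    if snapshot is not None:
        lat.restore(snapshot)
    mask = _stim_mask(proto, lat)
    keep = set(keep_v_beats)
    n_tot = proto.total_beats()
    c = np.empty((n_tot, lat.n_cells, lat.m))
    a = np.empty((n_tot, lat.S))
    cls = np.empty(n_tot)
    v_traces = {}
    b = 0
    for cl, n_beats in proto.stages:
        for _ in range(n_beats):
            rec = lat.run_beat(cl, stim_amp=proto.stim_amp, stim_mask=mask,
                               stim_dur_ms=proto.stim_dur_ms,
                               sample_ms=sample_ms, collect_v=True)
            a[b] = apd80(rec["v"], sample_ms)
            c[b] = rec["ca_peak"].reshape(lat.n_cells, lat.m)
            cls[b] = cl
            if b in keep:
                v_traces[b] = rec["v"]
            b += 1
    record = AlternansRecord(c=c, a=a, cl=cls, seed=seed,
                             meta={"model": spec.kind, "m": lat.m,
                                   "n_cells": lat.n_cells,
                                   "stages": list(proto.stages)})
    return RunResult(record=record, lattice=lat, v_traces=v_traces)


# ---------------------------------------------------------------------------
# AP clamp experiment (subcellular node pinning and drift)

def build_clamp_inputs(cl: float = 300.0, seed: int = 0,
                       ion: IonicParams | None = None,
                       ca: CaCyclingParams | None = None,
                       stable_u: float = 1.5, n_settle: int = 120):
    """Recorded inputs for the AP-clamp experiment.

    Returns (periodic_waveform, lsls_waveform, long_state, short_state):
    the periodic clamp is one steady AP of a single sarcomere with stable Ca
    cycling (u_release = stable_u); the alternating clamp concatenates the
    long and short APs of the default (unstable) sarcomere at steady
    alternans; the two states are end-of-beat sarcomere snapshots after a
    large and a small Ca transient, used to initialise a subcellular node.
    """
    ion = ion or IonicParams()
    ca = ca or CaCyclingParams()
    # stable run -> periodic waveform
    lat = Lattice(ion, ca.with_(u_release=stable_u), m=1, seed=seed)
    for _ in range(60):
        lat.run_beat(600.0, stim_amp=STIM_AMP, collect_v=False)
    for _ in range(n_settle):
        lat.run_beat(cl, stim_amp=STIM_AMP, collect_v=False)
    rec = lat.run_beat(cl, stim_amp=STIM_AMP, sample_ms=NOISE_FRAME_MS)
    periodic = APClampWaveform(np.arange(len(rec["v"])) * NOISE_FRAME_MS,
                               rec["v"][:, 0], "periodic", period=cl)
    # unstable run -> long/short APs and end-of-beat states
    lat = Lattice(ion, ca, m=1, seed=seed)
    for _ in range(60):
        lat.run_beat(600.0, stim_amp=STIM_AMP, collect_v=False)
    for _ in range(max(n_settle, 160)):
        lat.run_beat(cl, stim_amp=STIM_AMP, collect_v=False)
    r1 = lat.run_beat(cl, stim_amp=STIM_AMP, sample_ms=NOISE_FRAME_MS)
    s1 = lat.snapshot()
    r2 = lat.run_beat(cl, stim_amp=STIM_AMP, sample_ms=NOISE_FRAME_MS)
    s2 = lat.snapshot()
    if r1["ca_peak"][0, 0] >= r2["ca_peak"][0, 0]:
        long_state, short_state = s1, s2
    else:
        long_state, short_state = s2, s1
    # alternating clamp: the stable AP time-stretched / compressed by ±10%,
    # giving a long-short APD difference of roughly 2x18 ms
    base = rec["v"][:, 0]
    long_trace = _stretch_ap(base, 1.10)
    short_trace = _stretch_ap(base, 0.90)
    lsls = APClampWaveform.from_beats(long_trace, short_trace,
                                     NOISE_FRAME_MS, "LSLS")
    return periodic, lsls, long_state, short_state


def _stretch_ap(trace, factor):
    """Time-scale a single-beat AP trace within its own cycle window."""
    n = len(trace)
    t = np.arange(n, dtype=float)
    src = t / factor
    out = np.interp(src, t, trace)
    if factor > 1.0:
        # the scaled AP would overrun the cycle; it decays to rest within it
        out = np.where(src <= n - 1, out, trace[-1])
    return out


def run_ap_clamp(waveform: APClampWaveform, n_beats: int, cl: float = 300.0,
                 seed: int = 0, *, m: int = 75, node_index: int = 12,
                 ion: IonicParams | None = None,
                 ca: CaCyclingParams | None = None,
                 long_state: dict | None = None,
                 short_state: dict | None = None) -> RunResult:
    """Pace a whole cell with an imposed AP waveform and track the Ca node.

    Sarcomeres with index >= ``node_index`` start from the end-of-long-beat
    state and the rest from the end-of-short-beat state, creating a
    subcellular alternans node at ``node_index``; the clamp then either pins
    it (periodic) or drives it out through a boundary (LSLS/SLSL).
    """
    ion = ion or IonicParams()
    ca = ca or CaCyclingParams()
    if long_state is None or short_state is None:
        _, _, long_state, short_state = build_clamp_inputs(cl, seed, ion, ca)
    lat = Lattice(ion, ca, m=m, seed=seed)
    for f in ("ci", "cs", "cnsr", "cjsr", "rgate", "qrel"):
        arr = getattr(lat, f)
        arr[0, :node_index] = short_state[f][0, 0]
        arr[0, node_index:] = long_state[f][0, 0]
    lat.V[:] = long_state["V"][0]
    lat.vgate[:] = long_state["vgate"][0]
    lat.wgate[:] = long_state["wgate"][0]
    lat.fgate[:] = long_state["fgate"][0]
    c = np.empty((n_beats, 1, m))
    a = np.full((n_beats, 1), np.nan)
    for b in range(n_beats):
        t0 = lat.t
        rec = lat.run_beat(cl, clamp_fn=lambda tr: waveform(tr + (b * cl)),
                           collect_v=False)
        c[b] = rec["ca_peak"].reshape(1, m)
    record = AlternansRecord(c=c, a=a, cl=np.full(n_beats, cl), seed=seed,
                             meta={"model": "cell-clamp",
                                   "mode": waveform.mode, "m": m})
    return RunResult(record=record, lattice=lat)


def clamp_node_positions(record: AlternansRecord, start_beat: int = 2):
    """Per-beat Ca-node positions (sarcomere units) from a clamp record."""
    dca = record.dca[:, 0, :]
    out = []
    for n in range(start_beat, dca.shape[0]):
        try:
            out.append(detect_nodes(dca[n]))
        except DegenerateProfileError:
            out.append(np.array([]))
    return out


# ---------------------------------------------------------------------------
# S1-S2 wavebreak test

def run_s1s2(model, s1_cl: float, s2_interval: float, seed: int = 0, *,
             n_s1: int = 150, ion: IonicParams | None = None,
             ca: CaCyclingParams | None = None,
             stim_sites=("left_edge", 5), s2_window_ms: float = 300.0,
             snapshot: dict | None = None) -> dict:
    """Steady S1 pacing followed by one premature S2 from the same edge.

    Returns the S1 record, the S2 activation map, the block-site mask and a
    classification: "propagated" (all sites activated), "global_block"
    (nothing beyond the stimulated region activated) or "partial_block"
    (wavebreak; some sites blocked while neighbours activated).
    """
    spec = ModelSpec.parse(model)
    proto = PacingProtocol(stages=[(s1_cl, n_s1)], stim_sites=stim_sites)
    res = run_protocol(spec, proto, seed, ion=ion, ca=ca, snapshot=snapshot)
    lat = res.lattice
    mask = _stim_mask(proto, lat)
    # the premature S2 is delivered s2_interval after the last S1 stimulus,
    # i.e. the final cycle is truncated
    lat.run_beat(s2_interval, stim_amp=proto.stim_amp, stim_mask=mask,
                 stim_dur_ms=proto.stim_dur_ms, collect_v=False)
    rec = lat.run_beat(s2_window_ms, stim_amp=proto.stim_amp, stim_mask=mask,
                       stim_dur_ms=proto.stim_dur_ms, sample_ms=1.0)
    v = rec["v"]
    if lat.dims == 2:
        v = v.reshape(v.shape[0], lat.n_y, lat.n_x)
    act = activation_map(v, 1.0, require_reset=True)
    blocked = block_sites(act)
    stim_set = set(np.atleast_1d(mask).tolist()) if mask is not None else set()
    act_flat = np.asarray(act, dtype=float).ravel()
    non_stim = np.array([i for i in range(lat.S) if i not in stim_set])
    activated = ~np.isnan(act_flat[non_stim])
    if activated.all():
        outcome = "propagated"
    elif not activated.any():
        outcome = "global_block"
    else:
        outcome = "partial_block"
    return {"s1": res.record, "activation": act, "blocked": blocked,
            "outcome": outcome, "lattice": lat, "v": v}


# ---------------------------------------------------------------------------
# presets

def _fig8_stages(cl_hi=300.0, cl_lo=280.0, step=5.0, beats_per_step=100,
                 n_settle=400):
    stages = [(cl_hi, n_settle)]
    cl = cl_hi - step
    while cl >= cl_lo - 1e-9:
        stages.append((cl, beats_per_step))
        cl -= step
    return stages


PRESETS = {
    # name: (model, dict of scale -> protocol kwargs, description)
    "fig2": ("sarcomere", {
        "paper": dict(stages=[(600.0, 100), (300.0, 200)]),
        "small": dict(stages=[(600.0, 80), (300.0, 150)]),
    }, "single sarcomere, rate step 600->300 ms; slow alternans development"),
    "fig3": ("cell", {
        "paper": dict(stages=[(600.0, 100), (300.0, 400)]),
        "small": dict(stages=[(600.0, 80), (300.0, 250)]),
    }, "75-sarcomere cell, 600->300 ms; node formation, drift, extinction"),
    "fig5": ("multicell:5", {
        "paper": dict(stages=[(600.0, 100), (300.0, 400)]),
        "small": dict(stages=[(600.0, 80), (300.0, 250)]),
    }, "5 coupled cells, shared voltage; synchronisation to concordant phase"),
    "fig6": ("cable:200", {
        "paper": dict(stages=[(600.0, 100), (300.0, 400)]),
        "small": dict(stages=[(600.0, 60), (300.0, 200)]),
    }, "cable, all cells paced simultaneously; steady-state SDA"),
    "fig7": ("sheet:200x200", {
        "paper": dict(stages=[(600.0, 100), (300.0, 400)]),
        "small": dict(stages=[(600.0, 40), (300.0, 120)]),
    }, "2D sheet, simultaneous pacing; SDA nodal lines"),
    "fig8": ("cable:200", {
        "paper": dict(stages=_fig8_stages(), stim_sites=("left_edge", 5)),
        "small": dict(stages=_fig8_stages(beats_per_step=50, n_settle=200),
                      stim_sites=("left_edge", 5)),
    }, "cable paced at the left edge, CL 300->280 ms in 5 ms steps"),
}

_SMALL_MODEL = {"fig6": "cable:100", "fig7": "sheet:50x50",
                "fig8": "cable:100"}


def preset(name: str, scale: str = "small"):
    """Resolve a preset name to (ModelSpec, PacingProtocol, description).

    fig4 (AP clamp) and fig9 (S1-S2 wavebreak) have dedicated drivers
    (:func:`run_ap_clamp`, :func:`run_s1s2`); see the CLI.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)} "
                       "plus fig4a/b/c and fig9")
    model, by_scale, desc = PRESETS[name]
    if scale == "small":
        model = _SMALL_MODEL.get(name, model)
    kw = dict(by_scale[scale])
    return ModelSpec.parse(model), PacingProtocol(**kw), desc
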