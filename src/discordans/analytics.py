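"""Alternans analytics: amplitudes, phase maps, node detection and tracking,
diffusion length scales, activation maps and pattern statistics.

Conventions
-----------
The beat-to-beat alternans amplitude of a quantity ``x_n`` (peak Ca transient
``c_n`` in µM, or APD ``a_n`` in ms) is

    Δx_n = (-1)^n (x_n - x_{n-1}) / 2,

so opposite alternans phases carry opposite signs, and re-indexing the beats
by one flips every sign.  Nodes are the zero crossings of Δx along a spatial
profile; they separate out-of-phase regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AlternansRecord", "NodeTrack", "alternans_amplitude", "detect_nodes",
    "track_nodes", "diffusion_length", "phase_statistics", "activation_map",
    "block_sites", "apd80",
]


class InsufficientDataError(ValueError):
    """Fewer beats/points than the analysis needs."""


class DegenerateProfileError(ValueError):
    """An all-zero alternans profile has no phase anywhere."""


# --------------------------------------------------------------------------
# amplitudes

def alternans_amplitude(series, kind: str = "ca", axis: int = 0) -> np.ndarray:
    """Per-beat alternans amplitude Δx_n = (-1)^n (x_n - x_{n-1}) / 2.

    Parameters
    ----------
    series : array, beats along ``axis``
        Per-beat values (c_n or a_n).  NaN beats (capture failures)
        propagate to NaN amplitudes.
    kind : {"ca", "apd"}
        Documentation only; the algebra is identical.

    Returns an array with one fewer entry along ``axis`` (Δ defined for
    n ≥ 1; the returned index 0 corresponds to beat 1).
    """
    if kind not in ("ca", "apd"):
        raise ValueError(f"kind must be 'ca' or 'apd', got {kind!r}")
    x = np.asarray(series, dtype=float)
    if x.shape[axis] < 2:
        raise InsufficientDataError("need at least 2 beats for Δx_n")
    d = np.diff(x, axis=axis)
    n = np.arange(1, x.shape[axis])
    sgn = (-1.0) ** n
    shape = [1] * x.ndim
    shape[axis] = len(n)
    return sgn.reshape(shape) * d / 2.0


def _steady_amplitude(amp, tail=20):
    a = np.abs(amp[-tail:])
    return float(np.nanmean(a))


# --------------------------------------------------------------------------
# nodes

def detect_nodes(profile) -> np.ndarray:
    """Zero crossings of a 1D alternans profile, linearly interpolated.

    Values exactly zero mark a node at that index.  Crossings closer than
    half an index (e.g. an exact zero adjacent to an interpolated crossing)
    merge to their midpoint.  Raises :class:`DegenerateProfileError` for an
    all-zero profile.
    """
    y = np.asarray(profile, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise InsufficientDataError("profile must be 1D with length >= 2")
    if np.all(y == 0):
        raise DegenerateProfileError("all-zero profile: no phase anywhere")
    nodes = list(np.nonzero(y == 0)[0].astype(float))
    s = np.sign(y)
    for i in range(len(y) - 1):
        if s[i] != 0 and s[i + 1] != 0 and s[i] != s[i + 1]:
            # linear interpolation of the crossing
            x0 = i + y[i] / (y[i] - y[i + 1])
            nodes.append(x0)
    nodes = np.sort(np.asarray(nodes))
    # merge clusters closer than half an index to their midpoint
    merged = []
    i = 0
    while i < len(nodes):
        j = i
        while j + 1 < len(nodes) and nodes[j + 1] - nodes[j] < 0.5:
            j += 1
        merged.append(nodes[i:j + 1].mean())
        i = j + 1
    return np.asarray(merged)


@dataclass
class NodeTrack:
    """One node followed through beats.

    ``positions[k]`` is the node coordinate at ``beats[k]`` (continuous index
    units of the underlying profile).  ``death`` is "boundary",
    "annihilation" or "persists".
    """

    beats: list = field(default_factory=list)
    positions: list = field(default_factory=list)
    death: str = "persists"
    death_beat: int | None = None

    @property
    def birth_beat(self):
        return self.beats[0] if self.beats else None

    def drift_speed(self) -> float:
        """Mean drift in profile-index units per beat (signed, least squares)."""
        if len(self.beats) < 2:
            return 0.0
        b = np.asarray(self.beats, dtype=float)
        p = np.asarray(self.positions, dtype=float)
        return float(np.polyfit(b, p, 1)[0])


def track_nodes(node_sets, domain_length: float, max_jump_frac: float = 0.1,
                boundary_margin: float | None = None) -> list[NodeTrack]:
    """Match per-beat node sets into tracks by nearest-neighbour assignment.

    ``node_sets`` is a sequence (one entry per beat) of 1D coordinate arrays.
    Beat-to-beat matches farther than ``max_jump_frac * domain_length`` are
    rejected.  A track that disappears within ``boundary_margin`` of an end
    dies as "boundary"; two tracks that disappear on the same beat while
    approaching each other die as "annihilation"; an unmatched disappearance
    elsewhere is also "annihilation" (a collision partner may itself have
    just died).
    """
    if len(node_sets) < 2:
        raise InsufficientDataError("need node sets for at least 2 beats")
    max_jump = max_jump_frac * domain_length
    if boundary_margin is None:
        boundary_margin = max(0.05 * domain_length, max_jump)
    live: list[NodeTrack] = []
    done: list[NodeTrack] = []
    for n, nodes in enumerate(node_sets):
        nodes = np.sort(np.asarray(nodes, dtype=float))
        taken = np.zeros(len(nodes), dtype=bool)
        # greedy minimal-displacement matching
        pairs = []
        for ti, tr in enumerate(live):
            last = tr.positions[-1]
            for ni, x in enumerate(nodes):
                d = abs(x - last)
                if d <= max_jump:
                    pairs.append((d, ti, ni))
        pairs.sort()
        matched_t = set()
        for d, ti, ni in pairs:
            if ti in matched_t or taken[ni]:
                continue
            matched_t.add(ti)
            taken[ni] = True
            live[ti].beats.append(n)
            live[ti].positions.append(nodes[ni])
        # deaths
        dying = [tr for ti, tr in enumerate(live) if ti not in matched_t]
        survivors = [tr for ti, tr in enumerate(live) if ti in matched_t]
        if dying:
            for tr in dying:
                last = tr.positions[-1]
                if last <= boundary_margin or last >= domain_length - boundary_margin:
                    tr.death = "boundary"
                else:
                    tr.death = "annihilation"
                tr.death_beat = n
                done.append(tr)
        live = survivors
        # births
        for ni, x in enumerate(nodes):
            if not taken[ni]:
                live.append(NodeTrack(beats=[n], positions=[x]))
    for tr in live:
        tr.death = "persists"
        done.append(tr)
    done.sort(key=lambda t: (t.birth_beat if t.birth_beat is not None else 0))
    return done


# --------------------------------------------------------------------------
# length scales

def diffusion_length(d_cm2_per_s: float, cl_ms: float) -> float:
    """Per-beat diffusion length ξ = sqrt(D · CL), returned in cm.

    For subcellular Ca (D ≈ 3e-6 cm²/s) at CL = 300 ms this is ≈ 0.001 cm
    (0.01 mm), the minimum spacing of Ca alternans nodes; for voltage in
    tissue (D ≈ 1 cm²/s) it is ≈ 0.55 cm, the minimum spacing of APD nodes.
    """
    if d_cm2_per_s < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    if cl_ms <= 0:
        raise ValueError("cycle length must be > 0")
    return float(np.sqrt(d_cm2_per_s * cl_ms / 1000.0))


# --------------------------------------------------------------------------
# APD

def apd80(trace, dt_ms: float = 1.0):
    """APD at 80% repolarisation from a sampled voltage trace of one beat.

    Upstroke time is the maximum of dV/dt; the repolarisation level is
    V_peak - 0.8 (V_peak - V_dia), with V_dia the pre-upstroke minimum.
    Returns NaN when no action potential was elicited (capture failure).
    Accepts a 1D trace or (samples, sites) array; returns scalar or (sites,).
    """
    v = np.asarray(trace, dtype=float)
    if v.ndim == 1:
        return _apd80_1d(v, dt_ms)
    return np.array([_apd80_1d(v[:, s], dt_ms) for s in range(v.shape[1])])


def _apd80_1d(v, dt_ms):
    if len(v) < 4:
        return np.nan
    dv = np.diff(v)
    iup = int(np.argmax(dv))
    if dv[iup] <= 0.5 * dt_ms:  # no upstroke faster than 0.5 mV/ms
        return np.nan
    vdia = v[:iup].min() if iup > 0 else v.min()
    ipk = iup + int(np.argmax(v[iup:]))
    vpk = v[ipk]
    if vpk < -40.0:
        return np.nan
    level = vpk - 0.8 * (vpk - vdia)
    below = np.nonzero(v[ipk:] < level)[0]
    if len(below) == 0:
        return np.nan
    j = ipk + below[0]
    frac = (v[j - 1] - level) / (v[j - 1] - v[j])
    return (j - 1 + frac - iup) * dt_ms


# --------------------------------------------------------------------------
# records

@dataclass
class AlternansRecord:
    """Per-beat peaks and APDs of a pacing run, with derived amplitude maps.

    c : (n_beats, n_cells, m) peak cytosolic Ca per sarcomere, µM
    a : (n_beats, n_sites) APD per membrane site, ms (NaN = capture failure)
    cl : (n_beats,) cycle length of each beat, ms
    capture : (n_beats, n_sites) bool, True when the stimulus elicited an AP
    """

    c: np.ndarray
    a: np.ndarray
    cl: np.ndarray
    capture: np.ndarray | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.cl = np.asarray(self.cl, dtype=float)
        if self.capture is None and self.a.size:
            self.capture = ~np.isnan(self.a)

    @property
    def n_beats(self):
        return self.c.shape[0]

    @property
    def dca(self) -> np.ndarray:
        """Δc_n indexed (beat-1, cell, sarcomere)."""
        return alternans_amplitude(self.c, "ca", axis=0)

    @property
    def da(self) -> np.ndarray:
        """Δa_n indexed (beat-1, site)."""
        return alternans_amplitude(self.a, "apd", axis=0)


# --------------------------------------------------------------------------
# pattern statistics

def phase_statistics(records, tail: int = 20, amp_floor_frac: float = 0.05,
                     m: int | None = None) -> dict:
    """Summary statistics over repeated seeded runs of the same protocol.

    For each record the final alternans phase is the sign of the
    whole-cell-mean Δc averaged over the last ``tail`` beats.  Runs whose
    steady |Δc| is below ``amp_floor_frac`` of the mean peak are excluded
    (no sustained alternans) and counted in ``n_excluded``.

    Returns final-phase counts with a two-sided binomial p-value of the
    50/50 hypothesis, the mean node spacing, and the fraction of Ca nodes
    lying on cell boundaries (within half a sarcomere).
    """
    if len(records) < 2:
        raise InsufficientDataError("need >= 2 records for frequencies")
    signs, excluded = [], 0
    spacings, n_boundary, n_nodes = [], 0, 0
    for rec in records:
        dca = rec.dca
        prof = dca[-tail:].mean(axis=0).ravel()  # cells*m profile
        amp = np.abs(dca[-tail:]).mean()
        if amp < amp_floor_frac * np.nanmean(rec.c[-tail:]):
            excluded += 1
            continue
        signs.append(np.sign(prof.mean()))
        try:
            nodes = detect_nodes(prof)
        except DegenerateProfileError:
            nodes = np.array([])
        if len(nodes) > 1:
            spacings.extend(np.diff(nodes))
        if m is not None and len(nodes):
            n_nodes += len(nodes)
            rel = np.mod(nodes + 0.5, m)   # node between index k,k+1 sits at k+0.5
            n_boundary += int(np.sum((rel <= 1.0) | (rel >= m - 1.0)))
    signs = np.asarray(signs)
    n_pos = int(np.sum(signs > 0))
    n_tot = len(signs)
    pval = stats.binomtest(n_pos, n_tot, 0.5).pvalue if n_tot else np.nan
    return {
        "n_runs": n_tot,
        "n_excluded": excluded,
        "n_positive": n_pos,
        "n_negative": n_tot - n_pos,
        "binomial_p": float(pval) if pval == pval else np.nan,
        "mean_node_spacing": float(np.mean(spacings)) if spacings else np.nan,
        "boundary_node_fraction": (n_boundary / n_nodes) if n_nodes else np.nan,
    }


# --------------------------------------------------------------------------
# activation maps / conduction block

def activation_map(v_history, dt_ms: float = 1.0, threshold_mv: float = -20.0,
                   t0_ms: float = 0.0, require_reset: bool = False) -> np.ndarray:
    """First upward threshold crossing per site, in ms relative to ``t0_ms``.

    ``v_history`` is (samples, sites) or (samples, ny, nx).  Sites that never
    activate get NaN.  Crossings are linearly interpolated; only the first
    is reported (later re-activations within the window are ignored).  A
    site already above threshold at the window start is reported as 0 unless
    ``require_reset`` is set, in which case only a fresh upstroke (after the
    site has repolarised below threshold) counts — the right convention when
    mapping a premature-beat response on partly depolarised tissue.
    """
    v = np.asarray(v_history, dtype=float)
    shp = v.shape[1:]
    v2 = v.reshape(v.shape[0], -1)
    nt, ns = v2.shape
    out = np.full(ns, np.nan)
    above = v2 >= threshold_mv
    rising = ~above[:-1] & above[1:]
    for s in range(ns):
        idx = np.nonzero(rising[:, s])[0]
        if above[0, s] and not require_reset and not (len(idx) and idx[0] == 0):
            # already above threshold at window start
            out[s] = 0.0
            continue
        if len(idx):
            i = idx[0]
            frac = (threshold_mv - v2[i, s]) / (v2[i + 1, s] - v2[i, s])
            out[s] = (i + frac) * dt_ms + t0_ms
    return out.reshape(shp)


def block_sites(act_map) -> np.ndarray:
    """Boolean mask of conduction-block sites: never activated while at
    least one lattice neighbour activated."""
    act = np.asarray(act_map, dtype=float)
    blocked = np.isnan(act)
    if act.ndim == 1:
        neigh = np.zeros_like(blocked)
        neigh[:-1] |= ~np.isnan(act[1:])
        neigh[1:] |= ~np.isnan(act[:-1])
    else:
        neigh = np.zeros_like(blocked)
        neigh[:-1, :] |= ~np.isnan(act[1:, :])
        neigh[1:, :] |= ~np.isnan(act[:-1, :])
        neigh[:, :-1] |= ~np.isnan(act[:, 1:])
        neigh[:, 1:] |= ~np.isnan(act[:, :-1])
    return blocked & neigh
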