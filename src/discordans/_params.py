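"""Model parameters and their packed representation for the numba kernels.

Two parameter groups exist: :class:`CaCyclingParams` (subcellular Ca cycling
of one sarcomere) and :class:`IonicParams` (membrane currents).  The kernels
consume a single flat ``float64`` vector; :func:`pack_params` produces it and
the ``P_*`` index constants name its slots.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from enum import Enum

import numpy as np

__all__ = [
    "NoiseSource",
    "CaCyclingParams",
    "IonicParams",
    "pack_params",
    "NOISE_FRAME_MS",
    "SARCOMERE_SPACING_CM",
    "D_CA_CM2_PER_S",
]

#: Interval on which a fresh SERCA-noise variate is drawn; also the reference
#: step dt_ref of the Euler–Maruyama discretisation (ms).
NOISE_FRAME_MS = 0.1

#: Sarcomere spacing: a ~100 µm cell divided into 75 sarcomeres (cm).
SARCOMERE_SPACING_CM = 100e-4 / 75.0

#: Effective cytosolic Ca diffusion coefficient (cm²/s).
D_CA_CM2_PER_S = 3e-6


def _tau_from_d(d_cm2_per_s: float) -> float:
    """Nearest-neighbour exchange time constant (ms) for a diffusion
    coefficient on the sarcomere lattice: tau = dx² / D."""
    d_cm2_per_ms = d_cm2_per_s / 1000.0
    return SARCOMERE_SPACING_CM**2 / d_cm2_per_ms


class NoiseSource(str, Enum):
    """Which subcellular flux carries the stochastic term."""

    SERCA = "serca"
    SR_RELEASE = "sr_release"
    NONE = "none"


@dataclass
class CaCyclingParams:
    """Phenomenological four-compartment Ca cycling of one sarcomere.

    Concentrations are µM, times ms.  Fluxes between compartments are
    expressed per cytosolic volume; ``nu_*`` are compartment volumes relative
    to the cytosol, so the conserved total is
    ``c_i + nu_s*c_s + nu_n*c_nsr + nu_j*c_jsr``.
    """

    #: Release-load gain (1/ms).  The steepness of the effective SR
    #: release-load relation grows with this gain; the default is in the
    #: alternans-unstable regime, 1.5 is the stable reference value.
    u_release: float = 4.0
    #: Centre (µM) and width (µM) of the sigmoidal JSR-load dependence of
    #: release.
    c_jsr_thresh: float = 150.0
    c_jsr_slope: float = 12.0
    #: Maximal SERCA uptake rate (µM/ms) and half-saturation (µM); Hill
    #: coefficient 2.
    v_up_max: float = 0.12
    k_up: float = 0.35
    #: Effective number of SERCA pumps per sarcomere.  The per-step uptake
    #: variance scales as 1/n_pumps; at ``n_pumps == n_pumps_ref`` the
    #: relative per-step noise equals ``sigma_rel``.
    n_pumps: float = 2000.0
    n_pumps_ref: float = 2000.0
    #: Relative SERCA-noise amplitude at the reference pump count and
    #: reference step (dimensionless, calibrated to ~0.10).
    sigma_rel: float = 0.10
    noise_source: NoiseSource = NoiseSource.SERCA
    #: Inter-sarcomere coupling time constants (ms), tau = dx²/D_eff on the
    #: sarcomere lattice.  The cytosolic default encodes the buffered
    #: EFFECTIVE transport coefficient (~6e-7 cm²/s), an order of magnitude
    #: below the free-Ca diffusion coefficient; the luminal routes (NSR and
    #: the junctional terminals, which are continuous with the SR network)
    #: are slower still.
    tau_diff_cyto: float = 30.0
    tau_diff_nsr: float = 120.0
    tau_diff_jsr: float = 240.0
    #: NSR→JSR refill time constant (ms).
    tau_tr: float = 600.0
    #: Submembrane→cytosol relaxation time constant (ms).
    tau_sm: float = 2.0
    #: Release-gate recovery and spend time constants (ms).
    tau_r_recover: float = 150.0
    tau_r_spend: float = 8.0
    #: Spark lifetime: decay time of the recruited release flux (ms).
    tau_spark: float = 20.0
    #: Load-independent (graded) share of the release gain, and the gain at
    #: which the sigmoidal share has unit weight (1/ms).
    g_rel_lin: float = 0.02
    u_scale: float = 4.0
    #: Compartment volume ratios (relative to cytosol).
    nu_s: float = 0.2
    nu_n: float = 0.20
    nu_j: float = 0.25
    #: Trigger efficiency: fraction of the normalised L-type trigger that
    #: engages the release machinery per ms (dimensionless).  Sets the scale
    #: of the per-beat release fraction; the load steepness is u_release *
    #: the sigmoid slope.
    g_trig: float = 0.03
    #: L-type Ca influx gain (µM/ms per unit normalised trigger).
    g_ca_influx: float = 0.4
    #: NCX extrusion gain (µM/ms per unit NCX activation).
    g_ncx_flux: float = 0.08
    #: Background sarcolemmal leak influx (µM/ms), balances NCX at rest.
    g_leak_in: float = 1.6e-3
    #: SR leak conductance (1/ms); flux = g_sr_leak * (c_nsr - c_i).
    g_sr_leak: float = 7.55e-5
    #: Instantaneous cytosolic/submembrane Ca buffer: capacity (µM) and
    #: dissociation constant (µM).  State is carried as total Ca; fluxes act
    #: on the free concentration obtained by closed-form inversion.
    buf_b: float = 60.0
    buf_k: float = 0.6

    def validate(self) -> None:
        for name in (
            "u_release",
            "c_jsr_slope",
            "v_up_max",
            "k_up",
            "n_pumps",
            "tau_diff_cyto",
            "tau_diff_nsr",
            "tau_tr",
            "tau_sm",
            "tau_r_recover",
            "tau_r_spend",
            "nu_s",
            "nu_n",
            "nu_j",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"CaCyclingParams.{name} must be > 0")
        if self.sigma_rel < 0:
            raise ValueError("CaCyclingParams.sigma_rel must be >= 0")
        self.noise_source = NoiseSource(self.noise_source)

    def with_(self, **kw) -> "CaCyclingParams":
        p = replace(self, **kw)
        p.validate()
        return p

    @property
    def sigma_step(self) -> float:
        """Relative per-step uptake noise at the reference step dt_ref."""
        if self.noise_source is not NoiseSource.SERCA:
            return 0.0
        return self.sigma_rel * np.sqrt(self.n_pumps_ref / self.n_pumps)


@dataclass
class IonicParams:
    """Membrane model: a three-current (fast inward / slow outward / slow
    inward) formulation in normalised voltage u = (V - v_rest)/v_amp, mapped
    to physical mV, plus the two Ca-sensitive couplings computed per
    sarcomere (L-type trigger with Ca-induced inactivation, and an NCX-like
    inward current proportional to submembrane Ca occupancy).

    Per-sarcomere currents are normalised by the sarcomere count, so
    whole-cell magnitudes do not depend on M.
    """

    v_rest: float = -85.0  # mV
    v_amp: float = 100.0  # mV, excursion scale (peak ≈ v_rest + v_amp)
    c_m: float = 1.0  # µF/cm²
    u_c: float = 0.13  # excitation threshold (normalised)
    u_v: float = 0.04  # fast-gate kinetics switch (normalised)
    tau_d: float = 0.25  # fast inward time scale, ms
    tau_v1m: float = 19.6
    tau_v2m: float = 1250.0
    tau_vp: float = 3.33
    tau_0: float = 12.5  # subthreshold decay, ms
    tau_r: float = 33.0  # plateau repolarising current scale, ms
    tau_si: float = 30.0  # slow-inward (L-type-like) scale, ms
    k_si: float = 10.0
    u_csi: float = 0.84
    tau_wm: float = 20.0  # slow-gate recovery, ms
    tau_wp: float = 800.0
    #: NCX-like inward current gain (normalised 1/ms per unit occupancy).
    g_ncx_v: float = 0.02
    #: Submembrane-Ca half-saturation of NCX activation (µM).
    k_ncx: float = 5.0
    #: Ca-induced inactivation scale of the L-type trigger (µM).
    c_fca: float = 5.0
    #: Trigger-gate kinetics: voltage-dependent activation (u_d, k_d) and
    #: fast inactivation/recovery of the latch gate (ms).
    u_d: float = 0.45
    k_d: float = 0.05
    u_fi: float = 0.25
    k_fi: float = 0.05
    tau_f_inact: float = 8.0
    tau_f_rec: float = 40.0

    def validate(self) -> None:
        if self.c_m <= 0:
            raise ValueError("IonicParams.c_m must be > 0")
        for name in ("tau_d", "tau_0", "tau_r", "tau_si", "tau_wm", "tau_wp",
                     "tau_v1m", "tau_v2m", "tau_vp", "v_amp", "k_ncx", "c_fca",
                     "tau_f_inact", "tau_f_rec"):
            if getattr(self, name) <= 0:
                raise ValueError(f"IonicParams.{name} must be > 0")
        if self.g_ncx_v < 0:
            raise ValueError("IonicParams.g_ncx_v must be >= 0")

    def with_(self, **kw) -> "IonicParams":
        p = replace(self, **kw)
        p.validate()
        return p


# ---------------------------------------------------------------------------
# Packed layout consumed by the numba kernels.

_PACK_ORDER = [
    # membrane
    "v_rest", "v_amp", "c_m", "u_c", "u_v", "tau_d", "tau_v1m", "tau_v2m",
    "tau_vp", "tau_0", "tau_r", "tau_si", "k_si", "u_csi", "tau_wm", "tau_wp",
    "g_ncx_v", "k_ncx", "c_fca",
    # ca cycling
    "u_release", "c_jsr_thresh", "c_jsr_slope", "v_up_max", "k_up",
    "sigma_step", "tau_diff_cyto", "tau_diff_nsr", "tau_tr", "tau_sm",
    "tau_r_recover", "tau_r_spend", "nu_s", "nu_n", "nu_j", "g_ca_influx",
    "g_ncx_flux", "g_leak_in", "g_sr_leak", "noise_mode", "g_trig",
    "tau_spark", "g_rel_lin", "u_scale", "u_d", "k_d", "u_fi", "k_fi",
    "tau_f_inact", "tau_f_rec", "buf_b", "buf_k", "tau_diff_jsr",
]

for _i, _name in enumerate(_PACK_ORDER):
    globals()["P_" + _name.upper()] = _i
N_PACKED = len(_PACK_ORDER)

_NOISE_MODE = {NoiseSource.NONE: 0.0, NoiseSource.SERCA: 1.0,
               NoiseSource.SR_RELEASE: 2.0}


def free_from_total(total, b, k):
    """Free Ca from total for an instantaneous single-site buffer."""
    total = np.asarray(total, dtype=float)
    a = total - b - k
    return 0.5 * (a + np.sqrt(a * a + 4.0 * k * total))


def total_from_free(free, b, k):
    """Total (free + buffer-bound) Ca for an instantaneous buffer."""
    free = np.asarray(free, dtype=float)
    return free + b * free / (k + free)


def pack_params(ion: IonicParams, ca: CaCyclingParams) -> np.ndarray:
    """Flatten both parameter groups into the kernel vector."""
    ion.validate()
    ca.validate()
    out = np.empty(N_PACKED, dtype=np.float64)
    src = {f.name: getattr(ion, f.name) for f in fields(ion)}
    src.update({f.name: getattr(ca, f.name) for f in fields(ca)})
    src["sigma_step"] = ca.sigma_step
    src["noise_mode"] = _NOISE_MODE[NoiseSource(ca.noise_source)]
    for i, name in enumerate(_PACK_ORDER):
        out[i] = float(src[name])
    return out
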