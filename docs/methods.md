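# Methods

This note describes the model implemented in `discordans`, the reasoning
behind its design choices, its numerical scheme, what the built-in scenario
generator does and does not emulate, and its known limitations.

## 1. Overview

The package simulates the formation of spatially discordant alternans (SDA)
of action potential duration (APD) and Ca-transient amplitude in rapidly
paced cardiac tissue, in the regime where

1. the beat-to-beat instability originates in sarcoplasmic-reticulum (SR)
   Ca cycling (a steep relation between SR Ca release and SR load), not in
   voltage dynamics (APD restitution is kept flat);
2. Ca→APD coupling is positive (a large Ca transient prolongs the APD), so
   Ca and APD alternans are electromechanically concordant; and
3. alternans develops slowly, over on the order of 100 beats, as the cell
   accumulates Ca after an abrupt rate increase.

Under these conditions the alternans *phase* of each subcellular region is
decided, during the long low-amplitude growth period, by stochastic
fluctuations of Ca cycling; regions of opposite phase then coarsen through
Ca diffusion (short range) and the shared membrane voltage (long range)
into steady discordant patterns.

The model is organised in three nested scales:

* a **sarcomere**: four Ca compartments + release gating (the smallest
  stochastic unit);
* a **cell**: M = 75 sarcomeres exchanging Ca, one membrane voltage;
* **tissue**: cells coupled only through voltage (monodomain cable
  equation); Ca never crosses cell boundaries.

## 2. Subcellular Ca cycling

Each sarcomere carries free Ca concentrations in four compartments —
cytosol `c_i`, submembrane space `c_s`, network SR `c_nsr`, junctional SR
`c_jsr` (µM) — plus a release-recovery gate `r ∈ [0,1]` and a recruited
spark flux `q` (µM/ms).  Compartment volumes are expressed relative to the
cytosol (`nu_s`, `nu_n`, `nu_j`), so the conserved quantity is the
volume-weighted sum of total compartment Ca.

**Buffering.**  Cytosolic and submembrane Ca are buffered by an
instantaneous single-site buffer (capacity `buf_b` = 60 µM, K_d `buf_k` =
0.6 µM).  The integrator carries *total* Ca and computes the free
concentration by the closed-form inversion of the binding isotherm; all
rate laws act on free Ca.  Buffering is not cosmetic: it separates the
amount of Ca moved per beat (tens of µM total) from the free concentration
the SERCA pump sees (~0.1–1 µM), which is what makes SR re-uptake slow
relative to one cycle and allows a beat-to-beat SR-load memory to exist at
all.  Without buffers every released µM is re-sequestered within the same
cycle and the return map cannot period-double.

**Release (spark latch).**  The L-type trigger is a brief (~6 ms) pulse:
a fast voltage-dependent activation `d_inf(u)` times an inactivating latch
gate `f` (τ_inact = 8 ms depolarised, τ_rec = 40 ms at rest), times mild
Ca-induced inactivation `1/(1+(c_i/c_fca)²)`.  The trigger recruits a
release flux

    dq/dt = nu_j · g_trig · r · trig · gain(c_jsr) · c_jsr  −  q/τ_spark,
    gain(c_jsr) = u_release · (g_rel_lin + (u_release/u_scale) · σ(c_jsr)),

where σ is a sigmoid centred at `c_jsr_thresh` = 150 µM with width
`c_jsr_slope` = 12 µM, and τ_spark = 20 ms is the spark lifetime.  Two
features are essential.  First, the release amplitude is *latched* to the
JSR load at trigger time: a law that tracks the instantaneous (falling)
load self-terminates and caps the beat-to-beat map slope near one, so no
period-doubling is possible.  Second, the load-independent share
`g_rel_lin` = 0.02 is nearly zero: flux balance then forces the operating
point onto the sigmoid flank.  Because the sigmoidal share carries an
extra factor `u_release/u_scale`, the stable reference gain u = 1.5 ms⁻¹
operates on the saturated part of the sigmoid (no steepness → period-1),
while the default u = 4 ms⁻¹ operates mid-flank (steep → alternans).  This
makes the single parameter `u_release` the bifurcation dial, as intended.

**Uptake (stochastic SERCA).**  Deterministic uptake is Hill-2,
`J = v_up c_i²/(k_up²+c_i²)` with `v_up` = 0.12 µM/ms, `k_up` = 0.35 µM.
The finite number of pumps per sarcomere makes uptake noisy; the
Euler–Maruyama discretisation multiplies J by
`1 + σ_rel √(n_ref/n_pumps) √(dt_ref/dt) ξ`, ξ ~ N(0,1), with dt_ref = 0.1
ms, σ_rel = 0.10 and n_pumps = n_ref = 2000 by default.  The per-step
variance therefore scales as 1/(n_pumps·dt); at defaults the per-step
std/mean is 10%.  The exact dependence g(n_pumps) = √(n_ref/n_pumps) is a
modelling choice; only the ~10% amplitude and the 1/n_pumps variance
scaling are constrained.  An alternative noise source
(`noise_source="sr_release"`) applies uniform multiplicative noise of
amplitude ±σ_rel to the release flux instead; the tissue-scale phenomena
do not depend on which source is used.

**Other fluxes.**  NSR→JSR refill is first-order with τ_tr = 600 ms —
deliberately *slower than one cycle*, so the post-release load deficit of
a big beat survives into the next beat (the alternans memory).  The JSR is
the dominant releasable pool (`nu_j` = 0.25 vs `nu_n` = 0.20).
Submembrane→cytosol relaxation has τ_sm = 2 ms.  NCX extrusion is
`g_ncx_flux · c_s/(c_s+k_ncx)`; a constant background influx balances it
at rest, and a small linear SR leak (`g_sr_leak`) balances resting uptake
and sets the resting SR load.  The release gate recovers with τ = 150 ms
and is spent by the trigger (τ_spend = 8 ms), adding rate-dependence.

**Intra-cell coupling.**  Sarcomeres exchange Ca along the chain in exact
antisymmetric flux form (zero-flux ends): cytosolic total Ca with
τ_dc = 30 ms per lattice step, luminal Ca through the SR network —
both the NSR pool (τ_dn = 120 ms) and the junctional terminals
(τ_jsr = 240 ms), which are physically continuous with the network SR.
With 75 sarcomeres per 100 µm these constants correspond to effective
transport coefficients of roughly 6·10⁻⁷, 1.5·10⁻⁷ and 7·10⁻⁸ cm²/s.
They are an order of magnitude below the free-Ca diffusion coefficient
D_Ca ≈ 3·10⁻⁶ cm²/s because the exchanged quantity is buffered total Ca;
the free-Ca value is still what enters the analytic per-beat length
ξ_Ca = √(D_Ca·CL) reported by `analytics.diffusion_length`.  The luminal
JSR route matters: the alternans phase lives in the junctional load, and
without that route the phase field of a cell is effectively uncoupled and
fragments into ~10 independent micro-domains instead of synchronising.
The three constants were calibrated jointly against three behaviours: a
free-running cell synchronises its sarcomeres (0–1 interior nodes by ~300
beats), a node held by a *periodic* AP clamp stays pinned (>200 beats,
drift <1 sarcomere), and an *alternating* clamp expels the node.

## 3. Membrane model

The membrane is a three-current formulation in the normalised voltage
u = (V−V_rest)/V_amp (V_rest = −85 mV, V_amp = 100 mV, C_m = 1 µF/cm²):
a fast inward (Na-like) current gated by `v` with excitation threshold
u_c = 0.13; an outward (K-like) current, linear below threshold (τ_0) and
constant during the plateau (1/τ_r, with a soft guard that grows above
u = 1 to bound the plateau); and a slow inward (L-type-like) plateau
current `w·s_inf(u)/τ_si` computed per sarcomere with the Ca-induced
inactivation factor.  The per-sarcomere Ca-sensitive pair — slow inward
plus an NCX-like inward current `g_ncx_v · c_s/(c_s+k_ncx)` — is averaged
over the M sarcomeres, so whole-cell magnitudes are M-independent and
every sarcomere sees the same voltage.

The parameters were tuned to a behavioural contract rather than to any
specific ionic dataset: APD₈₀ ≈ 183 ms at CL = 600 ms, flat APD
restitution (no voltage-driven alternans down to CL = 250 ms with stable
Ca cycling), 1:1 capture at CL ≥ 280 ms, and positive Ca→APD coupling
(the NCX term dominates the negative Ca-induced-inactivation pathway, so
a ~20% larger Ca transient measurably prolongs the APD).  With the
unstable Ca gain, steady APD alternans is |Δa| ≈ 4 ms at CL = 300 ms and
always electromechanically concordant.

APD is measured as APD₈₀: from the maximum-dV/dt upstroke to 80%
repolarisation toward the pre-upstroke diastolic minimum, linearly
interpolated on the 1-ms sampled trace.  A beat whose peak V stays below
−40 mV, or that lacks an upstroke, is a capture failure (APD = NaN).

## 4. Tissue

Voltage obeys the monodomain cable equation with D_V = 10⁻³ cm²/ms and
Δx = 0.015 cm (one cell per site), integrated by operator splitting: a
reaction substep (every cell) followed by a diffusion substep — explicit
FTCS in 1D (the engine caps the step at the stability bound 0.5Δx²/D_V),
Peaceman–Rachford ADI in 2D (unconditionally stable) — with zero-flux
boundaries.  The time step adapts between 0.01 ms (while any site has
|dV/dt| > 5 mV/ms) and 0.1 ms, switching on 0.1-ms frames.  Ca diffusion
between cells is zero.  A small multi-cell group (2–5 cells) shares a
single voltage with I_ion averaged over all sarcomeres.

Stimuli are 40 µA/cm² for 1 ms (about twice the diastolic threshold),
delivered to all sites (simultaneous pacing, which excludes the classical
CV-restitution route to SDA by construction) or to an edge strip.

## 5. Noise and reproducibility

One noise variate per sarcomere is drawn per 0.1-ms frame and applied to
every substep within the frame, so the integrated fluctuation does not
depend on the adaptive substep choice.  Streams are Philox counter
generators keyed by (seed, global cell index): every cell owns an
independent, reproducible stream, identical runs give identical records,
and a cell simulated in isolation sees exactly the same draws as the same
cell inside a tissue with D_V = 0 (the decoupling limit is bitwise).

## 6. Scenario presets and scales

The presets reproduce the standard experiments: rate-step alternans
development in a sarcomere (`fig2`) and a cell (`fig3`); AP-clamp node
pinning and drift (`fig4a/b/c`); 5-cell synchronisation (`fig5`); cable
SDA under simultaneous pacing (`fig6`); 2D sheets (`fig7`, with D_V
overrides 2.5·10⁻³ and 6.25·10⁻⁴ cm²/ms); edge pacing with a gradual CL
step 300→280 ms in 5-ms stages (`fig8`); and the S1–S2 premature-stimulus
wavebreak test on steady SDA (`fig9`).  Every preset has a `paper` scale
(e.g. 200-cell cables, 200×200 sheets, 400 beats) and a `small`
desk scale.  The test suite uses reduced problem sizes chosen so the
whole suite completes in tens of minutes on one core — e.g. a 100-cell
cable (full 75-sarcomere cells) for the simultaneous-pacing check and a
30-sarcomere variant for the edge-pacing staircase, with a few hundred
beats of coarsening where the full pattern would take more; these
sizes are the package's own choice of desk scale and the qualitative
claims they check (node formation, concordance, boundary pinning, node
immobility under edge pacing) are scale-robust in our experience.

For the AP-clamp experiment the periodic waveform is one steady AP
recorded from a single sarcomere with stable Ca cycling (u = 1.5 ms⁻¹) at
CL = 300 ms; the alternating LSLS/SLSL waveforms stretch/compress that AP
by ±10% in time (APD difference ≈ 36 ms), following the convention of
composing two recorded APs of different duration.  The subcellular node is
initialised by assigning end-of-beat states from a large and a small beat
of the unstable sarcomere above/below sarcomere 12.

## 7. What the generator emulates — and what it does not

All inputs are generated by the simulator itself; there is no external
data.  The synthetic scenarios emulate: slow SR Ca accumulation after a
rate step; fluctuation-seeded random alternans phase; subcellular
discordance, node drift, pinning and annihilation; tissue-scale SDA with
Ca nodes clustering where |Δa| is small and migrating to cell boundaries;
node immobility under edge pacing (in contrast to the CV-restitution
mechanism); and conduction block of premature beats at phase boundaries.
They do **not** emulate: spark-resolved (discrete RyR cluster)
stochasticity; anatomical heterogeneity, fibre anisotropy or realistic
geometry; ionic-model detail (no I_to, I_Kr/I_Ks split, pump/background
current spectrum); mechanics; or the reentrant dynamics after wavebreak.
Passing tests therefore support the pattern-forming mechanism, not
quantitative electrophysiology of any particular species.

## 8. Numerical choices

* Forward Euler for voltage, gates and most fluxes; the JSR update and the
  release gate are semi-implicit (evaluated at the stabilised end-of-step
  value), which keeps the update exactly conservative and positive.
* With membrane fluxes and noise off, total cell Ca (including
  buffer-bound) is conserved to rounding (antisymmetric pairwise exchange;
  relative drift ≲10⁻¹² over 10⁵ steps).
* Negative concentrations (possible transiently under large noise) are
  clipped to zero and counted; a run aborts if clips exceed 0.1% of steps.
  NaN or out-of-range voltage raises an integration failure naming the
  field.
* Node detection uses linearly interpolated zero crossings of Δc or Δa
  profiles; exact zeros are nodes; crossings closer than half an index
  merge to their midpoint (a 1-index merge radius would contradict the
  exact-interpolation convention for adjacent-interval crossings).
* Node tracking is greedy minimal-displacement matching with a maximum
  per-beat jump of 10% of the domain; disappearances near a boundary are
  classified "boundary", otherwise "annihilation".
* The beat window for the Ca-transient peak is [stimulus, stimulus+CL),
  sampled at 1 ms.

## 9. Known limitations

* The membrane model is phenomenological; its APD restitution is
  deliberately flat, so phenomena that depend on steep voltage restitution
  are out of scope.
* Alternans amplitude saturates through the sigmoid; very deep SR
  depletion regimes (e.g. subcellular Ca waves) are not represented.
* The multi-cell group's deterministic steady state is identical across
  seeds when the common-mode rate-step transient dominates the (averaged)
  noise; phase randomisation is a single-sarcomere/small-amplitude
  property, as intended.
* 2D runs at the full 200×200 paper scale are supported but long-running
  (hours on one core); the test suite exercises reduced sheets only.
* The S1–S2 test classifies propagation/block from activation maps; it
  does not follow or classify the post-break reentry.
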