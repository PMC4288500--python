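# Methods

This note documents the models, the synthetic-data assumptions, the
numerical choices and the known limitations of `kmburst`. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`.

## Curve fitting

**Hill.** Responses are fitted with
y = E_max·Cⁿᴴ/(EC₅₀ⁿᴴ + Cⁿᴴ) by nonlinear least squares
(`scipy.optimize.curve_fit`), with standard errors from the curvature of
the objective (square roots of the covariance diagonal). A variant with a
bare EC₅₀ in the denominator — a form sometimes printed but dimensionally
inconsistent for n_H ≠ 1 — is available behind
`HillCurve(denominator="as_printed")` for comparison only. Initialization:
E_max at the response maximum, EC₅₀ at the concentration whose mean
response is nearest half-maximal, n_H = 1.

**Boltzmann.** Relative conductance is fitted with
G/G_max = 1/(1 + exp[−(V − V₁ᐟ₂)qF/RT]). The temperature enters through
RT/F (25.43 mV at the default 295 K, matching room-temperature recording);
*q* is the apparent gating charge in elementary charges. Initialization:
G_max at the conductance maximum, V₁ᐟ₂ at the voltage of half-range
conductance, q = 2. For whole-cell sweep data, chord conductance is
computed from end-of-pulse currents as G = I_end/(V − V_K) with V_K = −91
mV by default (the K⁺ reversal of the recording solutions and of the
model), then averaged across cells.

Both fitters are scikit-learn estimators (`fit`/`predict`, `get_params`);
non-convergence and degenerate inputs (constant responses) set
`converged_ = False` with a message instead of raising.

**Linear fits.** The whole-cell conductance is the OLS slope of I–V points
inside a closed voltage window (default −30..−10 mV); pA/mV equals nS. The
single-channel conductance is the regression slope of mean unitary
amplitudes on holding potential, optionally constrained through the
reversal, reported in pS.

## Synthetic data

The generators emulate the statistical structure the analyses assume; all
randomness flows from one integer seed through named, independent streams
(`kmburst._rng`), so identical specs and seeds give bit-identical output.

* **Voltage-step sweeps**: Boltzmann-activated conductance with
  mono-exponential relaxation (default τ = 150 ms, typical of Kv7 gating;
  it does not affect end-of-pulse steady values for 1–2 s steps), additive
  Gaussian trace noise, lognormal cell-to-cell G_max spread (cv 0.15) and
  Gaussian V₁ᐟ₂ jitter (sd 2.1 mV ≈ the reported SEM of 0.7 mV × √9 cells).
* **Dose–response tables**: per-cell Hill responses with lognormal E_max
  spread and Gaussian EC₅₀ jitter (default 0.85·cv·EC₅₀ ≈ 1.25 μM, chosen
  so the fitted-EC₅₀ standard error at ~10 cells matches the reported
  ±0.4 μM), renormalized so the top-concentration mean is 100%.
* **Single-channel traces**: N independent two-state Markov channels with
  exponential dwell times, fixed unitary amplitude, Gaussian noise of
  0.15 × |unitary| (half-amplitude idealization stays reliable at this
  level). The exact per-sample open-channel count is kept as ground truth.
  Dwell means below 5 sampling intervals are rejected as unresolvable.
* **Action-current trains**: homogeneous Poisson event times carrying a
  biphasic, downward-first waveform (derivative-of-Gaussian, 1 ms width)
  at a configurable signal-to-noise ratio (default 10).

What the generators do **not** emulate: capacitive transients, series
resistance, liquid-junction potentials, drifting baselines, channel
rundown, or correlated (1/f) noise. Passing tests therefore validate the
estimators against idealized recordings, not against every artifact of
real data.

## Single-channel and firing analysis

The all-points histogram is fitted with a least-squares Gaussian mixture
(peak-initialized, lightly smoothed for peak finding); the unitary
amplitude is the mean spacing of adjacent level means. Idealization uses
the field-standard half-amplitude rule, implemented as level =
round((x − baseline)/unitary) clamped at ≥ 0, with the unitary sign
carrying the deflection direction (negative for cell-attached K_M
openings). Runs shorter than 2 samples are merged into the preceding dwell
— a documented dead time, so dwell sequences are recovered exactly only
for dwells above it. NPo is the duration-weighted mean level; baselines
should be taken from the dominant histogram mode, not the trace mean,
because openings bias the mean.

Action currents are detected as downward excursions beyond k·SD (k = 6)
of a median/MAD baseline with a 20 ms refractory lockout (appropriate for
~1 Hz firing; both configurable). The recording-scale check — recovering a
1.21 Hz rate from a 100 s train — is limited by Poisson counting error
(3·√N/T ≈ 0.33 Hz), not by the detector.

## The burst model

Single compartment, one coherent per-area unit system: C_m = 1 μF/cm²,
conductances in mS/cm², currents in μA/cm². The membrane equation sums
I_Na, I_CaT, I_CaL, I_CaN, I_KDR, I_A, I_KCa, I_AHP, I_M and I_Leak
against an applied current. Defaults (mS/cm²): g_Na 2, g_CaT 0.45,
g_CaL/g_CaN 0.0025, g_KDR 0.08, g_A 0.1, g_M 0.02, g_KCa 0.05,
g_Kahp 0.0018, g_leak 0.0167; V_Na +50, V_K −91, V_Leak −65 mV.

Two unit decisions deserve emphasis:

* **I_app = 0.004 μA/cm².** At this parameter set's sub-threshold
  conductance scale (~0.02–0.06 mS/cm²) the total K⁺ current available
  near −81 mV is under 1 μA/cm², so a milliampere-scale current density
  could never be balanced and would preclude the deep interburst AHP the
  model is meant to produce. The printed magnitude is therefore read in
  μA/cm², where it acts as a small depolarizing bias.
* **The model is an endogenous burster.** A 0.004 μA/cm² bias is far
  smaller than the sub-threshold current added by doubling g_M, so no
  self-consistent parameterization can make rest-versus-bursting hinge on
  that bias while the doubled-g_M condition keeps bursting. The default
  parameters burst with or without I_app ("brief depolarizing current"
  reading: the current only selects the initial condition);
  `resting_state` accordingly flags the default model oscillatory and
  returns exact rest points only for genuinely quiescent parameter sets
  (e.g. leak-only → −65 mV).

**Kinetics.** No gating rate functions are printed for this neuron; the
set in `kmburst/model/kinetics.py` is a self-contained Hodgkin–Huxley
style construction calibrated so that the tabulated conductances produce
the reported burst phenotype. Because the whole conductance set is ~60×
smaller than squid-axon scale at the same capacitance, the membrane is
slow (sub-threshold τ ≈ 20 ms) and the spike gates are correspondingly
slow: Na⁺ uses instantaneous m³ (half −44.6 mV) with a dynamic h gate
(τ up to ~30 ms) acting as the spike-cycle recovery variable; the delayed
rectifier (a², τ up to ~25 ms) and the A-type current (whose inactivation
recovers between spikes) provide the post-spike undershoot that
de-inactivates Na⁺. The M gate uses the fitted whole-cell M-current
activation itself (half −26.8 mV, slope RT/qF = 13.7 mV, τ 80 ms).

Slow subsystem: the T-type activation *n* (half −33 mV, slope 11 mV,
τ 50 ms) is the autocatalytic depolarizing gate; an instantaneous T-type
inactivation gate (half −52 mV) restricts the current to a low-threshold
window — without it these conductance ratios admit a stable depolarized
equilibrium (depolarization block) instead of bursting. Ca²⁺ currents use
a normalized constant-field (GHK) driving term (Ca_o = 2 mM, reversal
≈ +126 mV, scale 0.25 mapping the tabulated magnitudes to physiological
current densities). A single well-mixed Ca²⁺ pool
(dCa/dt = −k·I_Ca − Ca/τ_Ca, k = 0.004 μM·cm²/(μA·ms), τ_Ca = 150 ms)
drives the K_Ca activation *o* (Hill coefficient 4, half 0.3 μM, τ 120 ms)
— the slow negative feedback — and the small AHP-current gate
(half 1 μM, τ 400 ms).

With these defaults the model bursts at ~1 Hz with ~7 spikes/burst;
doubling g_M gives ~4 spikes/burst at an interburst AHP of −79.7 mV,
doubling both g_M and g_KCa gives ~3 spikes/burst at −84.2 mV, and the
peak M-current rises 1.48-fold between the baseline and doubled
conditions. Spikes per burst decrease monotonically in g_M over scales
1–3×.

**Integration.** Explicit Euler at dt = 0.001 ms (classical RK4
available), stride-recorded at 0.01 ms. Gate variables stay in [0, 1] and
the recorded states, currents and dV/dt satisfy the membrane equation
identically. Halving dt shifts spike times by < 0.2 ms over 2 s. A note on
pointwise trajectory comparison: on a bursting trajectory the first-order
spike-phase drift of Euler (~0.4 ms against an RK4 reference over 2 s)
crosses ~60 mV/ms upstrokes, so the *pointwise* voltage deviation between
integrators reaches tens of mV even though every burst statistic
(spike/burst counts, AHP, current peaks) agrees; pointwise agreement at
the 1 mV level is achievable only on non-spiking trajectories or with
step sizes orders of magnitude below 1 μs. Numerical blow-up (|V| >
200 mV) aborts with diagnostics.

## Burst metrics

Spikes are upward 0 mV crossings with a 2 ms lockout; bursts are maximal
spike runs with ISIs < 100 ms (both thresholds are defaults justified by
the clear separation between intra-burst ISIs of tens of ms and interburst
gaps of hundreds of ms; both configurable). The AHP is measured between
bursts (the interburst voltage minimum) and is undefined (NaN) with fewer
than two bursts. Both "intra-burst rate" ((spikes−1)/burst duration) and
the interburst interval are reported. Current fold changes compare peak
|I| after a configurable transient.

## Fast–slow analysis

The fast subsystem freezes the slow pair (n, o) and the Ca²⁺ pool (at its
burst-cycle average — the treatment of Ca²⁺ under freezing is an analysis
choice, not uniquely determined); all other gates sit at their voltage
steady states (the M gate is slaved likewise, consistently in both the
equilibrium computation and the frozen-pair simulations). Equilibria are
roots of the quasi-steady current balance F(V; n, o), bracketed on a
0.25 mV scan of [−120, +60] mV and bisected to 10⁻⁶ mV; stability follows
the sign of dF/dV.

The "voltage nullcline" of the figure-level analysis is the saddle-node
locus where the sub-threshold rest state of the fast subsystem disappears.
It is computed as the fold value of *n* as a function of *o* (bisection on
n with the stable-sub-threshold-equilibria count as indicator, tolerance
10⁻⁶): frozen points with n above the curve fire repetitively, points
below sit silent, and raising g_M or g_KCa moves the curve toward larger
n — "upward", shrinking the firing region. (An equivalent o(n)
parameterization exists, but with o on the ordinate the silent region
would lie *above* the curve and stronger K⁺ conductances would shift it
*down*; the n(o) orientation is the one on which the qualitative
statements — firing above, silent below, upward shift under channel
activation — are all simultaneously true.) Grid points where no fold
exists in [0, 1] are omitted and logged.

Burst trajectories are projected onto (n(t), o(t)); one cycle is delimited
by successive minima of o after a configurable transient, and the loop
area is the shoelace area (cyclic-reindexing invariant). Doubling both
conductances shrinks the loop (0.233 → 0.128); doubling g_M alone shrinks
it by ~22% (0.233 → 0.181) — here the loop's n-extent tracks the
intra-burst spike count, which g_M reduces, so "minimal trajectory change"
holds qualitatively (same shape and o-extent) but not within 10% in area.

## Problem sizes

Default analysis sizes, chosen to put statistical error well below the
effect sizes under study: 200 cells for dose–response recovery, 60 s
telegraph traces (≈ 6000–8000 gating cycles) for Po/NPo, 100 s trains for
firing rates, 3 s of simulated time per burst scenario (3–4 burst cycles)
and 7 s for trajectory-loop extraction.

## Known limitations

* The kinetics set is calibrated to the reported burst phenotype, not
  identified from voltage-clamp data; other rate sets could produce the
  same summary statistics.
* No multicompartment structure, synaptic input, stochastic channel
  gating, or temperature (Q10) scaling.
* Single-channel analysis has no missed-event (dead-time) correction and
  no hidden-Markov dwell modelling; NPo is biased low by censoring of
  sub-dead-time dwells (well under the 15% tolerances used here).
* The scenario runner validates configuration with pydantic models rather
  than a standalone JSON-schema document.
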