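"""Gating kinetics for the CA3 burst model — the single constants file.

The model uses Hodgkin-Huxley-style gates with sigmoidal steady states
x_inf(V) = 1/(1+exp(-(V - half)/k)) and first-order relaxation.  The burst
mechanism is a square-wave (fold/homoclinic) oscillator built from two slow
gates:

* ``n`` — T-type Ca2+ (Ca_V3.1) activation, the slow *autocatalytic*
  variable: its steady state rises with depolarization and the Ca2+ current
  it carries depolarizes further;
* ``o`` — K_Ca (BK-type) activation, the slow *negative feedback*: it
  tracks the intracellular Ca2+ pool filled by the Ca2+ currents and pulls
  the membrane toward V_K, terminating each burst and setting the
  interburst after-hyperpolarization.

Spikes ride on a fast Na+/K+ subsystem (m3h Na+ with a dynamic h gate, a
squared delayed-rectifier gate, a transient A-type current).  The M-type
K+ gate ``w`` relaxes on the ~100 ms scale and brakes intra-burst firing.

Ca2+ currents use a constant-field (GHK) driving term normalized so that it
approaches the linear driving force V at hyperpolarized potentials and
reverses near +126 mV (Ca_o = 2 mM, resting Ca_i ~ 0.1 uM).

All voltages in mV, times in ms, Ca2+ in uM.  The numeric values below were
chosen to reproduce the reported burst phenotype of the modeled neuron
(bursting at the default conductances, interburst AHP near -81 mV with g_M
doubled and near -85 mV with g_M and g_KCa doubled); no claim of identity
with any particular published rate set is made.
"""

from __future__ import annotations

import numpy as np

# --- index constants into the kinetics vector ------------------------------
M_HALF, M_K = 0, 1                      # Na+ activation (instantaneous)
H_HALF, H_K = 2, 3                      # Na+ inactivation
TAUH_BASE, TAUH_AMP, TAUH_HALF, TAUH_K = 4, 5, 6, 7
A_HALF, A_K = 8, 9                      # delayed-rectifier activation
TAUA_BASE, TAUA_AMP, TAUA_HALF, TAUA_K = 10, 11, 12, 13
CA_HALF, CA_K = 14, 15                  # A-type activation (instantaneous)
D_HALF, D_K, TAUD = 16, 17, 18          # A-type inactivation
N_HALF, N_K, TAUN = 19, 20, 21          # T-type activation (slow, "n")
ML_HALF, ML_K = 22, 23                  # L-type activation (instantaneous)
MN_HALF, MN_K = 24, 25                  # N-type activation (instantaneous)
O_CA_HALF, O_HILL, TAUO = 26, 27, 28    # K_Ca activation (slow, "o"; Ca-gated)
Q_CA_HALF, Q_HILL, TAUQ = 29, 30, 31    # AHP-current Ca gate
W_HALF, W_K, TAUW = 32, 33, 34          # M-current gate
RT2F = 35                               # RT/2F in mV (divalent), 295 K
CA_SCALE = 36                           # GHK drive normalization (dimensionless)
HT_HALF, HT_K = 37, 38                  # T-type inactivation (instantaneous)

KINETICS = np.array([
    # Na+ activation (instantaneous, cubed)
    -44.57, 5.66,
    # Na+ inactivation: slow recovery makes h the spike-cycle recovery
    # variable (the whole conductance set is ~60x smaller than squid-axon
    # scale at the same Cm, so gate kinetics are correspondingly slow)
    -47.55, 3.26,
    3.5, 26.71, -37.34, 7.25,
    # delayed rectifier (squared)
    -34.52, 3.06,
    4.29, 20.97, -33.39, 10.56,
    # A-type: activation (instantaneous) and inactivation; the A-current
    # provides the post-spike undershoot that de-inactivates Na+
    -39.17, 5.49,
    -62.11, 5.19, 32.85,
    # T-type activation n (slow autocatalytic)
    -33.0, 11.0, 50.0,
    # L- and N-type activation
    -20.0, 7.0,
    -25.0, 7.0,
    # K_Ca gate o (slow negative feedback; Ca half-activation in uM)
    0.3, 4.0, 120.0,
    # AHP gate
    1.0, 2.0, 400.0,
    # M-current gate: half-activation and slope from the fitted whole-cell
    # activation curve of the M-current (V_1/2 -26.8 mV, q 1.86 e ->
    # RT/qF = 13.7 mV at 295 K)
    -26.8, 13.7, 80.0,
    # RT/2F at 295 K
    12.715,
    # GHK drive normalization: converts the normalized constant-field term
    # into an effective ohmic-equivalent driving force for the tabulated
    # Ca2+ conductance magnitudes
    0.25,
    # T-type inactivation (fast, slaved to voltage): gives the channel its
    # low-threshold window current and shuts it at spike potentials
    -52.04, 5.82,
], dtype=np.float64)

#: human-readable export of the kinetics vector for reports and docs
KINETICS_DOC = {
    "m_inf": "Na+ activation: half %.1f mV, slope %.1f mV (instantaneous, cubed)" % (KINETICS[M_HALF], KINETICS[M_K]),
    "h": "Na+ inactivation: half %.1f mV, slope -%.1f mV; tau %.1f + %.1f/(1+exp((V-(%.1f))/%.1f)) ms"
         % (KINETICS[H_HALF], KINETICS[H_K], KINETICS[TAUH_BASE], KINETICS[TAUH_AMP], KINETICS[TAUH_HALF], KINETICS[TAUH_K]),
    "a": "K_DR activation: half %.1f mV, slope %.1f mV (squared)" % (KINETICS[A_HALF], KINETICS[A_K]),
    "cA,d": "A-type: activation half %.1f mV (instantaneous); inactivation half %.1f mV, tau %.0f ms"
            % (KINETICS[CA_HALF], KINETICS[D_HALF], KINETICS[TAUD]),
    "n": "T-type activation: half %.1f mV, slope %.1f mV, tau %.0f ms (slow autocatalytic)"
         % (KINETICS[N_HALF], KINETICS[N_K], KINETICS[TAUN]),
    "o": "K_Ca activation: Hill in Ca_i, half %.2f uM, coefficient %.0f, tau %.0f ms (slow negative feedback)"
         % (KINETICS[O_CA_HALF], KINETICS[O_HILL], KINETICS[TAUO]),
    "q": "AHP-current Ca gate: half %.1f uM, coefficient %.0f, tau %.0f ms"
         % (KINETICS[Q_CA_HALF], KINETICS[Q_HILL], KINETICS[TAUQ]),
    "w": "M-current gate: half %.1f mV, slope %.1f mV, tau %.0f ms"
         % (KINETICS[W_HALF], KINETICS[W_K], KINETICS[TAUW]),
}
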