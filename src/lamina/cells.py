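"""Hand-coded reference implementations of the built-in cell models.

Every built-in cell type also ships as a declarative JSON definition (see
:mod:`lamina.registry`); the functions here are the independent, hand-coded
versions of the same vector fields.  They serve two purposes: they document
each model in plain Python, and they act as oracles against which the
expression compiler is verified.

Conventions (default units): time s, voltage mV, current pA, conductance
nS, capacitance nF, frequency Hz, concentration nM.  Synaptic inputs enter
either as a current ``I_syn`` (pA), a voltage rate ``V_syn`` (mV/s) or a
firing rate ``FR_syn`` (Hz); the external (stimulus) drive is ``ext`` in
the units the receiving model declares.

All functions are pure and numpy-vectorised: scalars or same-shaped arrays
may be passed for states and inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

__all__ = [
    "rectifier",
    "LinearCellParams",
    "NeurotransmitterCellParams",
    "GainControlParams",
    "MorrisLecarParams",
    "HodgkinHuxleyParams",
    "CorticalColumnParams",
    "AWCCellParams",
    "linear_cell_rhs",
    "pharma_cell_rhs",
    "neurotransmitter_amacrine_rhs",
    "gain_control_bipolar_rhs",
    "bipolar_response",
    "gain_control_ganglion_rhs",
    "ganglion_firing_rate",
    "electrode_rhs",
    "morris_lecar_rhs",
    "morris_lecar_ach_rhs",
    "morris_lecar_ach_sahp_rhs",
    "hodgkin_huxley_rhs",
    "cortical_column_rhs",
    "cortical_transfer",
    "awc_rhs",
    "awc_sigmoid",
]


def rectifier(V, theta):
    """Piecewise-linear rectifier N(V): V − θ above threshold, else 0.

    The inequality is strict: N(θ) = 0.
    """
    V = np.asarray(V, dtype=float)
    return np.where(V > theta, V - theta, 0.0)


# ---------------------------------------------------------------------------
# Linear cells


@dataclass
class LinearCellParams:
    """Leaky linear cell; also covers the pharmacology variant.

    ``tau`` is the membrane time constant C/g_L; the pharmacology variant
    adds a drug-sensitive conductance ``g_P`` with Nernst potential ``E_P``.
    """
    C: float = 0.1        # nF
    g_L: float = 1.0      # nS
    E_L: float = -60.0    # mV
    tau: float = 0.1      # s
    g_P: float = 0.0      # nS
    E_P: float = 0.0      # mV
    tau_ext: float = 0.05  # s (external-drive time constant, where used)


def linear_cell_rhs(V, p: LinearCellParams, V_syn=0.0):
    """dV/dt = −(V − E_L)/τ + V_syn   (mV/s)."""
    return -(V - p.E_L) / p.tau + V_syn


def pharma_cell_rhs(V, p: LinearCellParams, I_syn=0.0):
    """Linear cell with an extra tunable ionic conductance (e.g. a drug).

    dV/dt = −(g_L + g_P)·V/C + I_syn/C + (g_L·E_L + g_P·E_P)/C
    """
    return (-(p.g_L + p.g_P) * V + I_syn + (p.g_L * p.E_L + p.g_P * p.E_P)) / p.C


# ---------------------------------------------------------------------------
# Neurotransmitter-producing amacrine cell (GABA / AMPA)


@dataclass
class NeurotransmitterCellParams:
    k_d: float = 5.0       # Hz, transmitter decay
    k_p: float = 10.0      # production rate (nM/s at full activation)
    E_N: float = -40.0     # mV, half-activation voltage
    kappa_N: float = 5.0   # mV, sigmoid slope
    tau_A: float = 0.1     # s, membrane time constant
    C_A: float = 0.1       # nF
    beta_n: float = 5.0    # Hz, channel closing rate
    alpha_n: float = 1.0   # opening rate per unit transmitter


def neurotransmitter_amacrine_rhs(T, V, n, p: NeurotransmitterCellParams, I_syn=0.0):
    """Quasi-static transmitter production driven by a voltage sigmoid.

    dT/dt = −k_d·T + k_p / (1 + exp(−(V − E_N)/κ_N))
    dV/dt = −V/τ_A + I_syn/C_A
    dn/dt = −β_n·n + α_n·T·(1 − n)
    """
    dT = -p.k_d * T + p.k_p / (1.0 + np.exp(-(V - p.E_N) / p.kappa_N))
    dV = -V / p.tau_A + I_syn / p.C_A
    dn = -p.beta_n * n + p.alpha_n * T * (1.0 - n)
    return dT, dV, dn


# ---------------------------------------------------------------------------
# Gain-control bipolar and ganglion cells


@dataclass
class GainControlParams:
    # bipolar
    tau_AB: float = 0.2    # s, activity time constant
    h_B: float = 1.0       # activity gain
    theta_B: float = 0.0   # mV, rectification threshold
    tau_B: float = 0.05    # s, membrane time constant
    tau_ext: float = 0.02  # s, OPL drive time constant
    E_L: float = 0.0       # mV, bipolar leak reversal
    # ganglion
    tau_L: float = 0.05    # s, leak time constant
    V_L: float = 0.0       # mV, leak reversal
    g_T: float = 0.0       # nS, tunable (drug) conductance
    V_T: float = 0.0       # mV, its threshold/reversal
    C: float = 0.1         # nF
    tau_G: float = 0.2     # s, ganglion activity time constant
    H_G: float = 1.0       # activity gain
    theta_G: float = 0.0   # mV, firing-rate rectification threshold


def gain_control_bipolar_rhs(A_B, V, p: GainControlParams, ext=0.0, V_syn=0.0):
    """Bipolar cell with subtractive/divisive gain control.

    dA_B/dt = −A_B/τ_AB + h_B·N(V − θ_B)
    dV/dt   = −(V − E_L)/τ_B + V_ext/τ_ext + V_syn
    """
    dA = -A_B / p.tau_AB + p.h_B * rectifier(V, p.theta_B)
    dV = -(V - p.E_L) / p.tau_B + ext / p.tau_ext + V_syn
    return dA, dV


def bipolar_response(A_B, V, p: GainControlParams):
    """Rectified, activity-divided bipolar output fed to pooling synapses."""
    return rectifier(V, p.theta_B) / (1.0 + A_B)


def gain_control_ganglion_rhs(V, A_G, p: GainControlParams, V_syn=0.0):
    """Ganglion cell with gain control and a tunable rectified conductance.

    dV/dt   = −(V − V_L)/τ_L + V_syn − (g_T/C)·N(V − V_T)
    dA_G/dt = −A_G/τ_G + H_G·N(V − θ_G)
    """
    dV = -(V - p.V_L) / p.tau_L + V_syn - (p.g_T / p.C) * rectifier(V, p.V_T)
    dA = -A_G / p.tau_G + p.H_G * rectifier(V, p.theta_G)
    return dV, dA


def ganglion_firing_rate(V, A_G, p: GainControlParams):
    """Divisively gain-controlled rate: N(V − θ_G)/(1 + A_G) ≥ 0 (Hz)."""
    return rectifier(V, p.theta_G) / (1.0 + A_G)


# ---------------------------------------------------------------------------
# Electrode (passive low-pass)


def electrode_rhs(V, tau, C, I_ext=0.0):
    """dV/dt = −V/τ + I_ext/C — a passive low-pass prosthesis electrode."""
    return -V / tau + I_ext / C


# ---------------------------------------------------------------------------
# Morris–Lecar (plain, + ACh production, + slow AHP)


@dataclass
class MorrisLecarParams:
    """Morris–Lecar with the classical Hopf parameter set.

    The canonical per-area values (C = 20 uF/cm2, conductances in mS/cm2,
    phi = 0.04/ms) are expressed here as absolute nS/nF quantities with the
    same conductance-to-capacitance ratios, on a time base of seconds.
    """
    C: float = 0.02       # nF
    g_Ca: float = 4.4     # nS
    g_K: float = 8.0      # nS
    g_L: float = 2.0      # nS
    V_Ca: float = 120.0   # mV
    V_K: float = -84.0    # mV
    V_L: float = -60.0    # mV
    V1: float = -1.2      # mV
    V2: float = 18.0      # mV
    V3: float = 2.0       # mV
    V4: float = 30.0      # mV
    phi: float = 40.0     # 1/s
    # ACh extension
    mu_A: float = 50.0    # nM/s, max ACh production rate
    tau_Ach: float = 2.0  # s, ACh decay
    V_Ach: float = -30.0  # mV, half-activation of ACh production
    kappa_Ach: float = 5.0  # mV, slope
    # sAHP extension
    g_sAHP: float = 2.0   # nS
    E_K_sAHP: float = -84.0  # mV
    tau_R: float = 2.0    # s
    tau_S: float = 2.0    # s
    V_R: float = -25.0    # mV, half-activation of the sAHP driver
    kappa_R: float = 5.0  # mV


def _ml_minf(V, p):
    return 0.5 * (1.0 + np.tanh((V - p.V1) / p.V2))


def _ml_ninf(V, p):
    return 0.5 * (1.0 + np.tanh((V - p.V3) / p.V4))


def _ml_taun(V, p):
    return 1.0 / np.cosh((V - p.V3) / (2.0 * p.V4))


def morris_lecar_rhs(V, N, p: MorrisLecarParams, I_ext=0.0, I_syn=0.0):
    """Classical two-variable Morris–Lecar vector field."""
    I_ion = (p.g_Ca * _ml_minf(V, p) * (V - p.V_Ca)
             + p.g_K * N * (V - p.V_K)
             + p.g_L * (V - p.V_L))
    dV = (I_ext + I_syn - I_ion) / p.C
    dN = p.phi * (_ml_ninf(V, p) - N) * np.cosh((V - p.V3) / (2.0 * p.V4))
    return dV, dN


def _ach_production(V, p):
    return 1.0 / (1.0 + np.exp(-(V - p.V_Ach) / p.kappa_Ach))


def morris_lecar_ach_rhs(V, N, A, p: MorrisLecarParams, I_ext=0.0, I_syn=0.0):
    """Morris–Lecar releasing acetylcholine through a voltage sigmoid.

    dA/dt = −A/τ_Ach + μ_A·σ(V); A stays non-negative from A(0) ≥ 0.
    """
    dV, dN = morris_lecar_rhs(V, N, p, I_ext, I_syn)
    dA = -A / p.tau_Ach + p.mu_A * _ach_production(V, p)
    return dV, dN, dA


def morris_lecar_ach_sahp_rhs(V, N, A, R, S, p: MorrisLecarParams,
                              I_ext=0.0, I_syn=0.0):
    """ACh-producing Morris–Lecar with a slow after-hyperpolarising K current.

    The sAHP gate is a two-stage relaxation cascade driven by a voltage
    sigmoid (R tracks the sigmoid, S tracks R), contributing the current
    −g_sAHP·S⁴·(V − E_K).  This is a documented stand-in with the stated
    state variables; the exact kinetics of the source models are not
    reproduced here.
    """
    sig = 1.0 / (1.0 + np.exp(-(V - p.V_R) / p.kappa_R))
    I_sahp = p.g_sAHP * S ** 4 * (V - p.E_K_sAHP)
    I_ion = (p.g_Ca * _ml_minf(V, p) * (V - p.V_Ca)
             + p.g_K * N * (V - p.V_K)
             + p.g_L * (V - p.V_L)
             + I_sahp)
    dV = (I_ext + I_syn - I_ion) / p.C
    dN = p.phi * (_ml_ninf(V, p) - N) * np.cosh((V - p.V3) / (2.0 * p.V4))
    dA = -A / p.tau_Ach + p.mu_A * _ach_production(V, p)
    dR = (sig - R) / p.tau_R
    dS = (R - S) / p.tau_S
    return dV, dN, dA, dR, dS


# ---------------------------------------------------------------------------
# Hodgkin–Huxley (classical 1952 parameterisation, 6.3 °C)


@dataclass
class HodgkinHuxleyParams:
    """Classical squid-axon values with modern voltage convention (rest ≈ −65 mV).

    Per-area constants (C = 1 uF/cm2, g_Na = 120 mS/cm2, ...) are carried
    over as absolute quantities with identical g/C ratios; rate functions
    are the 1952 ones scaled from 1/ms to 1/s.
    """
    C: float = 0.01       # nF
    g_Na: float = 1200.0  # nS
    g_K: float = 360.0    # nS
    g_L: float = 3.0      # nS
    E_Na: float = 50.0    # mV
    E_K: float = -77.0    # mV
    E_L: float = -54.387  # mV


def hh_rates(V):
    """The six classical rate functions, in 1/s."""
    V = np.asarray(V, dtype=float)
    a_m = 1e3 * 0.1 * (V + 40.0) / (1.0 - np.exp(-(V + 40.0) / 10.0))
    b_m = 1e3 * 4.0 * np.exp(-(V + 65.0) / 18.0)
    a_h = 1e3 * 0.07 * np.exp(-(V + 65.0) / 20.0)
    b_h = 1e3 * 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    a_n = 1e3 * 0.01 * (V + 55.0) / (1.0 - np.exp(-(V + 55.0) / 10.0))
    b_n = 1e3 * 0.125 * np.exp(-(V + 65.0) / 80.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


def hodgkin_huxley_rhs(V, m, h, n, p: HodgkinHuxleyParams, I_ext=0.0, I_syn=0.0):
    """Classical Hodgkin–Huxley kinetics; gating variables stay in [0, 1]."""
    a_m, b_m, a_h, b_h, a_n, b_n = hh_rates(V)
    I_ion = (p.g_Na * m ** 3 * h * (V - p.E_Na)
             + p.g_K * n ** 4 * (V - p.E_K)
             + p.g_L * (V - p.E_L))
    dV = (I_ext + I_syn - I_ion) / p.C
    dm = a_m * (1.0 - m) - b_m * m
    dh = a_h * (1.0 - h) - b_h * h
    dn = a_n * (1.0 - n) - b_n * n
    return dV, dm, dh, dn


# ---------------------------------------------------------------------------
# Cortical column (rate stand-in)


@dataclass
class CorticalColumnParams:
    """Leaky rate-model stand-in for an excitatory or inhibitory population.

    The population voltage integrates a firing-rate input; the output rate
    is a monotone non-negative erf sigmoid of the voltage.  The exact
    mean-field equations of the source models are not reproduced.
    """
    tau: float = 0.02      # s, population time constant
    V_rest: float = -65.0  # mV
    V_thr: float = -50.0   # mV, transfer half-activation
    gain: float = 0.2      # 1/mV, transfer slope
    nu_max: float = 100.0  # Hz, saturation rate
    s_in: float = 1.0      # mV/s per Hz, synaptic rate-to-drive scale
    I_base: float = 0.0    # mV/s, baseline drive


def cortical_transfer(V, p: CorticalColumnParams):
    """Monotone, non-negative rate transfer: ν(V) in [0, nu_max] Hz."""
    return p.nu_max * 0.5 * (1.0 + erf(p.gain * (V - p.V_thr) / np.sqrt(2.0)))


def cortical_column_rhs(V, p: CorticalColumnParams, FR_syn=0.0):
    """dV/dt = (−(V − V_rest))/τ + s_in·FR_syn + I_base."""
    return -(V - p.V_rest) / p.tau + p.s_in * FR_syn + p.I_base


# ---------------------------------------------------------------------------
# Amari–Wilson–Cowan unit


@dataclass
class AWCCellParams:
    tau: float = 0.05  # s
    g: float = 0.5     # 1/mV, sigmoid gain


def awc_sigmoid(V, g):
    """f(V) = (1 + erf(g·V/√2))/2, the smooth rate nonlinearity; f(0) = 1/2."""
    return 0.5 * (1.0 + erf(g * np.asarray(V, dtype=float) / np.sqrt(2.0)))


def awc_rhs(V, p: AWCCellParams, V_syn=0.0, ext=0.0):
    """dV/dt = −V/τ + Σ_j J_ij f(V_j) + H_ext; the pooled term arrives as V_syn."""
    return -V / p.tau + V_syn + ext
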