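"""Hand-coded reference implementations of the built-in synapse rules.

Each rule maps pre- and post-synaptic cell outputs, the geometric edge
weight ``w`` produced by the connectivity generators, and the synapse
type's own parameters to one of three output kinds:

* a **current** (pA), summed into the post cell's ``I_syn`` slot;
* a **voltage rate** (mV/s, a post-synaptic-potential rate), summed into
  ``V_syn``;
* a **firing rate** (Hz), summed into ``FR_syn``.

The effective coupling of an edge is the product of the geometric weight
(constant or Gaussian, set by the graph generator) and the per-type gain
parameters.  As in the cell module, these functions double as oracles for
the registry-compiled versions of the same rules.

Synapses are instantaneous by default; a type becomes delayed by declaring
a parameter named exactly ``conduction_velocity`` (mm/s), in which case the
delay of an edge is the 2-D distance between its endpoints divided by that
velocity, discretised to the nearest whole number of integration steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SynapseParams",
    "ParameterError",
    "WiringError",
    "ach_current",
    "rectified_psp",
    "linear_psp",
    "pooling_psp",
    "gap_junction_psp",
    "cortical_rate_coupling",
    "ligand_gated_psp",
    "retino_cortical_rate",
    "synaptic_delay",
    "DelayBuffer",
    "total_input",
]


class ParameterError(ValueError):
    pass


class WiringError(ValueError):
    """An edge's synapse type and its endpoint cell types do not fit."""


@dataclass
class SynapseParams:
    """Union of the parameters used by the built-in rules (per-type subsets)."""
    g_A: float = 3.0             # nS, max ACh conductance
    gamma_A: float = 100.0       # nM^2, half-activation constant
    V_A: float = 0.0             # mV, ACh reversal
    gain: float = 1.0            # per-type gain multiplying the edge weight
    theta_pre: float = 0.0       # mV, rectifying threshold
    w_gap: float = 10.0          # Hz (nS/nF), gap-junction strength
    g: float = 1.0               # nS/nF scale of ligand-gated PSP rate
    E: float = -70.0             # mV, ligand reversal
    literal: float = 0.0         # 1.0 -> drive by V_pre instead of V_post
    weight: float = 1.0          # retino-cortical scale
    density_retina: float = 400.0   # mm^-2
    density_cortex: float = 4000.0  # mm^-2
    conduction_velocity: float | None = None  # mm/s; None -> instantaneous


def ach_current(A_pre, V_post, p: SynapseParams, w=1.0):
    """Nicotinic ACh current: −g_A·A²/(γ_A + A²)·(V_post − V_A), in pA."""
    A_pre = np.asarray(A_pre, dtype=float)
    return -w * p.g_A * A_pre ** 2 / (p.gamma_A + A_pre ** 2) * (V_post - p.V_A)


def rectified_psp(V_pre, p: SynapseParams, w=1.0):
    """Rectified synapse: w·max(V_pre − θ_pre, 0), in mV/s."""
    return w * p.gain * np.maximum(np.asarray(V_pre, dtype=float) - p.theta_pre, 0.0)


def linear_psp(V_pre, p: SynapseParams, w=1.0):
    """Linear synapse: w·V_pre, in mV/s."""
    return w * p.gain * np.asarray(V_pre, dtype=float)


def pooling_psp(bipolar_response_pre, p: SynapseParams, w=1.0):
    """Pooling synapse driven by the pre cell's ``bipolarResponse`` output."""
    return w * p.gain * np.asarray(bipolar_response_pre, dtype=float)


def gap_junction_psp(V_pre, V_post, p: SynapseParams, w=1.0):
    """Passive gap junction: −w_gap·(V_post − V_pre), in mV/s.

    Antisymmetric: a reciprocal pair with equal w_gap sums to zero.
    """
    return -w * p.w_gap * (np.asarray(V_post, dtype=float) - V_pre)


def cortical_rate_coupling(nu_pre, p: SynapseParams, w=1.0):
    """Rate-to-rate cortical coupling: w·ν_pre (w from the Gaussian profile)."""
    return w * p.gain * np.asarray(nu_pre, dtype=float)


def ligand_gated_psp(n_pre, V_pre, V_post, p: SynapseParams, w=1.0):
    """GABA_A / AMPA PSP rate: −g·n·(V_drive − E), in mV/s.

    The driving voltage is post-synaptic by default; ``literal=1`` selects
    the pre-synaptic voltage instead.
    """
    V_drive = p.literal * np.asarray(V_pre, dtype=float) + (1.0 - p.literal) * V_post
    return -w * p.g * np.asarray(n_pre, dtype=float) * (V_drive - p.E)


def retino_cortical_rate(FR_pre, p: SynapseParams, w=1.0):
    """Retina-to-cortex rate relay scaled by the cell-density ratio, in Hz."""
    if p.density_cortex <= 0:
        raise ParameterError("density_cortex must be > 0")
    return w * p.weight * (p.density_retina / p.density_cortex) * np.asarray(
        FR_pre, dtype=float)


def synaptic_delay(d_syn: float, v_C: float | None, dt: float) -> int:
    """Discretise the conduction delay d/v_C to a whole number of steps.

    A missing conduction velocity means an instantaneous synapse (0 steps);
    otherwise the continuous delay is rounded to the nearest step count.
    """
    if v_C is None:
        return 0
    if v_C <= 0:
        raise ParameterError("conduction_velocity must be > 0")
    if d_syn < 0:
        raise ParameterError("distance must be >= 0")
    return int(round((d_syn / v_C) / dt))


class DelayBuffer:
    """Ring buffer of per-step pre-synaptic output samples.

    ``read(k)`` returns the sample recorded ``k`` steps ago; ``read(0)`` is
    the most recently pushed (current) sample.  The buffer is pre-filled
    with the t = 0 value so that early reads are well defined.
    """

    def __init__(self, initial, max_delay_steps: int):
        if max_delay_steps < 0:
            raise ParameterError("max_delay_steps must be >= 0")
        initial = np.array(initial, dtype=float, copy=True)
        self.size = max_delay_steps + 1
        self._buf = np.stack([initial] * self.size)
        self._head = 0  # index of the newest sample

    def push(self, sample) -> None:
        self._head = (self._head + 1) % self.size
        self._buf[self._head] = sample

    def read(self, delay_steps: int):
        if not 0 <= delay_steps < self.size:
            raise IndexError(
                f"delay {delay_steps} outside buffer of depth {self.size}")
        return self._buf[(self._head - delay_steps) % self.size]


def total_input(post_slots, edges, pre_outputs, rules):
    """Reference per-edge summation of synaptic inputs for one cell.

    Parameters
    ----------
    post_slots:
        Iterable of input-slot names the post-synaptic cell exposes, among
        ``{"I_syn", "V_syn", "FR_syn"}``.
    edges:
        Iterable of ``(synapse_type, weight)`` incoming edges.
    pre_outputs:
        ``edge index -> dict`` of the (possibly delayed) pre-synaptic
        outputs seen by each edge.
    rules:
        ``synapse_type -> (slot, callable(pre_outputs, weight) -> value)``.

    Returns a dict slot -> summed value, zero for slots with no edges.
    This plain loop is the oracle for the engine's vectorised assembly.
    """
    totals = {slot: 0.0 for slot in post_slots}
    for idx, (stype, weight) in enumerate(edges):
        if stype not in rules:
            raise WiringError(f"unknown synapse type {stype!r}")
        slot, fn = rules[stype]
        if slot not in totals:
            raise WiringError(
                f"synapse {stype!r} feeds slot {slot!r}, absent on the post cell")
        totals[slot] = totals[slot] + fn(pre_outputs[idx], weight)
    return totals
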