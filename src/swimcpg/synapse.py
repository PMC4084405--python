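"""First-order-kinetics artificial synapse used by the dynamic clamp.

The injected current mimics the slow inhibitory component of the C2->VSI
synapse.  In every clamp cycle the current is

    I_syn = g_syn * S(t) * (V_syn - V_post),

with the instantaneous activation S(t) obeying

    (1 - S_inf(V_pre)) * tau_syn * dS/dt = S_inf(V_pre) - S(t),

and the steady-state activation

    S_inf(V_pre) = tanh((V_pre - V_thresh) / V_slope)  if V_pre > V_thresh,
                   0                                    otherwise.

Two kinetic components with different decay time constants (700 ms fast,
1300 ms slow) share the activation curve; their weighted sum carries the
total maximal conductance.  V_post is held fixed at the postsynaptic
resting potential, so the injected current is purely presynaptically
gated.  Conductance *subtraction* uses a negated g_syn of the same
magnitude.

Units are fixed throughout the package: mV, nS, pA, ms (nS * mV = pA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SynapseKinetics",
    "ActivationState",
    "steady_state_activation",
    "step_activation",
    "synaptic_current",
    "clamp_trace",
]

# Numerical guards for the singular (1 - S_inf) factor and the S in [0, 1)
# contract.  S_inf is kept strictly below 1; S itself strictly below 1.
_S_INF_CAP = 1.0 - 1e-6
_S_CAP = 1.0 - 1e-9

DEFAULT_COMPONENTS = ((0.5, 700.0), (0.5, 1300.0))


@dataclass(frozen=True)
class SynapseKinetics:
    """Parameters of the artificial C2->VSI synapse.

    Parameters
    ----------
    g_syn_ns : float
        Total maximal conductance in nS.  Negative values select
        conductance-subtraction mode.
    v_syn_mv : float
        Reversal potential of the synapse (mV).
    components : tuple[(weight, tau_ms), ...]
        Fractional split of ``g_syn_ns`` across kinetic components and
        their decay time constants.  Weights must sum to 1.
    v_thresh_mv : float
        Presynaptic release threshold; set at 50% height of the smallest
        presynaptic action potentials.
    v_slope_mv : float
        Slope of the activation curve (> 0).
    v_post_rest_mv : float
        Fixed postsynaptic potential standing in for V_post.
    """

    g_syn_ns: float = 1000.0
    v_syn_mv: float = -80.0
    components: tuple = DEFAULT_COMPONENTS
    v_thresh_mv: float = -10.0
    v_slope_mv: float = 20.0
    v_post_rest_mv: float = -50.0

    def __post_init__(self):
        if not self.components:
            raise ValueError("at least one kinetic component is required")
        wsum = 0.0
        for w, tau in self.components:
            if not (0.0 < w <= 1.0):
                raise ValueError(f"component weight {w} outside (0, 1]")
            if tau <= 0.0:
                raise ValueError(f"component tau {tau} must be positive")
            wsum += w
        if abs(wsum - 1.0) > 1e-9:
            raise ValueError(f"component weights sum to {wsum}, expected 1")
        if self.v_slope_mv <= 0.0:
            raise ValueError("v_slope_mv must be positive")

    @property
    def min_tau_ms(self) -> float:
        return min(tau for _, tau in self.components)

    def negated(self) -> "SynapseKinetics":
        """Subtraction-mode copy: g_syn of the same magnitude, negative."""
        return replace(self, g_syn_ns=-abs(self.g_syn_ns))


@dataclass
class ActivationState:
    """Per-component instantaneous activation S and current time."""

    s: np.ndarray = field(default_factory=lambda: np.zeros(2))
    t_ms: float = 0.0

    @classmethod
    def zeros(cls, kinetics: SynapseKinetics) -> "ActivationState":
        return cls(s=np.zeros(len(kinetics.components)), t_ms=0.0)


def steady_state_activation(v_pre_mv: float, kinetics: SynapseKinetics) -> float:
    """Steady-state activation S_inf for a presynaptic voltage sample.

    Returns ``tanh((V_pre - V_thresh) / V_slope)`` above threshold and 0
    otherwise; the result lies in [0, 1).
    """
    if not math.isfinite(v_pre_mv):
        raise ValueError(f"non-finite presynaptic voltage sample: {v_pre_mv!r}")
    if v_pre_mv <= kinetics.v_thresh_mv:
        return 0.0
    return math.tanh((v_pre_mv - kinetics.v_thresh_mv) / kinetics.v_slope_mv)


def step_activation(
    state: ActivationState,
    v_pre_mv: float,
    dt_ms: float,
    kinetics: SynapseKinetics,
) -> ActivationState:
    """Advance every kinetic component by one explicit-Euler step.

    With S_inf = 0 the update reduces exactly to exponential decay with
    the component's own time constant.  ``dt_ms`` must not exceed a tenth
    of the smallest tau (stability contract); near saturation, where the
    effective time constant (1 - S_inf) * tau collapses, the step snaps
    directly to S_inf instead of overshooting.
    """
    if dt_ms <= 0.0:
        raise ValueError("dt_ms must be positive")
    if dt_ms > kinetics.min_tau_ms / 10.0:
        raise ValueError(
            f"dt_ms={dt_ms} too large for stability: must be <= "
            f"min(tau)/10 = {kinetics.min_tau_ms / 10.0} ms"
        )
    s_inf = min(steady_state_activation(v_pre_mv, kinetics), _S_INF_CAP)
    s_new = np.empty_like(state.s)
    for i, (_, tau) in enumerate(kinetics.components):
        tau_eff = (1.0 - s_inf) * tau
        if dt_ms >= tau_eff:
            s_new[i] = s_inf
        else:
            s_new[i] = state.s[i] + dt_ms * (s_inf - state.s[i]) / tau_eff
    np.clip(s_new, 0.0, _S_CAP, out=s_new)
    return ActivationState(s=s_new, t_ms=state.t_ms + dt_ms)


def synaptic_current(state: ActivationState, kinetics: SynapseKinetics) -> float:
    """Injected current in pA for the current activation state.

    Sum over components of g_syn * weight * S * (V_syn - V_post); linear
    in g_syn, so subtraction mode (negative g_syn) flips the sign.
    """
    drive = kinetics.v_syn_mv - kinetics.v_post_rest_mv
    total = 0.0
    for i, (w, _) in enumerate(kinetics.components):
        total += kinetics.g_syn_ns * w * float(state.s[i]) * drive
    return total


def clamp_trace(
    v_pre_trace: np.ndarray,
    kinetics: SynapseKinetics,
    dt_ms: float,
) -> np.ndarray:
    """Run the clamp cycle over a uniformly sampled presynaptic trace.

    Starts from S = 0 and returns the injected-current trace (pA) with
    the same length as the input.
    """
    v = np.asarray(v_pre_trace, dtype=float)
    if v.size == 0:
        raise ValueError("empty presynaptic trace")
    if not np.all(np.isfinite(v)):
        bad = int(np.flatnonzero(~np.isfinite(v))[0])
        raise ValueError(f"non-finite presynaptic voltage at sample {bad}")
    if dt_ms <= 0.0:
        raise ValueError("dt_ms must be positive")
    if dt_ms > kinetics.min_tau_ms / 10.0:
        raise ValueError("dt_ms too large for stability (<= min(tau)/10)")

    # Vectorised S_inf, then a scalar recurrence per component.
    above = v > kinetics.v_thresh_mv
    s_inf = np.zeros_like(v)
    s_inf[above] = np.tanh((v[above] - kinetics.v_thresh_mv) / kinetics.v_slope_mv)
    np.minimum(s_inf, _S_INF_CAP, out=s_inf)

    drive = kinetics.v_syn_mv - kinetics.v_post_rest_mv
    out = np.zeros_like(v)
    s_inf_list = s_inf.tolist()
    for w, tau in kinetics.components:
        s = 0.0
        gw = kinetics.g_syn_ns * w * drive
        comp = np.empty_like(v)
        comp_list = comp  # filled by index below
        for i, si in enumerate(s_inf_list):
            tau_eff = (1.0 - si) * tau
            if dt_ms >= tau_eff:
                s = si
            else:
                s += dt_ms * (si - s) / tau_eff
            if s < 0.0:
                s = 0.0
            elif s > _S_CAP:
                s = _S_CAP
            comp_list[i] = s
        out += gw * comp
    return out
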