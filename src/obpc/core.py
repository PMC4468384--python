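"""Single-neuron and single-synapse primitives.

Membrane voltages follow a first-order relaxation toward the total synaptic
drive, integrated with a fixed-step Euler scheme.  Populations are either
*continuous* (their transfer-function output is used directly as a graded
signal) or *spiking* (the transfer function gives a per-timestep Bernoulli
spiking probability, with post-spike reset and an absolute refractory
period).  Synaptic conductances follow a difference-of-exponentials time
course keyed to the presynaptic neuron's most recent spike.

Everything here is pure computation on numpy arrays; the network wiring and
the integration loop live in :mod:`obpc.network`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CellParams",
    "NeuronState",
    "SynapseKernelParams",
    "SimulationDivergence",
    "DIVERGENCE_LIMIT_MV",
    "euler_membrane_step",
    "transfer",
    "conductance_kernel",
    "kernel_decay_factors",
    "synaptic_drive",
    "spike_and_reset",
    "ahp_step",
    "ahp_drive",
    "couple_mitral_compartments",
]

#: Hard guard against runaway voltages; exceeded values abort the simulation
#: instead of silently saturating.
DIVERGENCE_LIMIT_MV = 1.0e3


class SimulationDivergence(RuntimeError):
    """Raised when a membrane voltage leaves the plausible range."""


@dataclass(frozen=True)
class CellParams:
    """Membrane and transfer-function constants for one population.

    Parameters
    ----------
    tau
        Membrane time constant (ms).
    beta
        Exponent of the transfer nonlinearity (dimensionless).
    theta_min
        Minimum firing threshold (mV); output is 0 at or below it.
    theta_max
        Saturation threshold (mV); output is 1 at or above it.
    v_hyper
        Post-spike reset potential (mV).
    t_refrac
        Absolute refractory period (ms).
    is_spiking
        False for graded-output populations (sensory input channels and
        periglomerular dendrites), True otherwise.
    a_ahc
        Afterhyperpolarization amplitude; 0 disables adaptation.
    tau_ahc
        Adaptation decay time constant (ms).
    e_ahc
        Adaptation reversal potential (mV).
    a_ahc_ref
        Fixed normalizer converting the adaptation variable into a
        conductance-like gate; kept at the unmodulated amplitude so that
        scaling ``a_ahc`` down genuinely weakens the adaptation drive.
    """

    tau: float
    beta: float
    theta_min: float
    theta_max: float
    v_hyper: float = -10.0
    t_refrac: float = 2.0
    is_spiking: bool = True
    a_ahc: float = 0.0
    tau_ahc: float = 100.0
    e_ahc: float = -15.0
    a_ahc_ref: float = 40.0

    def __post_init__(self) -> None:
        if not self.theta_max > self.theta_min:
            raise ValueError(
                f"theta_max ({self.theta_max}) must exceed theta_min ({self.theta_min})"
            )
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.t_refrac < 0:
            raise ValueError(f"t_refrac must be >= 0, got {self.t_refrac}")
        if self.a_ahc < 0:
            raise ValueError(f"a_ahc must be >= 0, got {self.a_ahc}")
        if self.a_ahc > 0 and not self.tau_ahc > 0:
            raise ValueError("tau_ahc must be positive when adaptation is active")

    def with_updates(self, **kwargs) -> "CellParams":
        return replace(self, **kwargs)


@dataclass
class NeuronState:
    """Mutable per-population state advanced by the integration loop."""

    v: np.ndarray
    v_ahc: np.ndarray
    t_last_spike: np.ndarray  # ms; -inf means "never fired"
    output: np.ndarray  # last transfer value (continuous) or spike indicator

    @classmethod
    def zeros(cls, n: int) -> "NeuronState":
        return cls(
            v=np.zeros(n),
            v_ahc=np.zeros(n),
            t_last_spike=np.full(n, -np.inf),
            output=np.zeros(n),
        )


@dataclass(frozen=True)
class SynapseKernelParams:
    """Conductance time-course constants for one pathway.

    ``tau1``/``tau2`` are the rise and fall times.  The kernel is oriented
    so it is non-negative regardless of how the two constants are ordered
    (difference of the slow and fast exponential).
    """

    g_max: float
    e_nernst: float
    tau1: float
    tau2: float

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("kernel time constants must be positive")
        if self.tau1 == self.tau2:
            raise ValueError("tau1 and tau2 must differ")
        if self.g_max < 0:
            raise ValueError("g_max must be non-negative")

    @property
    def tau_rise(self) -> float:
        return min(self.tau1, self.tau2)

    @property
    def tau_fall(self) -> float:
        return max(self.tau1, self.tau2)

    @property
    def t_peak(self) -> float:
        """Time of the kernel maximum (closed form)."""
        tr, tf = self.tau_rise, self.tau_fall
        return np.log(tf / tr) * tr * tf / (tf - tr)


def _check_finite(name: str, x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise SimulationDivergence(f"non-finite values in {name}: {np.asarray(x)!r}")


def euler_membrane_step(
    v: np.ndarray, v_ext: np.ndarray, tau: float, dt: float
) -> np.ndarray:
    """One Euler step of ``tau dv/dt + v = v_ext``.

    Returns ``v + (dt / tau) * (v_ext - v)`` elementwise.  Requires
    ``0 < dt < tau`` for stability of the explicit scheme.
    """
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if not dt < tau:
        raise ValueError(f"dt ({dt}) must be smaller than tau ({tau})")
    v = np.asarray(v, dtype=float)
    v_ext = np.asarray(v_ext, dtype=float)
    _check_finite("v", v)
    _check_finite("v_ext", v_ext)
    return v + (dt / tau) * (v_ext - v)


def transfer(v: np.ndarray, p: CellParams) -> np.ndarray:
    """Piecewise power-law output nonlinearity.

    0 below ``theta_min``, 1 above ``theta_max`` and
    ``((v - theta_min) / (theta_max - theta_min)) ** beta`` in between.
    For spiking populations this is the per-timestep spiking probability;
    for continuous populations it is the graded output itself.
    """
    x = (np.asarray(v, dtype=float) - p.theta_min) / (p.theta_max - p.theta_min)
    x = np.clip(x, 0.0, 1.0)
    if p.beta == 1.0:
        return x
    return np.power(x, p.beta)


def conductance_kernel(t_since_spike, k: SynapseKernelParams) -> np.ndarray:
    """Difference-of-exponentials conductance at ``t`` ms after a spike.

    ``g_max * (exp(-t/tau_fall) - exp(-t/tau_rise))``: zero at t = 0,
    a single interior maximum, decay to zero.  Negative times are invalid.
    """
    t = np.asarray(t_since_spike, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_spike must be non-negative")
    return k.g_max * (np.exp(-t / k.tau_fall) - np.exp(-t / k.tau_rise))


def kernel_decay_factors(k: SynapseKernelParams, dt: float) -> tuple[float, float]:
    """Per-step decay multipliers (fall, rise) for incremental kernel state.

    Maintaining two exponential state variables that reset to 1 on a
    presynaptic spike and decay by these factors reproduces
    :func:`conductance_kernel` at every grid point exactly.
    """
    return float(np.exp(-dt / k.tau_fall)), float(np.exp(-dt / k.tau_rise))


def synaptic_drive(w, g, e_nernst: float, v_post) -> np.ndarray:
    """Drive ``w * g * (E - v_post)`` of one synapse type onto one neuron."""
    return np.asarray(w) * np.asarray(g) * (e_nernst - np.asarray(v_post))


def spike_and_reset(
    state: NeuronState,
    p: CellParams,
    t_now: float,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stochastic spike emission with reset and refractoriness.

    Each non-refractory neuron spikes with probability ``transfer(v)`` in
    this timestep.  Spiking neurons are reset to ``v_hyper`` and cannot
    spike again for ``t_refrac`` ms.  Returns the 0/1 spike indicator and
    mutates ``state`` in place.
    """
    if not p.is_spiking:
        raise ValueError("spike_and_reset called on a continuous population")
    if rng is None:
        raise ValueError("an explicit rng is required (no global randomness)")
    prob = transfer(state.v, p)
    refractory = (t_now - state.t_last_spike) < p.t_refrac
    draws = rng.random(state.v.shape[0])
    spiked = (draws < prob) & ~refractory
    state.v[spiked] = p.v_hyper
    state.t_last_spike[spiked] = t_now
    state.output = spiked.astype(float)
    return spiked


def ahp_step(
    v_ahc: np.ndarray, spiked: np.ndarray, p: CellParams, dt: float
) -> np.ndarray:
    """Advance the adaptation variable one step.

    ``v_ahc`` relaxes toward ``a_ahc * X`` with time constant ``tau_ahc``,
    where X is 1 in the step after a spike and 0 otherwise.
    """
    x = np.asarray(spiked, dtype=float)
    return v_ahc + (dt / p.tau_ahc) * (p.a_ahc * x - v_ahc)


def ahp_drive(v_ahc: np.ndarray, v: np.ndarray, p: CellParams) -> np.ndarray:
    """Hyperpolarizing drive of the adaptation variable on the membrane.

    The adaptation variable acts as a conductance-like gate
    ``v_ahc / a_ahc_ref`` pulling the membrane toward ``e_ahc``; zero when
    the neuron has not fired recently.
    """
    if p.a_ahc_ref <= 0:
        return np.zeros_like(v)
    return (v_ahc / p.a_ahc_ref) * (p.e_ahc - v)


def couple_mitral_compartments(
    v_apical: np.ndarray, v_soma: np.ndarray
) -> np.ndarray:
    """Electrical coupling drive of the apical compartment into the soma.

    The apical-minus-soma voltage difference is injected additively into
    the soma's membrane equation.
    """
    v_apical = np.asarray(v_apical, dtype=float)
    v_soma = np.asarray(v_soma, dtype=float)
    if v_apical.shape != v_soma.shape:
        raise ValueError(
            f"compartment shape mismatch: {v_apical.shape} vs {v_soma.shape}"
        )
    return v_apical - v_soma


def check_divergence(name: str, v: np.ndarray) -> None:
    """Abort with a diagnostic if voltages left the plausible range."""
    m = float(np.max(np.abs(v))) if v.size else 0.0
    if not np.isfinite(m) or m > DIVERGENCE_LIMIT_MV:
        raise SimulationDivergence(
            f"population {name!r} diverged: max |v| = {m:.3g} mV "
            f"(limit {DIVERGENCE_LIMIT_MV:g} mV); check parameters"
        )
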