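"""Hebbian learning on the cortical association fibers (Pyr -> Pyr).

Weight growth is driven by the coincidence of a postsynaptic depolarization
trace and a presynaptic glutamate-binding trace; when both peak together
the weight is driven toward 1 with a slow characteristic time.  There is no
unlearning: weights only grow.  A global normalization rescales the weights
used in the synaptic drive so they always sum to 1 over active synapses,
which concentrates the increments on the odor-responsive subnetwork.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PlasticityParams",
    "AssociativeWeights",
    "init_weights",
    "post_trace",
    "glu_trace",
    "glu_trace_peak_time",
    "hebbian_step",
    "normalize_weights",
    "save_weights",
    "load_weights",
]


@dataclass(frozen=True)
class PlasticityParams:
    """Time constants and knobs of the associative learning rule."""

    tau_pp: float = 800.0  # weight time constant (ms)
    tau_post: float = 2.0  # postsynaptic depolarization time (ms)
    tau_nmda_f: float = 7.0  # NMDA unbinding / fall (ms)
    tau_nmda_r: float = 1.0  # NMDA binding / rise (ms)
    t_delay: float = 1.0  # soma-to-recurrent-synapse conduction delay (ms)
    w_init_max: float = 0.04
    learning_enabled: bool = True
    # literal (monotone-decreasing) printed form of the glutamate trace,
    # kept for comparison only; the default is the rise-fall form.
    literal_glu_form: bool = False

    def __post_init__(self) -> None:
        for name in ("tau_pp", "tau_post", "tau_nmda_f", "tau_nmda_r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.w_init_max <= 0:
            raise ValueError("w_init_max must be positive")
        if self.t_delay < 0:
            raise ValueError("t_delay must be >= 0")


@dataclass
class AssociativeWeights:
    """Raw and drive-normalized Pyr->Pyr weight matrices.

    ``w[i, j]`` is the synapse from presynaptic cell i onto postsynaptic
    cell j; entries off the adjacency stay exactly 0.  ``w_normalized`` is
    the rescaled copy used in the conductance computation.
    """

    w: np.ndarray
    adjacency: np.ndarray  # bool (n_pre, n_post)
    w_normalized: np.ndarray

    @property
    def n_active(self) -> int:
        return int(self.adjacency.sum())

    def copy(self) -> "AssociativeWeights":
        return AssociativeWeights(
            self.w.copy(), self.adjacency, self.w_normalized.copy()
        )


def init_weights(adjacency: np.ndarray, seed) -> AssociativeWeights:
    """Uniform random weights on [0, w_init_max] over the active synapses."""
    adjacency = np.asarray(adjacency, dtype=bool)
    rng = np.random.default_rng(seed)
    w = np.zeros(adjacency.shape)
    w[adjacency] = rng.uniform(0.0, 0.04, size=int(adjacency.sum()))
    aw = AssociativeWeights(w=w, adjacency=adjacency, w_normalized=np.zeros_like(w))
    return normalize_weights(aw)


def post_trace(t_since_post_spike, p: PlasticityParams) -> np.ndarray:
    """Postsynaptic depolarization trace ``(t/tau) * exp(1 - t/tau)``.

    Zero at t = 0, unit peak exactly at ``t = tau_post``; negative t (no
    spike yet) maps to 0.
    """
    t = np.asarray(t_since_post_spike, dtype=float)
    valid = np.isfinite(t) & (t >= 0)
    x = np.where(valid, t, 0.0) / p.tau_post
    out = x * np.exp(1.0 - x)
    return np.where(valid, out, 0.0)


def glu_trace_peak_time(p: PlasticityParams) -> float:
    """Interior maximum of the rise-fall glutamate trace (closed form)."""
    tr, tf = p.tau_nmda_r, p.tau_nmda_f
    return tr * np.log((tf + tr) / tr)


def glu_trace(t_since_pre_arrival, p: PlasticityParams) -> np.ndarray:
    """Glutamate-binding trace on NMDA receptors, unit peak.

    Default form ``exp(-t/tau_f) * (1 - exp(-t/tau_r))`` rescaled to a
    peak of 1: zero at t = 0, single interior maximum, decay to zero.
    The literal printed variant (monotone-decreasing product of two
    exponentials) is available behind ``literal_glu_form``.
    """
    t = np.asarray(t_since_pre_arrival, dtype=float)
    valid = np.isfinite(t) & (t >= 0)
    ts = np.where(valid, t, 0.0)
    if p.literal_glu_form:
        out = np.exp(-ts / p.tau_nmda_f) * np.exp(1.0 - ts / p.tau_nmda_r)
        return np.where(valid, out, 0.0)
    t_star = glu_trace_peak_time(p)
    peak = np.exp(-t_star / p.tau_nmda_f) * (1.0 - np.exp(-t_star / p.tau_nmda_r))
    out = np.exp(-ts / p.tau_nmda_f) * (1.0 - np.exp(-ts / p.tau_nmda_r)) / peak
    return np.where(valid, out, 0.0)


def hebbian_step(
    w: AssociativeWeights,
    post_traces: np.ndarray,
    glu_traces: np.ndarray,
    dt: float,
    p: PlasticityParams,
) -> AssociativeWeights:
    """One Euler step of the coincidence rule, in place.

    Per active synapse (pre i -> post j):
    ``w_ij += dt * (1 - w_ij) * glu_i * post_j / tau_pp``.
    Weights are bounded in [0, 1] and never decrease.
    """
    if not p.learning_enabled:
        return w
    coincidence = np.outer(
        np.asarray(glu_traces, dtype=float), np.asarray(post_traces, dtype=float)
    )
    dw = (dt / p.tau_pp) * (1.0 - w.w) * coincidence
    dw[~w.adjacency] = 0.0
    np.clip(w.w + dw, 0.0, 1.0, out=w.w)
    return w


def normalize_weights(w: AssociativeWeights) -> AssociativeWeights:
    """Rescale so the normalized weights sum to 1 over active synapses.

    The raw weights are retained for learning; only ``w_normalized`` (the
    copy used in the drive computation) changes.
    """
    total = float(w.w[w.adjacency].sum())
    if total <= 0:
        raise ValueError("cannot normalize: all associative weights are zero")
    w.w_normalized = w.w / total
    return w


def save_weights(w: AssociativeWeights, path, **meta) -> None:
    """Persist a weight matrix plus a JSON sidecar.

    ``meta`` (seed, training odor spec, NE levels, session count, ...) goes
    into ``<path>.json`` so trained networks can be reloaded for recall.
    """
    path = Path(path)
    np.savez_compressed(path, w=w.w, adjacency=w.adjacency,
                        w_normalized=w.w_normalized)
    sidecar = path.with_suffix(path.suffix + ".json") if path.suffix == ".npz" \
        else Path(str(path) + ".npz.json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))


def load_weights(path) -> tuple[AssociativeWeights, dict]:
    """Inverse of :func:`save_weights`; returns (weights, sidecar metadata)."""
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    with np.load(path) as data:
        aw = AssociativeWeights(
            w=data["w"].copy(),
            adjacency=data["adjacency"].astype(bool),
            w_normalized=data["w_normalized"].copy(),
        )
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return aw, meta
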