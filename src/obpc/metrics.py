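"""Windowed firing rates, baseline-calibrated detection, and sparseness.

Detection asks whether the population rate pattern evoked by an odor is
farther from spontaneous activity than spontaneous activity is from itself:
the Euclidean distance between evoked and spontaneous rate vectors is
standardized against the mean and twice the standard deviation of pairwise
distances between independent spontaneous runs.  An index above 1 counts
as detectable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from .network import SimResult

__all__ = [
    "DetectionReport",
    "mean_rates",
    "euclidean_distance",
    "detection_index",
    "sparseness",
    "compare_conditions",
]


@dataclass(frozen=True)
class DetectionReport:
    """Baseline statistics plus the standardized evoked distance."""

    baseline_mean: float
    baseline_sd: float
    evoked_distance: float
    index: float
    detectable: bool
    n_baseline_pairs: int

    def to_json(self, **extra) -> str:
        d = asdict(self)
        d.update(extra)
        return json.dumps(d, indent=2, sort_keys=True)


def mean_rates(
    sim: SimResult,
    population: str,
    window_ms: float | None = None,
    settle_ms: float = 200.0,
) -> np.ndarray:
    """Per-neuron mean firing rate (Hz) over the analysis window.

    The window starts after ``settle_ms`` (activity stabilizes within a
    couple hundred ms) and spans ``window_ms`` (default: the remainder of
    the run).  Continuous populations report mean transfer output instead
    of a rate.
    """
    i0 = int(round(settle_ms / sim.dt))
    if window_ms is None:
        window_ms = sim.duration_ms - settle_ms
    i1 = i0 + int(round(window_ms / sim.dt))
    if window_ms <= 0 or i1 > sim.n_steps:
        raise ValueError(
            f"analysis window [{settle_ms}, {settle_ms + window_ms}) ms does not "
            f"fit in a {sim.duration_ms} ms simulation"
        )
    if population in sim.spikes:
        counts = sim.spikes[population][i0:i1].sum(axis=0)
        return counts * (1000.0 / window_ms)
    if population in sim.cont:
        return sim.cont[population][i0:i1].mean(axis=0).astype(float)
    raise KeyError(f"population {population!r} not recorded")


def euclidean_distance(a, b, normalized: bool = False,
                       norm_constant: float | None = None) -> float:
    """L2 distance between two equal-length vectors.

    With ``normalized=True`` the distance is divided by ``norm_constant``
    (e.g. the expected distance between two independent odors).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    d = float(np.linalg.norm(a - b))
    if normalized:
        if norm_constant is None or norm_constant <= 0:
            raise ValueError("normalized distance requires a positive norm_constant")
        d /= norm_constant
    return d


def detection_index(
    spont_runs: list[np.ndarray],
    evoked: np.ndarray,
    spont_ref: np.ndarray,
    sd_floor: float = 0.0,
) -> DetectionReport:
    """Standardized evoked-vs-spontaneous pattern distance.

    The baseline is built from all pairwise distances among independent
    spontaneous runs; the evoked distance is measured against a held-out
    spontaneous reference.  ``index = (d - mean) / (2 * sd)``; values above
    1 are detectable.

    A perfectly silent baseline (e.g. deep in the high-modulation corner
    where spontaneous activity is fully suppressed) has zero spread and no
    index can be issued; by default this is a hard failure.  Passing a
    positive ``sd_floor`` (natural choice: half the rate quantization of
    the analysis window, in the same units as the vectors) instead clips
    the baseline sd from below, keeping the index finite and monotone in
    the evoked distance.
    """
    if len(spont_runs) < 2:
        raise ValueError("need at least two spontaneous runs for a baseline")
    dists = [
        euclidean_distance(spont_runs[i], spont_runs[j])
        for i in range(len(spont_runs))
        for j in range(i + 1, len(spont_runs))
    ]
    mean = float(np.mean(dists))
    sd = float(np.std(dists, ddof=1)) if len(dists) > 1 else 0.0
    if sd <= 0 and sd_floor <= 0:
        raise ValueError(
            "degenerate baseline: spontaneous distances have zero spread "
            f"(pairs={len(dists)}, mean={mean:.4g}); pass sd_floor > 0 to "
            "clip at the measurement resolution instead"
        )
    sd = max(sd, sd_floor)
    d = euclidean_distance(evoked, spont_ref)
    index = (d - mean) / (2.0 * sd)
    return DetectionReport(
        baseline_mean=mean, baseline_sd=sd, evoked_distance=d,
        index=index, detectable=index > 1.0, n_baseline_pairs=len(dists),
    )


def sparseness(w) -> float:
    """How concentrated a non-negative vector is, in [0, 1].

    ``S = (1 - (sum(w)/N)^2 / (sum(w^2)/N)) / (1 - 1/N)``: exactly 0 for a
    uniform vector, exactly 1 for a one-hot vector.
    """
    w = np.asarray(w, dtype=float).ravel()
    n = w.size
    if n < 2:
        raise ValueError("sparseness needs at least two entries")
    if np.any(w < 0):
        raise ValueError("sparseness requires non-negative weights")
    sq = float(np.sum(w * w))
    if sq == 0:
        raise ValueError("sparseness undefined for an all-zero vector")
    mean_sq = (float(np.sum(w)) / n) ** 2
    return (1.0 - mean_sq / (sq / n)) / (1.0 - 1.0 / n)


def compare_conditions(
    samples_a,
    samples_b,
    test: str = "wilcoxon",
    n_comparisons: int = 1,
    alternative: str = "two-sided",
) -> tuple[float, float, float]:
    """Paired Wilcoxon or t-test with Bonferroni correction.

    Returns ``(statistic, p_raw, p_corrected)`` where the corrected p is
    ``min(1, p * n_comparisons)``.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    if test == "wilcoxon":
        if a.shape != b.shape:
            raise ValueError("wilcoxon requires paired samples of equal length")
        if a.size < 5:
            raise ValueError("too few pairs for a Wilcoxon test")
        if np.allclose(a, b):
            # all differences zero: cannot reject
            return 0.0, 1.0, 1.0
        res = stats.wilcoxon(a, b, alternative=alternative)
    elif test == "ttest":
        if min(a.size, b.size) < 2:
            raise ValueError("too few samples for a t-test")
        res = stats.ttest_ind(a, b, alternative=alternative)
    elif test == "ttest_paired":
        if a.shape != b.shape:
            raise ValueError("paired t-test requires equal-length samples")
        res = stats.ttest_rel(a, b, alternative=alternative)
    else:
        raise ValueError(f"unknown test {test!r}")
    p_raw = float(res.pvalue)
    return float(res.statistic), p_raw, min(1.0, p_raw * n_comparisons)
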