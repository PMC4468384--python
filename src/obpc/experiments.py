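"""The four simulation campaigns: detection grids, locus knockouts,
learning/recall, and perturbed-recall robustness.

Every grid point uses a fresh network and odor instantiation; all seeds are
derived deterministically from a master seed plus the point coordinates, so
conditions that should be compared in a paired fashion (e.g. knockout
conditions) share network, odor and noise seeds and differ only in the
modulation flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import compare_conditions, detection_index, mean_rates, sparseness
from .network import (
    Network,
    NetworkConfig,
    OdorStimulus,
    build_network,
    generate_odor,
    perturb_odor,
    run_simulation,
)
from .neuromod import NEState
from .plasticity import normalize_weights

__all__ = [
    "ExperimentSpec",
    "desk_spec",
    "paper_spec",
    "derive_seed",
    "evaluate_point",
    "train_network",
    "detection_grid",
    "locus_knockout",
    "learn_recall",
    "perturbation_curve",
    "KNOCKOUT_CONDITIONS",
]

#: Low / medium / high NE levels used in the learning protocols (uM);
#: "high" is effective saturation (1 M).
NE_LOW, NE_MED, NE_HIGH = 1.0e-2, 1.0, 1.0e6


@dataclass
class ExperimentSpec:
    """Scale and protocol knobs for one campaign."""

    ne_grid_um: list[float] = field(
        default_factory=lambda: list(np.logspace(-2, 6, 10)))
    odor_concentrations: list[float] = field(
        default_factory=lambda: list(np.linspace(0.1, 1.0, 10)))
    n_repeats: int = 10
    n_spont_runs: int = 5  # last run is the held-out evoked reference
    duration_ms: float = 1200.0
    settle_ms: float = 200.0
    training_sessions: int = 4
    session_ms: float = 5000.0
    training_ne_um: list[float] = field(
        default_factory=lambda: [NE_LOW, NE_MED, NE_HIGH])
    recall_ne_um: list[float] = field(
        default_factory=lambda: [NE_LOW, NE_MED, NE_HIGH])
    learn_concentrations: list[float] = field(default_factory=lambda: [0.2, 0.8])
    distances: list[float] = field(
        default_factory=lambda: [0.0, 0.2, 0.4, 0.6, 0.8])
    # low concentration: the learned component of the recall response
    # dominates there, which is what the robustness curves probe
    perturb_concentration: float = 0.2
    master_seed: int = 0
    config: NetworkConfig = field(default_factory=NetworkConfig)

    @property
    def window_ms(self) -> float:
        return self.duration_ms - self.settle_ms

    @property
    def sd_floor(self) -> float:
        """Baseline-sd floor at half the rate quantum of the window (Hz)."""
        return 0.5 * 1000.0 / self.window_ms


def desk_spec(master_seed: int = 0, **overrides) -> ExperimentSpec:
    """Reduced-scale profile for interactive runs and tests."""
    spec = ExperimentSpec(master_seed=master_seed)
    return replace(spec, **overrides) if overrides else spec


def paper_spec(master_seed: int = 0, **overrides) -> ExperimentSpec:
    """Full-scale profile: 30 x 30 grids, 40 repeats."""
    spec = ExperimentSpec(
        ne_grid_um=list(np.logspace(-2, 6, 30)),
        odor_concentrations=list(np.linspace(1 / 30, 1.0, 30)),
        n_repeats=40,
        master_seed=master_seed,
    )
    return replace(spec, **overrides) if overrides else spec


def derive_seed(master: int, *coords) -> int:
    """Deterministic child seed from the master seed and coordinates."""
    key = tuple((int(c) if isinstance(c, (int, np.integer)) else hash(c))
                & 0xFFFFFFFF for c in coords)
    ss = np.random.SeedSequence(entropy=int(master) & 0xFFFFFFFFFFFF,
                                spawn_key=key)
    return int(ss.generate_state(1, dtype=np.uint64)[0])


def evaluate_point(
    spec: ExperimentSpec,
    network: Network,
    odor: OdorStimulus | None,
    ne_state: NEState,
    point_seed: int,
    populations: tuple[str, ...] = ("Mi", "Pyr"),
) -> dict:
    """Spontaneous baseline + evoked run at one condition.

    Runs ``n_spont_runs`` spontaneous simulations (the last held out as the
    evoked reference, the rest forming the pairwise baseline) and one evoked
    simulation, then reports mean rate and detection index per population.
    """
    sims = [
        run_simulation(network, None, ne_state, spec.duration_ms,
                       derive_seed(point_seed, 1, k), record_cont=False)
        for k in range(spec.n_spont_runs)
    ]
    evoked_sim = run_simulation(network, odor, ne_state, spec.duration_ms,
                                derive_seed(point_seed, 2), record_cont=False)
    out: dict = {}
    for pop in populations:
        spont = [mean_rates(s, pop, spec.window_ms, spec.settle_ms) for s in sims]
        evoked = mean_rates(evoked_sim, pop, spec.window_ms, spec.settle_ms)
        rep = detection_index(spont[:-1], evoked, spont[-1],
                              sd_floor=spec.sd_floor)
        out[pop] = {
            "rate_mean": float(evoked.mean()),
            "spont_rate_mean": float(np.mean([v.mean() for v in spont])),
            "detection_index": rep.index,
            "detectable": rep.detectable,
        }
    return out


def train_network(
    network: Network,
    odor: OdorStimulus,
    ne_state: NEState,
    spec: ExperimentSpec,
    seed: int,
) -> Network:
    """Hebbian training: consecutive sessions with per-session normalization.

    Mutates and returns ``network``; weights only grow.
    """
    for s in range(spec.training_sessions):
        run_simulation(network, odor, ne_state, spec.session_ms,
                       derive_seed(seed, 7, s), learn=True, record_cont=False)
        normalize_weights(network.assoc)
    return network


def _point_rows(spec, ne_um, conc, repeat, result, extra=None) -> list[dict]:
    rows = []
    for pop, vals in result.items():
        row = {"ne_um": ne_um, "concentration": conc, "repeat": repeat,
               "population": pop, **vals}
        if extra:
            row.update(extra)
        rows.append(row)
    return rows


def detection_grid(spec: ExperimentSpec,
                   ne_state_factory=None) -> pd.DataFrame:
    """Rates and detection over the NE x concentration grid.

    ``ne_state_factory(ne_um) -> NEState`` customizes the modulation flags
    (default: modulation enabled in both structures at the grid level).
    """
    if len(spec.ne_grid_um) < 1 or len(spec.odor_concentrations) < 1:
        raise ValueError("empty grid")
    factory = ne_state_factory or (lambda c: NEState.uniform(c))
    rows: list[dict] = []
    for i, ne_um in enumerate(spec.ne_grid_um):
        for j, conc in enumerate(spec.odor_concentrations):
            for r in range(spec.n_repeats):
                seed = derive_seed(spec.master_seed, i, j, r)
                try:
                    network = build_network(spec.config, derive_seed(seed, 0))
                    odor = generate_odor(derive_seed(seed, 3), conc)
                    res = evaluate_point(spec, network, odor, factory(ne_um), seed)
                except Exception as err:  # annotate the failing coordinate
                    raise RuntimeError(
                        f"grid point (ne={ne_um:g} uM, c={conc:g}, repeat={r}) "
                        f"failed: {err}"
                    ) from err
                rows.extend(_point_rows(spec, ne_um, conc, r, res))
    return pd.DataFrame(rows)


KNOCKOUT_CONDITIONS = ("both_on", "both_off", "ob_only", "pc_only")


def _knockout_state(condition: str, ne_um: float) -> NEState:
    on = {"both_on": (True, True), "both_off": (False, False),
          "ob_only": (True, False), "pc_only": (False, True)}[condition]
    return NEState(ne_um, ne_um, enabled_ob=on[0], enabled_pc=on[1])


def locus_knockout(spec: ExperimentSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Four modulation conditions over the same (paired) grid.

    Returns the tidy grid and a statistics table comparing every condition
    against the both-on control on Pyr rates and detection with paired
    Wilcoxon tests, Bonferroni-corrected.
    """
    rows: list[dict] = []
    for cond in KNOCKOUT_CONDITIONS:
        for i, ne_um in enumerate(spec.ne_grid_um):
            for j, conc in enumerate(spec.odor_concentrations):
                for r in range(spec.n_repeats):
                    seed = derive_seed(spec.master_seed, i, j, r)  # paired
                    network = build_network(spec.config, derive_seed(seed, 0))
                    odor = generate_odor(derive_seed(seed, 3), conc)
                    res = evaluate_point(spec, network, odor,
                                         _knockout_state(cond, ne_um), seed)
                    rows.extend(_point_rows(spec, ne_um, conc, r, res,
                                            {"condition": cond}))
    df = pd.DataFrame(rows)

    pyr = df[df.population == "Pyr"].set_index(
        ["condition", "ne_um", "concentration", "repeat"]).sort_index()
    control = pyr.loc["both_on"]
    stats_rows = []
    others = [c for c in KNOCKOUT_CONDITIONS if c != "both_on"]
    for cond in others:
        sample = pyr.loc[cond]
        for measure in ("rate_mean", "detection_index"):
            stat, p_raw, p_corr = compare_conditions(
                sample[measure].to_numpy(), control[measure].to_numpy(),
                test="wilcoxon", n_comparisons=len(others),
            )
            stats_rows.append({
                "condition": cond, "measure": measure, "statistic": stat,
                "p_raw": p_raw, "p_bonferroni": p_corr,
                "mean_abs_diff": float(
                    np.abs(sample[measure].to_numpy()
                           - control[measure].to_numpy()).mean()),
            })
    return df, pd.DataFrame(stats_rows)


def learn_recall(spec: ExperimentSpec) -> pd.DataFrame:
    """Train at several NE levels, then recall the learned odor.

    For each repeat a fresh network and odor are drawn; the naive condition
    and every trained condition are evaluated at every recall NE level with
    plasticity frozen.  Rows carry ``train_ne_um`` = NaN for naive.
    """
    rows: list[dict] = []
    for r in range(spec.n_repeats):
        for conc in spec.learn_concentrations:
            seed = derive_seed(spec.master_seed, 11, r, int(conc * 1000))
            base_net = build_network(spec.config, derive_seed(seed, 0))
            odor = generate_odor(derive_seed(seed, 3), conc)
            conditions: list[tuple[float | None, Network]] = [(None, base_net)]
            for train_ne in spec.training_ne_um:
                net = base_net.copy()
                train_network(net, odor, NEState.uniform(train_ne), spec,
                              derive_seed(seed, 5, int(np.log10(train_ne) * 10)))
                conditions.append((train_ne, net))
            for train_ne, net in conditions:
                for recall_ne in spec.recall_ne_um:
                    res = evaluate_point(
                        spec, net, odor, NEState.uniform(recall_ne),
                        derive_seed(seed, 6, int(np.log10(recall_ne) * 10)),
                        populations=("Pyr",),
                    )
                    rows.extend(_point_rows(
                        spec, recall_ne, conc, r, res,
                        {"train_ne_um": np.nan if train_ne is None else train_ne,
                         "trained": train_ne is not None,
                         "recall_ne_um": recall_ne}))
    return pd.DataFrame(rows)


def perturbation_curve(spec: ExperimentSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recall of perturbed odors and sparseness of the learned weights.

    Networks are trained at each training NE level and always recalled at
    low NE across a ladder of normalized odor distances; the spontaneous
    baseline is shared across distances within one trained network.
    """
    recall_ne = NEState.uniform(NE_LOW)
    rows: list[dict] = []
    sparse_rows: list[dict] = []
    conc = spec.perturb_concentration
    for r in range(spec.n_repeats):
        seed = derive_seed(spec.master_seed, 13, r)
        base_net = build_network(spec.config, derive_seed(seed, 0))
        odor = generate_odor(derive_seed(seed, 3), conc)
        for train_ne in spec.training_ne_um:
            net = base_net.copy()
            train_network(net, odor, NEState.uniform(train_ne), spec,
                          derive_seed(seed, 5, int(np.log10(train_ne) * 10)))
            sparse_rows.append({
                "repeat": r, "train_ne_um": train_ne,
                "weight_sparseness": sparseness(
                    net.assoc.w_normalized[net.assoc.adjacency]),
            })
            # shared spontaneous baseline for this trained network
            spont_sims = [
                run_simulation(net, None, recall_ne, spec.duration_ms,
                               derive_seed(seed, 8, k), record_cont=False)
                for k in range(spec.n_spont_runs)
            ]
            spont = [mean_rates(s, "Pyr", spec.window_ms, spec.settle_ms)
                     for s in spont_sims]
            for d_i, dist in enumerate(spec.distances):
                test_odor = perturb_odor(odor, dist, derive_seed(seed, 9, d_i))
                evoked_sim = run_simulation(
                    net, test_odor, recall_ne, spec.duration_ms,
                    derive_seed(seed, 10, d_i), record_cont=False)
                evoked = mean_rates(evoked_sim, "Pyr", spec.window_ms,
                                    spec.settle_ms)
                rep = detection_index(spont[:-1], evoked, spont[-1],
                                      sd_floor=spec.sd_floor)
                rows.append({
                    "repeat": r, "train_ne_um": train_ne, "distance": dist,
                    "concentration": conc, "population": "Pyr",
                    "rate_mean": float(evoked.mean()),
                    "detection_index": rep.index,
                    "detectable": rep.detectable,
                })
    return pd.DataFrame(rows), pd.DataFrame(sparse_rows)
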