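"""Norepinephrine (NE) dose-response modulation of cell and synapse parameters.

A scalar NE concentration per structure (bulb / cortex) is mapped through
saturating receptor-occupancy curves to a handful of parameter endpoints:
each modulated parameter interpolates linearly between its unmodulated
value and its fully-modulated value as occupancy goes 0 -> 1.

Granule-cell firing threshold is the one compound target: two receptor
classes with different affinities push it in opposite directions, which is
what produces the non-monotonic dose-response of mitral spontaneous
activity.

Half-max concentrations are calibration constants (they set where on the
concentration axis the transitions happen) and are config-exposed; the
defaults preserve the affinity ordering alpha2 << alpha1 and put the
crossover inside the simulated range 1e-2 uM .. 1e6 uM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReceptorCurve",
    "ModulatedParam",
    "NEState",
    "DEFAULT_CURVES",
    "MODULATED_PARAMS",
    "occupancy",
    "granule_threshold",
    "modulate",
    "NE_MIN_UM",
    "NE_MAX_UM",
]

#: Simulated concentration range, in uM (1e6 uM = 1 M).
NE_MIN_UM = 1.0e-2
NE_MAX_UM = 1.0e6


@dataclass(frozen=True)
class ReceptorCurve:
    """One saturating dose-response curve."""

    name: str
    y_half: float  # uM at half-maximal modulation

    def __post_init__(self) -> None:
        if not self.y_half > 0:
            raise ValueError(f"y_half must be positive, got {self.y_half}")


#: Default half-max constants (uM).  alpha2 on granule cells is the
#: high-affinity receptor (half-engaged at the protocols' "low" level of
#: 1e-2 uM); the others transition around 10 uM.  These are calibration
#: constants: only the ordering alpha2 << alpha1 is dictated by the data.
DEFAULT_CURVES: dict[str, ReceptorCurve] = {
    "alpha2_gr": ReceptorCurve("alpha2_gr", 0.01),
    "alpha1_gr": ReceptorCurve("alpha1_gr", 10.0),
    "alpha1_mi": ReceptorCurve("alpha1_mi", 10.0),
    "cortical": ReceptorCurve("cortical", 10.0),
}


@dataclass(frozen=True)
class ModulatedParam:
    """One (target, endpoint-pair, curve) modulation entry.

    ``target`` is ``(owner, parameter)`` where owner is a population name
    or a pathway name; ``locus`` decides which structure's NE concentration
    drives it.
    """

    owner: str
    parameter: str
    value_off: float
    value_on: float
    curve: str
    locus: str  # "ob" or "pc"


#: Every dual-valued parameter, exactly once.  Granule theta_min is handled
#: by :func:`granule_threshold` (two opposing components) and is listed here
#: as its two components for bookkeeping.
MODULATED_PARAMS: tuple[ModulatedParam, ...] = (
    ModulatedParam("Mi", "theta_max", 9.0, 1.0, "alpha1_mi", "ob"),
    ModulatedParam("Gr", "theta_min_alpha1", -1.0, -2.4, "alpha1_gr", "ob"),
    ModulatedParam("Gr", "theta_min_alpha2", 0.0, 1.0, "alpha2_gr", "ob"),
    ModulatedParam("Fb", "theta_min", 0.0, -0.1, "cortical", "pc"),
    ModulatedParam("Pyr", "a_ahc", 40.0, 0.0, "cortical", "pc"),
    ModulatedParam("pyr_fb", "g_max", 0.25, 0.06, "cortical", "pc"),
    ModulatedParam("pyr_pyr", "g_max", 510.0, 260.0, "cortical", "pc"),
)


@dataclass(frozen=True)
class NEState:
    """NE concentration (uM) and on/off switch per structure."""

    concentration_ob: float = 0.0
    concentration_pc: float = 0.0
    enabled_ob: bool = True
    enabled_pc: bool = True

    def __post_init__(self) -> None:
        for c in (self.concentration_ob, self.concentration_pc):
            if c < 0:
                raise ValueError(f"NE concentration must be >= 0, got {c}")

    @classmethod
    def off(cls) -> "NEState":
        return cls(0.0, 0.0, enabled_ob=False, enabled_pc=False)

    @classmethod
    def uniform(cls, concentration_um: float) -> "NEState":
        return cls(concentration_um, concentration_um)


def occupancy(c: float, y_half: float) -> float:
    """Fractional receptor occupancy ``1 / (1 + y_half / c)``.

    0 at zero concentration, 0.5 at ``c == y_half``, saturating at 1.
    """
    if y_half <= 0:
        raise ValueError(f"y_half must be positive, got {y_half}")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    with np.errstate(divide="ignore"):
        out = np.where(c > 0, 1.0 / (1.0 + y_half / np.where(c > 0, c, 1.0)), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def _blend(value_off: float, value_on: float, occ: float) -> float:
    return value_off + occ * (value_on - value_off)


def granule_threshold(
    ne_ob_um: float, curves: dict[str, ReceptorCurve] | None = None
) -> float:
    """Effective granule-cell firing threshold (mV) at a bulbar NE level.

    Two opposing receptor components add on top of the base threshold:
    the high-affinity component raises it (silencing granule cells and
    disinhibiting mitral cells at low NE) while the low-affinity component
    lowers it (re-engaging inhibition at high NE).
    """
    curves = curves or DEFAULT_CURVES
    o1 = occupancy(ne_ob_um, curves["alpha1_gr"].y_half)
    o2 = occupancy(ne_ob_um, curves["alpha2_gr"].y_half)
    base, full1 = -1.0, -2.4  # alpha1 component endpoints
    d_alpha1 = full1 - base  # -1.4
    d_alpha2 = 1.0 - 0.0  # +1
    return base + o1 * d_alpha1 + o2 * d_alpha2


def modulate(
    cells: dict,
    pathway_gmax: dict[str, float],
    ne: NEState,
    curves: dict[str, ReceptorCurve] | None = None,
    entries: tuple[ModulatedParam, ...] = MODULATED_PARAMS,
) -> tuple[dict, dict[str, float]]:
    """Apply NE modulation to cell parameters and pathway conductances.

    ``cells`` maps population name -> CellParams (the *unmodulated*
    profile); ``pathway_gmax`` maps pathway name -> unmodulated g_max.
    Returns modulated copies; a disabled locus reproduces the inputs for
    its targets exactly.
    """
    curves = curves or DEFAULT_CURVES
    cells = dict(cells)
    pathway_gmax = dict(pathway_gmax)

    known_owners = set(cells) | set(pathway_gmax)
    for m in entries:
        if m.owner not in known_owners:
            raise KeyError(f"modulation target {m.owner!r} not in network")

    def locus_active(m: ModulatedParam) -> bool:
        return ne.enabled_ob if m.locus == "ob" else ne.enabled_pc

    def locus_conc(m: ModulatedParam) -> float:
        return ne.concentration_ob if m.locus == "ob" else ne.concentration_pc

    for m in entries:
        if m.owner == "Gr":
            continue  # compound target, handled below
        if not locus_active(m):
            continue
        occ = occupancy(locus_conc(m), curves[m.curve].y_half)
        value = _blend(m.value_off, m.value_on, occ)
        if m.owner in pathway_gmax:
            pathway_gmax[m.owner] = value
        else:
            cells[m.owner] = cells[m.owner].with_updates(**{m.parameter: value})

    if ne.enabled_ob and "Gr" in cells:
        cells["Gr"] = cells["Gr"].with_updates(
            theta_min=granule_threshold(ne.concentration_ob, curves)
        )
    return cells, pathway_gmax
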