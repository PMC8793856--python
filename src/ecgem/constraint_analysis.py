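"""Classical constraint-based analyses on a genome-scale model.

Flux balance analysis (FBA), parsimonious FBA, flux variability analysis
(FVA), blocked-reaction and stoichiometrically-balanced-cycle (SBC)
detection, subsystem flux-sum ranges, biomass-coupling classification, ATP
production scans and cross-model EC overlap.  The LP solving is delegated
to cobrapy's optlang/GLPK backend; every optimal solution is audited for
mass balance (``||S v||_inf``) and bound feasibility before it is returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import cobra
import numpy as np
import pandas as pd
from cobra.flux_analysis import flux_variability_analysis
from cobra.flux_analysis import pfba as _cobra_pfba
from cobra.util.solver import linear_reaction_coefficients

from .model_core import reaction_ec_numbers, stoichiometric_matrix

#: numerical feasibility tolerance for the post-solve audit
FEASIBILITY_TOL = 1e-6
#: a reaction is "blocked" when its FVA range at fraction 0 is within this of 0
BLOCKED_TOL = 1e-9
#: default bound magnitude of unconstrained reactions (mmol gDW^-1 h^-1)
DEFAULT_FLUX_CAP = 2000.0

__all__ = [
    "FluxSolution",
    "fba",
    "pfba",
    "fva",
    "blocked_reactions",
    "detect_sbc",
    "subsystem_flux_range",
    "classify_coupling",
    "atp_production",
    "jaccard_ec_overlap",
    "objective_reaction_id",
]


@dataclass
class FluxSolution:
    """One steady-state flux distribution.

    ``objective_value`` is the flux through the objective (growth, h^-1 when
    the biomass reaction is mass-normalized); ``fluxes`` is indexed by
    reaction id; ``status`` is ``optimal``/``infeasible``/``unbounded``.
    """

    objective_value: float
    fluxes: pd.Series | None
    status: str

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def objective_reaction_id(model: cobra.Model) -> str:
    coeffs = linear_reaction_coefficients(model)
    if len(coeffs) != 1:
        raise ValueError("model objective is not a single reaction")
    return next(iter(coeffs)).id


def _audit(model: cobra.Model, fluxes: pd.Series) -> None:
    S = stoichiometric_matrix(model)
    v = fluxes.reindex([r.id for r in model.reactions]).to_numpy()
    residual = np.abs(S @ v).max() if S.shape[0] else 0.0
    if residual > FEASIBILITY_TOL:
        raise RuntimeError(f"solution violates S v = 0 (|residual| = {residual:.2e})")
    for rxn in model.reactions:
        val = fluxes[rxn.id]
        if val < rxn.lower_bound - FEASIBILITY_TOL or val > rxn.upper_bound + FEASIBILITY_TOL:
            raise RuntimeError(f"solution violates bounds on {rxn.id}")


def fba(model: cobra.Model, objective_reaction: str | None = None) -> FluxSolution:
    """Maximize the objective flux subject to ``S v = 0`` and bounds."""
    with model:
        if objective_reaction is not None:
            model.objective = model.reactions.get_by_id(objective_reaction)
        solution = model.optimize(raise_error=False)
        if solution.status != "optimal":
            return FluxSolution(float("nan"), None, solution.status)
        fluxes = solution.fluxes.copy()
        _audit(model, fluxes)
        return FluxSolution(float(solution.objective_value), fluxes, "optimal")


def pfba(model: cobra.Model) -> FluxSolution:
    """Parsimonious FBA: among optima, minimize the total absolute flux.

    Implemented as the standard lexicographic two-step LP (fix the FBA
    optimum, then minimize the L1 norm of the flux vector over forward and
    reverse flux components).
    """
    obj_id = objective_reaction_id(model)
    with model:
        try:
            solution = _cobra_pfba(model)
        except Exception as err:  # infeasible first stage
            return FluxSolution(float("nan"), None, f"infeasible ({err})")
        fluxes = solution.fluxes.copy()
        _audit(model, fluxes)
        return FluxSolution(float(fluxes[obj_id]), fluxes, "optimal")


def fva(
    model: cobra.Model,
    fraction_of_optimum: float = 0.9,
    reactions: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-reaction flux ranges at ``v_bio >= fraction * optimum``.

    Returns a DataFrame with ``minimum``/``maximum`` columns indexed by
    reaction id.
    """
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must lie in [0, 1]")
    reaction_list = None
    if reactions is not None:
        reaction_list = [model.reactions.get_by_id(r) for r in reactions]
    result = flux_variability_analysis(
        model,
        reaction_list=reaction_list,
        fraction_of_optimum=fraction_of_optimum,
        processes=1,
    )
    return result[["minimum", "maximum"]]


def blocked_reactions(model: cobra.Model, tol: float = BLOCKED_TOL) -> set[str]:
    """Reactions that cannot carry flux in any steady state (FVA at 0)."""
    ranges = fva(model, fraction_of_optimum=0.0)
    width_ok = (ranges["minimum"].abs() <= tol) & (ranges["maximum"].abs() <= tol)
    return set(ranges.index[width_ok])


def detect_sbc(model: cobra.Model, tol: float = BLOCKED_TOL) -> set[str]:
    """Reactions participating in stoichiometrically balanced cycles.

    With *all* boundary reactions (exchanges and sinks) closed, any reaction
    still able to carry flux belongs to an internal loop.  Report-only: no
    automatic correction is applied.
    """
    closed = model.copy()
    boundary_ids = set()
    for rxn in closed.reactions:
        if rxn.boundary:
            rxn.bounds = (0.0, 0.0)
            boundary_ids.add(rxn.id)
    ranges = fva(closed, fraction_of_optimum=0.0)
    loose = (ranges["minimum"].abs() > tol) | (ranges["maximum"].abs() > tol)
    return set(ranges.index[loose]) - boundary_ids


def subsystem_flux_range(
    model: cobra.Model, subsystem: str, fraction: float = 0.9
) -> tuple[float, float]:
    """Min/max of the sum of subsystem fluxes at a guaranteed growth fraction.

    Requires a split-irreversible model (all fluxes nonnegative), so the
    flux sum is a plain linear objective.
    """
    members = [r for r in model.reactions if r.subsystem == subsystem]
    if not members:
        raise ValueError(f"unknown subsystem {subsystem!r}")
    if any(r.lower_bound < 0 for r in model.reactions):
        raise ValueError("subsystem_flux_range requires a split-irreversible model")
    obj_id = objective_reaction_id(model)
    optimum = fba(model).objective_value
    out = []
    with model:
        model.reactions.get_by_id(obj_id).lower_bound = fraction * optimum
        model.objective = {r: 1.0 for r in members}
        for sense in ("min", "max"):
            model.objective_direction = sense
            sol = model.optimize(raise_error=False)
            if sol.status != "optimal":
                raise RuntimeError(f"subsystem flux-sum LP not optimal ({sol.status})")
            out.append(float(sol.objective_value))
    return out[0], out[1]


def classify_coupling(
    model: cobra.Model,
    fraction: float = 0.9,
    tol: float = 1e-3,
    vmax: float = DEFAULT_FLUX_CAP,
) -> dict[str, str]:
    """Classify reactions by FVA-range width relative to the biomass range.

    At ``v_bio >= fraction * optimum``: a flux-carrying reaction is
    *hard*-coupled when its range width equals the biomass width (within
    ``tol``), *soft* when smaller, *partial* when strictly between the
    biomass width and the default bound magnitude ``vmax``, and *uncoupled*
    when equal to ``vmax``.  Reactions whose range is {0} are
    *non-carrying*.  The decision order guarantees a partition.
    """
    obj_id = objective_reaction_id(model)
    ranges = fva(model, fraction_of_optimum=fraction)
    widths = ranges["maximum"] - ranges["minimum"]
    bio_width = float(widths[obj_id])
    classes: dict[str, str] = {}
    for rxn_id in ranges.index:
        lo, hi = ranges.loc[rxn_id, "minimum"], ranges.loc[rxn_id, "maximum"]
        if abs(lo) <= BLOCKED_TOL and abs(hi) <= BLOCKED_TOL:
            classes[rxn_id] = "non-carrying"
            continue
        width = float(widths[rxn_id])
        if width >= vmax - tol:
            classes[rxn_id] = "uncoupled"
        elif abs(width - bio_width) <= tol:
            classes[rxn_id] = "hard"
        elif width < bio_width:
            classes[rxn_id] = "soft"
        else:
            classes[rxn_id] = "partial"
    return classes


def atp_production(
    model: cobra.Model,
    atp_sink_id: str,
    carbon_exchange_id: str,
    growth_fraction: float = 0.0,
) -> tuple[float, float]:
    """Maximal ATP sink flux and ATP yield per unit carbon uptake.

    Maximizes the flux through the ATP hydrolysis/sink reaction subject to
    ``v_bio >= growth_fraction * optimum``.  The yield denominator is the
    realized carbon uptake flux in mmol (not C-mol); it is NaN when no
    carbon is taken up.
    """
    if atp_sink_id not in model.reactions:
        raise ValueError(f"ATP sink reaction {atp_sink_id!r} not in model (check configuration)")
    if carbon_exchange_id not in model.reactions:
        raise ValueError(f"carbon exchange {carbon_exchange_id!r} not in model")
    obj_id = objective_reaction_id(model)
    optimum = fba(model).objective_value
    with model:
        model.reactions.get_by_id(obj_id).lower_bound = growth_fraction * optimum
        sol = fba(model, objective_reaction=atp_sink_id)
        if not sol.optimal:
            raise RuntimeError(f"ATP maximization not optimal ({sol.status})")
        atp_flux = sol.objective_value
        exch_flux = float(sol.fluxes[carbon_exchange_id])
    uptake = -exch_flux if exch_flux < 0 else 0.0
    yield_per_uptake = atp_flux / uptake if uptake > FEASIBILITY_TOL else float("nan")
    return atp_flux, yield_per_uptake


def _subsystem_ec_sets(
    model: cobra.Model, subsystem_map: Mapping[str, str] | None
) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for rxn in model.reactions:
        subsystem = subsystem_map.get(rxn.id, rxn.subsystem) if subsystem_map else rxn.subsystem
        if not subsystem:
            continue
        out.setdefault(subsystem, set()).update(reaction_ec_numbers(rxn))
    return out


def jaccard_ec_overlap(
    model_a: cobra.Model,
    model_b: cobra.Model,
    subsystem_map_a: Mapping[str, str] | None = None,
    subsystem_map_b: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Per-subsystem Jaccard index of EC-number sets between two models.

    Subsystems absent from both models (or with no EC annotation on either
    side) are omitted from the output.
    """
    sets_a = _subsystem_ec_sets(model_a, subsystem_map_a)
    sets_b = _subsystem_ec_sets(model_b, subsystem_map_b)
    out: dict[str, float] = {}
    for subsystem in sorted(set(sets_a) | set(sets_b)):
        ec_a = sets_a.get(subsystem, set())
        ec_b = sets_b.get(subsystem, set())
        union = ec_a | ec_b
        if not union:
            continue
        out[subsystem] = len(ec_a & ec_b) / len(union)
    return out
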