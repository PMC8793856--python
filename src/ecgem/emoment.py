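"""The eMOMENT MILP: enzyme-constrained growth prediction.

eMOMENT extends molecular-crowding flux balance analysis (MOMENT-style)
with an explicit enzyme-promiscuity constraint.  On a split-irreversible
model it maximizes growth subject to

* steady state ``S v = 0``;
* a capacity constraint ``0 <= v_i <= E_i^r * kcat_i`` for every
  enzyme-catalyzed (GPR-bearing) reaction, where ``E_i^r`` is the enzyme
  abundance available to reaction *i*;
* GPR recursion relating ``E_i^r`` to per-(gene, reaction) allocations:
  complexes (AND) take the minimum of their operand abundances
  (linearized as ``E^r <= each operand``), isozymes (OR) add up;
* promiscuity: the allocations of gene *k* across all reactions it
  catalyzes sum to its total abundance ``E_k^g``;
* molecular crowding: ``sum_k E_k^g * MW_k <= C`` with total protein
  content *C* in g gDW^-1 and molecular weights in g mmol^-1;
* binary expression indicators ``alpha * y_k <= E_k^g <= beta * y_k``
  with ``alpha = 1e-10`` and ``beta = 1`` mmol gDW^-1, so that an
  expressed gene carries at least a minimal abundance.

The MILP (and the derived abundance-variability and abundance-sampling
problems) is solved with HiGHS through :func:`scipy.optimize.milp`.

The module also covers the surrounding condition-specific machinery:
Michaelis-Menten uptake bounds for carbon-source concentrations, biomass
rescaling to a measured protein content, simulation of carbon-source x
concentration panels, the peroxisomal protein-pool split experiment, and
coefficient-of-variation plasticity summaries.
"""

from __future__ import annotations

import contextlib
import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import cobra
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .constraint_analysis import FEASIBILITY_TOL, fba, objective_reaction_id
from .kcat_assignment import assign_kcats
from .model_core import (
    GPRExpr,
    apply_medium,
    gpr_of,
    split_reversible,
    stoichiometric_matrix,
)

#: lower abundance bound for expressed genes, mmol gDW^-1
ALPHA = 1e-10
#: upper abundance bound for expressed genes, mmol gDW^-1
BETA = 1.0
#: relative MILP optimality gap
MIP_REL_GAP = 1e-9

__all__ = [
    "TransporterKinetics",
    "ConditionSpec",
    "EnzymeConstraintSet",
    "EMomentProblem",
    "EMomentSolution",
    "AbundanceSampleSet",
    "ConditionPanelResult",
    "PoolSplitResult",
    "uptake_bound",
    "rescale_biomass",
    "build_emoment",
    "solve_emoment",
    "abundance_variability",
    "sample_abundances",
    "audit_abundance_samples",
    "simulate_condition_panel",
    "protein_pool_split",
    "plasticity_cv",
]


# ---------------------------------------------------------------------------
# Condition machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransporterKinetics:
    """Michaelis-Menten parameters of a monosaccharide transporter."""

    vmax: float  # mmol gDW^-1 h^-1
    km: float  # mM
    substrate: str = ""

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.km <= 0:
            raise ValueError("Vmax and Km must be positive")


def uptake_bound(kinetics: TransporterKinetics, concentration_mM: float) -> float:
    """Transporter-limited uptake flux ``Vmax * [S] / (Km + [S])``."""
    if concentration_mM < 0:
        raise ValueError("substrate concentration must be nonnegative")
    if concentration_mM == 0:
        return 0.0
    return kinetics.vmax * concentration_mM / (kinetics.km + concentration_mM)


@dataclass(frozen=True)
class ConditionSpec:
    """One growth condition: a single carbon source at a concentration.

    ``protein_content`` is the measured total protein *C* (g gDW^-1) used
    both as the crowding budget and for biomass rescaling.  Palmitate stays
    in the medium (growth is impossible without the host-supplied lipid)
    but is capped at ``palmitate_cap`` to prevent compensation by
    beta-oxidation.
    """

    condition_id: str
    carbon_source: str
    concentration_mM: float
    protein_content: float
    kinetics: TransporterKinetics
    palmitate_key: str
    palmitate_cap: float

    def __post_init__(self) -> None:
        if not 0.0 < self.protein_content < 1.0:
            raise ValueError("protein content C must lie in (0, 1) g gDW^-1")
        if self.concentration_mM < 0:
            raise ValueError("concentration must be nonnegative")


@dataclass
class EnzymeConstraintSet:
    """kcat (h^-1, per split reaction), molecular weights (g mmol^-1), and C."""

    kcat: Mapping[str, float]
    mw: Mapping[str, float]
    C: float
    alpha: float = ALPHA
    beta: float = BETA

    def __post_init__(self) -> None:
        if self.C < 0:
            raise ValueError("total protein content C must be nonnegative")
        if not self.alpha < self.beta:
            raise ValueError("alpha must be smaller than beta")


def rescale_biomass(
    model: cobra.Model,
    C: float,
    component_weights: Mapping[str, float],
    protein_components: Iterable[str],
    biomass_reaction: str | None = None,
) -> cobra.Model:
    """Rescale biomass coefficients to a protein mass fraction of ``C``.

    The protein components' mass is set to ``C`` and the remaining weighted
    components are scaled by a common factor so the total precursor mass is
    1 g gDW^-1.  Components without an entry in ``component_weights``
    (e.g. the ATP maintenance term) are left untouched and count no mass.
    """
    if not 0.0 < C < 1.0:
        raise ValueError("C must lie strictly between 0 and 1 g gDW^-1")
    out = model.copy()
    bio_id = biomass_reaction or objective_reaction_id(out)
    bio = out.reactions.get_by_id(bio_id)
    protein_ids = set(protein_components)
    protein_mass = other_mass = 0.0
    weighted: list[tuple[cobra.Metabolite, float, float]] = []
    for met, coeff in bio.metabolites.items():
        if coeff >= 0 or met.id not in component_weights:
            continue
        mass = -coeff * component_weights[met.id]
        weighted.append((met, coeff, component_weights[met.id]))
        if met.id in protein_ids:
            protein_mass += mass
        else:
            other_mass += mass
    if protein_mass <= 0 or other_mass <= 0:
        raise ValueError("biomass needs weighted protein and non-protein components")
    protein_factor = C / protein_mass
    other_factor = (1.0 - C) / other_mass
    for met, coeff, _mw in weighted:
        factor = protein_factor if met.id in protein_ids else other_factor
        bio.add_metabolites({met: coeff * factor - coeff}, combine=True)
    total = sum(
        -c * component_weights[m.id]
        for m, c in bio.metabolites.items()
        if c < 0 and m.id in component_weights
    )
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"biomass mass sum {total} != 1 after rescaling")
    return out


# ---------------------------------------------------------------------------
# MILP assembly
# ---------------------------------------------------------------------------


@dataclass
class EMomentProblem:
    """Assembled eMOMENT MILP over a split-irreversible model.

    Holds the sparse constraint matrix with two-sided row bounds, variable
    bounds, integrality markers and the index maps needed to read solutions
    back out (flux, reaction-level enzyme, per-(gene, reaction) allocation,
    gene abundance and indicator variables).
    """

    model: cobra.Model
    enz: EnzymeConstraintSet
    biomass_id: str
    rxn_ids: list[str]
    genes: list[str]
    constrained: list[str]
    v_index: dict[str, int]
    er_index: dict[str, int]
    alloc_index: dict[tuple[str, str], int]
    eg_index: dict[str, int]
    y_index: dict[str, int]
    A: sp.csr_matrix
    row_lb: np.ndarray
    row_ub: np.ndarray
    var_lb: np.ndarray
    var_ub: np.ndarray
    integrality: np.ndarray

    @property
    def n_var(self) -> int:
        return self.A.shape[1]

    @property
    def biomass_var(self) -> int:
        return self.v_index[self.biomass_id]


@dataclass
class EMomentSolution:
    """Optimal growth, fluxes, gene abundances and expression indicators."""

    growth: float
    fluxes: pd.Series | None
    gene_abundances: pd.Series | None
    reaction_enzymes: pd.Series | None
    indicators: pd.Series | None
    status: str

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _merge(into: dict[int, float], other: Mapping[int, float]) -> None:
    for idx, coef in other.items():
        into[idx] = into.get(idx, 0.0) + coef


def build_emoment(
    model: cobra.Model,
    enz: EnzymeConstraintSet,
    objective_reaction: str | None = None,
    crowding_pools: Sequence[tuple[Iterable[str], float]] | None = None,
) -> EMomentProblem:
    """Encode the eMOMENT MILP for a split-irreversible model.

    ``crowding_pools`` optionally replaces the single crowding constraint by
    several (gene set, capacity) pools, as in the peroxisomal pool-split
    experiment; genes outside every pool are unconstrained in total mass.
    """
    reversible_constrained = [
        r.id for r in model.reactions
        if r.lower_bound < 0 and r.gene_reaction_rule and r.id in enz.kcat
    ]
    if reversible_constrained:
        raise ValueError(
            "enzyme-constrained reactions must be split-irreversible; "
            f"reversible: {reversible_constrained}"
        )
    bio_id = objective_reaction or objective_reaction_id(model)
    rxn_ids = [r.id for r in model.reactions]
    v_index = {rid: i for i, rid in enumerate(rxn_ids)}

    gprs: dict[str, GPRExpr] = {}
    for rxn in model.reactions:
        expr = gpr_of(rxn)
        if expr is not None and rxn.id in enz.kcat:
            gprs[rxn.id] = expr
    constrained = sorted(gprs)
    genes = sorted({g for expr in gprs.values() for g in _gpr_leaves(expr)})
    missing_mw = [g for g in genes if g not in enz.mw or not enz.mw[g] > 0]
    if missing_mw:
        raise ValueError(f"missing/invalid molecular weight for genes {missing_mw}")

    n_rxn = len(rxn_ids)
    n_var = n_rxn
    er_index = {}
    for rid in constrained:
        er_index[rid] = n_var
        n_var += 1
    alloc_index: dict[tuple[str, str], int] = {}
    for rid in constrained:
        for g in sorted(_gpr_leaves(gprs[rid])):
            alloc_index[(rid, g)] = n_var
            n_var += 1

    rows: list[tuple[dict[int, float], float, float]] = []
    n_aux = 0

    def new_aux() -> int:
        nonlocal n_var, n_aux
        idx = n_var
        n_var += 1
        n_aux += 1
        return idx

    def expr_terms(node: GPRExpr, rid: str) -> dict[int, float]:
        if node.op == "gene":
            return {alloc_index[(rid, node.gene)]: 1.0}
        if node.op == "or":
            merged: dict[int, float] = {}
            for child in node.children:
                _merge(merged, expr_terms(child, rid))
            return merged
        # AND: auxiliary variable bounded above by each operand expression
        aux = new_aux()
        for child in node.children:
            row = {aux: 1.0}
            for idx, coef in expr_terms(child, rid).items():
                row[idx] = row.get(idx, 0.0) - coef
            rows.append((row, -np.inf, 0.0))
        return {aux: 1.0}

    # GPR recursion: E^r_i <= value of the rule over allocations
    for rid in constrained:
        root = expr_terms(gprs[rid], rid)
        row = {er_index[rid]: 1.0}
        for idx, coef in root.items():
            row[idx] = row.get(idx, 0.0) - coef
        rows.append((row, -np.inf, 0.0))

    eg_index = {}
    y_index = {}
    for g in genes:
        eg_index[g] = n_var
        n_var += 1
    for g in genes:
        y_index[g] = n_var
        n_var += 1

    # steady state S v = 0
    S = stoichiometric_matrix(model).tocoo()
    s_rows: dict[int, dict[int, float]] = {}
    for i, j, val in zip(S.row, S.col, S.data):
        s_rows.setdefault(i, {})[j] = float(val)
    for i in range(S.shape[0]):
        rows.append((s_rows.get(i, {}), 0.0, 0.0))

    # capacity: v_i - kcat_i E^r_i <= 0
    for rid in constrained:
        rows.append(({v_index[rid]: 1.0, er_index[rid]: -float(enz.kcat[rid])}, -np.inf, 0.0))

    # promiscuity: allocations of gene k sum to E^g_k
    by_gene: dict[str, list[int]] = {g: [] for g in genes}
    for (rid, g), idx in alloc_index.items():
        by_gene[g].append(idx)
    for g in genes:
        row = {idx: 1.0 for idx in by_gene[g]}
        row[eg_index[g]] = row.get(eg_index[g], 0.0) - 1.0
        rows.append((row, 0.0, 0.0))

    # molecular crowding, one row per pool
    pools = crowding_pools
    if pools is None:
        pools = [(genes, enz.C)]
    for pool_genes, capacity in pools:
        members = [g for g in pool_genes if g in eg_index]
        row = {eg_index[g]: float(enz.mw[g]) for g in members}
        rows.append((row, -np.inf, float(capacity)))

    # expression indicators: alpha y <= E^g <= beta y
    for g in genes:
        rows.append(({y_index[g]: enz.alpha, eg_index[g]: -1.0}, -np.inf, 0.0))
        rows.append(({eg_index[g]: 1.0, y_index[g]: -enz.beta}, -np.inf, 0.0))

    data, ri, ci = [], [], []
    row_lb = np.empty(len(rows))
    row_ub = np.empty(len(rows))
    for r, (coefs, lo, hi) in enumerate(rows):
        row_lb[r] = lo
        row_ub[r] = hi
        for c, val in coefs.items():
            ri.append(r)
            ci.append(c)
            data.append(val)
    A = sp.csr_matrix((data, (ri, ci)), shape=(len(rows), n_var))

    var_lb = np.zeros(n_var)
    var_ub = np.full(n_var, np.inf)
    for rid, i in v_index.items():
        rxn = model.reactions.get_by_id(rid)
        var_lb[i] = rxn.lower_bound
        var_ub[i] = rxn.upper_bound
    integrality = np.zeros(n_var)
    for g in genes:
        var_ub[y_index[g]] = 1.0
        integrality[y_index[g]] = 1
    # gene abundances can never exceed beta (or the pool budget)
    for g in genes:
        var_ub[eg_index[g]] = enz.beta

    return EMomentProblem(
        model=model,
        enz=enz,
        biomass_id=bio_id,
        rxn_ids=rxn_ids,
        genes=genes,
        constrained=constrained,
        v_index=v_index,
        er_index=er_index,
        alloc_index=alloc_index,
        eg_index=eg_index,
        y_index=y_index,
        A=A,
        row_lb=row_lb,
        row_ub=row_ub,
        var_lb=var_lb,
        var_ub=var_ub,
        integrality=integrality,
    )


def _gpr_leaves(expr: GPRExpr) -> set[str]:
    if expr.op == "gene":
        return {expr.gene}
    out: set[str] = set()
    for child in expr.children:
        out |= _gpr_leaves(child)
    return out


_MILP_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded"}


try:
    import ctypes

    _LIBC = ctypes.CDLL(None)
except OSError:  # pragma: no cover
    _LIBC = None


@contextlib.contextmanager
def _silence_stdout():
    """Suppress HiGHS's C-level progress chatter during a solve."""
    try:
        fd = os.dup(1)
    except OSError:  # no usable stdout (unlikely); run unsilenced
        yield
        return
    devnull = os.open(os.devnull, os.O_WRONLY)
    try:
        os.dup2(devnull, 1)
        yield
    finally:
        if _LIBC is not None:  # flush buffered chatter into /dev/null
            _LIBC.fflush(None)
        os.dup2(fd, 1)
        os.close(fd)
        os.close(devnull)


def _solve_milp(
    problem: EMomentProblem,
    c: np.ndarray,
    maximize: bool,
    extra_rows: Sequence[tuple[Mapping[int, float], float, float]] = (),
) -> tuple[str, np.ndarray | None, float]:
    A, row_lb, row_ub = problem.A, problem.row_lb, problem.row_ub
    if extra_rows:
        data, ri, ci = [], [], []
        for r, (coefs, _lo, _hi) in enumerate(extra_rows):
            for col, val in coefs.items():
                ri.append(r)
                ci.append(col)
                data.append(val)
        extra = sp.csr_matrix((data, (ri, ci)), shape=(len(extra_rows), problem.n_var))
        A = sp.vstack([A, extra], format="csr")
        row_lb = np.concatenate([row_lb, [lo for _, lo, _ in extra_rows]])
        row_ub = np.concatenate([row_ub, [hi for _, _, hi in extra_rows]])
    with _silence_stdout(), warnings.catch_warnings():
        # the feasibility tolerances are HiGHS options scipy forwards
        # verbatim (with an "unrecognized options" warning); tight values
        # keep raw residuals far below the 1e-6 audit tolerance despite the
        # large kcat coefficients in the capacity rows
        warnings.filterwarnings("ignore", message="Unrecognized options")
        res = milp(
            c=-c if maximize else c,
            constraints=LinearConstraint(A, row_lb, row_ub),
            integrality=problem.integrality,
            bounds=Bounds(problem.var_lb, problem.var_ub),
            options={
                "mip_rel_gap": MIP_REL_GAP,
                "primal_feasibility_tolerance": 1e-9,
                "dual_feasibility_tolerance": 1e-9,
                "mip_feasibility_tolerance": 1e-9,
            },
        )
    status = _MILP_STATUS.get(res.status, f"solver status {res.status}")
    if res.x is None:
        return status, None, float("nan")
    value = float(c @ res.x)
    return status, res.x, value


def _extract(problem: EMomentProblem, x: np.ndarray) -> EMomentSolution:
    fluxes = pd.Series({rid: x[i] for rid, i in problem.v_index.items()}, dtype=float)
    eg = pd.Series({g: x[i] for g, i in problem.eg_index.items()}, dtype=float)
    er = pd.Series({rid: x[i] for rid, i in problem.er_index.items()}, dtype=float)
    y = pd.Series({g: int(round(x[i])) for g, i in problem.y_index.items()})
    return EMomentSolution(
        growth=float(x[problem.biomass_var]),
        fluxes=fluxes,
        gene_abundances=eg,
        reaction_enzymes=er,
        indicators=y,
        status="optimal",
    )


def _verify(problem: EMomentProblem, sol: EMomentSolution, tol: float = FEASIBILITY_TOL) -> None:
    enz = problem.enz
    v, er, eg, y = sol.fluxes, sol.reaction_enzymes, sol.gene_abundances, sol.indicators
    for rid in problem.constrained:
        if v[rid] > er[rid] * enz.kcat[rid] + tol:
            raise RuntimeError(f"capacity constraint violated on {rid}")
    for g in problem.genes:
        if not (enz.alpha * y[g] - tol <= eg[g] <= enz.beta * y[g] + tol):
            raise RuntimeError(f"indicator bounds violated for gene {g}")


def solve_emoment(
    problem: EMomentProblem,
    extra_rows: Sequence[tuple[Mapping[int, float], float, float]] = (),
) -> EMomentSolution:
    """Solve the eMOMENT MILP, maximizing growth; invariants are re-checked."""
    c = np.zeros(problem.n_var)
    c[problem.biomass_var] = 1.0
    status, x, _ = _solve_milp(problem, c, maximize=True, extra_rows=extra_rows)
    if x is None:
        return EMomentSolution(float("nan"), None, None, None, None, status)
    sol = _extract(problem, x)
    _verify(problem, sol)
    return sol


def growth_floor_row(
    problem: EMomentProblem, fraction: float, optimum: float
) -> tuple[dict[int, float], float, float]:
    """Constraint row enforcing ``v_bio >= fraction * optimum``."""
    return ({problem.biomass_var: 1.0}, fraction * optimum, np.inf)


# ---------------------------------------------------------------------------
# Abundance variability and sampling
# ---------------------------------------------------------------------------


def abundance_variability(
    problem: EMomentProblem, fraction: float = 0.99, optimum: float | None = None
) -> pd.DataFrame:
    """Feasible range of each gene abundance at near-optimal growth.

    Individually minimizes and maximizes ``E_k^g`` subject to the full
    eMOMENT constraints plus ``v_bio >= fraction * optimum``.
    """
    if optimum is None:
        sol = solve_emoment(problem)
        if not sol.optimal:
            raise RuntimeError(f"base problem not optimal ({sol.status})")
        optimum = sol.growth
    floor = [growth_floor_row(problem, fraction, optimum)]
    records = {}
    for g in problem.genes:
        c = np.zeros(problem.n_var)
        c[problem.eg_index[g]] = 1.0
        lo_status, _, lo = _solve_milp(problem, c, maximize=False, extra_rows=floor)
        hi_status, _, hi = _solve_milp(problem, c, maximize=True, extra_rows=floor)
        if lo_status != "optimal" or hi_status != "optimal":
            raise RuntimeError(f"abundance FVA failed for gene {g}")
        records[g] = (max(lo, 0.0), hi)
    return pd.DataFrame.from_dict(records, orient="index", columns=["minimum", "maximum"])


@dataclass
class AbundanceSampleSet:
    """Sampled feasible gene-abundance vectors (rows) at near-optimal growth.

    ``full_solutions`` retains the complete variable vector (fluxes,
    reaction enzymes, allocations, abundances, indicators) that supports
    each abundance row, so feasibility can be audited exactly.
    """

    samples: pd.DataFrame  # n x genes, mmol gDW^-1
    seed: int | None
    fraction_of_optimum: float
    failures: int = 0
    full_solutions: np.ndarray | None = None


def sample_abundances(
    problem: EMomentProblem,
    n: int = 1000,
    fraction: float = 0.99,
    seed: int | None = None,
    ranges: pd.DataFrame | None = None,
    norm: str = "l1",
) -> AbundanceSampleSet:
    """Sample feasible enzyme-abundance vectors.

    Each sample draws a reference vector ``E*`` uniformly within the
    per-gene feasible ranges and solves for the feasible abundance vector
    closest to it (L1 norm; each step stays a linear MILP) subject to the
    eMOMENT constraints and the growth floor.  Reproducible by seed;
    per-sample solver failures are skipped and counted.
    """
    if norm != "l1":
        raise NotImplementedError("only the L1 distance is supported")
    sol = solve_emoment(problem)
    if not sol.optimal:
        raise RuntimeError(f"base problem not optimal ({sol.status})")
    if ranges is None:
        ranges = abundance_variability(problem, fraction=fraction, optimum=sol.growth)
    genes = problem.genes
    lo = ranges["minimum"].reindex(genes).to_numpy()
    hi = ranges["maximum"].reindex(genes).to_numpy()
    floor = growth_floor_row(problem, fraction, sol.growth)

    # one distance variable per gene: d_k >= |E*_k - E^g_k|
    d_index = {g: problem.n_var + i for i, g in enumerate(genes)}
    c = np.zeros(problem.n_var + len(genes))
    extra_lb = np.zeros(len(genes))
    extra_ub = np.full(len(genes), np.inf)
    augmented = replace(
        problem,
        A=sp.hstack(
            [problem.A, sp.csr_matrix((problem.A.shape[0], len(genes)))], format="csr"
        ),
        var_lb=np.concatenate([problem.var_lb, extra_lb]),
        var_ub=np.concatenate([problem.var_ub, extra_ub]),
        integrality=np.concatenate([problem.integrality, np.zeros(len(genes))]),
    )
    for g in genes:
        c[d_index[g]] = 1.0

    rng = np.random.default_rng(seed)
    rows_out, full_out = [], []
    failures = 0
    for _ in range(n):
        target = rng.uniform(lo, hi)
        extra = [floor]
        for g, t in zip(genes, target):
            ei, di = problem.eg_index[g], d_index[g]
            extra.append(({ei: 1.0, di: -1.0}, -np.inf, float(t)))
            extra.append(({ei: 1.0, di: 1.0}, float(t), np.inf))
        status, x, _ = _solve_milp(augmented, c, maximize=False, extra_rows=extra)
        if status != "optimal" or x is None:
            failures += 1
            continue
        values = np.array([x[problem.eg_index[g]] for g in genes])
        # abundances are nonnegative; remove sub-tolerance solver slop
        if values.min() < -FEASIBILITY_TOL:
            failures += 1
            continue
        rows_out.append(np.maximum(values, 0.0))
        full_out.append(x[: problem.n_var])
    samples = pd.DataFrame(rows_out, columns=genes)
    return AbundanceSampleSet(
        samples=samples,
        seed=seed,
        fraction_of_optimum=fraction,
        failures=failures,
        full_solutions=np.array(full_out) if full_out else None,
    )


def audit_abundance_samples(
    problem: EMomentProblem,
    sample_set: AbundanceSampleSet,
    tol: float = FEASIBILITY_TOL,
) -> float:
    """Verify each sampled abundance vector against all constraints.

    Checks the complete supporting solution of every row (steady state,
    capacity, GPR recursion, promiscuity, crowding, indicator bounds) plus
    the growth floor, as raw constraint residuals.  Returns the worst
    violation found; raises if it exceeds ``tol``.
    """
    if sample_set.full_solutions is None or not len(sample_set.samples):
        raise ValueError("sample set carries no solutions to audit")
    enz = problem.enz
    base = solve_emoment(problem)
    floor = sample_set.fraction_of_optimum * base.growth
    X = sample_set.full_solutions
    AX = problem.A @ X.T  # rows x samples
    row_violation = np.maximum(
        problem.row_lb[:, None] - AX, AX - problem.row_ub[:, None]
    ).max()
    bound_violation = np.maximum(
        problem.var_lb[None, :] - X, X - problem.var_ub[None, :]
    ).max()
    floor_violation = float((floor - X[:, problem.biomass_var]).max())
    # the reported abundance rows must be the recorded solutions' abundances
    eg_cols = [problem.eg_index[g] for g in problem.genes]
    drift = np.abs(
        np.maximum(X[:, eg_cols], 0.0) - sample_set.samples[problem.genes].to_numpy()
    ).max()
    crowding = (sample_set.samples[problem.genes] * pd.Series(enz.mw)[problem.genes]).sum(axis=1)
    crowding_violation = float((crowding - enz.C).max())
    worst = max(row_violation, bound_violation, floor_violation, drift, crowding_violation)
    if worst > tol:
        raise RuntimeError(f"abundance samples violate constraints by {worst:.2e}")
    return float(max(worst, 0.0))


# ---------------------------------------------------------------------------
# Condition panels, pool split, plasticity
# ---------------------------------------------------------------------------


@dataclass
class ConditionPanelResult:
    """Growth predictions (eMOMENT and plain FBA) for each condition."""

    table: pd.DataFrame
    problems: dict[str, EMomentProblem] = field(default_factory=dict)
    solutions: dict[str, EMomentSolution] = field(default_factory=dict)


def simulate_condition_panel(
    model: cobra.Model,
    kcat_table: pd.DataFrame,
    mw: Mapping[str, float],
    conditions: Sequence[ConditionSpec],
    *,
    base_medium: Mapping[str, float],
    biomass_weights: Mapping[str, float],
    protein_components: Iterable[str],
) -> ConditionPanelResult:
    """Predict growth for a panel of carbon-source x concentration conditions.

    Per condition: the carbon source's uptake bound follows Michaelis-Menten
    kinetics at the given concentration, palmitate is capped, the biomass is
    rescaled to the measured protein content *C*, the crowding budget is set
    to *C*, and the eMOMENT MILP is solved.  Plain FBA growth under the same
    bounds is reported for contrast.
    """
    protein_components = set(protein_components)
    rows = []
    result = ConditionPanelResult(table=pd.DataFrame())
    for cond in conditions:
        medium = dict(base_medium)
        medium[cond.carbon_source] = uptake_bound(cond.kinetics, cond.concentration_mM)
        medium[cond.palmitate_key] = cond.palmitate_cap
        conditioned = apply_medium(model, medium)
        conditioned = rescale_biomass(
            conditioned, cond.protein_content, biomass_weights, protein_components
        )
        split = split_reversible(conditioned)
        assignment = assign_kcats(split.model, kcat_table)
        enz = EnzymeConstraintSet(kcat=assignment.values, mw=mw, C=cond.protein_content)
        problem = build_emoment(split.model, enz)
        sol = solve_emoment(problem)
        fba_sol = fba(split.model)
        rows.append(
            {
                "condition_id": cond.condition_id,
                "carbon_source": cond.carbon_source,
                "concentration_mM": cond.concentration_mM,
                "protein_content": cond.protein_content,
                "growth": sol.growth,
                "growth_fba": fba_sol.objective_value,
            }
        )
        result.problems[cond.condition_id] = problem
        result.solutions[cond.condition_id] = sol
    result.table = pd.DataFrame(rows).set_index("condition_id")
    return result


@dataclass
class PoolSplitResult:
    """Growth with/without myristate when protein is split into two pools.

    ``Z`` is the ratio of growth with myristate uptake allowed to the
    reference growth without it, per peroxisomal pool ratio ``alpha_pool``.
    """

    table: pd.DataFrame


def protein_pool_split(
    model: cobra.Model,
    kcat_table: pd.DataFrame,
    mw: Mapping[str, float],
    C: float,
    peroxisomal_genes: Iterable[str],
    alpha_grid: Sequence[float],
    myristate_key: str,
    myristate_uptake: float,
    base_medium: Mapping[str, float] | None = None,
) -> PoolSplitResult:
    """Peroxisomal pool-split experiment.

    For each ratio ``alpha_pool``, the crowding budget is split into a
    peroxisomal pool (``alpha_pool * C``) and a pool for the remaining
    enzymes (``(1 - alpha_pool) * C``).  Growth is predicted with myristate
    uptake closed (reference) and open, and their ratio ``Z`` reported.
    """
    peroxisomal = set(peroxisomal_genes)
    if not peroxisomal:
        raise ValueError("peroxisomal gene set must not be empty")
    if base_medium is not None:
        closed = apply_medium(model, base_medium)
        open_medium = dict(base_medium)
        open_medium[myristate_key] = myristate_uptake
        opened = apply_medium(model, open_medium)
    else:
        closed = model.copy()
        rxn = closed.reactions.get_by_id(myristate_key)
        rxn.lower_bound = 0.0
        opened = model.copy()
        opened.reactions.get_by_id(myristate_key).lower_bound = -myristate_uptake
    rows = []
    variants = {}
    for name, variant in (("without", closed), ("with", opened)):
        split = split_reversible(variant)
        assignment = assign_kcats(split.model, kcat_table)
        variants[name] = (split.model, assignment)
    all_genes = {
        g
        for m, a in variants.values()
        for rid in a.values
        for g in _gpr_leaves(gpr_of(m.reactions.get_by_id(rid)))
    }
    if not all_genes & peroxisomal:
        raise ValueError("no peroxisomal gene appears in any constrained reaction")
    for alpha_pool in alpha_grid:
        if not 0.0 <= alpha_pool <= 1.0:
            raise ValueError("pool ratios must lie in [0, 1]")
        growths = {}
        for name, (split_model, assignment) in variants.items():
            enz = EnzymeConstraintSet(kcat=assignment.values, mw=mw, C=C)
            pools = [
                (peroxisomal, alpha_pool * C),
                (all_genes - peroxisomal, (1.0 - alpha_pool) * C),
            ]
            problem = build_emoment(split_model, enz, crowding_pools=pools)
            growths[name] = solve_emoment(problem).growth
        z = growths["with"] / growths["without"] if growths["without"] > 0 else float("nan")
        rows.append(
            {
                "alpha_pool": alpha_pool,
                "growth_without_myristate": growths["without"],
                "growth_with_myristate": growths["with"],
                "Z": z,
            }
        )
    return PoolSplitResult(table=pd.DataFrame(rows).set_index("alpha_pool"))


def plasticity_cv(
    samples_by_condition: Mapping[str, pd.DataFrame], ddof: int = 1
) -> pd.Series:
    """Coefficient of variation of per-condition means across conditions.

    For each entity (gene or reaction), the per-condition sample means are
    reduced to ``std / mean`` (sample standard deviation, ``ddof=1``).
    Entities with zero mean are reported as NaN.
    """
    if len(samples_by_condition) < 2:
        raise ValueError("plasticity needs at least two conditions")
    means = pd.DataFrame(
        {cond: df.mean(axis=0) for cond, df in samples_by_condition.items()}
    ).T
    mean = means.mean(axis=0)
    std = means.std(axis=0, ddof=ddof)
    cv = std / mean.where(mean != 0)
    return cv
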