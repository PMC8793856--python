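"""Transcript-bounded simulation and comparison of fungal structures.

The three structures of an arbuscular mycorrhizal fungus (extraradical
mycelium ERM, intraradical mycelium IRM, arbuscles ARB) are compared by
converting relative transcript abundances into protein equivalents,
bounding each enzymatic reaction by ``kcat * tc^r`` (GPR rules applied
with AND -> min, OR -> max), predicting growth by FBA, sampling flux
distributions within the 99%-of-optimum flux-variability box, and calling
differentially activated reactions with the nonparametric common-language
effect size A_w.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import cobra
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog
from scipy.stats import rankdata

from .constraint_analysis import FEASIBILITY_TOL, FluxSolution, fba, fva, objective_reaction_id
from .model_core import evaluate_gpr, gpr_of, stoichiometric_matrix

#: default total protein content for structure simulations, g gDW^-1
#: (maximum content measured across growth conditions)
DEFAULT_STRUCTURE_C = 0.106
#: growth floor used for the sampling box
SAMPLING_FRACTION = 0.99
#: A_w thresholds for calling differentially activated reactions
DEFAULT_THRESHOLDS = (0.6, 0.7, 0.8)

__all__ = [
    "TranscriptProfile",
    "FluxSampleSet",
    "DifferentialResult",
    "StructureComparison",
    "transcript_to_protein",
    "transcript_reaction_bounds",
    "apply_structure_bounds",
    "structure_growth",
    "growth_with_protein_band",
    "flux_variability_99",
    "sample_fluxes",
    "effect_size_aw",
    "effect_size_table",
    "differential_reactions",
    "run_structure_comparison",
    "audit_flux_samples",
]


# ---------------------------------------------------------------------------
# Transcript -> protein equivalents -> reaction bounds
# ---------------------------------------------------------------------------


@dataclass
class TranscriptProfile:
    """Transcript counts and derived protein equivalents for one structure.

    ``normalized`` sums to 1; ``protein_equivalents`` satisfies
    ``sum_k tc_k^p * MW_k = C`` by construction.
    """

    structure: str
    counts: pd.Series
    normalized: pd.Series
    protein_equivalents: pd.Series  # mmol gDW^-1
    protein_content: float  # g gDW^-1


def transcript_to_protein(
    counts: Mapping[str, float] | pd.Series,
    C: float,
    mw: Mapping[str, float],
    structure: str = "",
) -> TranscriptProfile:
    """Convert raw counts to protein equivalents.

    ``tc^g' = tc^g / sum(tc^g)`` and ``tc^p = tc^g' * C / MW`` per gene.
    """
    counts = pd.Series(counts, dtype=float)
    total = counts.sum()
    if not total > 0:
        raise ValueError("total transcript count must be positive")
    if (counts < 0).any():
        raise ValueError("transcript counts must be nonnegative")
    missing = [g for g in counts.index if g not in mw]
    if missing:
        raise ValueError(f"missing molecular weights for genes {missing}")
    normalized = counts / total
    weights = pd.Series({g: float(mw[g]) for g in counts.index})
    protein = normalized * C / weights
    return TranscriptProfile(
        structure=structure,
        counts=counts,
        normalized=normalized,
        protein_equivalents=protein,
        protein_content=C,
    )


def transcript_reaction_bounds(
    model: cobra.Model, profile: TranscriptProfile, kcats: Mapping[str, float]
) -> pd.Series:
    """Per-reaction flux upper bounds ``kcat_i * tc_i^r``.

    ``tc^r`` applies the GPR rules to protein equivalents in transcript
    mode (minimum over complex members, maximum over isozymes).  Reactions
    without a GPR or without a kcat are left unbounded (absent).
    """
    values = profile.protein_equivalents.to_dict()
    bounds: dict[str, float] = {}
    for rxn in model.reactions:
        expr = gpr_of(rxn)
        if expr is None or rxn.id not in kcats:
            continue
        tc_r = evaluate_gpr(expr, values, mode="transcript")
        bounds[rxn.id] = float(kcats[rxn.id]) * tc_r
    return pd.Series(bounds, dtype=float)


def apply_structure_bounds(model: cobra.Model, bounds: Mapping[str, float]) -> cobra.Model:
    """Copy of the model with upper bounds tightened to the transcript limits."""
    out = model.copy()
    for rxn_id, ub in bounds.items():
        rxn = out.reactions.get_by_id(rxn_id)
        rxn.upper_bound = min(rxn.upper_bound, float(ub))
    return out


def structure_growth(model: cobra.Model, bounds: Mapping[str, float]) -> FluxSolution:
    """FBA optimum under the structure's transcript-derived reaction limits."""
    return fba(apply_structure_bounds(model, bounds))


def growth_with_protein_band(
    model: cobra.Model,
    counts: Mapping[str, float] | pd.Series,
    mw: Mapping[str, float],
    kcats: Mapping[str, float],
    C: float = DEFAULT_STRUCTURE_C,
    sigma: float = 0.0,
    structure: str = "",
) -> dict[str, float]:
    """Growth at protein contents C, C - sigma and C + sigma (error bars)."""
    out = {}
    for label, content in (("growth", C), ("growth_lo", C - sigma), ("growth_hi", C + sigma)):
        profile = transcript_to_protein(counts, content, mw, structure=structure)
        bounds = transcript_reaction_bounds(model, profile, kcats)
        out[label] = structure_growth(model, bounds).objective_value
    return out


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def flux_variability_99(
    model: cobra.Model,
    bounds: Mapping[str, float],
    fraction: float = SAMPLING_FRACTION,
) -> pd.DataFrame:
    """Per-reaction flux ranges at 99% of the structure's optimum.

    These ranges define the box from which reference vectors are drawn
    during flux sampling.
    """
    return fva(apply_structure_bounds(model, bounds), fraction_of_optimum=fraction)


@dataclass
class FluxSampleSet:
    """Sampled steady-state flux distributions for one structure."""

    samples: pd.DataFrame  # n x reactions
    structure: str
    seed: int | None
    fraction_of_optimum: float
    failures: int = 0


def sample_fluxes(
    model: cobra.Model,
    bounds: Mapping[str, float],
    n: int = 5000,
    seed: int | None = None,
    fraction: float = SAMPLING_FRACTION,
    ranges: pd.DataFrame | None = None,
    structure: str = "",
    norm: str = "l1",
) -> FluxSampleSet:
    """Sample flux distributions near the structure's optimum.

    Each sample draws a reference vector ``v*`` uniformly within the
    99%-optimum flux-variability box and solves the LP for the feasible
    flux vector of minimal L1 distance to it, subject to steady state, the
    transcript-derived bounds and the growth floor.  Seed-reproducible;
    per-sample solver failures are skipped and counted.
    """
    if norm != "l1":
        raise NotImplementedError("only the L1 distance is supported")
    bounded = apply_structure_bounds(model, bounds)
    opt = fba(bounded)
    if not opt.optimal:
        raise RuntimeError(f"structure model has no optimum ({opt.status})")
    if ranges is None:
        ranges = fva(bounded, fraction_of_optimum=fraction)
    rxn_ids = [r.id for r in bounded.reactions]
    bio_idx = rxn_ids.index(objective_reaction_id(bounded))
    n_rxn = len(rxn_ids)
    S = stoichiometric_matrix(bounded)
    lb = np.array([r.lower_bound for r in bounded.reactions])
    ub = np.array([r.upper_bound for r in bounded.reactions])
    lo = np.clip(ranges["minimum"].reindex(rxn_ids).to_numpy(), lb, ub)
    hi = np.clip(ranges["maximum"].reindex(rxn_ids).to_numpy(), lb, ub)

    # variables [v, d]; min sum(d) with d >= |v - v*|
    eye = sp.identity(n_rxn, format="csr")
    A_eq = sp.hstack([S, sp.csr_matrix(S.shape)], format="csr")
    b_eq = np.zeros(S.shape[0])
    growth_row = sp.csr_matrix(
        (np.array([-1.0]), (np.array([0]), np.array([bio_idx]))), shape=(1, 2 * n_rxn)
    )
    A_ub = sp.vstack(
        [
            sp.hstack([eye, -eye]),  # v - d <= v*
            sp.hstack([-eye, -eye]),  # -v - d <= -v*
            growth_row,  # -v_bio <= -fraction * opt
        ],
        format="csr",
    )
    c = np.concatenate([np.zeros(n_rxn), np.ones(n_rxn)])
    var_bounds = [(float(l), float(u)) for l, u in zip(lb, ub)] + [(0, None)] * n_rxn
    floor = fraction * opt.objective_value

    rng = np.random.default_rng(seed)
    rows, failures = [], 0
    for _ in range(n):
        target = rng.uniform(lo, hi)
        b_ub = np.concatenate([target, -target, [-floor]])
        res = linprog(
            c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=var_bounds, method="highs"
        )
        if res.status != 0 or res.x is None:
            failures += 1
            continue
        rows.append(res.x[:n_rxn])
    samples = pd.DataFrame(rows, columns=rxn_ids)
    return FluxSampleSet(
        samples=samples,
        structure=structure,
        seed=seed,
        fraction_of_optimum=fraction,
        failures=failures,
    )


def audit_flux_samples(
    model: cobra.Model,
    sample_set: FluxSampleSet,
    bounds: Mapping[str, float],
    tol: float = FEASIBILITY_TOL,
) -> float:
    """Maximum constraint violation over all sampled rows (should be <= tol).

    Checks steady state, the bound constraints (including the transcript
    limits) and the growth floor; raises if any row violates them.
    """
    bounded = apply_structure_bounds(model, bounds)
    rxn_ids = [r.id for r in bounded.reactions]
    S = stoichiometric_matrix(bounded)
    lb = np.array([r.lower_bound for r in bounded.reactions])
    ub = np.array([r.upper_bound for r in bounded.reactions])
    floor = sample_set.fraction_of_optimum * fba(bounded).objective_value
    bio = objective_reaction_id(bounded)
    V = sample_set.samples[rxn_ids].to_numpy()
    worst = 0.0
    if len(V):
        residual = np.abs(S @ V.T).max()
        bound_violation = max(np.max(lb - V), np.max(V - ub), 0.0)
        floor_violation = max(float(np.max(floor - sample_set.samples[bio].to_numpy())), 0.0)
        worst = max(residual, bound_violation, floor_violation)
    if worst > tol:
        raise RuntimeError(f"sampled fluxes violate constraints by {worst:.2e}")
    return float(worst)


# ---------------------------------------------------------------------------
# Effect sizes and differential reactions
# ---------------------------------------------------------------------------


def effect_size_aw(p: Sequence[float], q: Sequence[float]) -> float:
    """Nonparametric common-language effect size A_w.

    The probability that a draw from ``p`` exceeds a draw from ``q``, with
    ties counted half: ``(#(p > q) + 0.5 * #(p = q)) / (n1 * n2)``.
    Computed through the rank-sum identity (equivalent to exhaustive pair
    counting, ties handled by midranks).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.size == 0 or q.size == 0:
        raise ValueError("effect size needs nonempty sample vectors")
    n1, n2 = p.size, q.size
    ranks = rankdata(np.concatenate([p, q]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    return float(u1 / (n1 * n2))


def effect_size_table(samples_a: pd.DataFrame, samples_b: pd.DataFrame) -> pd.Series:
    """Per-reaction A_w between two flux sample sets (matched columns)."""
    if list(samples_a.columns) != list(samples_b.columns):
        raise ValueError("sample sets have mismatched reaction columns")
    return pd.Series(
        {col: effect_size_aw(samples_a[col], samples_b[col]) for col in samples_a.columns},
        dtype=float,
    )


@dataclass
class DifferentialResult:
    """Differentially activated reactions between a pair of structures."""

    aw: pd.Series
    calls: dict[float, list[str]]
    subsystem_tally: dict[float, Counter] = field(default_factory=dict)


def differential_reactions(
    samples_a: pd.DataFrame,
    samples_b: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    subsystems: Mapping[str, str] | None = None,
) -> DifferentialResult:
    """Call differential reactions at each A_w threshold.

    A reaction is differential when ``max(A_w, 1 - A_w) >= threshold``
    (direction-agnostic).  When a reaction -> subsystem map is supplied the
    calls are also tallied by subsystem.
    """
    aw = effect_size_table(samples_a, samples_b)
    extremity = np.maximum(aw, 1.0 - aw)
    result = DifferentialResult(aw=aw, calls={})
    for t in thresholds:
        called = sorted(aw.index[extremity >= t])
        result.calls[t] = called
        if subsystems is not None:
            result.subsystem_tally[t] = Counter(
                subsystems.get(r, "unassigned") for r in called
            )
    return result


# ---------------------------------------------------------------------------
# End-to-end comparison
# ---------------------------------------------------------------------------


@dataclass
class StructureComparison:
    """Growth, samples and pairwise differential calls for all structures."""

    growth: pd.Series
    bounds: dict[str, pd.Series]
    samples: dict[str, FluxSampleSet]
    pairwise: dict[tuple[str, str], DifferentialResult]


def run_structure_comparison(
    model: cobra.Model,
    counts_by_structure: Mapping[str, Mapping[str, float]],
    kcats: Mapping[str, float],
    mw: Mapping[str, float],
    C: float = DEFAULT_STRUCTURE_C,
    n: int = 5000,
    seed: int = 0,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    subsystems: Mapping[str, str] | None = None,
) -> StructureComparison:
    """Transcript-bounded growth + sampling + A_w comparison for each pair.

    Per-structure sampling seeds are derived deterministically from
    ``seed`` so the whole comparison is reproducible from one integer.
    """
    structures = list(counts_by_structure)
    growth, bounds_by, sets = {}, {}, {}
    for i, structure in enumerate(structures):
        profile = transcript_to_protein(
            counts_by_structure[structure], C, mw, structure=structure
        )
        bounds = transcript_reaction_bounds(model, profile, kcats)
        bounds_by[structure] = bounds
        growth[structure] = structure_growth(model, bounds).objective_value
        sets[structure] = sample_fluxes(
            model, bounds, n=n, seed=(seed + i) % (2**31), structure=structure
        )
    pairwise = {}
    for i, a in enumerate(structures):
        for b in structures[i + 1 :]:
            pairwise[(a, b)] = differential_reactions(
                sets[a].samples, sets[b].samples, thresholds=thresholds, subsystems=subsystems
            )
    return StructureComparison(
        growth=pd.Series(growth), bounds=bounds_by, samples=sets, pairwise=pairwise
    )
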