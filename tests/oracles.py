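"""Independent oracles used by the test suite and the acceptance script.

These deliberately avoid the package's own solver path: the enzyme-
allocation oracle enumerates all binary expression-indicator assignments
and solves each as a plain LP through optlang/GLPK (a different modeling
layer and solver than the package's scipy/HiGHS MILP), parsing the simple
GPR strings of the micro-models by hand; the effect-size oracle counts all
sample pairs exhaustively.
"""

from __future__ import annotations

import itertools

import numpy as np


def aw_bruteforce(p, q) -> float:
    """O(n1*n2) pair counting for the common-language effect size."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    diff = np.subtract.outer(p, q)
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def _simple_gpr_genes(rule: str) -> tuple[str, list[str]]:
    """Parse the micro-models' flat GPRs: 'g', 'g1 and g2' or 'g1 or g2'."""
    if " and " in rule:
        return "and", rule.split(" and ")
    if " or " in rule:
        return "or", rule.split(" or ")
    return "single", [rule]


def emoment_enumeration_oracle(model, enz) -> float:
    """Max growth over all 2^g indicator assignments, each solved as an LP.

    Encodes, independently of the package: steady state, capacity
    v <= kcat * E^r, the GPR semantics (complex -> min via per-operand
    upper bounds, isozymes -> sum), per-gene allocation balance, the
    crowding budget, and gene abundances fixed to [alpha*y, beta*y] for a
    fully enumerated binary vector y.
    """
    from optlang.glpk_interface import Constraint, Model as LPModel, Objective, Variable

    constrained = [r for r in model.reactions if r.gene_reaction_rule and r.id in enz.kcat]
    genes = sorted({g for r in constrained for g in _simple_gpr_genes(r.gene_reaction_rule)[1]})
    objective_rxn = next(
        r for r in model.reactions if r.objective_coefficient
    )

    best = -np.inf
    for assignment in itertools.product((0, 1), repeat=len(genes)):
        y = dict(zip(genes, assignment))
        lp = LPModel()
        v = {
            r.id: Variable(f"v_{r.id}", lb=r.lower_bound, ub=r.upper_bound)
            for r in model.reactions
        }
        eg = {
            g: Variable(f"eg_{g}", lb=enz.alpha * y[g], ub=enz.beta * y[g]) for g in genes
        }
        er = {r.id: Variable(f"er_{r.id}", lb=0) for r in constrained}
        alloc = {}
        constraints = []
        for met in model.metabolites:
            expr = sum(r.metabolites[met] * v[r.id] for r in met.reactions)
            constraints.append(Constraint(expr, lb=0, ub=0))
        for r in constrained:
            constraints.append(Constraint(v[r.id] - enz.kcat[r.id] * er[r.id], ub=0))
            kind, members = _simple_gpr_genes(r.gene_reaction_rule)
            local = {}
            for g in members:
                local[g] = Variable(f"a_{r.id}_{g}", lb=0)
                alloc.setdefault(g, []).append(local[g])
            if kind == "or":
                constraints.append(Constraint(er[r.id] - sum(local.values()), ub=0))
            else:  # single gene or complex: E^r below each member's allocation
                for g in members:
                    constraints.append(Constraint(er[r.id] - local[g], ub=0))
        for g in genes:
            constraints.append(Constraint(sum(alloc.get(g, [0])) - eg[g], lb=0, ub=0))
        constraints.append(Constraint(sum(enz.mw[g] * eg[g] for g in genes), ub=enz.C))
        lp.add(constraints)
        lp.objective = Objective(v[objective_rxn.id], direction="max")
        status = lp.optimize()
        if status == "optimal":
            best = max(best, lp.objective.value)
    return float(best)
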