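"""Core data model for constraint-based metabolic models.

This module wraps :class:`cobra.Model` as the in-memory container for
genome-scale metabolic models (GEMs) and adds the primitives every
downstream analysis relies on:

* SBML Level-3/fbc ingestion and emission, including EC-number annotations
  and subsystem labels (from the SBML groups package or a sidecar TSV);
* a small boolean algebra for gene-protein-reaction (GPR) rules with the
  two evaluation semantics used by enzyme- and transcript-constrained
  simulations (AND -> min; OR -> sum for enzyme abundances, max for
  transcript-derived protein equivalents);
* splitting of reversible reactions into irreversible forward/reverse
  copies, and recombination of split fluxes into net fluxes;
* application of a growth-medium definition to exchange-reaction bounds.

Sign convention: externally, uptake is a *negative* flux on an exchange
reaction (SBML convention); after :func:`split_reversible`, uptake is the
positive flux of the ``*_rev`` copy.  All bounds are in mmol gDW^-1 h^-1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import cobra
import pandas as pd
from cobra.util.array import create_stoichiometric_matrix

logger = logging.getLogger("ecgem")

#: id prefixes that mark sink/demand reactions (boundary, but not exchanges)
SINK_PREFIXES: tuple[str, ...] = ("SK_", "sink_", "DM_")

__all__ = [
    "GPRExpr",
    "GPRParseError",
    "MediumDefinition",
    "SplitModel",
    "parse_gpr",
    "gpr_of",
    "gpr_genes",
    "evaluate_gpr",
    "read_sbml",
    "write_sbml",
    "split_reversible",
    "merge_irreversible_fluxes",
    "apply_medium",
    "read_medium_tsv",
    "exchange_reactions",
    "sink_reactions",
    "is_sink",
    "reaction_ec_numbers",
    "stoichiometric_matrix",
    "validate_model",
    "summarize_model",
]


# ---------------------------------------------------------------------------
# GPR algebra
# ---------------------------------------------------------------------------


class GPRParseError(ValueError):
    """Raised for malformed GPR strings; carries the offending position."""


@dataclass(frozen=True)
class GPRExpr:
    """Boolean expression tree over gene identifiers.

    ``op`` is one of ``"gene"`` (leaf), ``"and"`` or ``"or"``.  AND nodes
    encode enzyme complexes, OR nodes encode isozymes.
    """

    op: str
    gene: str | None = None
    children: tuple["GPRExpr", ...] = ()

    def __post_init__(self) -> None:
        if self.op == "gene":
            if not self.gene:
                raise GPRParseError("gene leaf without identifier")
        elif self.op in ("and", "or"):
            if len(self.children) < 2:
                raise GPRParseError(f"{self.op!r} node needs >= 2 operands")
        else:  # pragma: no cover - guarded construction
            raise GPRParseError(f"unknown GPR node type {self.op!r}")


def _tokenize_gpr(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c == "(":
            tokens.append(("lpar", c, i))
            i += 1
        elif c == ")":
            tokens.append(("rpar", c, i))
            i += 1
        elif c in "&|":
            tokens.append(("and" if c == "&" else "or", c, i))
            i += 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in "()&|":
                j += 1
            word = text[i:j]
            low = word.lower()
            if low == "and":
                tokens.append(("and", word, i))
            elif low == "or":
                tokens.append(("or", word, i))
            else:
                tokens.append(("id", word, i))
            i = j
    return tokens


def parse_gpr(text: str) -> GPRExpr:
    """Parse a GPR string into a :class:`GPRExpr`.

    AND binds tighter than OR (the common SBML-fbc convention);
    parentheses override.  Raises :class:`GPRParseError` with the character
    position of the offending token.
    """
    tokens = _tokenize_gpr(text)
    if not tokens:
        raise GPRParseError("empty GPR string")
    pos = 0

    def peek() -> tuple[str, str, int] | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> tuple[str, str, int]:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GPRExpr:
        operands = [parse_and()]
        while peek() is not None and peek()[0] == "or":
            take()
            operands.append(parse_and())
        if len(operands) == 1:
            return operands[0]
        return GPRExpr("or", children=tuple(operands))

    def parse_and() -> GPRExpr:
        operands = [parse_atom()]
        while peek() is not None and peek()[0] == "and":
            take()
            operands.append(parse_atom())
        if len(operands) == 1:
            return operands[0]
        return GPRExpr("and", children=tuple(operands))

    def parse_atom() -> GPRExpr:
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of GPR at position {len(text)}")
        kind, word, at = take()
        if kind == "id":
            return GPRExpr("gene", gene=word)
        if kind == "lpar":
            inner = parse_or()
            closing = peek()
            if closing is None or closing[0] != "rpar":
                raise GPRParseError(f"unbalanced parenthesis opened at position {at}")
            take()
            return inner
        raise GPRParseError(f"unexpected token {word!r} at position {at}")

    expr = parse_or()
    if pos != len(tokens):
        kind, word, at = tokens[pos]
        raise GPRParseError(f"trailing token {word!r} at position {at}")
    return expr


def gpr_of(reaction: cobra.Reaction) -> GPRExpr | None:
    """Parsed GPR of a cobra reaction, or ``None`` if it has no rule."""
    rule = (reaction.gene_reaction_rule or "").strip()
    if not rule:
        return None
    return parse_gpr(rule)


def gpr_genes(expr: GPRExpr) -> set[str]:
    if expr.op == "gene":
        return {expr.gene}
    out: set[str] = set()
    for child in expr.children:
        out |= gpr_genes(child)
    return out


def evaluate_gpr(
    expr: GPRExpr, per_gene_value: Mapping[str, float], mode: str = "enzyme"
) -> float:
    """Evaluate a GPR tree over nonnegative per-gene values.

    ``mode="enzyme"``: complexes (AND) take the minimum of their operands,
    isozymes (OR) add up.  ``mode="transcript"``: AND -> min, OR -> max,
    the rule used when transcript-derived protein equivalents bound fluxes.
    """
    if mode not in ("enzyme", "transcript"):
        raise ValueError(f"unknown GPR evaluation mode {mode!r}")
    if expr.op == "gene":
        try:
            return float(per_gene_value[expr.gene])
        except KeyError:
            raise KeyError(f"no value for gene {expr.gene!r}") from None
    vals = [evaluate_gpr(c, per_gene_value, mode) for c in expr.children]
    if expr.op == "and":
        return min(vals)
    return sum(vals) if mode == "enzyme" else max(vals)


# ---------------------------------------------------------------------------
# SBML ingestion / emission
# ---------------------------------------------------------------------------


def reaction_ec_numbers(reaction: cobra.Reaction) -> list[str]:
    """EC numbers annotated on a reaction (``ec-code`` key), as a list."""
    ec = reaction.annotation.get("ec-code", [])
    if isinstance(ec, str):
        ec = [ec]
    return [str(e) for e in ec]


def _subsystems_from_groups(model: cobra.Model) -> None:
    for group in model.groups:
        for member in group.members:
            if isinstance(member, cobra.Reaction):
                member.subsystem = group.name or group.id


def read_sbml(
    path: str | Path,
    subsystem_tsv: str | Path | None = None,
    biomass_reaction: str | None = None,
) -> cobra.Model:
    """Read an SBML L3 (fbc) model.

    Subsystem labels are taken from the SBML groups package when present,
    otherwise from a sidecar TSV with columns ``reaction_id`` and
    ``subsystem``.  EC annotations are picked up from the standard
    ``ec-code`` annotation; unannotated reactions simply carry no GPR and
    an empty EC list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    model = cobra.io.read_sbml_model(str(path))
    if model.groups:
        _subsystems_from_groups(model)
    if subsystem_tsv is not None:
        table = pd.read_csv(subsystem_tsv, sep="\t")
        lookup = dict(zip(table["reaction_id"], table["subsystem"]))
        for rxn in model.reactions:
            if rxn.id in lookup:
                rxn.subsystem = str(lookup[rxn.id])
    if not any(r.gene_reaction_rule for r in model.reactions):
        logger.warning("model %s has no GPR rules; enzyme constraints will be empty", model.id)
    if biomass_reaction is not None and biomass_reaction not in model.reactions:
        raise ValueError(f"biomass reaction {biomass_reaction!r} not found in model")
    return model


def write_sbml(model: cobra.Model, path: str | Path) -> None:
    """Write an SBML L3/fbc file, emitting subsystems as SBML groups."""
    model = model.copy()
    existing = {g.id for g in model.groups}
    by_subsystem: dict[str, list[cobra.Reaction]] = {}
    for rxn in model.reactions:
        if rxn.subsystem:
            by_subsystem.setdefault(rxn.subsystem, []).append(rxn)
    for i, (name, members) in enumerate(sorted(by_subsystem.items())):
        gid = f"g{i + 1}"
        if gid in existing:
            continue
        group = cobra.core.Group(gid, name=name, kind="partonomy")
        # Group stores members as a set, which would serialize in arbitrary
        # order; substitute an id-sorted list so output is reproducible
        group._members = sorted(members, key=lambda r: r.id)
        model.add_groups([group])
    cobra.io.write_sbml_model(model, str(path))


# ---------------------------------------------------------------------------
# Exchanges, sinks, medium
# ---------------------------------------------------------------------------


def is_sink(reaction: cobra.Reaction) -> bool:
    return reaction.id.startswith(SINK_PREFIXES)


def exchange_reactions(model: cobra.Model) -> list[cobra.Reaction]:
    """Boundary reactions that cross the model boundary, excluding sinks."""
    return [r for r in model.reactions if r.boundary and not is_sink(r)]


def sink_reactions(model: cobra.Model) -> list[cobra.Reaction]:
    return [r for r in model.reactions if r.boundary and is_sink(r)]


#: a medium is a plain mapping: exchange metabolite (or reaction) id -> max uptake
MediumDefinition = Mapping[str, float]


def read_medium_tsv(path: str | Path) -> dict[str, float]:
    table = pd.read_csv(path, sep="\t")
    return {str(k): float(v) for k, v in zip(table["metabolite_id"], table["max_uptake"])}


def _resolve_medium_key(model: cobra.Model, key: str) -> cobra.Reaction | None:
    if key in model.reactions:
        rxn = model.reactions.get_by_id(key)
        return rxn if rxn.boundary else None
    for rxn in exchange_reactions(model):
        mets = list(rxn.metabolites)
        if len(mets) == 1 and mets[0].id == key:
            return rxn
    return None


def apply_medium(model: cobra.Model, medium: MediumDefinition) -> cobra.Model:
    """Return a copy with uptake bounds set from a medium definition.

    Listed components have their uptake bound (negative lower bound of the
    exchange) set to the given value; every other exchange has uptake closed.
    The secretion direction is left open, and sink reactions are untouched.
    """
    bad = [k for k, v in medium.items() if v < 0]
    if bad:
        raise ValueError(f"negative uptake fluxes for {bad}")
    out = model.copy()
    resolved: dict[cobra.Reaction, float] = {}
    missing: list[str] = []
    for key, value in medium.items():
        rxn = _resolve_medium_key(out, key)
        if rxn is None:
            missing.append(key)
        else:
            resolved[rxn] = float(value)
    if missing:
        raise ValueError(f"medium components not resolvable to exchange reactions: {missing}")
    for rxn in exchange_reactions(out):
        rxn.lower_bound = 0.0
    for rxn, value in resolved.items():
        rxn.lower_bound = -value
    return out


# ---------------------------------------------------------------------------
# Reversibility splitting
# ---------------------------------------------------------------------------


@dataclass
class SplitModel:
    """An irreversible model plus the forward/reverse id mapping.

    ``pairs`` maps each original reaction id to ``(forward_id, reverse_id)``;
    ``reverse_id`` is ``None`` for reactions that were already irreversible.
    """

    model: cobra.Model
    pairs: dict[str, tuple[str, str | None]] = field(default_factory=dict)


def split_reversible(model: cobra.Model) -> SplitModel:
    """Split every reversible reaction into forward and reverse copies.

    A reaction with bounds ``[lb, ub]`` and ``lb < 0`` is replaced by a
    forward copy ``[0, max(ub, 0)]`` and a reverse copy ``[max(-ub, 0),
    -lb]`` with negated stoichiometry.  GPR, EC annotation and subsystem are
    copied to both halves.  Already-irreversible models pass unchanged.
    """
    out = model.copy()
    pairs: dict[str, tuple[str, str | None]] = {}
    new_reactions: list[cobra.Reaction] = []
    for rxn in out.reactions:
        if rxn.lower_bound >= 0:
            pairs[rxn.id] = (rxn.id, None)
            continue
        rev = cobra.Reaction(
            rxn.id + "_rev",
            name=(rxn.name or rxn.id) + " (reverse)",
            lower_bound=max(-rxn.upper_bound, 0.0),
            upper_bound=-rxn.lower_bound,
        )
        rev.add_metabolites({m: -c for m, c in rxn.metabolites.items()})
        rev.subsystem = rxn.subsystem
        rev.annotation = dict(rxn.annotation)
        new_reactions.append((rev, rxn.gene_reaction_rule))
        pairs[rxn.id] = (rxn.id, rev.id)
        rxn.bounds = (0.0, max(rxn.upper_bound, 0.0))
    for rev, rule in new_reactions:
        out.add_reactions([rev])
        rev.gene_reaction_rule = rule
    return SplitModel(model=out, pairs=pairs)


def merge_irreversible_fluxes(
    split: SplitModel | Mapping[str, tuple[str, str | None]],
    fluxes: Mapping[str, float],
) -> pd.Series:
    """Net fluxes on the original reactions: forward minus reverse."""
    pairs = split.pairs if isinstance(split, SplitModel) else split
    net: dict[str, float] = {}
    for orig, (fwd, rev) in pairs.items():
        if fwd not in fluxes:
            raise KeyError(f"flux vector is missing split member {fwd!r}")
        value = float(fluxes[fwd])
        if rev is not None:
            if rev not in fluxes:
                raise KeyError(f"flux vector is missing split member {rev!r}")
            value -= float(fluxes[rev])
        net[orig] = value
    return pd.Series(net, dtype=float)


# ---------------------------------------------------------------------------
# Validation and summaries
# ---------------------------------------------------------------------------


def stoichiometric_matrix(model: cobra.Model):
    """Sparse stoichiometric matrix S (metabolites x reactions)."""
    return create_stoichiometric_matrix(model, array_type="lil").tocsr()


def validate_model(model: cobra.Model, biomass_reaction: str | None = None) -> list[str]:
    """Structural checks; returns a list of human-readable issues (empty = OK)."""
    issues: list[str] = []
    compartments = set(model.compartments)
    for met in model.metabolites:
        if met.compartment not in compartments:
            issues.append(f"metabolite {met.id} in undeclared compartment {met.compartment!r}")
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            issues.append(f"reaction {rxn.id} has lower_bound > upper_bound")
        if not rxn.metabolites and not rxn.boundary:
            issues.append(f"reaction {rxn.id} has empty stoichiometry")
        rule = rxn.gene_reaction_rule
        if rule:
            try:
                expr = parse_gpr(rule)
            except GPRParseError as err:
                issues.append(f"reaction {rxn.id}: unparsable GPR ({err})")
                continue
            unknown = gpr_genes(expr) - {g.id for g in model.genes}
            if unknown:
                issues.append(f"reaction {rxn.id}: GPR genes not in model: {sorted(unknown)}")
    if biomass_reaction is not None and biomass_reaction not in model.reactions:
        issues.append(f"biomass reaction {biomass_reaction!r} missing")
    return issues


def summarize_model(model: cobra.Model) -> dict:
    n_gpr = sum(1 for r in model.reactions if r.gene_reaction_rule)
    return {
        "reactions": len(model.reactions),
        "metabolites": len(model.metabolites),
        "genes": len(model.genes),
        "compartments": len(model.compartments),
        "exchanges": len(exchange_reactions(model)),
        "sinks": len(sink_reactions(model)),
        "gpr_coverage": n_gpr / len(model.reactions) if model.reactions else 0.0,
        "subsystems": sorted({r.subsystem for r in model.reactions if r.subsystem}),
    }
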