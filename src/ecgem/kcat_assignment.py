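"""Turnover-number (kcat) assignment from an EC-indexed parameter table.

Every enzymatic (GPR-bearing) reaction receives a turnover number by a
cascade of rules: collect all records matching any of the reaction's full
EC numbers; filter to substrate matches and then to fungal-lineage records,
each filter applied only when it leaves candidates; if no full-EC match
exists, retry with the EC pruned one level at a time (4 -> 3 -> 2 -> 1);
assign the *maximum* surviving value.  Reactions with a GPR but no match at
any level fall back to the median of all matched values.  Values are stored
in s^-1 in the table and converted to h^-1 (x 3600) on assignment.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import cobra
import pandas as pd

from .model_core import gpr_of, reaction_ec_numbers

SECONDS_PER_HOUR = 3600.0
#: lineage tag that identifies records measured on fungal enzymes
FUNGAL_TAG = "fungi"

_EC_PATTERN = re.compile(r"^\d+(\.(\d+|-)){0,3}$")

__all__ = [
    "KcatMatch",
    "KcatAssignment",
    "read_kcat_table",
    "validate_kcat_table",
    "match_kcat",
    "assign_kcats",
]


@dataclass(frozen=True)
class KcatMatch:
    """A resolved turnover number with its provenance.

    ``provenance`` is ``full-match``, ``pruned-level-{3,2,1}`` or
    ``median-fallback``.
    """

    value_per_s: float
    provenance: str


@dataclass
class KcatAssignment:
    """Per-reaction turnover numbers in h^-1 with provenance labels."""

    values: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    median_per_s: float = float("nan")

    @property
    def median_per_h(self) -> float:
        return self.median_per_s * SECONDS_PER_HOUR


def read_kcat_table(path: str | Path) -> pd.DataFrame:
    """Read a kcat TSV with columns ``ec, substrate, lineage, value_per_s``."""
    table = pd.read_csv(path, sep="\t", dtype={"ec": str, "substrate": str, "lineage": str})
    validate_kcat_table(table)
    return table


def validate_kcat_table(table: pd.DataFrame) -> None:
    required = {"ec", "substrate", "lineage", "value_per_s"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"kcat table is missing columns {sorted(missing)}")
    if (table["value_per_s"] <= 0).any():
        bad = table.loc[table["value_per_s"] <= 0, "ec"].tolist()
        raise ValueError(f"non-positive kcat values for EC {bad}")
    for ec in table["ec"].astype(str):
        if not _EC_PATTERN.match(ec):
            raise ValueError(f"malformed EC number {ec!r}")


def _ec_fields(ec: str) -> list[str]:
    return [f for f in str(ec).split(".") if f and f != "-"]


def _prefix_match(record_ec: str, query_ec: str, level: int) -> bool:
    rec, query = _ec_fields(record_ec), _ec_fields(query_ec)
    if len(rec) < level or len(query) < level:
        return False
    return rec[:level] == query[:level]


def _is_fungal(lineage: object) -> bool:
    if lineage is None or (isinstance(lineage, float) and pd.isna(lineage)):
        return False
    tags = re.split(r"[;,]", str(lineage))
    return any(t.strip().lower() == FUNGAL_TAG for t in tags)


def match_kcat(
    ecs: Sequence[str],
    substrates: Iterable[str],
    table: pd.DataFrame,
) -> KcatMatch | None:
    """Resolve a turnover number for a reaction's EC numbers.

    Returns ``None`` when no record matches at any pruning level (distinct
    from an error); the caller decides on the median fallback.
    """
    if not ecs:
        raise ValueError("at least one EC number is required")
    validate_kcat_table(table)
    substrate_set = {str(s).lower() for s in substrates}
    record_ecs = table["ec"].astype(str)
    for level in (4, 3, 2, 1):
        mask = pd.Series(False, index=table.index)
        for query in ecs:
            mask |= record_ecs.map(lambda rec: _prefix_match(rec, query, level))
        candidates = table[mask]
        if candidates.empty:
            continue
        # each filter is applied only when it does not empty the candidate set
        if substrate_set:
            by_substrate = candidates[
                candidates["substrate"].astype(str).str.lower().isin(substrate_set)
            ]
            if not by_substrate.empty:
                candidates = by_substrate
        fungal = candidates[candidates["lineage"].map(_is_fungal)]
        if not fungal.empty:
            candidates = fungal
        value = float(candidates["value_per_s"].max())
        provenance = "full-match" if level == 4 else f"pruned-level-{level}"
        return KcatMatch(value, provenance)
    return None


def _reaction_substrates(reaction: cobra.Reaction) -> list[str]:
    names = []
    for met, coeff in reaction.metabolites.items():
        if coeff < 0:
            names.append(met.name or met.id)
    return names


def assign_kcats(
    model: cobra.Model, table: pd.DataFrame, reverse_suffix: str = "_rev"
) -> KcatAssignment:
    """Assign a turnover number (h^-1) to every GPR-bearing reaction.

    Reactions without a GPR (exchanges, sinks, biomass, spontaneous
    reactions) are never enzyme-constrained and are absent from the result.
    The median fallback is computed over the matched values only; a model
    in which no reaction matches at all is an error (undefined median).

    Turnover numbers are not direction-specific: the reverse copy of a
    split reversible reaction (id ``<base><reverse_suffix>``) inherits the
    forward copy's value instead of being matched on its own substrates,
    and does not contribute a duplicate value to the median.
    """
    validate_kcat_table(table)
    matched: dict[str, KcatMatch] = {}
    unmatched: list[str] = []
    reverse_of: dict[str, str] = {}
    for rxn in model.reactions:
        if gpr_of(rxn) is None:
            continue
        base = rxn.id[: -len(reverse_suffix)] if rxn.id.endswith(reverse_suffix) else None
        if base is not None and base in model.reactions:
            reverse_of[rxn.id] = base
            continue
        ecs = reaction_ec_numbers(rxn)
        match = match_kcat(ecs, _reaction_substrates(rxn), table) if ecs else None
        if match is None:
            unmatched.append(rxn.id)
        else:
            matched[rxn.id] = match
    if not matched:
        raise ValueError("no reaction matched any kcat record; median fallback undefined")
    median_s = float(statistics.median(m.value_per_s for m in matched.values()))
    assignment = KcatAssignment(median_per_s=median_s)
    for rxn_id, match in matched.items():
        assignment.values[rxn_id] = match.value_per_s * SECONDS_PER_HOUR
        assignment.provenance[rxn_id] = match.provenance
    for rxn_id in unmatched:
        assignment.values[rxn_id] = median_s * SECONDS_PER_HOUR
        assignment.provenance[rxn_id] = "median-fallback"
    for rev_id, base_id in reverse_of.items():
        if base_id in assignment.values:
            assignment.values[rev_id] = assignment.values[base_id]
            assignment.provenance[rev_id] = assignment.provenance[base_id]
    return assignment
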